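"""Deposition-fraction metrics, impaction-parameter curves and histograms.

Number and mass deposition fractions:

    nDF = (n_Stick + n_Scape * ICRP_correction) / n_Total
    mDF = (m_Stick + m_Scape) / m_Total            (printed convention)

where "Scape" counts particles escaping through the distal outlets into
the unmodeled bronchiolar/alveolar generations and the ICRP correction
is the fraction of those credited as deposited there.  The printed mDF
form counts all escaped mass as deposited; exhaled mass is tracked
separately and excluded from the numerator (the only reading consistent
with sub-unity tabulated mDF values).  A symmetric ICRP-corrected mass
convention is available via :class:`MetricsConfig`.

Regional (left/right lobe) fractions normalize lobar stuck amounts by
the lobar total, so the pair always sums to 1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import BreathingPattern, SteadyFlow

__all__ = [
    "DepositionTally",
    "MetricsConfig",
    "tally_from_records",
    "ndf",
    "mdf",
    "regional_fractions",
    "impaction_parameter",
    "impaction_curve",
    "size_histogram",
    "load_printed_deposition_table",
    "mdf_spread",
    "max_lobar_difference",
]


@dataclass
class DepositionTally:
    """Counts and masses by particle fate, plus lobar/per-group splits."""

    n_stick: int
    n_escaped: int
    n_exhaled: int
    n_total: int
    m_stick: float
    m_escaped: float
    m_exhaled: float
    m_total: float
    n_stick_left: int = 0
    n_stick_right: int = 0
    m_stick_left: float = 0.0
    m_stick_right: float = 0.0
    per_segment_stick: dict = field(default_factory=dict)
    per_generation_stick: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_stick, self.n_escaped, self.n_exhaled, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_stick + self.n_escaped + self.n_exhaled > self.n_total:
            raise ValueError("fates exceed the injected total")

    @property
    def n_airborne(self) -> int:
        return self.n_total - self.n_stick - self.n_escaped - self.n_exhaled


@dataclass(frozen=True)
class MetricsConfig:
    """Required, explicit metric settings.

    ``icrp_correction`` (fraction of escaped particles credited as
    deposited distally) has no defensible default and must be supplied.
    ``mass_convention`` is 'printed' (escaped mass fully credited) or
    'icrp' (escaped mass weighted by the same correction as the number
    fraction).  Histogram defaults: 19 equal bins on [0, 10] um.
    """

    icrp_correction: float
    mass_convention: str = "printed"
    histogram_bins: int = 19
    histogram_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if self.icrp_correction is None or not 0.0 <= self.icrp_correction <= 1.0:
            raise ValueError("icrp_correction must be given explicitly in [0, 1]")
        if self.mass_convention not in ("printed", "icrp"):
            raise ValueError("mass_convention must be 'printed' or 'icrp'")


def tally_from_records(records: pd.DataFrame, tree=None) -> DepositionTally:
    """Build a tally from per-particle track records.

    ``records`` needs columns d_p [um], rho_p, status and (for lobar
    splits) lobe; generation splits additionally need ``tree``.
    """
    d_m = records["d_p"].to_numpy() * 1e-6
    mass = math.pi / 6.0 * d_m**3 * records["rho_p"].to_numpy()
    status = records["status"].to_numpy()
    stuck = status == "stuck"
    escaped = status == "escaped"
    exhaled = status == "exhaled"
    lobe = records["lobe"].fillna("").to_numpy() if "lobe" in records else np.full(len(records), "")
    left = stuck & (lobe == "left")
    right = stuck & (lobe == "right")

    per_seg: dict = {}
    per_gen: dict = {}
    if "segment_id" in records:
        seg_ids = records["segment_id"].to_numpy()
        for sid in np.unique(seg_ids[stuck]):
            per_seg[int(sid)] = int(np.sum(stuck & (seg_ids == sid)))
        if tree is not None:
            for sid, cnt in per_seg.items():
                gen = tree.segment(sid).generation
                per_gen[gen] = per_gen.get(gen, 0) + cnt

    return DepositionTally(
        n_stick=int(stuck.sum()), n_escaped=int(escaped.sum()),
        n_exhaled=int(exhaled.sum()), n_total=len(records),
        m_stick=float(mass[stuck].sum()), m_escaped=float(mass[escaped].sum()),
        m_exhaled=float(mass[exhaled].sum()), m_total=float(mass.sum()),
        n_stick_left=int(left.sum()), n_stick_right=int(right.sum()),
        m_stick_left=float(mass[left].sum()), m_stick_right=float(mass[right].sum()),
        per_segment_stick=per_seg, per_generation_stick=per_gen,
    )


def ndf(tally: DepositionTally, config: MetricsConfig) -> float:
    """Number deposition fraction with the ICRP escape credit."""
    if tally.n_total <= 0:
        raise ValueError("n_total must be > 0")
    val = (tally.n_stick + tally.n_escaped * config.icrp_correction) / tally.n_total
    return float(val)


def mdf(tally: DepositionTally, config: MetricsConfig) -> float:
    """Mass deposition fraction (convention per config)."""
    if tally.m_total <= 0:
        raise ValueError("m_total must be > 0")
    credit = 1.0 if config.mass_convention == "printed" else config.icrp_correction
    return float((tally.m_stick + tally.m_escaped * credit) / tally.m_total)


def regional_fractions(tally: DepositionTally) -> tuple[float, float, float, float]:
    """(mDF_L, mDF_R, nDF_L, nDF_R): lobar stuck amounts over lobar totals.

    Each left/right pair sums to 1 exactly.
    """
    m_tot = tally.m_stick_left + tally.m_stick_right
    n_tot = tally.n_stick_left + tally.n_stick_right
    if m_tot <= 0 or n_tot <= 0:
        raise ValueError("no lobar deposition: regional fractions undefined")
    return (tally.m_stick_left / m_tot, tally.m_stick_right / m_tot,
            tally.n_stick_left / n_tot, tally.n_stick_right / n_tot)


def impaction_parameter(d_p_um, q_lpm) -> np.ndarray | float:
    """d_p^2 Q in um^2 L/min (d_p in um, Q in L/min)."""
    out = np.asarray(d_p_um, float) ** 2 * np.asarray(q_lpm, float)
    return float(out) if out.ndim == 0 else out


def impaction_curve(d_p_um, efficiency, flow,
                    exclude_below: float = 0.1) -> pd.DataFrame:
    """Deposition-efficiency curve vs the impaction parameter d_p^2 Q.

    ``flow`` is a scalar Q in L/min, a BreathingPattern (Q taken as the
    mean inhalation flow, (2/pi) Qmax) or a SteadyFlow.  Points with
    d_p^2 Q < ``exclude_below`` um^2 L/min are excluded (the boundary
    value itself is retained); the result is sorted by the parameter.
    """
    d_p_um = np.asarray(d_p_um, float)
    efficiency = np.asarray(efficiency, float)
    if d_p_um.shape != efficiency.shape:
        raise ValueError("d_p and efficiency must align")
    if isinstance(flow, (BreathingPattern, SteadyFlow)):
        q_lpm = flow.mean_inhalation_rate_lpm
    else:
        q_lpm = float(flow)
        if q_lpm <= 0:
            raise ValueError("Q must be > 0 L/min (units: d_p in um, Q in L/min)")
    param = impaction_parameter(d_p_um, q_lpm)
    # keep the boundary value itself despite float rounding of d_p^2 Q
    keep = param >= exclude_below * (1.0 - 1e-9)
    df = pd.DataFrame({"impaction_parameter": param[keep],
                       "d_p_um": d_p_um[keep],
                       "q_lpm": q_lpm,
                       "efficiency": efficiency[keep]})
    return df.sort_values("impaction_parameter", ignore_index=True)


def size_histogram(diameters_um, config: MetricsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Normalized diameter histogram of an airborne snapshot.

    Equal-width bins (default 19 on [0, 10] um); densities integrate
    to 1 over the in-range mass.  Returns (density, bin_edges).
    """
    diameters_um = np.asarray(diameters_um, float)
    lo, hi = config.histogram_range
    in_range = diameters_um[(diameters_um >= lo) & (diameters_um <= hi)]
    if in_range.size == 0:
        raise ValueError("empty snapshot: histogram undefined")
    density, edges = np.histogram(in_range, bins=config.histogram_bins,
                                  range=config.histogram_range, density=True)
    return density, edges


# Printed per-geometry deposition fractions (percent) for the eight
# phenotype representatives; a reference input table for aggregate
# consistency checks, not something this package recomputes.
PRINTED_DEPOSITION_TABLE_CSV = """\
geometry,mdf,ndf,mdf_l,mdf_r,ndf_l,ndf_r
mb,85.30,23.10,23.50,76.50,40.20,59.80
mm,62.70,40.50,42.50,57.50,41.10,58.90
ms,52.40,30.80,14.20,85.80,33.90,66.10
bb,48.00,44.90,24.40,75.60,49.80,50.20
bm,81.50,40.90,81.30,18.70,50.20,49.80
bs,57.00,46.20,62.20,37.80,59.20,40.80
sb,57.90,39.30,37.40,62.20,29.10,70.90
sm,62.00,26.10,34.60,65.40,46.00,54.00
"""


def load_printed_deposition_table(rounding_tol_pp: float = 0.6) -> pd.DataFrame:
    """Parse the printed per-geometry deposition table (values in %).

    Verifies that each lobar pair sums to 100% within the printed
    rounding tolerance (percentage points).
    """
    df = pd.read_csv(io.StringIO(PRINTED_DEPOSITION_TABLE_CSV))
    for a, b in (("mdf_l", "mdf_r"), ("ndf_l", "ndf_r")):
        bad = (df[a] + df[b] - 100.0).abs() > rounding_tol_pp
        if bad.any():
            raise ValueError(f"rows {df.loc[bad, 'geometry'].tolist()}: "
                             f"{a}+{b} deviates from 100% beyond rounding")
    return df


def mdf_spread(table: pd.DataFrame) -> float:
    """max - min of the mDF column, percentage points."""
    return float(table["mdf"].max() - table["mdf"].min())


def max_lobar_difference(table: pd.DataFrame, which: str = "mdf") -> float:
    """Largest |left - right| lobar difference, percentage points."""
    return float((table[f"{which}_l"] - table[f"{which}_r"]).abs().max())
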