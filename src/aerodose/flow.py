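"""Reduced-order carrier airflow.

The 3-D turbulence-resolving flow solution is replaced by quasi-steady
per-segment pipe flow: the instantaneous inlet flow Q(t) (a sinusoidal
breathing waveform or a steady rate) is distributed through the tree by
Poiseuille conductance (d^4/L of the downstream subtrees) and converted
to an axial velocity profile (parabolic by default) in each segment.
The particle tracker only queries fluid velocity at points, so a
CFD-sampled field could be substituted without touching the tracker.

The transitional-turbulence inlet boundary-condition calculators
(turbulent kinetic energy k, specific dissipation rate omega, turbulence
intensity Tu, intermittency gamma and the transition momentum-thickness
Reynolds number Re_theta) are provided for parity with a full RANS
k-omega SST setup; their outputs do not feed the reduced-order flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AirwayTree

LPM_TO_M3S = 1e-3 / 60.0  # L/min -> m^3/s

__all__ = [
    "BreathingPattern",
    "SteadyFlow",
    "AirProperties",
    "TurbulenceBC",
    "SegmentFlow",
    "breathing_waveform",
    "flow_fractions",
    "distribute_flow",
    "local_velocity",
    "inlet_turbulence_bc",
    "transition_re_theta",
]


@dataclass(frozen=True)
class BreathingPattern:
    """Sinusoidal breathing waveform Q(t) = Qmax sin(2 pi t / T).

    ``qmax_lpm`` in L/min, period ``period_s`` in seconds.  Positive Q is
    inhalation, on t in [0, T/2]; negative Q is exhalation.  Defaults are
    heavy-exercise conditions (90 L/min peak, 2 s cycle).
    """

    qmax_lpm: float = 90.0
    period_s: float = 2.0

    def __post_init__(self) -> None:
        if self.qmax_lpm <= 0 or self.period_s <= 0:
            raise ValueError("Qmax and T must be > 0")

    def rate(self, t: float) -> float:
        """Volumetric flow in m^3/s at time t >= 0."""
        return self.qmax_lpm * LPM_TO_M3S * math.sin(2.0 * math.pi * t / self.period_s)

    @property
    def mean_inhalation_rate_lpm(self) -> float:
        """Mean of Q over one inhalation half-cycle: (2/pi) Qmax, L/min."""
        return 2.0 / math.pi * self.qmax_lpm


@dataclass(frozen=True)
class SteadyFlow:
    """Constant inspiratory flow (L/min)."""

    q_lpm: float = 90.0

    def rate(self, t: float) -> float:
        return self.q_lpm * LPM_TO_M3S

    @property
    def mean_inhalation_rate_lpm(self) -> float:
        return self.q_lpm


def breathing_waveform(t: float | np.ndarray, pattern: BreathingPattern) -> float | np.ndarray:
    """Q(t) in m^3/s; vectorized over t."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = pattern.qmax_lpm * LPM_TO_M3S * np.sin(2.0 * np.pi * t / pattern.period_s)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AirProperties:
    """Carrier-air properties (SI).  Defaults: 1.177 kg/m^3 at 300 K."""

    density: float = 1.177  # kg/m^3
    temperature: float = 300.0  # K
    viscosity: float = 1.85e-5  # Pa s (dynamic, ~300 K)
    k_b: float = 1.380649e-23  # J/K

    def __post_init__(self) -> None:
        if min(self.density, self.temperature, self.viscosity, self.k_b) <= 0:
            raise ValueError("air properties must be positive")


@dataclass(frozen=True)
class TurbulenceBC:
    """Inlet turbulence quantities for a transitional k-omega SST setup."""

    k: float  # turbulent kinetic energy, m^2/s^2
    omega: float  # specific dissipation rate, 1/s
    intensity: float  # turbulence intensity I (fraction)
    u_ref: float  # reference (peak inhalation) speed, m/s
    length_scale: float  # m (hydraulic diameter of the inlet)
    tu_percent: float  # Tu = 100 sqrt(2k/3)/|u_ref|
    gamma: float  # intermittency (1 at the inlet)
    re_theta: float  # transition momentum-thickness Reynolds number
    c_mu: float = 0.09


def inlet_turbulence_bc(u_ref: float, intensity: float = 0.04,
                        length_scale: float | None = None,
                        air: AirProperties = AirProperties(),
                        c_mu: float = 0.09) -> TurbulenceBC:
    """Inlet k, omega, Tu, gamma, Re_theta from isotropic-turbulence formulas.

    k = (3/2)(I |u_ref|)^2;  omega = sqrt(k)/(C_mu^0.25 L);
    Tu = 100 sqrt(2k/3)/|u_ref| (= 100 I);  gamma = 1 at the inlet.
    ``length_scale`` is the inlet hydraulic diameter in metres.
    """
    if u_ref <= 0:
        raise ValueError("u_ref must be > 0")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if length_scale is None or length_scale <= 0:
        raise ValueError("length_scale (inlet hydraulic diameter, m) must be > 0")
    k = 1.5 * (intensity * u_ref) ** 2
    omega = math.sqrt(k) / (c_mu**0.25 * length_scale)
    tu = 100.0 * math.sqrt(2.0 / 3.0 * k) / u_ref
    re_theta = transition_re_theta(tu) if tu > 0 else float("nan")
    return TurbulenceBC(k=k, omega=omega, intensity=intensity, u_ref=u_ref,
                        length_scale=length_scale, tu_percent=tu, gamma=1.0,
                        re_theta=re_theta, c_mu=c_mu)


def transition_re_theta(tu: float) -> float:
    """Transition momentum-thickness Reynolds number vs Tu (percent).

    Piecewise correlation with the branch boundary at Tu = 1.3 (the
    low-Tu branch is used at equality):

        Tu <= 1.3:  1173.51 - 589.428 Tu + 0.2196 / Tu^2
        Tu >  1.3:  331.5 / (Tu - 0.5658)^0.671
    """
    if tu <= 0:
        raise ValueError("Tu must be > 0")
    if tu <= 1.3:
        return 1173.51 - 589.428 * tu + 0.2196 / tu**2
    return 331.5 / (tu - 0.5658) ** 0.671


@dataclass
class SegmentFlow:
    """Per-segment volumetric flows for a given instantaneous inlet flow.

    ``fractions`` maps segment id -> fraction of the inlet flow carried;
    they are static (conductance-based) while ``flows`` (m^3/s), mean
    axial velocities (m/s) and profile kind refer to one instant.
    Positive flow points proximal -> distal (inhalation).
    """

    fractions: dict[int, float]
    flows: dict[int, float]
    mean_velocity: dict[int, float]
    profile: str = "parabolic"

    def __post_init__(self) -> None:
        if self.profile not in ("parabolic", "plug"):
            raise ValueError("profile must be 'parabolic' or 'plug'")


def flow_fractions(tree: AirwayTree) -> dict[int, float]:
    """Fraction of inlet flow through each segment, by Poiseuille conductance.

    Subtree resistance: R = L/d^4 of the segment plus the parallel
    combination of its children's subtree resistances.  Junction splits
    are proportional to downstream subtree conductance; conservation at
    every junction is exact by construction.
    """
    res: dict[int, float] = {}

    def subtree_resistance(seg_id: int) -> float:
        if seg_id in res:
            return res[seg_id]
        s = tree.segment(seg_id)
        if s.diameter <= 0:
            raise ValueError(f"segment {seg_id}: zero diameter")
        r = s.length / s.diameter**4
        kids = tree.children(seg_id)
        if kids:
            inv = sum(1.0 / subtree_resistance(k.id) for k in kids)
            r += 1.0 / inv
        res[seg_id] = r
        return r

    fractions = {tree.root.id: 1.0}
    stack = [tree.root]
    while stack:
        s = stack.pop()
        kids = tree.children(s.id)
        if not kids:
            continue
        conds = np.array([1.0 / subtree_resistance(k.id) for k in kids])
        shares = conds / conds.sum()
        for k, share in zip(kids, shares):
            fractions[k.id] = fractions[s.id] * float(share)
            stack.append(k)
    return fractions


def distribute_flow(tree: AirwayTree, q_total: float,
                    profile: str = "parabolic") -> SegmentFlow:
    """Distribute an instantaneous inlet flow (m^3/s) through the tree."""
    if not math.isfinite(q_total):
        raise ValueError("q_total must be finite")
    fr = flow_fractions(tree)
    flows = {sid: q_total * f for sid, f in fr.items()}
    mean_v = {}
    for s in tree.segments:
        area_m2 = math.pi * (s.radius * 1e-3) ** 2
        mean_v[s.id] = flows[s.id] / area_m2
    return SegmentFlow(fractions=fr, flows=flows, mean_velocity=mean_v, profile=profile)


def local_velocity(segment, r: float, seg_flow: SegmentFlow) -> np.ndarray:
    """Fluid velocity vector (m/s) at radial offset r (m) in a segment.

    Parabolic: u = 2 U (1 - (r/R)^2) along the axis; plug: u = U.  The
    cross-section integral of either profile equals the segment flow.
    """
    radius_m = segment.radius * 1e-3
    if r < 0 or r > radius_m:
        raise ValueError("radial offset outside the lumen (particle should have deposited)")
    u_mean = seg_flow.mean_velocity[segment.id]
    if seg_flow.profile == "parabolic":
        mag = 2.0 * u_mean * (1.0 - (r / radius_m) ** 2)
    else:
        mag = u_mean
    return mag * segment.axis
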