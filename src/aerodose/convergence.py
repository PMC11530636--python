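"""Grid-convergence toolkit (observed order, GCI, asymptotic check).

Generic Richardson-extrapolation-based verification for any scalar
functional f sampled at decreasing element base sizes h, following the
NPARC-style protocol: refinement ratios between 1.25 and 2, observed
order of convergence from a least-squares fit (or the three-grid closed
form), the Grid Convergence Index with a safety factor, and the
asymptotic-range ratio.  No CFD lives here: the functionals come from
manufactured data or from the tracker's own sub-step convergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MeshStudy", "OscillatoryConvergenceError", "fit_order", "gci",
           "asymptotic_ratio"]


class OscillatoryConvergenceError(RuntimeError):
    """Non-monotone grid-to-grid differences: no order can be reported."""


@dataclass
class MeshStudy:
    """Grid-refinement samples: (h, f) pairs with h strictly decreasing.

    ``safety_factor`` defaults to 1.25 (three or more grids).  Ratios
    outside [1.25, 2] trigger a warning per the verification protocol,
    not an error.
    """

    h: np.ndarray
    f: np.ndarray
    safety_factor: float = 1.25

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, float)
        self.f = np.asarray(self.f, float)
        if self.h.shape != self.f.shape or self.h.ndim != 1:
            raise ValueError("h and f must be matching 1-D arrays")
        if len(self.h) < 3:
            raise ValueError("need at least 3 grids to fit an order")
        if not np.all(np.diff(self.h) < 0):
            raise ValueError("h must be strictly decreasing (coarse to fine)")
        r = self.refinement_ratios
        if np.any((r < 1.25 - 1e-12) | (r > 2.0 + 1e-12)):
            warnings.warn("refinement ratio outside [1.25, 2]", stacklevel=2)

    @property
    def refinement_ratios(self) -> np.ndarray:
        return self.h[:-1] / self.h[1:]


def fit_order(study: MeshStudy, method: str = "auto") -> float:
    """Observed order of convergence p.

    ``auto``: the three-grid closed form
    p = ln((f3-f2)/(f2-f1)) / ln r when exactly three grids share a
    common ratio, otherwise a joint least-squares fit of
    f(h) = f_exact + C h^p over (f_exact, C, p).  Oscillatory
    (sign-changing) grid-to-grid differences raise
    OscillatoryConvergenceError.
    """
    diffs = np.diff(study.f)
    signs = np.sign(diffs[diffs != 0.0])
    if len(signs) and not (np.all(signs > 0) or np.all(signs < 0)):
        raise OscillatoryConvergenceError(
            "oscillatory convergence: grid-to-grid differences change sign")

    r = study.refinement_ratios
    three_grid = len(study.h) == 3 and np.allclose(r, r[0], rtol=1e-9)
    if method == "closed_form" or (method == "auto" and three_grid):
        if len(study.h) != 3:
            raise ValueError("closed-form order needs exactly 3 grids")
        f_coarse, f_mid, f_fine = study.f  # h decreasing: coarse first
        num = f_coarse - f_mid
        den = f_mid - f_fine
        if den == 0 or num / den <= 0:
            raise OscillatoryConvergenceError("degenerate differences; no order")
        return float(math.log(num / den) / math.log(r[0]))

    # joint fit of (f_exact, C, p); initialized from the closed form on
    # the finest triple when possible
    h, f = study.h, study.f
    p0 = 2.0
    try:
        tail = MeshStudy(h[-3:], f[-3:], study.safety_factor)
        p0 = fit_order(tail, method="closed_form")
    except Exception:
        pass
    c0 = (f[0] - f[-1]) / (h[0] ** p0 - h[-1] ** p0)
    x0 = np.array([f[-1] - c0 * h[-1] ** p0, c0, p0])

    def resid(x):
        f_ex, c, p = x
        return f_ex + c * np.power(h, p) - f

    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
    return float(sol.x[2])


def gci(f_fine: float, f_coarse: float, r: float, p: float,
        safety_factor: float = 1.25) -> float:
    """Grid Convergence Index, percent.

    GCI = Fs |(f_coarse - f_fine)/f_fine| / (r^p - 1) * 100.
    """
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if p <= 0:
        raise ValueError("order p must be > 0")
    if f_fine == 0:
        raise ValueError("f_fine must be non-zero (relative error undefined)")
    return float(safety_factor * abs((f_coarse - f_fine) / f_fine) / (r**p - 1.0) * 100.0)


def asymptotic_ratio(gci_23: float, gci_12: float, r: float, p: float) -> float:
    """GCI_23 / (r^p GCI_12); values near 1 indicate the asymptotic range.

    Pair 12 is fine-to-medium, pair 23 medium-to-coarse, computed with a
    common refinement ratio r and observed order p.
    """
    if gci_12 == 0:
        raise ValueError("GCI_12 is zero: ratio undefined")
    return float(gci_23 / (r**p * gci_12))
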