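"""Lagrangian aerosol transport through an airway tree.

Each computational parcel is one physical particle.  The momentum
balance integrates drag (Schiller-Naumann), gravity, Brownian forcing
and, optionally, shear lift and virtual mass:

    m_p dv_p/dt = (1/2) C_d rho A_p |v_s| v_s + m_p g (1 - alpha_p)
                  + f_Brownian + f_lift + f_virtual_mass

with slip velocity v_s = u - v_p, projected area A_p = (pi/4) d_p^2 and
particle mass m_p = (pi/6) d_p^3 rho_p.  Drag is integrated with an
exponential (point-implicit) update that is exact for constant carrier
velocity and unconditionally stable, so the sub-step is set by transit
resolution and Brownian step size, not by the relaxation time
tau_p = rho_p d_p^2 / (18 eta).

Walls are perfectly absorbing ("stick upon contact"); particles crossing
a terminal outlet face escape to the unmodeled distal airways; particles
crossing the inlet face leave as exhaled.  All positions/velocities are
SI (m, m/s); particle diameters are SI internally and reported in um in
the track records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow import AirProperties, BreathingPattern, SteadyFlow, flow_fractions
from .geometry import AirwayTree, LOBE_CENTRAL, LOBE_LEFT, LOBE_RIGHT

STATUS_AIRBORNE = "airborne"
STATUS_STUCK = "stuck"
STATUS_ESCAPED = "escaped"
STATUS_EXHALED = "exhaled"
_STATUS_NAMES = np.array([STATUS_AIRBORNE, STATUS_STUCK, STATUS_ESCAPED, STATUS_EXHALED])

MEAN_FREE_PATH_AIR = 68e-9  # m, for the optional Cunningham correction

__all__ = [
    "ParticleState",
    "ParticleSourceConfig",
    "SimulationConfig",
    "DepositionResult",
    "sample_particle_sizes",
    "drag_coefficient",
    "drag_factor",
    "cunningham_factor",
    "brownian_kick",
    "diffusion_coefficient",
    "advance_particle",
    "simulate_deposition",
    "write_tracks",
    "read_tracks",
]


@dataclass
class ParticleState:
    """One tracked particle (SI units)."""

    position: np.ndarray
    velocity: np.ndarray
    diameter: float  # m
    density: float = 4390.0  # kg/m^3 (solid iodine aerosol)
    status: str = STATUS_AIRBORNE
    segment_id: int | None = None
    lobe: str | None = None
    deposit_time: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.velocity = np.asarray(self.velocity, float)
        if self.diameter <= 0:
            raise ValueError("particle diameter must be > 0")

    @property
    def mass(self) -> float:
        return math.pi / 6.0 * self.diameter**3 * self.density


@dataclass(frozen=True)
class ParticleSourceConfig:
    """Aerosol source-size distribution.

    ``lognormal`` with count-median diameter ``median_um`` and geometric
    standard deviation ``gsd`` (defaults 0.42 um / 3.5, the aerosolized
    radioiodine source term), or ``uniform`` (monodisperse at
    ``median_um``).  ``truncation_um`` optionally clips the support by
    resampling.
    """

    kind: str = "lognormal"
    median_um: float = 0.42
    gsd: float = 3.5
    truncation_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "uniform"):
            raise ValueError("kind must be 'lognormal' or 'uniform'")
        if self.median_um <= 0:
            raise ValueError("median diameter must be > 0")
        if self.kind == "lognormal" and self.gsd <= 1:
            raise ValueError("geometric standard deviation must be > 1")


def sample_particle_sizes(n: int, source: ParticleSourceConfig,
                          seed_or_rng: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n particle diameters in metres; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if source.kind == "uniform":
        d_um = np.full(n, source.median_um)
    else:
        mu, sigma = math.log(source.median_um), math.log(source.gsd)
        d_um = rng.lognormal(mean=mu, sigma=sigma, size=n)
        if source.truncation_um is not None:
            lo, hi = source.truncation_um
            bad = (d_um < lo) | (d_um > hi)
            while bad.any():
                d_um[bad] = rng.lognormal(mean=mu, sigma=sigma, size=int(bad.sum()))
                bad = (d_um < lo) | (d_um > hi)
    return d_um * 1e-6


def drag_coefficient(re_p: float | np.ndarray) -> float | np.ndarray:
    """Schiller-Naumann drag coefficient.

    C_d = (24/Re)(1 + 0.15 Re^0.687) for 0 < Re <= 1000, 0.44 above.
    Diverges as Re -> 0 (Stokes); use :func:`drag_factor` in force
    evaluations, which stays finite.
    """
    re_p = np.asarray(re_p, float)
    if np.any(re_p < 0):
        raise ValueError("Re_p must be >= 0")
    with np.errstate(divide="ignore"):
        cd = np.where(re_p > 1000.0, 0.44,
                      24.0 / re_p * (1.0 + 0.15 * re_p**0.687))
    return float(cd) if cd.ndim == 0 else cd


def drag_factor(re_p: np.ndarray) -> np.ndarray:
    """f = C_d Re_p / 24: the finite Stokes-normalized drag multiplier.

    f -> 1 as Re -> 0, so the drag force (3 pi eta d f v_s) is evaluated
    in a form linear in v_s with no division blow-up.
    """
    re_p = np.asarray(re_p, float)
    return np.where(re_p > 1000.0, 0.44 / 24.0 * re_p,
                    1.0 + 0.15 * np.maximum(re_p, 0.0) ** 0.687)


def cunningham_factor(d_p: np.ndarray, mean_free_path: float = MEAN_FREE_PATH_AIR) -> np.ndarray:
    """Cunningham slip correction Cc = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn))."""
    kn = 2.0 * mean_free_path / np.asarray(d_p, float)
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def friction_coefficient(d_p, air: AirProperties, cunningham: bool = False):
    """Stokes friction gamma_f = 3 pi eta d_p (= 1/mobility), kg/s."""
    gamma = 3.0 * math.pi * air.viscosity * np.asarray(d_p, float)
    if cunningham:
        gamma = gamma / cunningham_factor(d_p)
    return gamma


def diffusion_coefficient(d_p, air: AirProperties, cunningham: bool = False):
    """Stokes-Einstein diffusivity D = k_b T / gamma_f, m^2/s."""
    return air.k_b * air.temperature / friction_coefficient(d_p, air, cunningham)


def brownian_kick(d_p, air: AirProperties, dt: float, rng: np.random.Generator,
                  n: int | None = None, cunningham: bool = False,
                  printed_mobility_form: bool = False) -> np.ndarray:
    """Random Brownian force vector(s) for one sub-step, N.

    Default (fluctuation-dissipation consistent): per-axis amplitude
    sqrt(2 k_b T_o gamma_f / dt) with gamma_f = 3 pi eta d_p = 1/alpha,
    zero mean, so free-particle MSD = 2 D t per axis.  The variant with
    the mobility alpha in the numerator is available behind
    ``printed_mobility_form`` for comparison only (it is dimensionally
    inconsistent).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d_p = np.atleast_1d(np.asarray(d_p, float))
    m = len(d_p) if n is None else n
    gamma = friction_coefficient(d_p, air, cunningham)
    coef = gamma if not printed_mobility_form else 1.0 / gamma
    amp = np.sqrt(2.0 * air.k_b * air.temperature * coef / dt)
    xi = rng.standard_normal((m, 3))
    out = amp[:, None] * xi
    return out[0] if (n is None and out.shape[0] == 1 and np.ndim(d_p) == 1 and d_p.size == 1) else out


@dataclass
class SimulationConfig:
    """Run configuration for the Lagrangian tracker.

    ``flow_dt`` is the carrier-flow update step (0.015-0.025 s range by
    convention); particle sub-steps are chosen automatically as
    min(flow_dt, shortest segment transit / transit_fraction, Brownian
    rms-step cap) -- the exponential drag update is stable at any dt.
    ``injection_window`` defaults to the inhalation half of the second
    breathing cycle (flow only during the first).
    """

    gravity: tuple[float, float, float] = (0.0, 0.0, -9.81)
    alpha_p: float = 0.0  # particle volume fraction in Eq-of-motion gravity term
    flow_dt: float = 0.02
    transit_fraction: int = 20
    brownian_step_fraction: float = 30.0  # rms Brownian step <= R_min / this
    forces: dict = field(default_factory=lambda: {
        "drag": True, "gravity": True, "brownian": True,
        "lift": False, "virtual_mass": False,
    })
    cunningham: bool = False
    printed_mobility_form: bool = False
    n_particles: int = 100_000
    particle_density: float = 4390.0
    injection_window: tuple[float, float] | None = None
    t_start: float = 0.0
    t_end: float | None = None
    profile: str = "parabolic"
    snapshot_times: tuple[float, ...] = ()
    max_substeps_per_flow_step: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_dt <= 0:
            raise ValueError("flow_dt must be > 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass
class DepositionResult:
    """Outcome of a tracking run.

    ``records`` has one row per injected particle with columns
    id, t, x, y, z [m], d_p [um], rho_p, status, segment_id, lobe.
    ``snapshots`` maps requested times to the airborne diameter arrays
    (um) at that time.
    """

    records: pd.DataFrame
    n_injected: int
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    @property
    def counts(self) -> dict[str, int]:
        c = self.records["status"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in
                (STATUS_AIRBORNE, STATUS_STUCK, STATUS_ESCAPED, STATUS_EXHALED)}

    def deposited_fraction(self) -> float:
        return self.counts[STATUS_STUCK] / self.n_injected


def _integrate(x, v, u, tau_over_f, accel, dt, drag: bool = True):
    """One exponential-drag step; exact for constant u and accel.

    dv/dt = (u - v)/ (tau/f) + accel.  Returns (x_new, v_new).
    With drag disabled the motion is ballistic under accel.
    """
    if not drag:
        v_new = v + accel * dt
        x_new = x + v * dt + 0.5 * accel * dt**2
        return x_new, v_new
    ueff = u + tau_over_f * accel
    e = np.exp(-dt / tau_over_f)
    v_new = ueff + (v - ueff) * e
    x_new = x + ueff * dt + (v - ueff) * tau_over_f * (1.0 - e)
    return x_new, v_new


def advance_particle(state: ParticleState, u: np.ndarray, air: AirProperties,
                     config: SimulationConfig, dt: float,
                     rng: np.random.Generator | None = None,
                     segment=None) -> ParticleState:
    """Advance one airborne particle by dt given the local fluid velocity.

    Free-space integration (drag/gravity/Brownian per ``config.forces``);
    if ``segment`` (an AirwaySegment) is given, wall contact (radial
    distance >= local R) marks the particle stuck at the contact point.
    """
    if state.status != STATUS_AIRBORNE:
        raise ValueError("particle is no longer airborne")
    u = np.asarray(u, float)
    if not np.all(np.isfinite(state.position)) or not np.all(np.isfinite(state.velocity)):
        raise FloatingPointError("NaN/inf particle state; simulation aborted")
    tau = state.density * state.diameter**2 / (18.0 * air.viscosity)
    if config.cunningham:
        tau = tau * float(cunningham_factor(state.diameter))
    vs = u - state.velocity
    re = air.density * np.linalg.norm(vs) * state.diameter / air.viscosity
    f = float(drag_factor(np.asarray([re]))[0])
    accel = np.zeros(3)
    if config.forces.get("gravity", True):
        accel = accel + np.asarray(config.gravity) * (1.0 - config.alpha_p)
    if config.forces.get("brownian", True) and rng is not None:
        fb = brownian_kick(state.diameter, air, dt, rng,
                           cunningham=config.cunningham,
                           printed_mobility_form=config.printed_mobility_form)
        accel = accel + np.asarray(fb) / state.mass
    tau_eff = tau
    if config.forces.get("virtual_mass", False):
        tau_eff = tau * (1.0 + 0.5 * air.density / state.density)
    x, v = _integrate(state.position, state.velocity, u, tau_eff / f, accel, dt,
                      drag=config.forces.get("drag", True))
    new = replace(state, position=x, velocity=v)
    if segment is not None:
        prox_m = segment.proximal * 1e-3
        axis = segment.axis
        rel = x - prox_m
        s = float(np.dot(rel, axis))
        rvec = rel - s * axis
        r = float(np.linalg.norm(rvec))
        radius_m = segment.radius * 1e-3
        if r >= radius_m:
            contact = prox_m + s * axis + rvec * (radius_m / max(r, 1e-300))
            new = replace(new, position=contact, status=STATUS_STUCK,
                          segment_id=segment.id, lobe=segment.lobe)
    return new


# ---------------------------------------------------------------------------
# vectorized tree tracker


_LOBE_CODES = {LOBE_CENTRAL: 0, LOBE_LEFT: 1, LOBE_RIGHT: 2}
_LOBE_NAMES = np.array([LOBE_CENTRAL, LOBE_LEFT, LOBE_RIGHT])


class _TreeArrays:
    """Contiguous per-segment arrays (SI) for the vectorized tracker."""

    def __init__(self, tree: AirwayTree):
        segs = sorted(tree.segments, key=lambda s: s.id)
        self.index = {s.id: i for i, s in enumerate(segs)}
        self.ids = np.array([s.id for s in segs])
        n = len(segs)
        self.prox = np.array([s.proximal for s in segs]) * 1e-3
        self.axis = np.array([s.axis for s in segs])
        self.length = np.array([s.length for s in segs]) * 1e-3
        self.radius = np.array([s.radius for s in segs]) * 1e-3
        self.parent = np.array([-1 if s.parent_id is None else self.index[s.parent_id]
                                for s in segs])
        self.child1 = np.full(n, -1)
        self.child2 = np.full(n, -1)
        for s in segs:
            kids = tree.children(s.id)
            if len(kids) >= 1:
                self.child1[self.index[s.id]] = self.index[kids[0].id]
            if len(kids) == 2:
                self.child2[self.index[s.id]] = self.index[kids[1].id]
        self.lobe = np.array([_LOBE_CODES[s.lobe] for s in segs])
        self.terminal = np.array([s.terminal for s in segs])
        self.area = math.pi * self.radius**2
        fr = flow_fractions(tree)
        self.fraction = np.array([fr[s.id] for s in segs])
        self.root = self.index[tree.root.id]


def _local_coords(ta: _TreeArrays, seg: np.ndarray, pos: np.ndarray):
    rel = pos - ta.prox[seg]
    ax = ta.axis[seg]
    s = np.einsum("ij,ij->i", rel, ax)
    rvec = rel - s[:, None] * ax
    r = np.linalg.norm(rvec, axis=1)
    return s, r, rvec


def _fluid_velocity(ta: _TreeArrays, seg: np.ndarray, r: np.ndarray,
                    q_total: float, profile: str) -> np.ndarray:
    u_mean = q_total * ta.fraction[seg] / ta.area[seg]
    if profile == "parabolic":
        ratio = np.clip(r / ta.radius[seg], 0.0, 1.0)
        mag = 2.0 * u_mean * (1.0 - ratio**2)
    else:
        mag = u_mean
    return mag[:, None] * ta.axis[seg]


def simulate_deposition(tree: AirwayTree, flow, source: ParticleSourceConfig,
                        config: SimulationConfig,
                        air: AirProperties = AirProperties()) -> DepositionResult:
    """Track a particle population through the tree until the end time.

    ``flow`` is a BreathingPattern or SteadyFlow.  Particles are injected
    on the inlet face, flux-weighted over the cross-section, spread
    uniformly over the injection window, with the local fluid velocity.
    Every particle ends airborne, stuck, escaped or exhaled; counts and
    masses are conserved exactly.  Deterministic (bit-identical tallies)
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    ta = _TreeArrays(tree)
    g = np.asarray(config.gravity, float) * (1.0 - config.alpha_p)

    if isinstance(flow, BreathingPattern):
        window = config.injection_window or (flow.period_s, 1.5 * flow.period_s)
        t_end = config.t_end if config.t_end is not None else 2.0 * flow.period_s
        t_start = config.t_start if config.t_start else flow.period_s
    else:
        window = config.injection_window or (0.0, 0.0)
        t_start = config.t_start
        if config.t_end is None:
            raise ValueError("t_end is required for steady flow")
        t_end = config.t_end
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")

    n = config.n_particles
    d_p = sample_particle_sizes(n, source, rng)
    rho_p = np.full(n, config.particle_density)
    mass = math.pi / 6.0 * d_p**3 * rho_p
    t_inject = np.linspace(window[0], window[1], n) if window[1] > window[0] \
        else np.full(n, window[0])

    # flux-weighted radial injection position on the inlet face
    u01 = rng.random(n)
    if config.profile == "parabolic":
        y = 1.0 - np.sqrt(1.0 - u01)  # CDF of 2y - y^2, y = (r/R)^2
    else:
        y = u01
    r0 = ta.radius[ta.root] * np.sqrt(y) * 0.999
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    ax0 = ta.axis[ta.root]
    e1 = np.cross(ax0, [0.0, 1.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(ax0, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax0, e1)
    offset = (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2) * r0[:, None]
    x0 = ta.prox[ta.root] + 1e-4 * ta.length[ta.root] * ax0 + offset

    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    status = np.zeros(n, dtype=np.int8)  # 0 air 1 stuck 2 escaped 3 exhaled
    injected = np.zeros(n, dtype=bool)
    seg = np.full(n, ta.root)
    lobe_out = np.zeros(n, dtype=np.int8)
    t_event = np.full(n, np.nan)

    tau0 = rho_p * d_p**2 / (18.0 * air.viscosity)
    if config.cunningham:
        tau0 = tau0 * cunningham_factor(d_p)
    gamma_f = 3.0 * math.pi * air.viscosity * d_p
    if config.cunningham:
        gamma_f = gamma_f / cunningham_factor(d_p)
    d_diff = air.k_b * air.temperature / gamma_f
    if config.forces.get("virtual_mass", False):
        tau0 = tau0 * (1.0 + 0.5 * air.density / rho_p)

    use_brownian = config.forces.get("brownian", True)
    use_drag = config.forces.get("drag", True)
    use_gravity = config.forces.get("gravity", True)
    use_lift = config.forces.get("lift", False)
    brown_coef = gamma_f if not config.printed_mobility_form else 1.0 / gamma_f

    # Brownian rms-step cap (independent of flow): sqrt(2 D dt) <= R_min/frac
    if use_brownian:
        dt_brown = (ta.radius.min() / config.brownian_step_fraction) ** 2 / (2.0 * d_diff.max())
    else:
        dt_brown = np.inf

    snapshots: dict[float, np.ndarray] = {}
    snap_times = sorted(config.snapshot_times)
    snap_i = 0

    t = t_start
    while t < t_end - 1e-12:
        q = flow.rate(t)
        # transit-resolution sub-step from the current flow magnitude
        with np.errstate(divide="ignore"):
            u_seg = np.abs(q) * ta.fraction / ta.area
            transit = np.where(u_seg > 0, ta.length / np.maximum(u_seg, 1e-300), np.inf)
        dt_transit = transit.min() / config.transit_fraction
        dt_sub = min(config.flow_dt, dt_transit, dt_brown)
        n_sub = int(min(max(1, math.ceil(config.flow_dt / dt_sub)),
                        config.max_substeps_per_flow_step))
        dt_sub = config.flow_dt / n_sub
        t_next = min(t + config.flow_dt, t_end)
        n_sub = max(1, int(round((t_next - t) / dt_sub)))
        dt_sub = (t_next - t) / n_sub

        for _ in range(n_sub):
            newly = (~injected) & (t_inject <= t) & (status == 0)
            if newly.any():
                idx = np.flatnonzero(newly)
                pos[idx] = x0[idx]
                s_in, r_in, _ = _local_coords(ta, seg[idx], pos[idx])
                vel[idx] = _fluid_velocity(ta, seg[idx], r_in, q, config.profile)
                injected[idx] = True

            act = np.flatnonzero(injected & (status == 0))
            if act.size:
                sg = seg[act]
                s_c, r_c, rvec = _local_coords(ta, sg, pos[act])
                u = _fluid_velocity(ta, sg, r_c, q, config.profile)
                vs = u - vel[act]
                re = air.density * np.linalg.norm(vs, axis=1) * d_p[act] / air.viscosity
                f = drag_factor(re)
                accel = np.zeros((act.size, 3))
                if use_gravity:
                    accel += g
                if use_brownian:
                    amp = np.sqrt(2.0 * air.k_b * air.temperature * brown_coef[act] / dt_sub)
                    accel += amp[:, None] * rng.standard_normal((act.size, 3)) / mass[act, None]
                if use_lift:
                    accel += _saffman_lift(ta, sg, r_c, rvec, vs, d_p[act], air, q,
                                           config.profile) / mass[act, None]
                tau_over_f = tau0[act] / f
                if use_drag:
                    ueff = u + tau_over_f[:, None] * accel
                    e = np.exp(-dt_sub / tau_over_f)[:, None]
                    v_new = ueff + (vel[act] - ueff) * e
                    x_new = pos[act] + ueff * dt_sub + (vel[act] - ueff) * tau_over_f[:, None] * (1.0 - e)
                else:
                    v_new = vel[act] + accel * dt_sub
                    x_new = pos[act] + vel[act] * dt_sub + 0.5 * accel * dt_sub**2
                if not np.all(np.isfinite(x_new)):
                    raise FloatingPointError("NaN particle state; simulation aborted")
                pos_prev = pos[act].copy()
                s_prev = s_c
                pos[act] = x_new
                vel[act] = v_new

                # classify against the current segment
                s_n, r_n, rvec_n = _local_coords(ta, sg, pos[act])
                radius = ta.radius[sg]
                length = ta.length[sg]

                hit_wall = (r_n >= radius) & (s_n >= 0.0) & (s_n <= length)
                past = (s_n > length) & ~hit_wall
                before = (s_n < 0.0) & ~hit_wall

                if hit_wall.any():
                    w = act[hit_wall]
                    sw = sg[hit_wall]
                    scale = (radius[hit_wall] / np.maximum(r_n[hit_wall], 1e-300))[:, None]
                    pos[w] = ta.prox[sw] + s_n[hit_wall, None] * ta.axis[sw] \
                        + rvec_n[hit_wall] * scale
                    status[w] = 1
                    lobe_out[w] = ta.lobe[sw]
                    t_event[w] = t

                if past.any():
                    p_idx = act[past]
                    sp = sg[past]
                    # interpolate to the exit-plane crossing so containment is
                    # judged there, independent of the sub-step overshoot
                    denom = np.maximum(s_n[past] - s_prev[past], 1e-300)
                    theta = np.clip((length[past] - s_prev[past]) / denom, 0.0, 1.0)
                    x_cross = pos_prev[past] + theta[:, None] * (pos[p_idx] - pos_prev[past])
                    term = ta.terminal[sp]
                    # terminal outlet -> escaped
                    status[p_idx[term]] = 2
                    t_event[p_idx[term]] = t
                    # junction: move to a child containing the crossing point,
                    # else the particle impacted the junction wall
                    jn = ~term
                    if jn.any():
                        ji = p_idx[jn]
                        xc = x_cross[jn]
                        cc1, cc2 = ta.child1[sp[jn]], ta.child2[sp[jn]]
                        _, r1, _ = _local_coords(ta, np.maximum(cc1, 0), xc)
                        in1 = (cc1 >= 0) & (r1 < ta.radius[np.maximum(cc1, 0)])
                        _, r2, _ = _local_coords(ta, np.maximum(cc2, 0), xc)
                        in2 = (cc2 >= 0) & (r2 < ta.radius[np.maximum(cc2, 0)])
                        # both daughters contain the crossing point in the
                        # overlap lens at the junction: split by which side of
                        # the carina the particle crosses on
                        rel = xc - ta.prox[np.maximum(cc1, 0)]
                        split_dir = ta.axis[np.maximum(cc1, 0)] - ta.axis[np.maximum(cc2, 0)]
                        side1 = np.einsum("ij,ij->i", rel, split_dir) >= 0.0
                        pick1 = in1 & (~in2 | side1)
                        pick2 = in2 & ~pick1
                        seg[ji[pick1]] = cc1[pick1]
                        seg[ji[pick2]] = cc2[pick2]
                        none = ~(pick1 | pick2)
                        if none.any():
                            w = ji[none]
                            sw = sp[jn][none]
                            pos[w] = xc[none]
                            status[w] = 1  # impacted on the junction wall
                            lobe_out[w] = ta.lobe[sw]
                            t_event[w] = t

                if before.any():
                    b_idx = act[before]
                    sb = sg[before]
                    denom = np.minimum(s_n[before] - s_prev[before], -1e-300)
                    theta = np.clip((0.0 - s_prev[before]) / denom, 0.0, 1.0)
                    x_cross = pos_prev[before] + theta[:, None] * (pos[b_idx] - pos_prev[before])
                    at_root = sb == ta.root
                    status[b_idx[at_root]] = 3  # crossed the inlet face
                    t_event[b_idx[at_root]] = t
                    up = ~at_root
                    if up.any():
                        ui = b_idx[up]
                        pu = ta.parent[sb[up]]
                        _, r_p, _ = _local_coords(ta, pu, x_cross[up])
                        ok = r_p < ta.radius[pu]
                        seg[ui[ok]] = pu[ok]
                        if (~ok).any():
                            w = ui[~ok]
                            sw = pu[~ok]
                            pos[w] = x_cross[up][~ok]
                            status[w] = 1
                            lobe_out[w] = ta.lobe[sw]
                            t_event[w] = t

            t += dt_sub
            while snap_i < len(snap_times) and t >= snap_times[snap_i] - 1e-12:
                air_mask = injected & (status == 0)
                snapshots[snap_times[snap_i]] = d_p[air_mask] * 1e6
                snap_i += 1

    # un-injected particles (window beyond t_end) count as airborne, never entered
    records = pd.DataFrame({
        "id": np.arange(n),
        "t": np.where(np.isnan(t_event), t_end, t_event),
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "d_p": d_p * 1e6,
        "rho_p": rho_p,
        "status": _STATUS_NAMES[status],
        "segment_id": ta.ids[seg],
        "lobe": np.where(status == 1, _LOBE_NAMES[lobe_out], ""),
    })
    return DepositionResult(records=records, n_injected=n, snapshots=snapshots,
                            seed=config.seed)


def _saffman_lift(ta, sg, r, rvec, vs, d_p, air, q_total, profile):
    """Saffman shear-lift force (N), radial direction; off by default."""
    if profile != "parabolic":
        return np.zeros_like(rvec)
    u_mean = q_total * ta.fraction[sg] / ta.area[sg]
    shear = np.abs(-4.0 * u_mean * r / ta.radius[sg] ** 2)
    vs_ax = np.einsum("ij,ij->i", vs, ta.axis[sg])
    mag = 1.615 * air.density * np.sqrt(air.viscosity / air.density) \
        * d_p**2 * np.sqrt(np.maximum(shear, 0.0)) * vs_ax
    rhat = np.where(r[:, None] > 0, rvec / np.maximum(r[:, None], 1e-300), 0.0)
    return -mag[:, None] * rhat  # toward the axis for a lagging particle


def write_tracks(result: DepositionResult, path) -> None:
    """Write the per-particle track records as CSV (dosimetry input)."""
    result.records.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "t", "x", "y", "z", "d_p", "rho_p", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    return df
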