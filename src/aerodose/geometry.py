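"""Parametrized bifurcating airway-tree geometry.

The lower human respiratory tract (trachea plus bronchial tree) is
represented analytically as a tree of straight circular tube segments.
Each segment is a cylinder of constant diameter running from a proximal
to a distal point; daughters attach at the parent's distal point.  This
analytic representation replaces CT-reconstructed surfaces: it permits
exact inside/outside tests for particle-wall contact and exact
morphometric measurements.

Units: all geometry in this module is in **millimetres**.  The particle
tracker converts to SI internally.

Coordinate conventions (configurable through :class:`TreeSpec`): right
handed axes, trachea pointing along -z, gravity along -z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

LOBE_LEFT = "left"
LOBE_RIGHT = "right"
LOBE_CENTRAL = "central"

__all__ = [
    "AirwaySegment",
    "AirwayTree",
    "HRTParameters",
    "TreeSpec",
    "CLUSTER_ANCHORS",
    "cluster_spec",
    "generate_airway_tree",
    "measure_parameters",
    "validate_tree",
    "upper_airway_surrogate",
    "single_tube",
    "bend_fixture",
]


@dataclass
class AirwaySegment:
    """One straight tube segment of the airway tree.

    ``proximal`` / ``distal`` are 3-vectors in mm; ``diameter`` in mm.
    ``generation`` 0 is the trachea.  ``lobe`` tags which lung the
    segment drains into (``central`` for the trachea and extrathoracic
    surrogates).
    """

    id: int
    parent_id: int | None
    generation: int
    proximal: np.ndarray
    distal: np.ndarray
    diameter: float
    lobe: str = LOBE_CENTRAL
    terminal: bool = False

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.diameter <= 0:
            raise ValueError(f"segment {self.id}: diameter must be > 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: zero-length segment")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from proximal to distal end."""
        d = self.distal - self.proximal
        return d / np.linalg.norm(d)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        """Cylinder volume in mm^3."""
        return math.pi * self.radius**2 * self.length


@dataclass
class AirwayTree:
    """A connected, acyclic collection of airway segments.

    Exactly one segment has generation 0 (the root/trachea).  Internal
    segments carry one child (straight continuation, e.g. a constriction
    or a bend joint) or two children (a bifurcation).
    """

    segments: list[AirwaySegment]
    gravity_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self) -> None:
        self.gravity_axis = np.asarray(self.gravity_axis, dtype=float)
        n = np.linalg.norm(self.gravity_axis)
        if n == 0:
            raise ValueError("gravity_axis must be non-zero")
        self.gravity_axis = self.gravity_axis / n
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise ValueError("duplicate segment ids")

    def segment(self, seg_id: int) -> AirwaySegment:
        return self._by_id[seg_id]

    @property
    def root(self) -> AirwaySegment:
        roots = [s for s in self.segments if s.generation == 0]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one generation-0 segment, found {len(roots)}")
        return roots[0]

    def children(self, seg_id: int) -> list[AirwaySegment]:
        return [s for s in self.segments if s.parent_id == seg_id]

    @property
    def terminals(self) -> list[AirwaySegment]:
        return [s for s in self.segments if s.terminal]

    @property
    def inlet_face(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(center, inward normal, radius) of the trachea proximal disk, mm."""
        r = self.root
        return r.proximal.copy(), r.axis, r.radius

    @property
    def outlet_faces(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """(center, outward normal, radius) per terminal segment, mm."""
        return [(s.distal.copy(), s.axis, s.radius) for s in self.terminals]

    @property
    def volume(self) -> float:
        """Total lumen volume as the sum of per-segment cylinders, mm^3."""
        return sum(s.volume for s in self.segments)

    @property
    def total_length(self) -> float:
        """Cumulative centerline length over all segments, mm."""
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class HRTParameters:
    """The four morphometric parameters of a lower-airway geometry."""

    t_d: float  # volume-averaged (length-weighted) trachea diameter, mm
    b_a: float  # carina angle between the two main-bronchi axes, degrees
    volume: float  # total lumen volume, mm^3
    total_length: float  # cumulative bronchial length, mm

    def __post_init__(self) -> None:
        if self.t_d <= 0:
            raise ValueError("t_d must be > 0")
        if not 0 < self.b_a < 180:
            raise ValueError("b_a must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")


@dataclass(frozen=True)
class TreeSpec:
    """Parameters driving the synthetic airway-tree generator.

    ``t_d`` and ``b_a`` are reproduced exactly by construction; when
    ``volume`` / ``total_length`` targets are given the generator solves
    for a per-generation diameter ratio and a global length scale so the
    measured values match as well.

    The per-generation conventions (``diameter_ratio`` 0.78, Weibel-like;
    lengths 3x diameter) are fixture defaults, not anatomical claims, and
    are overridable.  ``asymmetry_*`` factors are relative perturbation
    amplitudes applied to daughter angles, diameters and lengths from
    generation 2 on (and as a left/right tilt of the carina split that
    preserves the total carina angle); zero asymmetry yields a tree whose
    left subtree is the mirror image of the right.
    """

    t_d: float = 16.2
    b_a: float = 79.1
    n_generations: int = 7
    diameter_ratio: float = 0.78
    length_to_diameter: float = 3.0
    trachea_length: float | None = None
    branching_half_angle: float = 35.0  # degrees, generations >= 2
    roll_angle: float = 90.0  # degrees, rotation of successive branching planes
    asymmetry_angle: float = 0.0
    asymmetry_diameter: float = 0.0
    asymmetry_length: float = 0.0
    volume: float | None = None
    total_length: float | None = None
    trachea_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    gravity_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.t_d <= 0:
            raise ValueError("t_d must be > 0")
        if not 0 < self.b_a < 180:
            raise ValueError("b_a must lie in (0, 180) degrees")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0 < self.diameter_ratio < 1:
            raise ValueError("diameter_ratio must lie in (0, 1)")
        if self.length_to_diameter <= 0:
            raise ValueError("length_to_diameter must be > 0")
        for name in ("asymmetry_angle", "asymmetry_diameter", "asymmetry_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.volume is not None and self.volume <= 0:
            raise ValueError("volume target must be > 0")
        if self.total_length is not None and self.total_length <= 0:
            raise ValueError("total_length target must be > 0")


# Per-phenotype anchors: carina angle b_a [deg] and mean trachea diameter
# t_d [mm] -- (mean, sd, min, max) for each of the nine clusters on the
# (small|mean|big t_d) x (small|mean|big b_a) grid.
CLUSTER_ANCHORS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "bs": {"b_a": (76.81, 2.42, 71.4, 81.2), "t_d": (17.0, 0.5, 16.2, 17.7)},
    "bm": {"b_a": (80.9, 3.57, 76.4, 87.0), "t_d": (17.3, 0.6, 16.1, 18.2)},
    "bb": {"b_a": (97.83, 3.53, 91.6, 104.0), "t_d": (18.2, 0.3, 17.8, 18.6)},
    "mb": {"b_a": (95.18, 3.15, 90.6, 101.0), "t_d": (17.0, 0.4, 16.0, 17.6)},
    "mm": {"b_a": (79.1, 3.5, 73.6, 84.5), "t_d": (16.2, 0.4, 15.9, 16.9)},
    "ms": {"b_a": (69.23, 3.0, 64.0, 73.2), "t_d": (14.9, 0.4, 14.3, 15.9)},
    "sb": {"b_a": (88.57, 3.6, 81.7, 93.2), "t_d": (15.0, 0.5, 14.0, 15.8)},
    "sm": {"b_a": (82.65, 3.36, 78.4, 89.7), "t_d": (14.3, 0.5, 13.7, 15.5)},
    "ss": {"b_a": (67.63, 3.2, 61.4, 73.1), "t_d": (13.46, 0.1, 13.4, 13.7)},
}


def cluster_spec(name: str, **overrides) -> TreeSpec:
    """TreeSpec anchored at the mean t_d/b_a of one phenotype cluster."""
    if name not in CLUSTER_ANCHORS:
        raise KeyError(f"unknown cluster {name!r}; choose from {sorted(CLUSTER_ANCHORS)}")
    a = CLUSTER_ANCHORS[name]
    kwargs = {"t_d": a["t_d"][0], "b_a": a["b_a"][0]}
    kwargs.update(overrides)
    return TreeSpec(**kwargs)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v (deterministic choice)."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _build_nodes(spec: TreeSpec, diameter_ratio: float, length_scale: float):
    """Build the node list for given ratio/length-scale.

    Returns a list of dicts with keys id, parent, gen, dir, d, L, lobe,
    mirror (sign carried down each side so that the zero-asymmetry tree
    is mirror symmetric).  Perturbation draws come from a dedicated RNG
    seeded from the spec, in a construction-order-stable sequence, and
    are scaled by the asymmetry factors (zero factors => exact symmetry
    regardless of the draws).
    """
    rng = np.random.default_rng(spec.seed)
    axis = np.asarray(spec.trachea_axis, float)
    axis = axis / np.linalg.norm(axis)
    normal0 = _perp(axis)

    L0 = spec.trachea_length if spec.trachea_length is not None else spec.length_to_diameter * spec.t_d
    nodes = [
        dict(id=0, parent=None, gen=0, dir=axis, normal=normal0, d=spec.t_d,
             L=L0 * length_scale, lobe=LOBE_CENTRAL, mirror=1.0)
    ]
    if spec.n_generations == 1:
        nodes[0]["terminal"] = True
        return nodes
    nodes[0]["terminal"] = False

    # carina split: theta_left + theta_right = b_a exactly
    tilt = spec.asymmetry_angle * rng.uniform(-0.5, 0.5)
    half = math.radians(spec.b_a) / 2.0
    theta = {LOBE_RIGHT: half * (1.0 - tilt), LOBE_LEFT: half * (1.0 + tilt)}

    queue = []
    next_id = 1
    for side, sign in ((LOBE_RIGHT, +1.0), (LOBE_LEFT, -1.0)):
        jd = 1.0 + spec.asymmetry_diameter * rng.uniform(-0.5, 0.5)
        jl = 1.0 + spec.asymmetry_length * rng.uniform(-0.5, 0.5)
        d1 = spec.t_d * diameter_ratio * jd
        child_dir = _rotate(axis, normal0, sign * theta[side])
        child_normal = _rotate(normal0, child_dir, sign * math.radians(spec.roll_angle))
        node = dict(id=next_id, parent=0, gen=1, dir=child_dir, normal=child_normal,
                    d=d1, L=spec.length_to_diameter * d1 * jl * length_scale,
                    lobe=side, mirror=sign,
                    terminal=spec.n_generations == 2)
        nodes.append(node)
        queue.append(node)
        next_id += 1

    while queue:
        parent = queue.pop(0)
        gen = parent["gen"] + 1
        if gen >= spec.n_generations:
            continue
        phi0 = math.radians(spec.branching_half_angle)
        sign0 = parent["mirror"]
        for k, s in enumerate((+1.0, -1.0)):
            ja = spec.asymmetry_angle * rng.uniform(-0.5, 0.5)
            jd = 1.0 + spec.asymmetry_diameter * rng.uniform(-0.5, 0.5)
            jl = 1.0 + spec.asymmetry_length * rng.uniform(-0.5, 0.5)
            phi = phi0 * (1.0 + ja)
            child_dir = _rotate(parent["dir"], parent["normal"], sign0 * s * phi)
            child_normal = _rotate(parent["normal"], child_dir, sign0 * math.radians(spec.roll_angle))
            d = parent["d"] * diameter_ratio * jd
            node = dict(id=next_id, parent=parent["id"], gen=gen, dir=child_dir,
                        normal=child_normal, d=d,
                        L=spec.length_to_diameter * d * jl * length_scale,
                        lobe=parent["lobe"], mirror=sign0,
                        terminal=gen == spec.n_generations - 1)
            nodes.append(node)
            queue.append(node)
            next_id += 1
    return nodes


def _nodes_totals(nodes) -> tuple[float, float]:
    vol = sum(math.pi * (n["d"] / 2.0) ** 2 * n["L"] for n in nodes)
    length = sum(n["L"] for n in nodes)
    return vol, length


def generate_airway_tree(spec: TreeSpec) -> AirwayTree:
    """Generate a synthetic bifurcating airway tree from a TreeSpec.

    The returned tree reproduces ``spec.t_d`` and ``spec.b_a`` exactly by
    construction; when volume and/or total-length targets are set they
    are matched by solving for the per-generation diameter ratio and a
    global length scale (both monotone in the respective target).
    Deterministic for a fixed seed.
    """
    spec.validate()

    ratio = spec.diameter_ratio
    scale = 1.0

    def totals(r: float, s: float) -> tuple[float, float]:
        return _nodes_totals(_build_nodes(spec, r, s))

    lo, hi = 0.40, 0.985

    def _solve(g, what: str) -> float:
        # g may be non-monotone in the ratio; bracket every sign change on
        # a grid and take the root nearest the nominal diameter ratio.
        grid = np.linspace(lo, hi, 40)
        vals = np.array([g(r) for r in grid])
        brackets = [(grid[i], grid[i + 1]) for i in range(len(grid) - 1)
                    if vals[i] == 0 or vals[i] * vals[i + 1] < 0]
        if not brackets:
            raise ValueError(f"{what} target outside attainable range")
        a, b = min(brackets, key=lambda ab: abs(0.5 * (ab[0] + ab[1]) - spec.diameter_ratio))
        return float(brentq(g, a, b, xtol=1e-13))

    if spec.volume is not None and spec.total_length is not None:
        # lengths scale linearly: V = s*V0(r), L = s*L0(r); match V/L first.
        target = spec.volume / spec.total_length

        def g_ratio(r: float) -> float:
            v0, l0 = totals(r, 1.0)
            return v0 / l0 - target

        ratio = _solve(g_ratio, "volume/total_length")
        scale = spec.total_length / totals(ratio, 1.0)[1]
    elif spec.total_length is not None:
        scale = spec.total_length / totals(ratio, 1.0)[1]
    elif spec.volume is not None:
        ratio = _solve(lambda r: totals(r, 1.0)[0] - spec.volume, "volume")

    nodes = _build_nodes(spec, ratio, scale)

    # positions by BFS from the origin
    pos = {None: np.zeros(3)}
    segs: list[AirwaySegment] = []
    prox = {0: np.zeros(3)}
    by_id = {n["id"]: n for n in nodes}
    for n in nodes:  # nodes are in BFS order already
        p = prox[n["id"]]
        dist = p + n["dir"] * n["L"]
        segs.append(
            AirwaySegment(id=n["id"], parent_id=n["parent"], generation=n["gen"],
                          proximal=p, distal=dist, diameter=n["d"], lobe=n["lobe"],
                          terminal=n["terminal"])
        )
        for m in nodes:
            if m["parent"] == n["id"]:
                prox[m["id"]] = dist
    tree = AirwayTree(segments=segs, gravity_axis=np.asarray(spec.gravity_axis, float))
    validate_tree(tree, strict_bifurcation=True)
    return tree


def validate_tree(tree: AirwayTree, strict_bifurcation: bool = False) -> None:
    """Check structural invariants; raise ValueError on violation.

    With ``strict_bifurcation`` every non-terminal segment must have
    exactly two children; otherwise one child (a straight continuation,
    constriction or bend joint) is also accepted.
    """
    root = tree.root  # raises if not exactly one generation-0 segment
    seen: set[int] = set()
    stack = [root]
    while stack:
        s = stack.pop()
        if s.id in seen:
            raise ValueError("cycle detected in airway tree")
        seen.add(s.id)
        kids = tree.children(s.id)
        if s.terminal and kids:
            raise ValueError(f"terminal segment {s.id} has children")
        if not s.terminal:
            want = (2,) if strict_bifurcation else (1, 2)
            if len(kids) not in want:
                raise ValueError(
                    f"non-terminal segment {s.id} has {len(kids)} children, expected {want}"
                )
        for c in kids:
            if c.generation != s.generation + 1:
                raise ValueError(f"segment {c.id}: generation must increment from parent")
            if not np.allclose(c.proximal, s.distal, atol=1e-9):
                raise ValueError(f"segment {c.id}: proximal point detached from parent distal")
            stack.append(c)
    if seen != set(s.id for s in tree.segments):
        raise ValueError("airway tree is not connected")


def measure_parameters(tree: AirwayTree) -> HRTParameters:
    """Measure the four morphometric parameters from any airway tree.

    t_d is the length-weighted mean diameter over generation-0 segments;
    b_a the angle between the two generation-1 segment axes at the
    carina; volume the sum of per-segment cylinder volumes; total_length
    the cumulative centerline length.
    """
    if len(tree.segments) < 3:
        raise ValueError("tree must have at least trachea + 2 main bronchi")
    g0 = [s for s in tree.segments if s.generation == 0]
    g1 = [s for s in tree.segments if s.generation == 1]
    if len(g1) != 2:
        raise ValueError(
            f"carina angle undefined: need exactly 2 generation-1 segments, found {len(g1)}"
        )
    t_d = sum(s.diameter * s.length for s in g0) / sum(s.length for s in g0)
    cosang = float(np.clip(np.dot(g1[0].axis, g1[1].axis), -1.0, 1.0))
    b_a = math.degrees(math.acos(cosang))
    return HRTParameters(t_d=t_d, b_a=b_a, volume=tree.volume, total_length=tree.total_length)


# ---------------------------------------------------------------------------
# Fixture builders


def _chain(specs: Sequence[tuple[np.ndarray, float, float]],
           start: np.ndarray | None = None,
           lobe: str = LOBE_CENTRAL,
           gravity_axis=(0.0, 0.0, -1.0)) -> AirwayTree:
    """Serial chain of segments given (direction, diameter, length) triples."""
    p = np.zeros(3) if start is None else np.asarray(start, float)
    segs = []
    for i, (d_vec, dia, length) in enumerate(specs):
        d_vec = np.asarray(d_vec, float)
        d_vec = d_vec / np.linalg.norm(d_vec)
        q = p + d_vec * length
        segs.append(AirwaySegment(id=i, parent_id=None if i == 0 else i - 1,
                                  generation=i, proximal=p, distal=q, diameter=dia,
                                  lobe=lobe, terminal=i == len(specs) - 1))
        p = q
    return AirwayTree(segments=segs, gravity_axis=np.asarray(gravity_axis, float))


def single_tube(diameter: float, length: float,
                direction=(1.0, 0.0, 0.0), gravity_axis=(0.0, 0.0, -1.0)) -> AirwayTree:
    """One straight tube segment (mm); handy for analytic benchmarks."""
    return _chain([(np.asarray(direction, float), diameter, length)],
                  gravity_axis=gravity_axis)


def bend_fixture(diameter: float = 6.0, leg_length: float = 30.0) -> AirwayTree:
    """Single 90-degree bend: one horizontal and one vertical leg."""
    return _chain([
        (np.array([1.0, 0.0, 0.0]), diameter, leg_length),
        (np.array([0.0, 0.0, -1.0]), diameter, leg_length),
    ])


def upper_airway_surrogate() -> AirwayTree:
    """UA-1: extrathoracic (mouth-throat) surrogate.

    A serial tube chain with three 90-degree bends and a 6 mm hydraulic
    diameter laryngeal constriction: mouth (12 mm, horizontal), pharynx
    (9 mm, vertical), larynx (6 mm, vertical), a horizontal 6 mm jet
    section and a final vertical 8 mm outlet.  At heavy-exercise flow the
    constriction Stokes number for 10 um particles exceeds unity, so the
    fixture captures the inertial filtering of the upper airway.
    """
    down = np.array([0.0, 0.0, -1.0])
    fwd = np.array([1.0, 0.0, 0.0])
    return _chain([
        (fwd, 12.0, 40.0),   # oral cavity
        (down, 9.0, 40.0),   # pharynx (bend 1)
        (down, 6.0, 20.0),   # laryngeal constriction
        (fwd, 6.0, 20.0),    # jet section (bend 2)
        (down, 8.0, 40.0),   # sub-laryngeal outlet (bend 3)
    ])
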