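"""Airway-tree file formats.

Two interchange formats are supported:

* **JSON tree** (``aerodose-tree/1``): a lossless, versioned segment
  table in millimetres.  ``write_tree`` / ``read_tree`` round-trip is
  the identity.
* **STL surface**: export triangulates every segment as a capped
  cylinder (watertight per component); import skeletonizes a watertight
  surface back into a segment tree via voxelization, a 3-D medial-axis
  thinning and a Euclidean distance transform for local radii.  The
  skeletonization is approximate (voxel resolution limited) and intended
  for tube-like surfaces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import AirwaySegment, AirwayTree, LOBE_CENTRAL

TREE_SCHEMA = "aerodose-tree/1"
_REQUIRED_SEGMENT_FIELDS = ("id", "parent_id", "generation", "proximal", "distal",
                            "diameter", "lobe", "terminal")

__all__ = ["read_tree", "write_tree", "write_stl", "tree_to_mesh",
           "tree_from_surface", "TREE_SCHEMA"]


def write_tree(tree: AirwayTree, path: str | Path) -> None:
    """Write the JSON tree representation (units: mm)."""
    doc = {
        "schema": TREE_SCHEMA,
        "units": "mm",
        "gravity_axis": tree.gravity_axis.tolist(),
        "segments": [
            {
                "id": s.id,
                "parent_id": s.parent_id,
                "generation": s.generation,
                "proximal": s.proximal.tolist(),
                "distal": s.distal.tolist(),
                "diameter": s.diameter,
                "lobe": s.lobe,
                "terminal": s.terminal,
            }
            for s in tree.segments
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


class TreeParseError(ValueError):
    """Malformed tree file."""


def read_tree(path: str | Path) -> AirwayTree:
    """Read a JSON tree file; raises TreeParseError naming missing fields."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise TreeParseError(f"not valid JSON: {e}") from e
    if not isinstance(doc, dict) or doc.get("schema") != TREE_SCHEMA:
        raise TreeParseError(f"missing or unsupported 'schema' (expected {TREE_SCHEMA!r})")
    if "segments" not in doc:
        raise TreeParseError("missing field 'segments'")
    segments = []
    for i, rec in enumerate(doc["segments"]):
        for f in _REQUIRED_SEGMENT_FIELDS:
            if f not in rec:
                raise TreeParseError(f"segment {i}: missing field {f!r}")
        segments.append(
            AirwaySegment(
                id=int(rec["id"]),
                parent_id=None if rec["parent_id"] is None else int(rec["parent_id"]),
                generation=int(rec["generation"]),
                proximal=np.asarray(rec["proximal"], float),
                distal=np.asarray(rec["distal"], float),
                diameter=float(rec["diameter"]),
                lobe=str(rec["lobe"]),
                terminal=bool(rec["terminal"]),
            )
        )
    gravity = np.asarray(doc.get("gravity_axis", [0.0, 0.0, -1.0]), float)
    return AirwayTree(segments=segments, gravity_axis=gravity)


def tree_to_mesh(tree: AirwayTree, sections: int = 48):
    """Triangulated tube surface: one capped cylinder per segment (mm).

    Each cylinder is individually watertight, so the concatenated mesh is
    watertight component-wise.
    """
    import trimesh

    meshes = []
    for s in tree.segments:
        cyl = trimesh.creation.cylinder(radius=s.radius, height=s.length, sections=sections)
        # align +z cylinder axis with the segment axis, center at midpoint
        T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], s.axis)
        T[:3, 3] = (s.proximal + s.distal) / 2.0
        cyl.apply_transform(T)
        meshes.append(cyl)
    return trimesh.util.concatenate(meshes)


def write_stl(tree: AirwayTree, path: str | Path, sections: int = 48, ascii: bool = False) -> None:
    mesh = tree_to_mesh(tree, sections=sections)
    path = Path(path)
    if ascii:
        path.write_text(mesh.export(file_type="stl_ascii"))
    else:
        mesh.export(path)


def tree_from_surface(mesh_or_path, pitch: float = 0.5,
                      min_branch_len: float = 2.0) -> AirwayTree:
    """Skeletonize a watertight tube surface into an airway tree.

    Method: voxelize and fill the surface at ``pitch`` mm, thin the solid
    to a one-voxel medial skeleton, take local radii from the Euclidean
    distance transform, build the voxel adjacency graph, and collapse
    each path between branch/end nodes into one straight segment whose
    diameter is twice the mean interior EDT radius.  The root is the
    endpoint with the largest local radius (trachea).

    Approximate by construction; raises ValueError for non-watertight
    input.
    """
    import networkx as nx
    import trimesh
    from scipy import ndimage
    from skimage.morphology import skeletonize

    if isinstance(mesh_or_path, (str, Path)):
        mesh = trimesh.load(str(mesh_or_path))
    else:
        mesh = mesh_or_path
    if not mesh.is_watertight:
        raise ValueError("surface is not watertight; cannot skeletonize")

    vox = mesh.voxelized(pitch).fill()
    solid = np.asarray(vox.matrix, bool)
    skel = skeletonize(solid)
    edt = ndimage.distance_transform_edt(solid) * pitch

    idx = np.argwhere(skel)
    if len(idx) < 2:
        raise ValueError("skeletonization produced no centerline")
    voxset = {tuple(v) for v in idx}
    g = nx.Graph()
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for v in voxset:
        g.add_node(v)
        for o in offsets:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if w in voxset:
                g.add_edge(v, w)

    # collapse degree-2 chains between junction/end nodes
    special = [n for n in g.nodes if g.degree(n) != 2]
    if not special:  # closed loop or straight chain wrap; pick extremes
        special = [tuple(idx[0]), tuple(idx[-1])]

    def to_mm(v):
        return vox.indices_to_points(np.asarray([v], float))[0]

    paths = []
    visited_edges = set()
    for n in special:
        for nb in g.neighbors(n):
            if (n, nb) in visited_edges or (nb, n) in visited_edges:
                continue
            path = [n, nb]
            visited_edges.add((n, nb))
            while g.degree(path[-1]) == 2 and path[-1] not in special:
                nxt = [x for x in g.neighbors(path[-1]) if x != path[-2]]
                if not nxt:
                    break
                visited_edges.add((path[-1], nxt[0]))
                path.append(nxt[0])
            paths.append(path)

    # deduplicate reversed paths
    uniq = {}
    for p in paths:
        key = (p[0], p[-1]) if p[0] <= p[-1] else (p[-1], p[0])
        if key not in uniq or len(p) > len(uniq[key]):
            uniq[key] = p
    paths = [p for p in uniq.values()
             if np.linalg.norm(to_mm(p[0]) - to_mm(p[-1])) >= min_branch_len]
    if not paths:
        raise ValueError("no centerline branches longer than min_branch_len")

    # root end: skeleton endpoint with the largest EDT radius
    ends = [(p, e) for p in paths for e in (p[0], p[-1])
            if g.degree(e) == 1 or len(paths) == 1]
    if not ends:
        ends = [(paths[0], paths[0][0])]
    root_path, root_end = max(ends, key=lambda pe: edt[pe[1]])
    if root_path[0] != root_end:
        root_path = root_path[::-1]

    # orient remaining paths away from the root by BFS over shared endpoints
    remaining = [p for p in paths if p is not root_path]
    frontier = [(root_path, None, 0)]
    order = []
    while frontier:
        path, parent_sid, gen = frontier.pop(0)
        interior = path[1:-1] if len(path) > 2 else path
        radius = float(np.mean([edt[v] for v in interior]))
        a, b = to_mm(path[0]), to_mm(path[-1])
        sid = len(order)
        order.append(dict(id=sid, parent=parent_sid, gen=gen, prox=a, dist=b,
                          d=max(2.0 * radius, pitch), end=path[-1]))
        still = []
        for q in remaining:
            if q[0] == path[-1]:
                frontier.append((q, sid, gen + 1))
            elif q[-1] == path[-1]:
                frontier.append((q[::-1], sid, gen + 1))
            else:
                still.append(q)
        remaining = still

    id_children = {}
    for n in order:
        id_children.setdefault(n["parent"], []).append(n["id"])
    segments = []
    for n in order:
        # snap child proximal to parent distal so tree invariants hold
        prox = n["prox"] if n["parent"] is None else np.asarray(
            next(m for m in order if m["id"] == n["parent"])["dist"], float)
        segments.append(
            AirwaySegment(id=n["id"], parent_id=n["parent"], generation=n["gen"],
                          proximal=prox, distal=np.asarray(n["dist"], float),
                          diameter=n["d"], lobe=LOBE_CENTRAL,
                          terminal=n["id"] not in id_children)
        )
    return AirwayTree(segments=segments)
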