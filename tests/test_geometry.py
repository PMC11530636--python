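"""Synthetic airway-tree generation and morphometric measurement."""

import math

import numpy as np
import pytest

from aerodose.geometry import (
    CLUSTER_ANCHORS,
    AirwaySegment,
    AirwayTree,
    HRTParameters,
    TreeSpec,
    cluster_spec,
    generate_airway_tree,
    measure_parameters,
    single_tube,
    upper_airway_surrogate,
    validate_tree,
)


class TestGenerate:
    def test_cluster_bb_lands_inside_printed_ranges(self):
        tree = generate_airway_tree(cluster_spec("bb", n_generations=5, seed=0))
        p = measure_parameters(tree)
        assert 17.8 <= p.t_d <= 18.6
        assert 91.6 <= p.b_a <= 104.0

    @pytest.mark.parametrize("name", sorted(CLUSTER_ANCHORS))
    def test_all_nine_cluster_centers_inside_ranges(self, name):
        p = measure_parameters(generate_airway_tree(cluster_spec(name, n_generations=4, seed=2)))
        a = CLUSTER_ANCHORS[name]
        assert a["t_d"][2] <= p.t_d <= a["t_d"][3]
        assert a["b_a"][2] <= p.b_a <= a["b_a"][3]

    def test_deterministic_for_fixed_seed(self):
        spec = TreeSpec(n_generations=5, asymmetry_angle=0.2, asymmetry_diameter=0.1, seed=9)
        a = generate_airway_tree(spec)
        b = generate_airway_tree(spec)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.distal, sb.distal)
            assert sa.diameter == sb.diameter

    def test_mirror_symmetry_at_zero_asymmetry(self, small_symmetric_tree):
        tree = small_symmetric_tree
        left = [s for s in tree.segments if s.lobe == "left"]
        right = [s for s in tree.segments if s.lobe == "right"]
        # volumes identical to machine precision
        assert sum(s.volume for s in left) == pytest.approx(
            sum(s.volume for s in right), abs=1e-12)
        # positions mirror across the plane containing the trachea axis
        lp = sorted(tuple(np.round(s.distal * np.array([1, -1, 1]), 9)) for s in left)
        rp = sorted(tuple(np.round(s.distal, 9)) for s in right)
        assert lp == rp

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TreeSpec(t_d=-1.0).validate()
        with pytest.raises(ValueError):
            TreeSpec(b_a=190.0).validate()
        with pytest.raises(ValueError):
            TreeSpec(n_generations=0).validate()

    def test_round_trip_parameter_recovery(self):
        """100 random specs: measured t_d/volume/length within 1%, b_a within 0.5 deg."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            spec = TreeSpec(
                t_d=rng.uniform(13.0, 19.0),
                b_a=rng.uniform(60.0, 105.0),
                n_generations=int(rng.integers(3, 6)),
                asymmetry_angle=rng.uniform(0, 0.3),
                asymmetry_diameter=rng.uniform(0, 0.15),
                asymmetry_length=rng.uniform(0, 0.15),
                seed=int(rng.integers(1 << 31)),
            )
            base = measure_parameters(generate_airway_tree(spec))
            target = TreeSpec(**{**spec.__dict__,
                                 "volume": base.volume * rng.uniform(0.95, 1.05),
                                 "total_length": base.total_length * rng.uniform(0.97, 1.03)})
            p = measure_parameters(generate_airway_tree(target))
            assert abs(p.t_d - target.t_d) / target.t_d <= 0.01
            assert abs(p.b_a - target.b_a) <= 0.5
            assert abs(p.volume - target.volume) / target.volume <= 0.01
            assert abs(p.total_length - target.total_length) / target.total_length <= 0.01

    def test_volume_against_per_segment_voxelization(self):
        """Analytic cylinder-sum volume vs brute-force mesh voxelization."""
        import trimesh

        def mesh_voxel_volume(mesh, pitch):
            # voxel-center membership by z-ray crossing parity against the
            # triangle soup; no analytic cylinder formula involved
            tri = mesh.triangles  # (m, 3, 3)
            lo, hi = mesh.bounds
            xs = np.arange(lo[0] + pitch / 2, hi[0], pitch)
            ys = np.arange(lo[1] + pitch / 2, hi[1], pitch)
            zs = np.arange(lo[2] + pitch / 2, hi[2], pitch)
            px, py = np.meshgrid(xs, ys, indexing="ij")
            pts2 = np.stack([px.ravel(), py.ravel()], axis=1)
            counts = np.zeros((len(pts2), len(zs)), dtype=int)
            a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
            for A, B, C in zip(a, b, c):
                # 2-D point-in-triangle (xy projection) via sign of cross products
                d1 = (pts2[:, 0] - B[0]) * (A[1] - B[1]) - (A[0] - B[0]) * (pts2[:, 1] - B[1])
                d2 = (pts2[:, 0] - C[0]) * (B[1] - C[1]) - (B[0] - C[0]) * (pts2[:, 1] - C[1])
                d3 = (pts2[:, 0] - A[0]) * (C[1] - A[1]) - (C[0] - A[0]) * (pts2[:, 1] - A[1])
                inside = ((d1 < 0) & (d2 < 0) & (d3 < 0)) | ((d1 > 0) & (d2 > 0) & (d3 > 0))
                if not inside.any():
                    continue
                n = np.cross(B - A, C - A)
                if abs(n[2]) < 1e-14:
                    continue
                zi = A[2] - (n[0] * (pts2[inside, 0] - A[0])
                             + n[1] * (pts2[inside, 1] - A[1])) / n[2]
                counts[inside] += zi[:, None] > zs[None, :]
            return (counts % 2 == 1).sum() * pitch**3

        tree = generate_airway_tree(TreeSpec(t_d=16.0, b_a=80.0, n_generations=3, seed=5))
        voxel_volume = sum(
            mesh_voxel_volume(
                trimesh.creation.cylinder(radius=s.radius, height=s.length, sections=64),
                pitch=s.radius / 10.0)
            for s in tree.segments)
        assert voxel_volume == pytest.approx(tree.volume, rel=0.02)


class TestMeasure:
    def test_carina_angle_from_symmetric_daughters(self):
        """Daughters at +-38.405 deg off the trachea axis give b_a = 76.81."""
        tree = generate_airway_tree(TreeSpec(t_d=17.0, b_a=76.81, n_generations=3, seed=0))
        g1 = [s for s in tree.segments if s.generation == 1]
        off_axis = [math.degrees(math.acos(abs(np.dot(s.axis, [0, 0, -1])))) for s in g1]
        assert off_axis == pytest.approx([38.405, 38.405], abs=1e-9)
        assert measure_parameters(tree).b_a == pytest.approx(76.81, abs=1e-9)

    def test_constant_diameter_trachea(self):
        tree = generate_airway_tree(TreeSpec(t_d=17.0, b_a=80.0, n_generations=3, seed=0))
        assert measure_parameters(tree).t_d == pytest.approx(17.0, abs=1e-12)

    def test_angle_matches_centerline_sampling_oracle(self):
        """b_a equals a brute-force angle from densely sampled centerline points."""
        tree = generate_airway_tree(TreeSpec(
            t_d=15.5, b_a=88.0, n_generations=4, asymmetry_angle=0.25, seed=11))
        g1 = [s for s in tree.segments if s.generation == 1]
        dirs = []
        for s in g1:
            ts = np.linspace(0.0, 0.3, 200)  # points near the carina
            pts = s.proximal[None, :] + ts[:, None] * (s.distal - s.proximal)[None, :]
            d = pts[-1] - pts[0]
            dirs.append(d / np.linalg.norm(d))
        brute = math.degrees(math.acos(np.clip(np.dot(dirs[0], dirs[1]), -1, 1)))
        assert measure_parameters(tree).b_a == pytest.approx(brute, abs=0.5)

    def test_missing_main_bronchi_is_an_error(self):
        tube = single_tube(10.0, 50.0)
        with pytest.raises(ValueError, match="at least"):
            measure_parameters(tube)
        three_chain = upper_airway_surrogate()
        with pytest.raises(ValueError, match="carina"):
            measure_parameters(three_chain)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HRTParameters(t_d=-1, b_a=80, volume=1, total_length=1)
        with pytest.raises(ValueError):
            HRTParameters(t_d=15, b_a=181, volume=1, total_length=1)


class TestInvariants:
    def test_generated_trees_are_strictly_bifurcating(self, mm_tree):
        validate_tree(mm_tree, strict_bifurcation=True)

    def test_segment_invariants(self, mm_tree):
        for s in mm_tree.segments:
            assert s.diameter > 0 and s.length > 0
            if s.parent_id is not None:
                parent = mm_tree.segment(s.parent_id)
                assert np.allclose(s.proximal, parent.distal)
                assert s.generation == parent.generation + 1

    def test_broken_trees_rejected(self):
        seg = AirwaySegment(id=0, parent_id=None, generation=0,
                            proximal=[0, 0, 0], distal=[0, 0, -10], diameter=10.0,
                            terminal=False)
        with pytest.raises(ValueError):
            validate_tree(AirwayTree(segments=[seg]))  # non-terminal, no children

    def test_ua1_fixture_shape(self):
        ua = upper_airway_surrogate()
        validate_tree(ua)
        # three right-angle direction changes and a 6 mm constriction
        axes = [s.axis for s in ua.segments]
        turns = [math.degrees(math.acos(np.clip(np.dot(a, b), -1, 1)))
                 for a, b in zip(axes, axes[1:])]
        assert sum(1 for t in turns if abs(t - 90.0) < 1e-9) == 3
        assert min(s.diameter for s in ua.segments) == 6.0
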