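"""Per-segment metrics, branching angles and inter-vessel distances."""

import numpy as np
import pytest

from vasckit.graph import VoxelVolume
from vasckit.morphometry import (
    ZeroChordError,
    branching_angles,
    cumulative_volume_by_order,
    grouped_summary,
    intervessel_midpoint_distance,
    intervessel_voxel_distance,
    segment_metrics,
)
from vasckit.ordering import OrderingResult, compute_ordering
from vasckit.graph import find_root

from conftest import graph_from_segments, straight_segment


class TestSegmentMetrics:
    def test_straight_segment_closed_form(self):
        g = graph_from_segments([straight_segment(radius=10.0)])
        row = segment_metrics(g).loc[0]
        assert row["length"] == pytest.approx(100.0)
        assert row["tortuosity"] == pytest.approx(1.0)
        assert row["length_radius_ratio"] == pytest.approx(10.0)
        assert row["volume"] == pytest.approx(np.pi * 100.0 * 100.0)  # ~31415.9 μm³
        assert row["chord"] == pytest.approx(100.0)

    def test_literal_tortuosity_is_inverse(self):
        seg = straight_segment(n_points=11)
        seg.points[5] += np.array([0.0, 20.0, 0.0])
        g = graph_from_segments([seg])
        t = segment_metrics(g).loc[0, "tortuosity"]
        t_lit = segment_metrics(g, literal_tortuosity=True).loc[0, "tortuosity"]
        assert t > 1.0
        assert t_lit == pytest.approx(1.0 / t)

    @pytest.mark.parametrize("step_deg", [5.0, 1.0])
    def test_semicircle_tortuosity_converges_to_half_pi(self, step_deg):
        theta = np.radians(np.arange(0.0, 180.0 + step_deg, step_deg))
        R = 500.0
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros_like(theta)])
        from vasckit.graph import Segment

        seg = Segment(id=0, start_node=0, end_node=1, points=pts,
                      radii=np.full(len(pts), 5.0))
        g = graph_from_segments([seg])
        tol = 1e-3 if step_deg == 1.0 else 2e-2
        assert segment_metrics(g).loc[0, "tortuosity"] == pytest.approx(np.pi / 2, rel=tol)

    def test_zero_chord_flagged(self):
        from vasckit.graph import Segment

        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 0, 0]], dtype=float)
        seg = Segment(id=0, start_node=0, end_node=0, points=pts, radii=np.ones(3))
        from vasckit.graph import Node, SpatialGraph

        g = SpatialGraph.build([Node(id=0, position=np.zeros(3))], [seg])
        with pytest.raises(ZeroChordError):
            segment_metrics(g)

    def test_tortuosity_at_least_one_on_random_trees(self, medium_tree):
        table = segment_metrics(medium_tree)
        assert (table["tortuosity"] >= 1.0 - 1e-12).all()
        assert (table["length"] >= table["chord"] - 1e-9).all()


class TestBranchingAngles:
    def test_symmetric_y(self):
        parent = straight_segment(0, (0, 0, 0), (0, 0, 100), start_node=0, end_node=1)
        off = 100 * np.sin(np.radians(30.0)), 100 * np.cos(np.radians(30.0))
        c1 = straight_segment(1, (0, 0, 100), (off[0], 0, 100 + off[1]),
                              start_node=1, end_node=2)
        c2 = straight_segment(2, (0, 0, 100), (-off[0], 0, 100 + off[1]),
                              start_node=1, end_node=3)
        g = graph_from_segments([parent, c1, c2])
        table = branching_angles(g, root=0)
        cc = table[table["kind"] == "child_child"]["angle_deg"]
        cp = table[table["kind"] == "child_parent"]["angle_deg"]
        assert cc.to_list() == [pytest.approx(60.0)]
        assert sorted(cp) == [pytest.approx(150.0), pytest.approx(150.0)]

    def test_straight_continuation_scores_180(self):
        a = straight_segment(0, (0, 0, 0), (100, 0, 0), start_node=0, end_node=1)
        b = straight_segment(1, (100, 0, 0), (200, 0, 0), start_node=1, end_node=2)
        g = graph_from_segments([a, b])
        table = branching_angles(g, root=0)
        cp = table[table["kind"] == "child_parent"]["angle_deg"]
        assert cp.to_list() == [pytest.approx(180.0)]

    def test_perpendicular_side_branch(self):
        a = straight_segment(0, (0, 0, 0), (100, 0, 0), start_node=0, end_node=1)
        b = straight_segment(1, (100, 0, 0), (200, 0, 0), start_node=1, end_node=2)
        c = straight_segment(2, (100, 0, 0), (100, 80, 0), start_node=1, end_node=3)
        g = graph_from_segments([a, b, c])
        table = branching_angles(g, root=0)
        cp = table[(table["kind"] == "child_parent") & (table["segment_a"] == 2)]
        assert cp["angle_deg"].to_list() == [pytest.approx(90.0)]
        # trifurcation-free: two children -> exactly one child_child pair
        assert (table["kind"] == "child_child").sum() == 1


class TestMidpointIVD:
    def test_two_parallel_segments(self):
        a = straight_segment(0, (0, 0, 0), (100, 0, 0), start_node=0, end_node=1)
        b = straight_segment(1, (0, 30, 0), (100, 30, 0), start_node=2, end_node=3)
        ivd = intervessel_midpoint_distance(graph_from_segments([a, b]))
        assert np.allclose(ivd.to_numpy(), [30.0, 30.0])

    def test_matches_brute_force_on_random_segments(self):
        rng = np.random.default_rng(8)
        segs = []
        for i in range(20):
            start = rng.uniform(0, 1000, 3)
            end = start + rng.uniform(10, 100, 3)
            segs.append(straight_segment(i, start, end, radius=2.0,
                                         start_node=2 * i, end_node=2 * i + 1))
        g = graph_from_segments(segs)
        ivd = intervessel_midpoint_distance(g)
        mids = np.array([0.5 * (s.points[0] + s.points[-1]) for s in segs])
        d = np.linalg.norm(mids[:, None] - mids[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(ivd.to_numpy(), d.min(axis=1))

    def test_single_segment_rejected(self):
        g = graph_from_segments([straight_segment()])
        with pytest.raises(ValueError):
            intervessel_midpoint_distance(g)

    def test_translation_invariance(self, binary_tree4):
        base = intervessel_midpoint_distance(binary_tree4)
        shifted = binary_tree4.copy()
        for s in shifted.segments.values():
            s.points = s.points + np.array([1000.0, -500.0, 250.0])
        assert np.allclose(intervessel_midpoint_distance(shifted).to_numpy(),
                           base.to_numpy())


class TestVoxelIVD:
    def test_full_mask_all_zero(self):
        mask = VoxelVolume(np.ones((4, 4, 4), dtype=bool), 10.0)
        field, _ = intervessel_voxel_distance(mask)
        assert not field.data.any()

    def test_zone_with_vessels_is_closer(self):
        mask = np.zeros((4, 16, 16), dtype=bool)
        mask[:, :, 0] = True  # vessels along one face
        labels = np.ones((4, 16, 16), dtype=np.uint8)
        labels[:, :, 8:] = 2
        field, summary = intervessel_voxel_distance(
            VoxelVolume(mask, 10.0), VoxelVolume(labels, 10.0))
        assert summary.loc[1, "mean"] < summary.loc[2, "mean"]

    def test_corner_distance_analytic(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[:, 0, 0] = True  # tube along z at the y=x=0 edge
        field, _ = intervessel_voxel_distance(VoxelVolume(mask, 50.0))
        want = np.hypot(7, 7) * 50.0
        assert field.data[3, 7, 7] == pytest.approx(want, abs=50.0)

    def test_grid_mismatch_rejected(self):
        mask = VoxelVolume(np.ones((4, 4, 4), dtype=bool), 10.0)
        labels = VoxelVolume(np.ones((5, 4, 4), dtype=np.uint8), 10.0)
        with pytest.raises(ValueError):
            intervessel_voxel_distance(mask, labels)


class TestAggregation:
    def test_cumulative_volume_equal_segments(self):
        segs = [straight_segment(i, (0, 0, 100 * i), (0, 0, 100 * (i + 1)), radius=10.0,
                                 start_node=i, end_node=i + 1) for i in range(9)]
        g = graph_from_segments(segs)
        metrics = segment_metrics(g)
        ordering = OrderingResult(root=0, strahler={i: i + 1 for i in range(9)})
        frac = cumulative_volume_by_order(metrics, ordering)
        assert frac.loc[4] == pytest.approx(4 / 9)
        assert frac.iloc[-1] == pytest.approx(1.0)

    def test_cumulative_volume_matches_direct_sums(self, medium_tree):
        metrics = segment_metrics(medium_tree)
        ordering = compute_ordering(medium_tree, find_root(medium_tree))
        frac = cumulative_volume_by_order(metrics, ordering)
        total = metrics["volume"].sum()
        running = 0.0
        for order in sorted(frac.index):
            ids = [sid for sid, o in ordering.strahler.items() if o == order]
            running += metrics.loc[ids, "volume"].sum()
            assert frac.loc[order] == pytest.approx(running / total)
        assert total == pytest.approx(medium_tree.total_volume())

    def test_unordered_segment_rejected(self):
        g = graph_from_segments([straight_segment()])
        metrics = segment_metrics(g)
        with pytest.raises(ValueError):
            cumulative_volume_by_order(metrics, OrderingResult(root=0, strahler={}))

    def test_grouped_summary_single_segment(self):
        g = graph_from_segments([straight_segment()])
        metrics = segment_metrics(g)
        out = grouped_summary(metrics, OrderingResult(root=0, strahler={0: 1}))
        assert len(out) == 1
        assert out.loc[1, "n"] == 1
        assert out.loc[1, "radius_sd"] == 0.0

    def test_grouped_summary_constant_radii_per_order(self, binary_tree4):
        ordering = compute_ordering(binary_tree4, find_root(binary_tree4))
        metrics = segment_metrics(binary_tree4)
        out = grouped_summary(metrics, ordering)
        # murray split with a = 0.8 gives order-dependent but not constant radii;
        # rebuild with a = 1 so radii are constant within each order
        from vasckit.synthetic import TreeSpec, generate_tree

        g = generate_tree(TreeSpec(depth=4, branching_ratio=2.0, asymmetry=1.0,
                                   tortuosity_amp=0.0, seed=1))
        o = compute_ordering(g, find_root(g))
        out = grouped_summary(segment_metrics(g), o)
        assert np.allclose(out["radius_sd"], 0.0)
        assert out["n"].to_list() == [8, 4, 2, 1]
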