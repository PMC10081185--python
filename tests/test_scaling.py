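"""Branching ratio, Murray's law, outlier removal and F tests."""

import numpy as np
import pytest

from vasckit.graph import find_root
from vasckit.morphometry import segment_metrics
from vasckit.ordering import compute_ordering, order_counts
from vasckit.scaling import (
    BifurcationRecord,
    OutlierConfig,
    compare_scaling,
    extra_ss_ftest,
    extract_bifurcations,
    extrapolate_orders,
    fit_branching_ratio,
    murray_regression,
    remove_outliers,
)
from vasckit.synthetic import TreeSpec, generate_tree

# per-Strahler-order segment counts of the whole-kidney arterial network
KIDNEY_ORDER_COUNTS = {1: 5105, 2: 3030, 3: 1295, 4: 516, 5: 150, 6: 69, 7: 20, 8: 4, 9: 1}


class TestBranchingRatioProperties:
    """Hypothesis invariants: exact geometric tables and line-safety."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(gamma=st.floats(1.2, 5.0), n_orders=st.integers(3, 10),
           scale=st.floats(1.0, 1e4))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_exact_geometric_table_recovers_gamma(self, gamma, n_orders, scale):
        counts = {o: scale * gamma ** (n_orders - o) for o in range(1, n_orders + 1)}
        fit = fit_branching_ratio(counts)
        assert fit.gamma == pytest.approx(gamma, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    @given(slope=st.floats(-3.0, 3.0), intercept=st.floats(-10.0, 10.0),
           q=st.floats(1e-5, 0.05))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_outlier_removal_never_touches_exact_lines(self, slope, intercept, q):
        x = np.linspace(0.0, 5.0, 30)
        y = slope * x + intercept
        kept, removed = remove_outliers(x, y, OutlierConfig(q=q))
        assert len(removed) == 0


class TestBranchingRatio:
    def test_geometric_counts_exact(self):
        fit = fit_branching_ratio({1: 8, 2: 4, 3: 2, 4: 1})
        assert fit.gamma == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        fit = fit_branching_ratio({1: 9, 2: 3, 3: 1})
        assert fit.gamma == pytest.approx(3.0, abs=1e-12)

    def test_kidney_counts_reproduce_published_ratio(self):
        fit = fit_branching_ratio(KIDNEY_ORDER_COUNTS)
        assert fit.gamma == pytest.approx(2.921, abs=0.02)

    def test_scale_invariance_in_counts(self):
        a = fit_branching_ratio({1: 8, 2: 4, 3: 2, 4: 1})
        b = fit_branching_ratio({1: 8000, 2: 4000, 3: 2000, 4: 1000})
        assert b.gamma == pytest.approx(a.gamma)
        assert b.n0 == pytest.approx(1000 * a.n0)

    def test_too_few_orders_rejected(self):
        with pytest.raises(ValueError):
            fit_branching_ratio({1: 5})


class TestBifurcations:
    def test_binary_tree_depth3_has_three_junctions(self):
        g = generate_tree(TreeSpec(depth=3, branching_ratio=2.0, tortuosity_amp=0.0, seed=1))
        o = compute_ordering(g, find_root(g))
        records = extract_bifurcations(g, segment_metrics(g), o)
        assert len(records) == 3
        assert all(len(r.child_radii) == 2 for r in records)

    def test_path_graph_has_none(self):
        from conftest import graph_from_segments, straight_segment

        g = graph_from_segments([
            straight_segment(0, (0, 0, 0), (1, 0, 0), start_node=0, end_node=1),
            straight_segment(1, (1, 0, 0), (2, 0, 0), start_node=1, end_node=2),
        ])
        o = compute_ordering(g, 0)
        assert extract_bifurcations(g, segment_metrics(g), o) == []

    def test_trifurcation_single_record(self):
        from conftest import graph_from_segments, straight_segment

        segs = [straight_segment(0, (0, 0, 0), (0, 0, 10), start_node=0, end_node=1)]
        for i, dx in enumerate((-5, 0, 5)):
            segs.append(straight_segment(i + 1, (0, 0, 10), (dx, 3, 18),
                                         start_node=1, end_node=2 + i))
        g = graph_from_segments(segs)
        o = compute_ordering(g, 0)
        records = extract_bifurcations(g, segment_metrics(g), o)
        assert len(records) == 1
        assert len(records[0].child_radii) == 3


class TestMurrayRegression:
    @pytest.mark.parametrize("asymmetry", [0.3, 0.6, 0.8, 1.0])
    def test_murray_tree_lies_on_identity_line(self, asymmetry):
        g = generate_tree(TreeSpec(depth=5, asymmetry=asymmetry, tortuosity_amp=0.0, seed=4))
        o = compute_ordering(g, find_root(g))
        records = extract_bifurcations(g, segment_metrics(g), o)
        fit = murray_regression(records)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.intercept) < 1e-7
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_slope_is_unit_scale_invariant(self):
        g = generate_tree(TreeSpec(depth=5, asymmetry=0.7, seed=5))
        o = compute_ordering(g, find_root(g))
        records = extract_bifurcations(g, segment_metrics(g), o)
        fit_um = murray_regression(records, unit_scale=1.0)
        fit_m = murray_regression(records, unit_scale=1e-6)
        assert fit_m.slope == pytest.approx(fit_um.slope, rel=1e-9)
        assert fit_m.intercept == pytest.approx(fit_um.intercept * 1e-6, rel=1e-6, abs=1e-15)

    def test_symmetric_split_point_on_line(self):
        records = [
            BifurcationRecord(node_id=i, parent_segment=i, parent_radius=1.0,
                              child_radii=[2 ** (-1 / 3), 2 ** (-1 / 3)])
            for i in range(3)
        ]
        x = sum(r**3 for r in records[0].child_radii) ** (1 / 3)
        assert x == pytest.approx(1.0)
        fit = murray_regression(records + [
            BifurcationRecord(node_id=9, parent_segment=9, parent_radius=2.0,
                              child_radii=[2 ** (2 / 3), 2 ** (2 / 3)])])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_records_rejected(self):
        with pytest.raises(ValueError):
            murray_regression([])


class TestOutliers:
    def _line(self, n=50, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 10, n)
        y = 2.0 * x + 1.0 + (rng.normal(0, noise, n) if noise else 0.0)
        return x, y

    def test_exact_line_keeps_everything(self):
        x, y = self._line()
        kept, removed = remove_outliers(x, y, OutlierConfig(q=0.05))
        assert len(removed) == 0
        assert len(kept) == len(x)

    def test_single_gross_outlier_removed(self):
        x, y = self._line(noise=0.1, seed=3)
        y[17] += 100.0
        kept, removed = remove_outliers(x, y, OutlierConfig(q=0.0005))
        assert removed.tolist() == [17]

    def test_q_zero_removes_nothing(self):
        x, y = self._line(noise=1.0, seed=4)
        y[5] += 50.0
        kept, removed = remove_outliers(x, y, OutlierConfig(q=0.0))
        assert len(removed) == 0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.ones(10), np.arange(10.0), OutlierConfig())

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.arange(3.0), np.arange(3.0), OutlierConfig())


class TestFTest:
    def test_equal_ss_gives_f_zero_p_one(self):
        result = extra_ss_ftest(1.5, 4, 1.5, 2)
        assert result.f == 0.0
        assert result.p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        result = extra_ss_ftest(2.0, 4, 1.0, 2)
        assert result.f == pytest.approx(((2 - 1) / 2) / (1 / 2))
        assert result.df_num == 2
        assert result.df_den == 2

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            extra_ss_ftest(2.0, 2, 1.0, 0)
        with pytest.raises(ValueError):
            extra_ss_ftest(1.0, 4, 2.0, 2)


class TestCompareScaling:
    def _dataset(self, slope, orders=range(1, 10), r9=1000.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return {o: r9 * np.exp(slope * (o - 9)) * np.exp(rng.normal(0, noise))
                for o in orders}

    def test_identical_datasets_f_zero(self):
        d = self._dataset(0.4)
        out = compare_scaling(d, d)
        assert out.ftest.f == pytest.approx(0.0, abs=1e-9)

    def test_normalisation_contract(self):
        d = self._dataset(0.4, r9=123.0)
        out = compare_scaling(d, self._dataset(0.3, r9=77.0))
        # after normalisation ln(radius at ref order) = 0, so the separate
        # fits must pass through (9, 0)
        for slope, intercept, _ in out.fits.values():
            assert slope * 9 + intercept == pytest.approx(0.0, abs=1e-12)

    def test_different_slopes_match_brute_force_ss(self):
        a = self._dataset(0.3, noise=0.05, seed=1)
        b = self._dataset(0.5, noise=0.05, seed=2)
        out = compare_scaling(a, b)
        ln_a = np.log(np.array([a[o] for o in range(1, 10)]) / a[9])
        ln_b = np.log(np.array([b[o] for o in range(1, 10)]) / b[9])
        o_arr = np.arange(1, 10, dtype=float)

        def ss(x, y):
            s, i = np.polyfit(x, y, 1)
            return ((y - s * x - i) ** 2).sum()

        ss_alt = ss(o_arr, ln_a) + ss(o_arr, ln_b)
        x_all = np.concatenate([o_arr, o_arr])
        y_all = np.concatenate([ln_a, ln_b])
        ss_null = ss(x_all, y_all)
        want_f = ((ss_null - ss_alt) / 2) / (ss_alt / (18 - 4))
        assert out.ftest.f == pytest.approx(want_f, rel=1e-9)
        assert out.ftest.f > 0

    def test_missing_ref_order_rejected(self):
        with pytest.raises(ValueError):
            compare_scaling({1: 1.0, 2: 2.0}, {1: 1.0, 9: 5.0}, ref_order=9)


class TestLogLinearRecovery:
    @pytest.mark.parametrize("slope", [0.2, 0.35, 0.5])
    def test_radius_slope_recovered_within_5pct(self, slope):
        g = generate_tree(TreeSpec(depth=7, branching_ratio=2.5, radius_law="log_linear",
                                   log_linear_slope=slope, seed=6))
        o = compute_ordering(g, find_root(g))
        metrics = segment_metrics(g)
        orders = np.array([o.strahler[sid] for sid in metrics.index], dtype=float)
        mean_by_order = {int(v): metrics["radius"][orders == v].mean()
                         for v in np.unique(orders)}
        xs = np.array(sorted(mean_by_order))
        ys = np.log([mean_by_order[int(v)] for v in xs])
        fitted = np.polyfit(xs, ys, 1)[0]
        assert abs(fitted - slope) / slope < 0.05


class TestExtrapolation:
    def test_cases(self):
        assert extrapolate_orders(100, 100, 2.5) == 0
        assert extrapolate_orders(10, 80, 2.0) == 3
        assert extrapolate_orders(5105, 5105 * 2.92**3, 2.92) == 3

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            extrapolate_orders(10, 100, 1.0)

    def test_negative_clipped_to_zero(self):
        assert extrapolate_orders(1000, 10, 3.0) == 0
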