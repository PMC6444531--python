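"""Edge matrix structure, DP optimality vs brute force, baselines, splines."""

import numpy as np
import pytest

import chronopick as cp
from chronopick.objectives import ObjectiveSpec
from chronopick.selector import EdgeMatrix


def _random_edges(rng, N=12):
    W = rng.uniform(0.0, 1.0, size=(N + 2, N + 2))
    return EdgeMatrix(weights=W)


def _grid(n):
    return cp.TimeGrid(np.linspace(0.0, 1.0, n))


class TestEdgeMatrix:
    def test_backward_edges_infinite(self):
        rng = np.random.default_rng(0)
        e = _random_edges(rng, 5)
        assert np.all(np.isinf(e.weights[np.tril_indices(7)]))

    def test_linear_samples_zero_interior_edges(self):
        g = _grid(11)
        vals = np.outer([1.0, -2.0, 0.5], g.times) + 1.0
        s = cp.SampledCurves(grid=g, values=vals)
        e = cp.build_edge_matrix(s, ObjectiveSpec("f1"))
        sub = e.weights[1:12, 1:12]
        fwd = np.triu_indices(11, k=1)
        assert np.max(sub[fwd]) < 1e-28

    def test_adjacent_edges_zero(self, fitted_samples):
        _, samples = fitted_samples
        e = cp.build_edge_matrix(samples, ObjectiveSpec("f1"))
        N = samples.grid.n
        for i in range(1, N):
            assert e.weights[i, i + 1] == 0.0

    def test_single_quadratic_sample_hand_value(self):
        # one sample w(t)=t² on the grid (0, 0.5, 1): edge(1,3) is the
        # trapezoid of (t² − t)² on those three points = 0.03125
        g = _grid(3)
        s = cp.SampledCurves(grid=g, values=(g.times**2)[None, :])
        e = cp.build_edge_matrix(s, ObjectiveSpec("f1"))
        hand = 0.5 * (0.25 - 0.5) ** 2   # only the midpoint deviates; h = 0.5
        np.testing.assert_allclose(e.weights[1, 3], hand, rtol=1e-12)

    def test_pin_endpoints(self, fitted_samples):
        _, samples = fitted_samples
        e = cp.build_edge_matrix(samples, ObjectiveSpec("f1"), pin_endpoints=True)
        sel = cp.dp_select(e, 4)
        assert sel.indices[0] == 1 and sel.indices[-1] == samples.grid.n


class TestDPOptimality:
    def test_matches_brute_force_randomised(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            e = _random_edges(rng, N=12)
            for M in range(2, 7):
                dp = cp.dp_select(e, M)
                bf = cp.brute_force_select(e, M)
                assert dp.indices == bf.indices
                assert dp.objective_estimate == bf.objective_estimate

    def test_tie_break_lexicographic(self):
        # all-equal weights: every M-subset ties; both must pick (1, 2, .., M)
        N = 8
        e = EdgeMatrix(weights=np.ones((N + 2, N + 2)))
        for M in (1, 3, 5):
            assert cp.dp_select(e, M).indices == tuple(range(1, M + 1))
            assert cp.brute_force_select(e, M).indices == tuple(range(1, M + 1))

    def test_full_selection_zero_cost(self, fitted_samples):
        _, samples = fitted_samples
        e = cp.build_edge_matrix(samples, ObjectiveSpec("f1"))
        N = samples.grid.n
        sel = cp.dp_select(e, N)
        assert sel.indices == tuple(range(1, N + 1))
        assert sel.objective_estimate < 1e-24

    def test_single_point_selection_matches_exhaustive(self):
        # M=1 on a single triangular-bump sample: the DP choice must agree
        # with exhaustive scoring of every candidate point.  (Under constant
        # extrapolation the apex is the *worst* single point — it pins the
        # whole reconstruction at the bump height — so the optimum is a
        # baseline point; ties break to the lexicographically smallest.)
        g = _grid(9)
        apex = 5
        v = np.zeros(9)
        v[apex] = 1.0                 # triangular bump after linear interp
        s = cp.SampledCurves(grid=g, values=v[None, :])
        e = cp.build_edge_matrix(s, ObjectiveSpec("f1"))
        sel = cp.dp_select(e, 1)
        spec = ObjectiveSpec("f1")
        costs = {i: cp.estimate_objective((i,), s, spec) for i in range(1, 10)}
        best_cost = min(costs.values())
        best = min(i for i, c in costs.items() if c <= best_cost + 1e-15)
        assert sel.indices == (best,)
        assert costs[apex + 1] == max(costs.values())

    def test_cost_non_increasing_in_m(self, fitted_samples):
        _, samples = fitted_samples
        e = cp.build_edge_matrix(samples, ObjectiveSpec("f1"))
        costs = [cp.dp_select(e, M).objective_estimate
                 for M in range(1, samples.grid.n + 1)]
        assert all(b <= a + 1e-15 for a, b in zip(costs, costs[1:]))

    def test_dp_beats_baselines_on_its_objective(self, fitted_samples):
        _, samples = fitted_samples
        spec = ObjectiveSpec("f1")
        e = cp.build_edge_matrix(samples, spec)
        N = samples.grid.n
        for M in (3, 5, 8):
            dp_cost = cp.dp_select(e, M).objective_estimate
            for strat, seed in (("even", 0), ("random", 1), ("random", 2)):
                b = cp.baseline_select(N, M, strat, seed=seed)
                assert dp_cost <= cp.estimate_objective(b, samples, spec) + 1e-12

    def test_path_cost_equals_edge_sum(self):
        rng = np.random.default_rng(3)
        e = _random_edges(rng, N=10)
        sel = cp.dp_select(e, 4)
        nodes = [0, *sel.indices, 11]
        total = sum(e.weights[a, b] for a, b in zip(nodes, nodes[1:]))
        assert abs(total - sel.objective_estimate) < 1e-12

    def test_m_out_of_range(self):
        e = EdgeMatrix(weights=np.ones((7, 7)))
        with pytest.raises(ValueError):
            cp.dp_select(e, 6)
        with pytest.raises(ValueError):
            cp.dp_select(e, 0)


class TestBaselines:
    def test_even_saturation(self):
        assert cp.baseline_select(12, 12, "even").indices == tuple(range(1, 13))

    def test_even_endpoints(self):
        assert cp.baseline_select(5, 2, "even").indices == (1, 5)

    def test_random_reproducible(self):
        a = cp.baseline_select(20, 6, "random", seed=9)
        b = cp.baseline_select(20, 6, "random", seed=9)
        assert a.indices == b.indices
        assert len(set(a.indices)) == 6

    def test_even_strictly_increasing_all_nm(self):
        for N in (5, 7, 12, 25):
            for M in range(1, N + 1):
                idx = cp.baseline_select(N, M, "even").indices
                assert len(idx) == M
                assert all(b > a for a, b in zip(idx, idx[1:]))
                assert 1 <= idx[0] and idx[-1] <= N


class TestSplineMode:
    def test_degree_one_reduces_to_linear_dp(self, fitted_samples):
        _, samples = fitted_samples
        spec = ObjectiveSpec("f1", interpolation="spline", spline_degree=1)
        sel_s = cp.spline_select(samples, spec, 5)
        sel_l = cp.dp_select(cp.build_edge_matrix(samples, ObjectiveSpec("f1")), 5)
        assert sel_s.indices == sel_l.indices

    def test_spline_selection_not_worse_than_linear_selection(self, fitted_samples):
        from chronopick.selector import _exact_spline_score
        _, samples = fitted_samples
        spec = ObjectiveSpec("f1", interpolation="spline", spline_degree=3)
        sel_s = cp.spline_select(samples, spec, 6)
        sel_l = cp.dp_select(cp.build_edge_matrix(samples, ObjectiveSpec("f1")), 6)
        lin_rescored = _exact_spline_score(samples.values, samples.grid.times,
                                           list(sel_l.indices), spec)
        assert sel_s.objective_estimate <= lin_rescored + 1e-12

    def test_symmetric_samples_forward_backward_agree(self):
        g = _grid(21)
        t = g.times
        vals = np.stack([np.exp(-0.5 * ((t - 0.5) / w) ** 2)
                         for w in (0.1, 0.15, 0.2)])   # symmetric about 0.5
        s = cp.SampledCurves(grid=g, values=vals)
        spec = ObjectiveSpec("f1", interpolation="spline", spline_degree=2)
        sel = cp.spline_select(s, spec, 5)
        mirrored = tuple(sorted(22 - i for i in sel.indices))
        ms = cp.Selection(indices=mirrored)
        from chronopick.selector import _exact_spline_score
        a = _exact_spline_score(vals, t, list(sel.indices), spec)
        b = _exact_spline_score(vals, t, list(mirrored), spec)
        assert abs(a - b) < 1e-9

    def test_m_must_exceed_degree(self, fitted_samples):
        _, samples = fitted_samples
        spec = ObjectiveSpec("f1", interpolation="spline", spline_degree=3)
        with pytest.raises(ValueError):
            cp.spline_select(samples, spec, 3)
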