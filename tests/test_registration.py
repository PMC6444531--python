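"""SRSF transform, elastic pairwise/template alignment, sphere geometry."""

import warnings

import numpy as np
import pytest

import chronopick as cp
from chronopick.registration import (
    grid_norm,
    segment_inner,
    trapezoid_weights,
    warp_srsf,
)


def _grid(n):
    return cp.TimeGrid(np.linspace(0.0, 1.0, n))


class TestSRSF:
    @pytest.mark.parametrize(
        "f,expected_q",
        [
            (lambda t: np.full_like(t, 2.0), lambda t: np.zeros_like(t)),
            (lambda t: t, lambda t: np.ones_like(t)),
        ],
    )
    def test_flat_and_linear(self, f, expected_q):
        g = _grid(51)
        q = cp.srsf_transform(g, f(g.times))
        np.testing.assert_allclose(q.q, expected_q(g.times), atol=1e-12)

    def test_quadratic_matches_closed_form(self):
        # f = t² has q(t) = √(2t); finite differences are exact for quadratics
        # in the interior, so only the one-sided boundary points deviate.
        g = _grid(101)
        q = cp.srsf_transform(g, g.times**2)
        expected = np.sqrt(2 * g.times)
        h = g.times[1] - g.times[0]
        assert np.max(np.abs(q.q[1:] - expected[1:])) < np.sqrt(h)
        assert np.max(np.abs(q.q[2:] - expected[2:])) < 2 * h

    def test_nan_rejected(self):
        g = _grid(11)
        v = g.times.copy()
        v[3] = np.nan
        with pytest.raises(ValueError):
            cp.srsf_transform(g, v)

    def test_inverse_examples(self):
        g = _grid(11)
        const = cp.srsf_inverse(cp.SRSFCurve(grid=g, q=np.zeros(11), f0=3.0))
        np.testing.assert_allclose(const, 3.0)
        lin = cp.srsf_inverse(cp.SRSFCurve(grid=g, q=np.ones(11), f0=0.0))
        np.testing.assert_allclose(lin, g.times, atol=1e-12)

    def test_roundtrip_sine(self):
        g = _grid(101)
        f = np.sin(2 * np.pi * g.times)
        back = cp.srsf_inverse(cp.srsf_transform(g, f))
        assert np.max(np.abs(back - f)) < 1e-2

    def test_roundtrip_first_order_in_h(self):
        # the reconstruction error should shrink when the grid is refined
        errs = []
        for n in (51, 101, 201):
            g = _grid(n)
            f = np.sin(2 * np.pi * g.times) + 0.5 * g.times**3
            back = cp.srsf_inverse(cp.srsf_transform(g, f))
            errs.append(np.max(np.abs(back - f)))
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[0] / errs[2] > 2.0  # at least first order over a 4x refinement


class TestAlignPair:
    def test_self_alignment_is_identity(self, gauss_bump, unit_grid_101):
        q = cp.srsf_transform(unit_grid_101, gauss_bump)
        w, dy = cp.align_pair(q, q)
        assert dy < 1e-8
        assert np.max(np.abs(w.gamma - unit_grid_101.times)) < 0.02

    def test_recovers_exponential_warp(self, gauss_bump, unit_grid_101):
        t = unit_grid_101.times
        gamma0 = (np.exp(t) - 1.0) / (np.e - 1.0)
        warped = np.interp(gamma0, t, gauss_bump)   # f∘γ₀
        q_w = cp.srsf_transform(unit_grid_101, warped)
        q_f = cp.srsf_transform(unit_grid_101, gauss_bump)
        # γ aligning f onto f∘γ₀ is γ₀ itself
        w, _ = cp.align_pair(q_w, q_f)
        assert np.max(np.abs(w.gamma - gamma0)) < 0.05

    def test_distance_zero_for_identical(self, unit_grid_101):
        rng = np.random.default_rng(1)
        h = np.cumsum(rng.normal(size=101)) / 10.0
        q = cp.srsf_transform(unit_grid_101, h)
        _, dy = cp.align_pair(q, q)
        assert dy < 1e-8

    def test_alignment_never_increases_distance(self, unit_grid_101):
        # D_y(q1, q2) <= ||q1 - q2|| since the identity warp is feasible
        rng = np.random.default_rng(5)
        t = unit_grid_101.times
        for _ in range(5):
            f1 = np.sin(2 * np.pi * (t + rng.uniform(0, 1)))
            f2 = rng.uniform(0.5, 2) * np.exp(-0.5 * ((t - rng.uniform(0.2, 0.8)) / 0.1) ** 2)
            q1 = cp.srsf_transform(unit_grid_101, f1)
            q2 = cp.srsf_transform(unit_grid_101, f2)
            _, dy = cp.align_pair(q1, q2)
            assert dy <= grid_norm(q1.q - q2.q, t) + 1e-9

    def test_grid_mismatch_rejected(self):
        q1 = cp.srsf_transform(_grid(11), np.zeros(11))
        q2 = cp.srsf_transform(_grid(21), np.zeros(21))
        with pytest.raises(ValueError):
            cp.align_pair(q1, q2)


class TestAlignSet:
    def test_identical_curves(self, unit_grid_21):
        vals = np.tile(np.sin(2 * np.pi * unit_grid_21.times), (3, 1))
        cs = cp.CurveSet(grid=unit_grid_21, values=vals)
        ar = cp.align_set(cs)
        for w in ar.warps:
            assert np.max(np.abs(w.gamma - unit_grid_21.times)) < 1e-8
        assert np.all(ar.distances < 1e-8)

    def test_warped_family_realigns(self, gauss_bump, unit_grid_101):
        t = unit_grid_101.times
        gamma0 = (np.exp(t) - 1.0) / (np.e - 1.0)
        gamma0_inv = np.interp(t, gamma0, t)
        vals = np.stack([
            gauss_bump,
            np.interp(gamma0, t, gauss_bump),
            np.interp(gamma0_inv, t, gauss_bump),
        ])
        cs = cp.CurveSet(grid=unit_grid_101, values=vals)
        ar = cp.align_set(cs)
        unaligned = sum(
            np.trapezoid((vals[i] - vals[j]) ** 2, t)
            for i in range(3) for j in range(i + 1, 3)
        )
        aligned = sum(
            np.trapezoid((ar.aligned_values[i] - ar.aligned_values[j]) ** 2, t)
            for i in range(3) for j in range(i + 1, 3)
        )
        assert aligned < 0.05 * unaligned

    def test_needs_two_curves(self, unit_grid_21):
        cs = cp.CurveSet(grid=unit_grid_21, values=np.zeros((1, 21)) + 1.0)
        with pytest.raises(ValueError):
            cp.align_set(cs)


class TestWarpingFunction:
    def test_psi_unit_norm_and_monotone(self, unit_grid_101):
        t = unit_grid_101.times
        for gamma in (t, t**2, np.sqrt(t), (np.exp(2 * t) - 1) / (np.exp(2) - 1)):
            w = cp.WarpingFunction(grid=unit_grid_101, gamma=gamma)
            psi = w.psi()
            assert abs(segment_inner(psi, psi, t) - 1.0) < 1e-6
            assert np.all(np.diff(w.gamma) >= 0)

    def test_inverse_composes_to_identity(self, unit_grid_101):
        t = unit_grid_101.times
        w = cp.WarpingFunction(grid=unit_grid_101, gamma=t**2)
        comp = w(w.inverse().gamma)
        assert np.max(np.abs(comp - t)) < 1e-3

    def test_bad_endpoints_rejected(self, unit_grid_21):
        with pytest.raises(ValueError):
            cp.WarpingFunction(grid=unit_grid_21, gamma=unit_grid_21.times + 0.1)


class TestSphereGeometry:
    def _pair(self, n=101):
        g = _grid(n)
        base = cp.WarpingFunction(grid=g, gamma=g.times**2)
        point = base.inverse()
        return g, base, point

    def test_log_at_base_is_zero(self):
        _, base, _ = self._pair()
        v = cp.log_map(base, base)
        assert v.norm() < 1e-8

    def test_log_norm_equals_arccos(self):
        g, base, point = self._pair()
        v = cp.log_map(base, point)
        c = segment_inner(base.psi(), point.psi(), g.times)
        assert abs(v.norm() - np.arccos(np.clip(c, -1, 1))) < 1e-8

    def test_tangent_orthogonal_to_base(self):
        g, base, point = self._pair()
        v = cp.log_map(base, point)
        assert abs(segment_inner(v.v, base.psi(), g.times)) < 1e-6

    def test_exp_log_roundtrip(self):
        g, base, point = self._pair()
        back = cp.exp_map(base, cp.log_map(base, point))
        assert np.max(np.abs(back.gamma - point.gamma)) < 1e-6

    def test_exp_zero_is_base(self):
        g, base, _ = self._pair()
        out = cp.exp_map(base, np.zeros(g.n - 1))
        np.testing.assert_allclose(out.gamma, base.gamma, atol=1e-12)

    def test_exp_preserves_unit_norm(self):
        g, base, point = self._pair()
        rng = np.random.default_rng(0)
        for _ in range(5):
            raw = rng.normal(0, 0.1, g.n - 1)
            pb = base.psi()
            raw -= segment_inner(raw, pb, g.times) * pb   # project to tangent
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out = cp.exp_map(base, raw)
            psi = out.psi()
            assert abs(segment_inner(psi, psi, g.times) - 1.0) < 1e-8


class TestKarcherMean:
    def test_identity_fixed_point(self, unit_grid_21):
        ident = cp.WarpingFunction.identity(unit_grid_21)
        km = cp.karcher_mean_warps([ident, ident, ident])
        assert np.max(np.abs(km.gamma - unit_grid_21.times)) < 1e-10

    def test_single_warp(self, unit_grid_21):
        w = cp.WarpingFunction(grid=unit_grid_21, gamma=unit_grid_21.times**2)
        km = cp.karcher_mean_warps([w])
        np.testing.assert_allclose(km.gamma, w.gamma)

    def test_matches_geodesic_grid_search(self, unit_grid_101):
        # Fréchet-mean oracle: for two points the mean lies on the geodesic;
        # scan it finely and compare the summed squared geodesic distances.
        from chronopick.registration import _exp_psi
        g = unit_grid_101
        t = g.times
        w1 = cp.WarpingFunction(grid=g, gamma=t**2)
        w2 = w1.inverse()
        km = cp.karcher_mean_warps([w1, w2])
        v12 = cp.log_map(w1, w2)
        p1, p2 = w1.psi(), w2.psi()

        def frechet(psi):
            return sum(
                np.arccos(np.clip(segment_inner(psi, p, t), -1, 1)) ** 2
                for p in (p1, p2)
            )

        best_val, best_psi = np.inf, None
        for s in np.linspace(0, 1, 2001):
            cand, _ = _exp_psi(p1, s * v12.v, t)
            val = frechet(cand)
            if val < best_val:
                best_val, best_psi = val, cand
        assert np.max(np.abs(km.psi() - best_psi)) < 1e-3
        assert frechet(km.psi()) <= min(frechet(p1), frechet(p2)) + 1e-12

    def test_frechet_value_not_above_inputs(self, unit_grid_101):
        t = unit_grid_101.times
        warps = [
            cp.WarpingFunction(grid=unit_grid_101, gamma=t**e)
            for e in (0.7, 1.0, 1.6)
        ]
        km = cp.karcher_mean_warps(warps)

        def frechet(psi):
            return sum(
                np.arccos(np.clip(segment_inner(psi, w.psi(), t), -1, 1)) ** 2
                for w in warps
            )

        assert frechet(km.psi()) <= min(frechet(w.psi()) for w in warps) + 1e-12
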