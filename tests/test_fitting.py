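"""Bounded NLLS decay fitting, goodness of fit, and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mexpt2 import (
    NoiseProfile,
    SearchSpace,
    fit_biexponential,
    fit_monoexponential,
    fit_voxelwise,
    goodness_of_fit,
    select_model,
    simulate_decay,
)
from conftest import ADIPOSE_PARAMS, fixed_class, one_region_phantom
from _oracles import adj_r2_oracle, bi_grid_oracle, loglinear_mono, mono_grid_oracle


class TestGoodnessOfFit:
    def test_perfect_fit(self, tes):
        y = simulate_decay(500, 100, tes=tes)
        r2, adj = goodness_of_fit(y, y.copy(), m=2)
        assert r2 == 1.0 and adj == 1.0

    def test_mean_predictor_gives_zero_r2(self):
        rng = np.random.default_rng(0)
        y = rng.random(24) * 100
        G = np.full(24, y.mean())
        r2, adj = goodness_of_fit(y, G, m=2)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert adj == pytest.approx(1 - 23 / 21, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 4])
    def test_matches_independent_formula_evaluation(self, m):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.normal(size=24) * rng.uniform(1, 100)
            G = y + rng.normal(size=24)
            r2, adj = goodness_of_fit(y, G, m)
            r2_o, adj_o = adj_r2_oracle(y, G, m)
            assert r2 == pytest.approx(r2_o, abs=1e-12)
            assert adj == pytest.approx(adj_o, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            goodness_of_fit(np.arange(5.0), np.arange(5.0), m=4)

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            goodness_of_fit(np.full(24, 7.0), np.zeros(24), m=2)

    @given(r2=st.floats(-2, 0.999999), K=st.integers(10, 40))
    @settings(max_examples=60, deadline=None)
    def test_adjustment_strictly_decreases_with_m(self, r2, K):
        def adj(m):
            return 1 - (1 - r2) * (K - 1) / (K - m - 1)
        assert adj(4) < adj(2)


class TestMonoexponentialFit:
    def test_exact_recovery_noiseless(self, tes, space):
        y = simulate_decay(500, 100, tes=tes)
        fit = fit_monoexponential(y, tes, space)
        assert fit.A[0] == pytest.approx(500, rel=1e-6)
        assert fit.T2[0] == pytest.approx(100, rel=1e-6)
        assert fit.m == 2 and fit.model_order == 1
        assert fit.converged

    def test_truth_below_bound_pins_at_lower_bound(self, tes, space):
        y = simulate_decay(500, 10, tes=tes)
        fit = fit_monoexponential(y, tes, space)
        rss_o, _, t2_o = mono_grid_oracle(y, tes)
        assert fit.T2[0] == pytest.approx(27.0, abs=0.01)
        assert t2_o == pytest.approx(27.0, rel=1e-3)
        rss = float(np.sum((fit.fitted_curve - y) ** 2))
        assert rss <= rss_o + 1e-8

    def test_matches_loglinear_closed_form(self, tes, space):
        for a, t2 in [(120, 60), (900, 400), (1500, 1200)]:
            y = simulate_decay(a, t2, tes=tes)
            fit = fit_monoexponential(y, tes, space)
            a_o, t2_o = loglinear_mono(y, tes)
            assert fit.A[0] == pytest.approx(a_o, rel=1e-6)
            assert fit.T2[0] == pytest.approx(t2_o, rel=1e-6)

    def test_zero_signal_flagged(self, tes, space):
        fit = fit_monoexponential(np.zeros_like(tes), tes, space)
        assert not fit.converged


class TestBiexponentialFit:
    @pytest.mark.parametrize("params", [
        (300, 40, 700, 200),
        (504, 45, 751, 191),   # adipose-tissue literature values
    ])
    def test_exact_recovery_noiseless(self, params, tes, space):
        a1, t1, a2, t2 = params
        y = simulate_decay(a1, t1, a2, t2, tes=tes)
        fit = fit_biexponential(y, tes, space)
        assert fit.converged and fit.m == 4
        for got, want in zip(np.r_[fit.A, fit.T2], (a1, a2, t1, t2)):
            assert got == pytest.approx(want, rel=1e-4)
        assert fit.T2[0] < fit.T2[1]

    def test_residual_beats_grid_oracle(self, tes, space):
        y = simulate_decay(280, 55, 640, 300, tes=tes)
        fit = fit_biexponential(y, tes, space)
        rss_o, *_ = bi_grid_oracle(y, tes, space, n1=40, n2=60)
        rss = float(np.sum((fit.fitted_curve - y) ** 2))
        assert rss <= rss_o + 1e-8

    def test_zero_signal_degenerate(self, tes, space):
        fit = fit_biexponential(np.zeros_like(tes), tes, space)
        assert not fit.converged
        assert np.all(fit.A == 0)

    def test_parameters_respect_bounds(self, tes, space):
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = simulate_decay(
                rng.uniform(10, 1500), rng.uniform(28, 115),
                rng.uniform(10, 1500), rng.uniform(130, 2000), tes=tes,
            ) + rng.normal(0, 20, tes.size)
            fit = fit_biexponential(y, tes, space)
            assert space.amp_lo <= fit.A[0] <= space.amp_hi
            assert space.amp_lo <= fit.A[1] <= space.amp_hi
            assert space.bi_T2_1_lo <= fit.T2[0] <= space.bi_T2_1_hi
            assert space.bi_T2_2_lo <= fit.T2[1] <= space.bi_T2_2_hi


class TestSelectModel:
    def _fit_pair(self, y, tes, space):
        return (fit_monoexponential(y, tes, space),
                fit_biexponential(y, tes, space))

    def test_higher_adjusted_r2_wins(self, tes, space):
        y = simulate_decay(**ADIPOSE_PARAMS, tes=tes)
        mono, bi = self._fit_pair(y, tes, space)
        assert bi.adj_r2 > mono.adj_r2
        assert select_model(mono, bi) is bi

    def test_tie_resolves_to_mono(self, tes, space):
        # noiseless mono truth: both models reach R^2 ~ 1; parsimony tie-break
        y = simulate_decay(500, 100, tes=tes)
        mono, bi = self._fit_pair(y, tes, space)
        assert mono.r2 == pytest.approx(1.0, abs=1e-12)
        assert bi.r2 == pytest.approx(1.0, abs=1e-12)
        assert select_model(mono, bi).model_order == 1

    def test_nonconverged_fit_excluded(self, tes, space):
        y = simulate_decay(500, 100, tes=tes)
        mono, bi = self._fit_pair(y, tes, space)
        bi.converged = False
        assert select_model(mono, bi) is mono
        mono.converged = False
        assert select_model(mono, bi) is None


class TestFitVoxelwise:
    def test_noiseless_bi_region_all_model_2(self, protocol, space):
        stack, _, labels, bg = one_region_phantom(
            fixed_class("bi", 0.0), protocol, height=3, width=3, sigma=0.0)
        eff = stack[:, :, 1:]
        prof = NoiseProfile(e=np.zeros(24), n_background_voxels=1)
        maps = fit_voxelwise(eff, labels > 0, prof, space, protocol=protocol)
        assert np.all(maps.model_map[labels > 0] == 2)
        assert np.all(maps.model_map[labels == 0] == 0)

    def test_noiseless_mono_region_all_model_1(self, protocol, space):
        stack, _, labels, _ = one_region_phantom(
            fixed_class("mono", 1.0), protocol, height=3, width=3, sigma=0.0)
        eff = stack[:, :, 1:]
        prof = NoiseProfile(e=np.zeros(24), n_background_voxels=1)
        maps = fit_voxelwise(eff, labels > 0, prof, space, protocol=protocol)
        assert np.all(maps.model_map[labels > 0] == 1)
        sel = labels > 0
        np.testing.assert_allclose(maps.mono_t2[sel], 100, rtol=1e-5)
        assert np.all(np.isnan(maps.bi_t2_long[sel]))

    def test_run_to_run_identical(self, protocol, space):
        stack, _, labels, bg = one_region_phantom(
            fixed_class("bi", 0.0), protocol, height=3, width=3, sigma=4.0,
            seed=21)
        eff = stack[:, :, 1:]
        prof = NoiseProfile(e=np.zeros(24), n_background_voxels=1)
        m1 = fit_voxelwise(eff, labels > 0, prof, space, protocol=protocol)
        m2 = fit_voxelwise(eff, labels > 0, prof, space, protocol=protocol)
        for name in m1.map_names():
            np.testing.assert_array_equal(
                getattr(m1, name), getattr(m2, name), err_msg=name)

    def test_empty_mask_raises(self, protocol, space):
        prof = NoiseProfile(e=np.zeros(24), n_background_voxels=1)
        with pytest.raises(ValueError, match="empty"):
            fit_voxelwise(np.ones((4, 4, 24)), np.zeros((4, 4), bool),
                          prof, space, protocol=protocol)
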