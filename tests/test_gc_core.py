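"""VAR identification, conditional GC, F-test calibration, FDR."""

import numpy as np
import pytest
from statsmodels.tsa.api import VAR as StatsmodelsVAR

import glomnet as gn
from glomnet.gc_core import (SingularityError, UnstableModelError, VARModel,
                             pairwise_gc_matrix)

from conftest import simulate_var


def population_model(coeffs, sigma=None):
    """Wrap exact population parameters into a VARModel."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    M = coeffs.shape[1]
    if sigma is None:
        sigma = np.eye(M)
    return VARModel(coefficients=coeffs, residual_covariance=np.asarray(sigma),
                    n_samples=0)


class TestFitVar:
    def test_scalar_ar1_recovery(self):
        rng = np.random.default_rng(0)
        x = simulate_var(np.array([[0.5]]), 10_000, rng)
        model = gn.fit_var(x, 1)
        assert abs(model.coefficients[0, 0, 0] - 0.5) < 0.03

    def test_independent_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.normal(size=(n, 2))
        model = gn.fit_var(x, 1)
        se = 1.0 / np.sqrt(n)  # asymptotic SE of an AR coefficient on white noise
        assert np.all(np.abs(model.coefficients) < 4 * se)

    def test_bivariate_var1_recovery(self):
        a_true = np.array([[0.5, 0.0], [0.4, 0.5]])
        rng = np.random.default_rng(2)
        x = simulate_var(a_true, 10_000, rng)
        model = gn.fit_var(x, 1)
        np.testing.assert_allclose(model.coefficients[0], a_true, atol=0.05)

    def test_matches_statsmodels_ols(self):
        # independent oracle: same OLS problem solved by statsmodels
        rng = np.random.default_rng(3)
        a = np.array([[0.4, 0.1], [-0.2, 0.3]])
        x = simulate_var(a, 2000, rng)
        model = gn.fit_var(x, 2)
        sm = StatsmodelsVAR(x - x.mean(axis=0)).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(model.coefficients, sm.coefs, atol=1e-8)

    def test_duplicate_channel_raises(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(500, 1))
        with pytest.raises(SingularityError):
            gn.fit_var(np.hstack([x, x]), 2)

    def test_insufficient_samples_error_names_requirement(self):
        with pytest.raises(ValueError, match="M\\*p"):
            gn.fit_var(np.zeros((12, 3)) + np.random.default_rng(5).normal(
                size=(12, 3)), 4)


class TestSelectOrder:
    def test_recovers_true_order_two(self):
        a = [np.array([[0.4, 0.2], [0.3, 0.4]]),
             np.array([[0.3, 0.0], [0.0, 0.3]])]
        hits = 0
        for seed in range(20):
            x = simulate_var(np.stack(a), 3000, np.random.default_rng(seed))
            hits += gn.select_order(x, max_order=8) == 2
        assert hits >= 15  # large majority over seeds

    def test_white_noise_selects_smallest_order(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(100 + seed).normal(size=(2000, 3))
            hits += gn.select_order(x, max_order=6) == 1
        assert hits >= 18

    def test_single_candidate(self):
        x = np.random.default_rng(6).normal(size=(500, 2))
        assert gn.select_order(x, max_order=1) == 1


class TestConditionalGC:
    def test_population_closed_form(self):
        # y1 driven by own noise; y2_n = a*y1_{n-1} + u2 => GC(1->2) = ln(1+a^2)
        for a in (0.5, 1.0, 2.0):
            model = population_model(np.array([[0.0, 0.0], [a, 0.0]]))
            g = gn.conditional_gc_matrix(model)
            assert abs(g[0, 1] - np.log(1 + a ** 2)) < 1e-10
            assert g[1, 0] == 0.0

    def test_state_space_equals_two_regression_route_on_population(self):
        # for M=2 the restricted model of the target is an AR on its own
        # past; closed-form restricted variance var(a*y1 + u2) = a^2 + 1
        a = 0.7
        model = population_model(np.array([[0.0, 0.0], [a, 0.0]]))
        g = gn.conditional_gc_matrix(model)
        explicit = np.log((a ** 2 + 1.0) / 1.0)
        assert abs(g[0, 1] - explicit) < 1e-6

    def test_null_model_gives_zero(self):
        model = population_model(np.diag([0.5, 0.3, 0.2])[None] *
                                 np.ones((1, 3, 3)) * np.eye(3))
        g = gn.conditional_gc_matrix(model)
        np.testing.assert_array_equal(g, np.zeros((3, 3)))

    def test_chain_conditioning_removes_indirect_link(self):
        # 1 -> 2 -> 3 with no direct 1 -> 3
        a = np.array([[0.2, 0.0, 0.0], [0.5, 0.2, 0.0], [0.0, 0.5, 0.2]])
        model = population_model(a)
        g_cond = gn.conditional_gc_matrix(model)
        assert g_cond[0, 2] == 0.0
        assert g_cond[0, 1] > 0.1 and g_cond[1, 2] > 0.1
        # on data: pairwise GC leaks through the chain, conditional does not
        x = simulate_var(a, 10_000, np.random.default_rng(7))
        fitted = gn.fit_var(x, gn.select_order(x, max_order=5))
        g_data = gn.conditional_gc_matrix(fitted)
        g_pair = pairwise_gc_matrix(x, 2)
        assert g_pair[0, 2] > 0.01
        assert g_data[0, 2] < g_pair[0, 2] / 3
        assert g_data[0, 2] < 0.005

    def test_nonnegativity_and_floor(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2000, 4))
        g = gn.conditional_gc_matrix(gn.fit_var(x, 2))
        assert np.all(g >= 0)
        assert np.all((g == 0) | (g >= 1e-12))

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        a = np.array([[0.4, 0.0, 0.1], [0.3, 0.4, 0.0], [0.0, 0.2, 0.3]])
        x = simulate_var(a, 4000, rng)
        g1 = gn.conditional_gc_matrix(gn.fit_var(x, 1))
        y = x.copy()
        y[:, 1] *= 37.5
        g2 = gn.conditional_gc_matrix(gn.fit_var(y, 1))
        np.testing.assert_allclose(g1, g2, atol=1e-8)

    def test_unstable_model_raises(self):
        model = population_model(np.array([[1.01]]))
        with pytest.raises(UnstableModelError):
            gn.conditional_gc_matrix(model)


class TestSignificance:
    def test_pvalues_in_unit_interval_diagonal_nan(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(1000, 3))
        model = gn.fit_var(x, 2)
        pv = gn.gc_significance(x, model)
        off = ~np.eye(3, dtype=bool)
        assert np.all((pv[off] >= 0) & (pv[off] <= 1))
        assert np.all(np.isnan(np.diag(pv)))

    def test_null_pvalues_uniform(self):
        # calibration: independent channels => off-diagonal p-values ~ U(0,1)
        pvals = []
        for seed in range(300):
            x = np.random.default_rng(1000 + seed).normal(size=(500, 2))
            model = gn.fit_var(x, 1)
            pv = gn.gc_significance(x, model)
            pvals += [pv[0, 1], pv[1, 0]]
        pvals = np.asarray(pvals)
        from scipy.stats import kstest
        ks = kstest(pvals, "uniform")
        assert ks.statistic < 0.06
        rate = np.mean(pvals <= 0.05)
        # binomial 99% band around 0.05 with n=600
        assert abs(rate - 0.05) < 2.6 * np.sqrt(0.05 * 0.95 / len(pvals))

    def test_power_on_planted_link(self):
        a = np.array([[0.0, 0.0], [0.5, 0.0]])
        forward, reverse = [], []
        for seed in range(20):
            x = simulate_var(a, 3000, np.random.default_rng(2000 + seed))
            model = gn.fit_var(x, 1)
            pv = gn.gc_significance(x, model)
            forward.append(pv[0, 1])
            reverse.append(pv[1, 0])
        assert max(forward) < 1e-6
        # reverse direction behaves like a null test (allow ~1 false alarm)
        assert np.sum(np.asarray(reverse) < 0.05) <= 2


class TestFdrValidate:
    def test_all_ones_yields_empty_mask(self):
        pv = np.ones((10, 10))
        np.fill_diagonal(pv, np.nan)
        sig, weighted = gn.fdr_validate(pv, gc=np.ones((10, 10)))
        assert not sig.any()
        assert np.all(weighted == 0)

    def test_bh_step_up_hand_computed(self):
        # 9 p-values 0.0001k for k=1..9, the remaining 81 at 0.9:
        # the 9th ordered p-value 0.0009 <= 9*0.05/90 = 0.005 -> keep all 9
        pv = np.full((10, 10), 0.9)
        off = np.argwhere(~np.eye(10, dtype=bool))
        for k in range(9):
            i, j = off[k]
            pv[i, j] = 0.0001 * (k + 1)
        np.fill_diagonal(pv, np.nan)
        sig, _ = gn.fdr_validate(pv, alpha=0.05)
        assert sig.sum() == 9
        assert all(pv[i, j] <= 0.0009 + 1e-12 for i, j in np.argwhere(sig))

    def test_single_moderate_pvalue_rejected(self):
        # 0.04 > 1*0.05/90: the BH step-up keeps nothing
        pv = np.ones((10, 10))
        pv[0, 1] = 0.04
        np.fill_diagonal(pv, np.nan)
        sig, _ = gn.fdr_validate(pv, alpha=0.05)
        assert not sig.any()

    def test_weighted_is_gc_masked(self):
        rng = np.random.default_rng(11)
        gc = rng.random((4, 4))
        pv = rng.random((4, 4))
        np.fill_diagonal(pv, np.nan)
        sig, weighted = gn.fdr_validate(pv, alpha=0.5, gc=gc)
        np.testing.assert_array_equal(weighted, np.where(sig, gc, 0.0))


class TestConnectivityEndToEnd:
    def test_mask_seams_drops_boundary_rows(self, protocol_tensor):
        ws = gn.window_concatenate(protocol_tensor, "OFF6", 0, 0)
        res_naive = gn.connectivity(ws, order=2, mask_seams=False)
        res_masked = gn.connectivity(ws, order=2, mask_seams=True)
        assert res_masked.n_samples == res_naive.n_samples - 2 * (30 - 1)

    def test_result_roundtrip_dict(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(800, 3))
        res = gn.connectivity(x, order=1)
        back = gn.ConnectivityResult.from_dict(res.to_dict())
        np.testing.assert_allclose(back.gc, res.gc)
        np.testing.assert_array_equal(back.significant, res.significant)
        assert back.labels == res.labels
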