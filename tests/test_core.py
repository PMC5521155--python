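import math

import numpy as np
import pytest
from scipy import stats

from gatetest import (build_null, enumerate_compositions, fct_test,
                      fit_ggd_null, gate_pvalue, gate_statistic, gate_test,
                      max_xi, mcpc_split, mcpc_test, xi_statistic)
from gatetest.core import NullDistribution, _max_xi_batch, gate_pvalues_batch


class TestCompositions:
    def test_m5_k2(self):
        assert enumerate_compositions(5, 2) == [(1, 4), (2, 3), (3, 2), (4, 1)]

    def test_counts_match_stars_and_bars(self):
        assert len(enumerate_compositions(20, 2)) == 19
        assert len(enumerate_compositions(8, 4)) == math.comb(7, 3)

    def test_k1_single_composition(self):
        assert enumerate_compositions(4, 1) == [(4,)]

    def test_k_above_m_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compositions(3, 5)

    def test_explosion_guard(self):
        with pytest.raises(ValueError, match="guard"):
            enumerate_compositions(60, 20)


class TestXi:
    def test_zero_vector_gives_zero(self):
        assert xi_statistic(np.zeros(6), (2, 4)) == pytest.approx(0.0)

    def test_two_group_closed_form(self):
        # chi2_1 survival is erfc(sqrt(x/2)): independent special-function
        # route for the (1,1) composition at T = (1, 2)
        expected = -2 * (math.log(math.erfc(math.sqrt(0.5)))
                         + math.log(math.erfc(math.sqrt(2.0))))
        assert xi_statistic(np.array([1.0, 2.0]), (1, 1)) == pytest.approx(
            expected, rel=1e-12)

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            xi_statistic(np.zeros(5), (2, 2))

    def test_fixed_composition_null_distribution_is_chi2_2k(self):
        """Each group's F-transform is exactly uniform under the null, so
        xi for a fixed K-group composition is exactly chi-square 2K."""
        rng = np.random.default_rng(12)
        t2 = rng.standard_normal((5000, 7)) ** 2
        cs = np.concatenate([np.zeros((5000, 1)), np.cumsum(t2, axis=1)], 1)
        xi = -2 * (stats.chi2.logsf(cs[:, 3], 3)
                   + stats.chi2.logsf(cs[:, 7] - cs[:, 3], 4))
        assert stats.kstest(xi, "chi2", args=(4,)).pvalue > 0.01

    def test_mcpc_is_xi_at_the_variance_split(self, rng):
        lam = np.sort(rng.uniform(0.1, 3.0, 6))[::-1]
        t = rng.standard_normal(6)
        s = mcpc_split(lam)
        assert mcpc_test(t, lam).statistic == pytest.approx(
            xi_statistic(t, (s, 6 - s)))


class TestMaxXi:
    @pytest.mark.parametrize("m,K", [(3, 2), (7, 2), (7, 3), (6, 4)])
    def test_matches_exhaustive_enumeration(self, m, K, rng):
        for _ in range(20):
            t = rng.standard_normal(m)
            vals = [(xi_statistic(t, c), c) for c in enumerate_compositions(m, K)]
            best_val = max(v for v, _ in vals)
            best_comp = next(c for v, c in vals if v == best_val)
            got_val, got_comp = max_xi(t, K)
            assert got_val == pytest.approx(best_val)
            assert got_comp == best_comp

    def test_k1_equals_xi_full(self, rng):
        t = rng.standard_normal(9)
        val, comp = max_xi(t, 1)
        assert comp == (9,)
        assert val == pytest.approx(xi_statistic(t, (9,)))

    def test_dominant_leading_statistic_is_isolated(self):
        t = np.array([30.0, 0.1, 0.2, 0.1, 0.3])
        _, comp = max_xi(t, 2)
        assert comp == (1, 4)

    def test_batch_agrees_with_single(self, rng):
        t2 = rng.standard_normal((40, 6)) ** 2
        for K in (1, 2, 3):
            batch = _max_xi_batch(t2, K)
            single = [max_xi(np.sqrt(row), K)[0] for row in t2]
            np.testing.assert_allclose(batch, single, rtol=1e-10)


class TestNullDistribution:
    def test_reproducible_bit_for_bit(self):
        a = build_null(6, 2, 1000, seed=5)
        b = build_null(6, 2, 1000, seed=5)
        assert np.array_equal(a.maxxi_draws, b.maxxi_draws)
        assert np.array_equal(a.eta_draws, b.eta_draws)

    def test_eta_range_and_resolution(self):
        null = build_null(6, 2, 1000, seed=5)
        assert null.eta_draws.min() >= 0.0
        assert null.eta_draws.max() <= 1.0
        np.testing.assert_allclose((null.eta_draws * null.B) % 1, 0,
                                   atol=1e-9)

    def test_b_floor_enforced(self):
        with pytest.raises(ValueError, match="at least 1000"):
            build_null(6, 2, 500, seed=5)

    def test_one_layer_matches_two_layer_oracle(self):
        """Evaluating the same outer draws against an independent inner
        resample (the brute-force two-layer scheme) reorders almost nothing."""
        null = build_null(5, 2, 2000, seed=11)
        rng = np.random.default_rng(999)
        inner = rng.standard_normal((2000, 5)) ** 2
        ecdfs = [np.sort(_max_xi_batch(inner, K)) for K in (1, 2)]
        tails = np.column_stack([
            (2000 - np.searchsorted(ecdfs[k], null.maxxi_draws[:, k],
                                    side="right")) / 2000
            for k in range(2)])
        rho = stats.spearmanr(null.eta_draws, tails.min(axis=1)).statistic
        assert rho > 0.99

    def test_null_pvalues_uniform(self):
        """Independent null Wald vectors pushed through the pipeline give
        uniform p-values (the calibration the resampling must deliver)."""
        null = build_null(10, 2, 10000, seed=3)
        obs = np.random.default_rng(77).standard_normal((3000, 10))
        p = gate_pvalues_batch(obs, null)
        assert stats.kstest(p, "uniform").pvalue > 0.01
        # stochastically >= uniform at the tested levels
        for alpha in (0.01, 0.05):
            assert (p <= alpha).mean() <= alpha + 3 * np.sqrt(
                alpha * (1 - alpha) / 3000)

    def test_save_load_roundtrip(self, tmp_path):
        null = build_null(5, 2, 1000, seed=9)
        null.save(tmp_path / "null.npz")
        back = NullDistribution.load(tmp_path / "null.npz")
        assert np.array_equal(back.eta_draws, null.eta_draws)
        assert (back.m, back.k_max, back.B, back.seed) == (5, 2, 1000, 9)


class TestGate:
    def test_k_max_1_is_rank_equivalent_to_fct(self):
        """With one group GATE is a monotone transform of the Fisher-combined
        statistic: eta0 never decreases as the FCT p-value increases."""
        null = build_null(6, 1, 10000, seed=21)
        rng = np.random.default_rng(4)
        ts = rng.standard_normal((500, 6))
        eta0 = np.array([gate_statistic(t, null).eta0 for t in ts])
        fct_p = np.array([fct_test(t).p_value for t in ts])
        order = np.argsort(fct_p, kind="stable")
        assert np.all(np.diff(eta0[order]) >= 0)

    def test_all_zero_wald_vector_gives_eta_one(self):
        null = build_null(5, 2, 1000, seed=2)
        res = gate_statistic(np.zeros(5), null)
        assert res.eta0 == 1.0
        assert gate_pvalue(res, null) == 1.0

    def test_overwhelming_signal_gives_eta_zero(self):
        null = build_null(5, 2, 1000, seed=2)
        t = np.array([50.0, 0.0, 0.0, 0.0, 0.0])
        res = gate_statistic(t, null)
        assert res.eta0 == 0.0
        p = gate_pvalue(res, null)
        assert p <= 2 / null.B  # only the per-K extreme draws tie at zero

    def test_zero_pvalue_formatting(self):
        null = build_null(5, 2, 1000, seed=2)
        res = gate_statistic(np.zeros(5), null)
        res.p_value = 0.0
        assert res.formatted_p() == "< 0.001"

    def test_paper_formula_is_the_complement_count(self):
        null = build_null(5, 2, 2000, seed=8)
        t = np.random.default_rng(1).standard_normal(5) * 1.5
        res = gate_statistic(t, null)
        p_def = gate_pvalue(res, null)
        p_lit = gate_pvalue(res, null, paper_formula=True)
        assert p_def + p_lit == pytest.approx(1.0)  # counts <= and > partition B

    def test_add_one_correction_avoids_zero(self):
        null = build_null(5, 2, 1000, seed=2)
        res = gate_statistic(np.array([50.0, 0, 0, 0, 0.0]), null)
        p = gate_pvalue(res, null, add_one_correction=True)
        assert 0 < p <= 3 / null.B

    def test_null_is_marker_free_and_reusable(self, rng):
        """One NullDistribution serves every variant of a scan: results match
        rebuilding it from the same key."""
        null = build_null(4, 2, 1000, seed=13)
        y = rng.standard_normal((150, 4))
        for _ in range(3):
            g = rng.binomial(2, 0.3, 150).astype(float)
            r1 = gate_test(y, g, null=null)
            r2 = gate_test(y, g, null=build_null(4, 2, 1000, seed=13))
            assert r1.eta0 == r2.eta0 and r1.p_value == r2.p_value

    def test_batch_matches_scalar_path(self, rng):
        null = build_null(6, 2, 1000, seed=17)
        ts = rng.standard_normal((30, 6))
        batch = gate_pvalues_batch(ts, null)
        for i, t in enumerate(ts):
            res = gate_statistic(t, null)
            assert gate_pvalue(res, null) == pytest.approx(batch[i])

    def test_wrong_dimension_rejected(self):
        null = build_null(5, 2, 1000, seed=2)
        with pytest.raises(ValueError, match="m="):
            gate_statistic(np.zeros(7), null)


@pytest.fixture(scope="module")
def big_null_and_fit():
    null = build_null(20, 2, 100000, seed=31)
    return null, fit_ggd_null(null)


class TestGGDFit:
    def test_tail_quantile_matches_empirical(self, big_null_and_fit):
        null, fit = big_null_and_fit
        x = -2 * np.log(np.maximum(null.eta_draws, 1 / (2 * null.B)))
        emp95 = np.quantile(x, 0.95)
        assert abs(fit.quantile(0.95) - emp95) / emp95 < 0.05

    def test_quantile_function_monotone(self, big_null_and_fit):
        _, fit = big_null_and_fit
        qs = fit.quantile(np.linspace(0.05, 0.999, 40))
        assert np.all(np.diff(qs) > 0)

    def test_degenerate_input_rejected(self):
        null = build_null(5, 2, 1000, seed=2)
        null.eta_draws = np.full(1000, 0.25)
        with pytest.raises(RuntimeError, match="degenerate"):
            fit_ggd_null(null)
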