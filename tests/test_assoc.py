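"""Per-variant association tests and window p-value sets."""

import numpy as np
import pytest
from scipy import stats

from goftscan import (CollapseConfig, PhenotypeVector, UntestableVariantError,
                      variant_pvalue, window_pvalues)
from goftscan.assoc import logistic_score_pvalues, ols_slope_pvalues
from tests.conftest import toy_matrix


def _pheno(values, trait="quantitative", cov=None):
    return PhenotypeVector([f"S{i}" for i in range(len(values))],
                           np.asarray(values, float), trait, cov)


class TestVariantPValue:
    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        g = rng.integers(0, 3, 80).astype(float)
        y = 0.3 * g + rng.standard_normal(80)
        res = variant_pvalue(g, _pheno(y))
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-9)
        assert res.effect_direction == np.sign(fit.params[1])
        assert res.test_used == "ols_slope_t"

    def test_matches_statsmodels_ols_with_covariates(self, rng):
        import statsmodels.api as sm
        n = 100
        g = rng.integers(0, 3, n).astype(float)
        cov = rng.standard_normal((n, 2))
        y = 0.2 * g + cov @ [0.5, -0.7] + rng.standard_normal(n)
        res = variant_pvalue(g, _pheno(y, cov=cov))
        X = sm.add_constant(np.column_stack([g, cov]))
        fit = sm.OLS(y, X).fit()
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_matches_statsmodels_logistic_score(self, rng):
        import statsmodels.api as sm
        n = 200
        g = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + 0.4 * g)))).astype(float)
        res = variant_pvalue(g, _pheno(y, trait="binary"))
        null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
        chi2, p_ref, _df = null.model.score_test(null.params, exog_extra=g[:, None])
        assert res.p == pytest.approx(float(np.ravel(p_ref)[0]), rel=1e-8)
        assert res.test_used == "logistic_score"

    def test_perfect_association(self):
        g = np.tile([0.0, 1.0, 2.0], 34)[:100]
        res = variant_pvalue(g, _pheno(g))
        assert res.p < 1e-10

    def test_zero_variance_flagged_untestable(self):
        with pytest.raises(UntestableVariantError):
            variant_pvalue(np.ones(30), _pheno(np.arange(30.0)))

    def test_misaligned_lengths_error(self):
        with pytest.raises(ValueError):
            variant_pvalue(np.arange(5.0), _pheno(np.arange(6.0)))

    def test_deterministic(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        y = rng.standard_normal(50)
        assert variant_pvalue(g, _pheno(y)) == variant_pvalue(g, _pheno(y))


class TestNullUniformity:
    def test_quantitative_pvalues_uniform_under_null(self):
        # 2,000 independent null repetitions, n = 500, Binomial(2, 0.3) dosage
        rng = np.random.default_rng(2026)
        n, reps = 500, 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.standard_normal((n, reps))
        P, _ = ols_slope_pvalues(g[:, None], Y)
        ks = stats.kstest(P[0], "uniform").statistic
        crit_1pct = 1.63 / np.sqrt(reps)  # asymptotic 1% critical value
        assert ks < crit_1pct
        assert abs(P[0].mean() - 0.5) < 0.02

    def test_binary_score_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        n, reps = 400, 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        Y = (rng.random((n, reps)) < 0.4).astype(float)
        P, _ = logistic_score_pvalues(g[:, None], Y)
        assert abs(P[0].mean() - 0.5) < 0.02


class TestWindowPValues:
    def _setup(self, dosage, positions):
        gm = toy_matrix(dosage, positions)
        from goftscan import assign_variants, make_windows
        ws = make_windows("chr1", 1, max(positions), 10_000)
        assign_variants(ws, gm.variants)
        return gm, ws[0]

    def test_count_without_collapsing(self, rng):
        dosage = rng.integers(0, 3, size=(60, 3)).astype(float)
        gm, w = self._setup(dosage, [100, 200, 300])
        pheno = _pheno(rng.standard_normal(60))
        pheno.sample_ids = list(gm.sample_ids)
        ps = window_pvalues(w, gm, pheno, CollapseConfig(enabled=False))
        assert ps.L == 3

    def test_count_with_collapsing_two_common_three_rare(self, rng):
        # layout C r r r C -> 2 common + 1 collapsed run = L of 3
        n = 80
        common = rng.integers(0, 3, size=(n, 2)).astype(float)
        rare = (rng.random((n, 3)) < 0.02).astype(float)
        rare[0] = 1
        dosage = np.column_stack([common[:, 0], rare, common[:, 1]])
        gm, w = self._setup(dosage, [100, 200, 300, 400, 500])
        pheno = _pheno(rng.standard_normal(n))
        pheno.sample_ids = list(gm.sample_ids)
        ps = window_pvalues(w, gm, pheno, CollapseConfig(enabled=True))
        assert ps.L == 3

    def test_monomorphic_only_window_untested(self, rng):
        gm, w = self._setup(np.zeros((30, 1)), [50])
        pheno = _pheno(rng.standard_normal(30))
        pheno.sample_ids = list(gm.sample_ids)
        assert window_pvalues(w, gm, pheno, CollapseConfig()) is None

    def test_missing_policies(self, rng):
        dosage = rng.integers(0, 3, size=(40, 2)).astype(float)
        dosage[3, 0] = np.nan
        gm, w = self._setup(dosage, [100, 200])
        pheno = _pheno(rng.standard_normal(40))
        pheno.sample_ids = list(gm.sample_ids)
        ps_drop = window_pvalues(w, gm, pheno, CollapseConfig(), missing="drop")
        ps_imp = window_pvalues(w, gm, pheno, CollapseConfig(), missing="impute")
        assert ps_drop.L == ps_imp.L == 2
        assert not np.allclose(ps_drop.values, ps_imp.values)


def test_binary_phenotype_validation():
    with pytest.raises(ValueError):
        _pheno([0, 0, 0, 0], trait="binary")  # one class only
    with pytest.raises(ValueError):
        _pheno([0, 1, 2, 1], trait="binary")
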