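"""Synthetic genotype/phenotype generator and power/type-I-error evaluation."""

import numpy as np
import pytest

from goftscan import (EvaluationCurve, GoftResult, SimScenario, evaluate,
                      select_causal, simulate_genotypes, simulate_phenotype)
from goftscan.assoc import ols_slope_pvalues
from goftscan.simulate import replicate_seed


class TestSimulateGenotypes:
    def test_layout_one_window_per_interval(self):
        scn = SimScenario(n_samples=30, n_windows=4, variants_per_window=6, seed=1)
        gm, windows = simulate_genotypes(scn)
        assert gm.n_variants == 24 and len(windows) == 4
        for w in windows:
            assert len(w.variant_indices) == 6
            for i in w.variant_indices:
                assert w.contains(gm.variants[i].position)

    def test_realized_maf_within_binomial_error(self):
        # all-common single-MAF spectrum so the target is pinned
        scn = SimScenario(n_samples=5_000, n_windows=1, variants_per_window=10,
                          fraction_rare=0.0, common_maf_range=(0.3, 0.3),
                          ld_rho=0.0, seed=3)
        gm, _ = simulate_genotypes(scn)
        se = np.sqrt(0.3 * 0.7 / (2 * scn.n_samples))
        for v in gm.variants:
            assert abs(v.maf - 0.3) <= 3 * se

    def test_all_rare_spectrum_stays_rare(self):
        scn = SimScenario(n_samples=5_000, n_windows=2, variants_per_window=20,
                          fraction_rare=1.0, rare_maf_range=(0.005, 0.04),
                          ld_rho=0.0, seed=4)
        gm, _ = simulate_genotypes(scn)
        se = np.sqrt(0.04 * 0.96 / (2 * scn.n_samples))
        assert all(v.maf < 0.05 + 3 * se for v in gm.variants)

    def test_zero_ld_gives_uncorrelated_neighbours(self):
        scn = SimScenario(n_samples=5_000, n_windows=1, variants_per_window=10,
                          fraction_rare=0.0, ld_rho=0.0, seed=5)
        gm, _ = simulate_genotypes(scn)
        D = gm.dosage
        for j in range(D.shape[1] - 1):
            r = np.corrcoef(D[:, j], D[:, j + 1])[0, 1]
            assert abs(r) < 0.05

    def test_positive_ld_gives_correlated_neighbours(self):
        scn = SimScenario(n_samples=5_000, n_windows=1, variants_per_window=10,
                          fraction_rare=0.0, ld_rho=0.8, seed=6)
        gm, _ = simulate_genotypes(scn)
        D = gm.dosage
        rs = [np.corrcoef(D[:, j], D[:, j + 1])[0, 1] for j in range(9)]
        assert np.mean(rs) > 0.3


class TestSimulatePhenotype:
    def test_zero_effect_is_pure_noise(self):
        scn = SimScenario(n_samples=800, n_windows=5, variants_per_window=10,
                          effect_size=0.0, true_window_fraction=0.4, seed=7)
        gm, windows = simulate_genotypes(scn)
        truth = select_causal(gm, windows, scn)
        y = simulate_phenotype(gm, truth, scn)
        testable = np.ptp(gm.dosage, axis=0) > 0
        P, _ = ols_slope_pvalues(gm.dosage[:, testable], y.values[:, None])
        assert abs(P[:, 0].mean() - 0.5) < 0.1

    def test_noiseless_causal_variant_detected(self):
        scn = SimScenario(n_samples=500, n_windows=2, variants_per_window=5,
                          fraction_rare=0.0, trait_noise_sd=0.0,
                          true_window_fraction=0.5, causal_per_true_window=1,
                          causal_class="common", effect_size=1.0, seed=8)
        gm, windows = simulate_genotypes(scn)
        truth = select_causal(gm, windows, scn)
        y = simulate_phenotype(gm, truth, scn)
        (causal_col,) = [c for cols in truth.values() for c in cols]
        P, _ = ols_slope_pvalues(gm.dosage[:, [causal_col]], y.values[:, None])
        assert P[0, 0] < 1e-10

    def test_same_direction_rare_effects(self):
        scn = SimScenario(n_samples=2_000, n_windows=4, variants_per_window=20,
                          true_window_fraction=0.5, causal_per_true_window=8,
                          effect_size=0.5, seed=9)
        gm, windows = simulate_genotypes(scn)
        truth = select_causal(gm, windows, scn)
        y = simulate_phenotype(gm, truth, scn)
        for cols in truth.values():
            for c in cols:
                assert gm.variants[c].maf < 0.05  # rare causal by default
                r = np.corrcoef(gm.dosage[:, c], y.values)[0, 1]
                # every causal effect pulls the trait in the same direction
                assert r > -0.05

    def test_heritability_recovery(self):
        # single common causal variant: realised variance fraction matches
        # the closed form 2 maf (1-maf) beta^2 / var(y) within 10%
        scn = SimScenario(n_samples=10_000, n_windows=1, variants_per_window=1,
                          fraction_rare=0.0, common_maf_range=(0.25, 0.25),
                          ld_rho=0.0, true_window_fraction=1.0,
                          causal_per_true_window=1, causal_class="common",
                          effect_size=0.4, trait_noise_sd=1.0, seed=10)
        gm, windows = simulate_genotypes(scn)
        truth = select_causal(gm, windows, scn)
        y = simulate_phenotype(gm, truth, scn)
        g = gm.dosage[:, truth[0][0]]
        maf = gm.variants[truth[0][0]].maf
        analytic = 2 * maf * (1 - maf) * scn.effect_size ** 2 / np.var(y.values)
        realized = (scn.effect_size ** 2 * np.var(g)) / np.var(y.values)
        assert realized == pytest.approx(analytic, rel=0.10)


class TestEvaluate:
    def _result(self, label, p, true):
        from goftscan import Window
        w = Window("chr1", 0, 100, is_true=true)
        return GoftResult(window_id=label, G_observed=1.0, M=100,
                          exceed_count=int(p * 100), p_empirical=p, seed=0,
                          window=w, L=1)

    def _windows(self, labels_truth):
        from goftscan import Window
        ws = []
        for i, (label, t) in enumerate(labels_truth):
            w = Window("chr1", i * 100, (i + 1) * 100, is_true=t)
            ws.append(w)
        return ws

    def test_no_detections_at_small_cutoff(self):
        from goftscan import Window
        ws = [Window("chr1", i * 10, (i + 1) * 10, is_true=(i == 0)) for i in range(4)]
        results = [[GoftResult(w.label, 0.5, 10, 10, 1.0, 0, window=w, L=1)
                    for w in ws]]
        curve = evaluate(results, ws, cutoffs=(1.0, 0.05))
        assert curve.power_at(0.05) == 0.0 and curve.fpr_at(0.05) == 0.0
        assert curve.power_at(1.0) == 1.0 and curve.fpr_at(1.0) == 1.0

    def test_direct_fpr_count(self):
        from goftscan import Window
        ws = [Window("chr1", i * 10, (i + 1) * 10, is_true=False) for i in range(100)]
        ps = [0.01] * 10 + [0.5] * 90
        results = [[GoftResult(w.label, 1.0, 100, int(p * 100), p, 0, window=w, L=1)
                    for w, p in zip(ws, ps)]]
        curve = evaluate(results, ws, cutoffs=(0.05,))
        assert curve.fpr_at(0.05) == pytest.approx(0.10)

    def test_undefined_tpr_without_true_windows(self):
        from goftscan import Window
        ws = [Window("chr1", 0, 10, is_true=False)]
        results = [[GoftResult(ws[0].label, 1.0, 10, 5, 0.5, 0, window=ws[0], L=1)]]
        curve = evaluate(results, ws, cutoffs=(0.05,))
        assert np.isnan(curve.power_at(0.05))

    def test_curves_monotone_in_cutoff(self, rng):
        from goftscan import Window
        ws = [Window("chr1", i * 10, (i + 1) * 10, is_true=(i % 3 == 0))
              for i in range(60)]
        results = [[GoftResult(w.label, 1.0, 100, 0, float(p), 0, window=w, L=1)
                    for w, p in zip(ws, rng.uniform(size=60))]]
        curve = evaluate(results, ws)
        assert np.all(np.diff(curve.tpr) <= 0) and np.all(np.diff(curve.fpr) <= 0)


def test_wider_windows_dilute_power_at_strict_cutoff():
    """Regrouping the same variants into 10x wider windows adds noise
    variants around each causal span, so power drops at a strict cutoff."""
    from goftscan import assign_variants, make_windows, scan
    scn = SimScenario(n_samples=500, n_windows=40, variants_per_window=12,
                      fraction_rare=0.9, rare_maf_range=(0.001, 0.01),
                      true_window_fraction=0.25, causal_per_true_window=8,
                      effect_size=0.5, n_replicates=5, seed=1)
    gm, narrow = simulate_genotypes(scn)
    truth = select_causal(gm, narrow, scn)
    wide = make_windows(scn.chrom, 1, scn.n_windows * scn.window_width, 100_000)
    assign_variants(wide, gm.variants)
    true_starts = {w.start for w in narrow if w.is_true}
    for w in wide:
        w.is_true = any(w.start <= s < w.end for s in true_starts)
    res_narrow, res_wide = [], []
    for r in range(scn.n_replicates):
        y = simulate_phenotype(gm, truth, scn,
                               np.random.default_rng([scn.seed, 2, r]))
        seed_r = replicate_seed(scn.seed, r)
        res_narrow.append(scan(gm, y, narrow, M=400, seed=seed_r))
        res_wide.append(scan(gm, y, wide, M=400, seed=seed_r))
    p_narrow = evaluate(res_narrow, narrow, cutoffs=(0.005,)).power_at(0.005)
    p_wide = evaluate(res_wide, wide, cutoffs=(0.005,)).power_at(0.005)
    assert p_narrow > p_wide


def test_replicate_seed_stable_and_bounded():
    assert replicate_seed(1, 3) == replicate_seed(1, 3)
    assert replicate_seed(1, 3) != replicate_seed(1, 4)
    assert 0 <= replicate_seed(12345, 999) < 2 ** 31


def test_scenario_validation():
    with pytest.raises(ValueError):
        SimScenario(ld_rho=1.0)
    with pytest.raises(ValueError):
        SimScenario(true_window_fraction=1.5)
    with pytest.raises(ValueError):
        SimScenario(n_replicates=0)
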