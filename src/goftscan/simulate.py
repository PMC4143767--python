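"""Synthetic genotype/phenotype scenarios and power / type-I-error evaluation.

The generator emulates the statistical regime the scan is designed for —
a mixed spectrum of rare (MAF < 5%) and common biallelic variants with
local linkage disequilibrium, a sparse set of causal windows, weak
same-direction effects of rare causal alleles on a Gaussian trait, and
many phenotype replicates over one fixed genotype panel — without
reproducing any particular cohort's pedigree or ascertainment.

Genotypes are built from two latent-Gaussian haplotypes per sample: the
latent process is AR(1) along the variants of a window with
autocorrelation ``ld_rho`` and is thresholded at the normal quantile of
each variant's target MAF, giving marginal Bernoulli(MAF) alleles with
local correlation.  The trait is ``y = sum_k beta_k g_k + eps`` with
Gaussian noise; all rare causal effects share one sign, the regime in
which burden collapsing concentrates signal.

Power is the true-positive rate of true windows and the type-I error
the false-positive rate of false windows, both over a decreasing grid
of p-value cutoffs, pooled across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .assoc import PhenotypeVector
from .io import GenotypeMatrix
from .permutation import GoftResult, scan
from .segmentation import (CollapseConfig, VariantInfo, Window, assign_variants,
                           make_windows)

DEFAULT_CUTOFFS = (1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001)


@dataclass
class SimScenario:
    """Full parameterisation of one synthetic experiment.

    Defaults mirror the analysis setting the scan targets: a small panel
    of unrelated individuals (n = 142), 10-kbp windows, a variant
    spectrum dominated by rare sites, moderate local LD, sparse causal
    windows with several weak same-direction rare effects, and many
    phenotype replicates over one genotype draw.
    """

    n_samples: int = 142
    n_windows: int = 100
    variants_per_window: int = 30
    window_width: int = 10_000
    fraction_rare: float = 0.7
    rare_maf_range: tuple[float, float] = (0.001, 0.05)
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    true_window_fraction: float = 0.1
    causal_per_true_window: int = 8
    causal_class: str = "rare"  # rare | common | any
    effect_size: float = 0.3
    trait_noise_sd: float = 1.0
    n_replicates: int = 200
    seed: int = 0
    chrom: str = "chrSIM"

    def __post_init__(self) -> None:
        for name in ("fraction_rare", "true_window_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.causal_class not in ("rare", "common", "any"):
            raise ValueError(f"unknown causal_class {self.causal_class!r}")


@dataclass
class EvaluationCurve:
    """Power (TPR on true windows) and type-I error (FPR on false windows)."""

    cutoffs: np.ndarray  # decreasing
    tpr: np.ndarray  # NaN when no true windows
    fpr: np.ndarray
    n_true: int = 0
    n_false: int = 0

    def power_at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.cutoffs - alpha)))
        if not np.isclose(self.cutoffs[idx], alpha):
            raise KeyError(f"cutoff {alpha} not on the grid")
        return float(self.tpr[idx])

    def fpr_at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.cutoffs - alpha)))
        if not np.isclose(self.cutoffs[idx], alpha):
            raise KeyError(f"cutoff {alpha} not on the grid")
        return float(self.fpr[idx])


def _draw_mafs(scn: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Target MAFs for one window from the rare/common mixture spectrum."""
    L = scn.variants_per_window
    rare = rng.random(L) < scn.fraction_rare
    lo_r, hi_r = scn.rare_maf_range
    lo_c, hi_c = scn.common_maf_range
    maf = np.where(rare, rng.uniform(lo_r, hi_r, L), rng.uniform(lo_c, hi_c, L))
    return maf


def simulate_genotypes(scn: SimScenario, rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, list[Window]]:
    """Draw the genotype panel and the windows it tiles.

    Each window holds ``variants_per_window`` evenly spaced variants;
    dosages come from two latent-AR(1) haplotypes thresholded at each
    variant's MAF quantile, so adjacent variants are locally correlated
    when ``ld_rho > 0`` while marginal allele frequencies match their
    targets in expectation.
    """
    if rng is None:
        rng = np.random.default_rng([scn.seed, 0])
    n, L, W = scn.n_samples, scn.variants_per_window, scn.n_windows
    spacing = scn.window_width / (L + 1)
    variants: list[VariantInfo] = []
    dosage_blocks = []
    for w in range(W):
        maf = _draw_mafs(scn, rng)
        thresh = stats.norm.ppf(maf)
        # two haplotypes per sample, AR(1) latent along the window
        z = np.empty((2 * n, L))
        z[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, L - 1)) if L > 1 else None
        for j in range(1, L):
            z[:, j] = scn.ld_rho * z[:, j - 1] + np.sqrt(1 - scn.ld_rho ** 2) * innov[:, j - 1]
        alleles = (z < thresh).astype(float)
        dosage_blocks.append(alleles[:n] + alleles[n:])
        for j in range(L):
            pos = int(w * scn.window_width + round((j + 1) * spacing))
            variants.append(VariantInfo(chrom=scn.chrom, position=pos,
                                        id=f"sim{w}_{j}", maf=float(maf[j])))
    dosage = np.hstack(dosage_blocks)
    gm = GenotypeMatrix([f"S{i:05d}" for i in range(n)], dosage, variants,
                        meta={"source": "simulate_genotypes", "scenario_seed": scn.seed})
    gm.compute_mafs()
    windows = make_windows(scn.chrom, 1, W * scn.window_width, scn.window_width)
    assign_variants(windows, gm.variants)
    return gm, windows


def select_causal(gm: GenotypeMatrix, windows: Sequence[Window], scn: SimScenario,
                  rng: np.random.Generator | None = None) -> dict[int, list[int]]:
    """Pick causal windows and causal variant columns; label windows.

    ``round(true_window_fraction * n_windows)`` windows are causal; in
    each, ``causal_per_true_window`` variants of the requested class
    (realised sample MAF) carry an effect.  Windows get ``is_true``
    labels for downstream evaluation.
    """
    if rng is None:
        rng = np.random.default_rng([scn.seed, 1])
    n_true = int(round(scn.true_window_fraction * len(windows)))
    true_idx = set(rng.choice(len(windows), size=n_true, replace=False).tolist()) \
        if n_true else set()
    truth: dict[int, list[int]] = {}
    for s, w in enumerate(windows):
        w.is_true = s in true_idx
        if not w.is_true:
            continue
        cols = np.asarray(w.variant_indices)
        maf = np.array([gm.variants[j].maf for j in cols])
        if scn.causal_class == "rare":
            pool = cols[(maf > 0) & (maf < 0.05)]
        elif scn.causal_class == "common":
            pool = cols[maf >= 0.05]
        else:
            pool = cols[maf > 0]
        k = min(scn.causal_per_true_window, pool.size)
        truth[s] = sorted(rng.choice(pool, size=k, replace=False).tolist())
    return truth


def simulate_phenotype(gm: GenotypeMatrix, truth: dict[int, list[int]],
                       scn: SimScenario, rng: np.random.Generator | None = None
                       ) -> PhenotypeVector:
    """Gaussian trait with additive causal effects, all of one sign.

    ``y = sum_k beta g_k + eps``, ``eps ~ N(0, trait_noise_sd^2)``; the
    shared positive sign of the rare causal effects emulates the
    predominantly deleterious direction of missense rare alleles, the
    regime in which genotype-sum collapsing is efficient.
    """
    if rng is None:
        rng = np.random.default_rng([scn.seed, 2])
    y = rng.normal(0.0, scn.trait_noise_sd, gm.n_samples)
    for cols in truth.values():
        if cols:
            y = y + scn.effect_size * gm.dosage[:, cols].sum(axis=1)
    return PhenotypeVector(list(gm.sample_ids), y, "quantitative")


def evaluate(results_by_replicate: Sequence[Sequence[GoftResult]],
             windows: Sequence[Window],
             cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> EvaluationCurve:
    """Pool window p-values across replicates into TPR/FPR per cutoff.

    ``tpr(c)`` is the fraction of (true window, replicate) pairs with
    empirical p <= c; ``fpr(c)`` the analogue over false windows.
    Untested windows are excluded.  With no true windows the TPR is
    reported as NaN (undefined), not 0.
    """
    label_truth = {w.label: bool(w.is_true) for w in windows if w.is_true is not None}
    p_true, p_false = [], []
    for results in results_by_replicate:
        for r in results:
            if r.status != "tested":
                continue
            t = label_truth.get(r.window_id)
            if t is None:
                continue
            (p_true if t else p_false).append(r.p_empirical)
    p_true = np.asarray(p_true)
    p_false = np.asarray(p_false)
    cut = np.sort(np.asarray(cutoffs, dtype=float))[::-1]
    tpr = np.array([(p_true <= c).mean() if p_true.size else np.nan for c in cut])
    fpr = np.array([(p_false <= c).mean() if p_false.size else np.nan for c in cut])
    return EvaluationCurve(cut, tpr, fpr, n_true=int(p_true.size),
                           n_false=int(p_false.size))


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Stable scan seed for one replicate, kept below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), int(replicate)])
               .generate_state(1)[0] % (2 ** 31))


def run_scenario(scn: SimScenario, M: int = 200,
                 collapse: CollapseConfig | None = None,
                 external_fn: Callable | None = None,
                 missing: str = "drop") -> tuple[list[Window], list[list[GoftResult]]]:
    """Simulate one scenario end to end and scan every replicate.

    Genotypes (and the causal map) are drawn once; each replicate
    redraws the phenotype noise and runs the permutation scan.
    ``external_fn(gm, windows, truth, replicate)`` may supply an
    :class:`~goftscan.meta.ExternalPValueTable` per replicate for
    meta-analysis scans.
    """
    gm, windows = simulate_genotypes(scn)
    truth = select_causal(gm, windows, scn)
    results = []
    for r in range(scn.n_replicates):
        pheno = simulate_phenotype(gm, truth, scn,
                                   np.random.default_rng([scn.seed, 2, r]))
        external = external_fn(gm, windows, truth, r) if external_fn else None
        results.append(scan(gm, pheno, windows, collapse=collapse, M=M,
                            seed=replicate_seed(scn.seed, r), external=external,
                            missing=missing))
    return windows, results


def simulate_external_study(scn: SimScenario, truth: dict[int, list[int]],
                            base_gm: GenotypeMatrix, windows: Sequence[Window],
                            replicate: int, variants_per_window: int = 3,
                            n_samples: int | None = None):
    """Per-variant p-values from an independent second cohort (array-style).

    Emulates adding a separately analysed GWAS panel: a new sample of
    individuals is genotyped at a few common sites per window (positions
    offset from the sequenced sites, so nothing duplicates an internal
    variant), the same causal windows act on its trait through its own
    causal variants, and single-variant p-values are returned as an
    :class:`~goftscan.meta.ExternalPValueTable`.
    """
    from .assoc import association_pvalues
    from .meta import ExternalPValueTable

    ext_scn = replace(scn, variants_per_window=variants_per_window,
                      fraction_rare=0.0,
                      n_samples=n_samples or scn.n_samples)
    rng = np.random.default_rng([scn.seed, 3, replicate])
    gm2, _w2 = simulate_genotypes(ext_scn, rng)
    internal_pos = {(v.chrom, v.position) for v in base_gm.variants}
    for v in gm2.variants:  # nudge off any coincidental internal site
        while (v.chrom, v.position) in internal_pos:
            v.position += 1
    # causal windows act on the external cohort's trait via its own variants
    truth2: dict[int, list[int]] = {}
    for s in truth:
        w = windows[s]
        cols = [j for j, v in enumerate(gm2.variants) if w.contains(v.position)]
        truth2[s] = cols
    y2 = simulate_phenotype(gm2, truth2, ext_scn, rng)
    testable = np.ptp(gm2.dosage, axis=0) > 0
    P, _ = association_pvalues(gm2.dosage[:, testable], y2.values[:, None],
                               "quantitative")
    kept = [v for v, t in zip(gm2.variants, testable) if t]
    return ExternalPValueTable(
        chrom=[v.chrom for v in kept],
        position=[v.position for v in kept],
        id=[v.id for v in kept],
        p=P[:, 0], source_label="synthetic-array-cohort")
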