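"""Per-variant association tests feeding the window statistic.

Quantitative traits use the two-sided t-test on the slope of an ordinary
least-squares regression of trait on additive dosage; binary traits use
the two-sided score test of a logistic regression on dosage.  Covariates,
when supplied, are adjusted for (residualisation for OLS via
Frisch-Waugh-Lovell; a null-model fit for the logistic score test).
Both tests are evaluated in closed form so that a whole window x
permutation block can be computed with dense linear algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PValueSet
from .segmentation import CollapseConfig, Window, collapse_plan

logger = logging.getLogger(__name__)


class UntestableVariantError(ValueError):
    """Raised when a dosage column carries no information (zero variance)."""


@dataclass
class PhenotypeVector:
    """Trait values aligned to sample ids, with optional covariates."""

    sample_ids: list[str]
    values: np.ndarray
    trait_type: str = "quantitative"  # or "binary"
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.sample_ids):
            raise ValueError("values must be 1-D and match sample_ids")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            u = set(np.unique(self.values))
            if not u <= {0.0, 1.0} or len(u) < 2:
                raise ValueError("binary trait must contain both 0 and 1 and nothing else")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.values.size:
                raise ValueError("covariates must have one row per sample")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class VariantPValue:
    """One variant's association p-value and effect direction."""

    variant_key: tuple
    p: float
    test_used: str
    effect_direction: int  # sign of the estimated effect


def _residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, covariates] (least squares)."""
    X = np.column_stack([np.ones(M.shape[0]), covariates])
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def ols_slope_pvalues(D: np.ndarray, Y: np.ndarray,
                      covariates: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided slope-test p-values for every (dosage column, trait column).

    Parameters
    ----------
    D : (n, L) design columns; Y : (n, m) trait columns.

    Returns
    -------
    (L, m) p-values and (L, m) effect signs.  The t statistic is
    computed from the partial correlation between dosage and trait after
    removing the intercept (and covariates, if any), which is identical
    to the OLS slope t-test.
    """
    n = D.shape[0]
    k = 0
    if covariates is not None:
        D = _residualize(D, covariates)
        Y = _residualize(Y, covariates)
        k = covariates.shape[1]
    Dc = D - D.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    dn = np.sqrt((Dc ** 2).sum(axis=0))
    yn = np.sqrt((Yc ** 2).sum(axis=0))
    if np.any(dn == 0):
        raise UntestableVariantError("zero-variance dosage column")
    if np.any(yn == 0):
        raise ValueError("constant trait")
    r = (Dc.T @ Yc) / np.outer(dn, yn)
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"not enough samples (n={n}) for {k} covariates")
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r ** 2, np.finfo(float).tiny)
    with np.errstate(over="ignore"):  # |r| = 1 -> t = inf -> p = 0, then floored
        t = r * np.sqrt(df / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, np.finfo(float).tiny), np.sign(r).astype(int)


def logistic_score_pvalues(D: np.ndarray, Y: np.ndarray,
                           covariates: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Score-test p-values of a logistic regression of each Y column on dosage.

    Without covariates the null model is intercept-only and the score
    statistic is U^2 / V with U = sum g_i (y_i - ybar) and
    V = ybar (1 - ybar) sum (g_i - gbar)^2, chi-square(1) under the null.
    With covariates the null logistic model is fitted per trait column.
    """
    n, L = D.shape
    m = Y.shape[1]
    Dc = D - D.mean(axis=0)
    if np.any((Dc ** 2).sum(axis=0) == 0):
        raise UntestableVariantError("zero-variance dosage column")
    P = np.empty((L, m))
    S = np.empty((L, m), dtype=int)
    if covariates is None:
        p0 = Y.mean(axis=0)  # (m,)
        U = Dc.T @ Y  # sum g_c y = sum g (y - p0)
        V = np.outer((Dc ** 2).sum(axis=0), p0 * (1 - p0))
        chi2 = U ** 2 / V
        P = stats.chi2.sf(chi2, df=1)
        S = np.sign(U).astype(int)
    else:
        import statsmodels.api as sm

        X0 = sm.add_constant(covariates)
        for j in range(m):
            y = Y[:, j]
            fit = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
            pi = fit.fittedvalues
            W = pi * (1 - pi)
            U = D.T @ (y - pi)  # (L,)
            XtWX_inv = np.linalg.inv(X0.T @ (X0 * W[:, None]))
            DW = D * W[:, None]
            V = (DW * D).sum(axis=0) - np.einsum(
                "ln,nk,lk->l", D.T @ (X0 * W[:, None]), XtWX_inv, D.T @ (X0 * W[:, None]))
            P[:, j] = stats.chi2.sf(U ** 2 / V, df=1)
            S[:, j] = np.sign(U)
    return np.maximum(P, np.finfo(float).tiny), S


def association_pvalues(D: np.ndarray, Y: np.ndarray, trait_type: str,
                        covariates: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch on trait type; D (n, L), Y (n, m) -> (L, m) p-values, signs."""
    if trait_type == "quantitative":
        return ols_slope_pvalues(D, Y, covariates)
    if trait_type == "binary":
        return logistic_score_pvalues(D, Y, covariates)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def variant_pvalue(dosages: Sequence[float], phenotype: PhenotypeVector,
                   variant_key: tuple = ("", 0, "")) -> VariantPValue:
    """Association p-value of one variant against the trait.

    Raises :class:`UntestableVariantError` for a zero-variance (e.g.
    monomorphic) dosage column; callers exclude such variants from the
    window's p-value set.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size != phenotype.n:
        raise ValueError(f"dosage length {d.size} != phenotype length {phenotype.n}")
    if np.ptp(d) == 0:
        raise UntestableVariantError(f"variant {variant_key}: constant dosage")
    P, S = association_pvalues(d[:, None], phenotype.values[:, None],
                               phenotype.trait_type, phenotype.covariates)
    test = "ols_slope_t" if phenotype.trait_type == "quantitative" else "logistic_score"
    return VariantPValue(variant_key, float(P[0, 0]), test, int(S[0, 0]))


def window_design(window: Window, genotypes, phenotype: PhenotypeVector,
                  collapse: CollapseConfig, missing: str = "drop"
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, list]:
    """Assemble the window's testable design matrix and aligned trait.

    Applies rare-run collapsing, handles missing genotypes (``drop``
    removes samples with any missing call in the window; ``impute``
    replaces missing dosages with the variant mean), and removes
    zero-variance columns.  Returns (D, y, covariates, labels); D may
    have zero columns when nothing in the window is testable.
    """
    if list(genotypes.sample_ids) != list(phenotype.sample_ids):
        raise ValueError("genotype and phenotype sample ids are not aligned")
    block = genotypes.dosage[:, window.variant_indices].astype(float)
    if missing == "drop":
        keep = np.isfinite(block).all(axis=1)
    elif missing == "impute":
        mu = np.nanmean(block, axis=0)
        idx = np.where(~np.isfinite(block))
        block[idx] = np.take(mu, idx[1])
        keep = np.ones(block.shape[0], dtype=bool)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("window %s: dropped %d incomplete sample(s)", window.label, n_dropped)
    block = block[keep]
    plan = collapse_plan(window, genotypes.variants, collapse)
    design, labels = [], []
    pos_in_window = {gidx: k for k, gidx in enumerate(window.variant_indices)}
    for label, idxs, _collapsed in plan:
        local = [pos_in_window[i] for i in idxs]
        col = block[:, local].sum(axis=1)
        if np.ptp(col) == 0:
            logger.debug("window %s: column %s untestable (zero variance)", window.label, label)
            continue
        design.append(col)
        labels.append(label)
    D = np.column_stack(design) if design else np.empty((int(keep.sum()), 0))
    y = phenotype.values[keep]
    cov = phenotype.covariates[keep] if phenotype.covariates is not None else None
    return D, y, cov, labels


def window_pvalues(window: Window, genotypes, phenotype: PhenotypeVector,
                   collapse: CollapseConfig, missing: str = "drop") -> PValueSet | None:
    """Sorted p-value set of one window, or None when nothing is testable.

    Collapsing (when enabled) replaces each maximal run of rare variants
    with its burden column before testing, so L equals the number of
    testable common variants plus the number of non-empty rare runs.
    """
    D, y, cov, labels = window_design(window, genotypes, phenotype, collapse, missing)
    if D.shape[1] == 0:
        logger.info("window %s: untested (no testable variants)", window.label)
        return None
    P, _ = association_pvalues(D, y[:, None], phenotype.trait_type, cov)
    return PValueSet(P[:, 0], window_id=window.label)
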