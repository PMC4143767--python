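"""Permutation null distribution and empirical p-values for the window scan.

The null of no genotype-trait association is simulated by permuting the
sample-to-phenotype assignment (equivalent to jointly permuting whole
genotype rows), which preserves linkage disequilibrium within every
window.  One shared permutation per replicate ``m`` is reused across all
windows, so genome-wide exchangeability holds and the scan costs one
trait matrix.  The empirical p-value of window ``s`` is

    p_s = #{ G_s^m >= G_s , m = 1..M } / M

with the weak inequality (ties count as exceedances).  The default
``M = 1000``; ``p_s`` can be exactly 0, and the (#+1)/(M+1) estimator is
available behind ``add_one`` for downstream -log10 displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assoc import PhenotypeVector, association_pvalues, window_design
from .core import DEFAULT_P_FLOOR, goft_statistic_columns
from .segmentation import CollapseConfig, Window

logger = logging.getLogger(__name__)

DEFAULT_M = 1000

# Offset separating the external-p-value resampling streams from the
# permutation streams in the seed space (see permute_assignment).
_EXTERNAL_STREAM = 1 << 20


@dataclass
class GoftResult:
    """Observed statistic, permutation count and empirical p-value of a window."""

    window_id: object
    G_observed: float
    M: int
    exceed_count: int
    p_empirical: float
    seed: int
    L: int = 0
    status: str = "tested"
    window: Window | None = None
    n_external: int = 0
    observed_pvalues: np.ndarray | None = None  # sorted, incl. merged externals

    def __post_init__(self) -> None:
        if self.status == "tested" and not (0 <= self.exceed_count <= self.M):
            raise ValueError("exceed_count must lie in [0, M]")


def permute_assignment(n_samples: int, m: int, seed: int) -> np.ndarray:
    """Uniform random permutation of sample indices, reproducible from (seed, m).

    The same permutation ``m`` is reused for every window in a scan, so
    results are independent of window scheduling.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to permute")
    rng = np.random.default_rng([int(seed), int(m)])
    return rng.permutation(n_samples)


def empirical_pvalue(G_obs: float, G_perm: Sequence[float],
                     add_one: bool = False, window_id: object = None,
                     seed: int = 0) -> GoftResult:
    """Empirical p-value from a permutation sample of the statistic.

    ``p = #{G^m >= G_obs} / M``; with ``add_one``, ``(# + 1) / (M + 1)``.
    """
    G_perm = np.asarray(G_perm, dtype=float)
    if G_perm.size == 0:
        raise ValueError("empty permutation sample")
    M = int(G_perm.size)
    exceed = int(np.sum(G_perm >= G_obs))
    p = (exceed + 1) / (M + 1) if add_one else exceed / M
    return GoftResult(window_id=window_id, G_observed=float(G_obs), M=M,
                      exceed_count=exceed, p_empirical=float(p), seed=seed)


def _permuted_traits(values: np.ndarray, M: int, seed: int) -> np.ndarray:
    """(n, M+1) trait matrix: column 0 observed, column m the m-th permutation."""
    n = values.size
    Y = np.empty((n, M + 1))
    Y[:, 0] = values
    for m in range(1, M + 1):
        Y[:, m] = values[permute_assignment(n, m, seed)]
    return Y


def scan(genotypes, phenotype: PhenotypeVector, windows: Sequence[Window],
         collapse: CollapseConfig | None = None, M: int = DEFAULT_M,
         seed: int = 0, external=None, missing: str = "drop",
         add_one: bool = False, p_floor: float = DEFAULT_P_FLOOR
         ) -> list[GoftResult]:
    """Permutation scan of all windows: observed G and empirical p-value each.

    For every window the observed statistic comes from the window's
    per-variant p-values (after collapsing); each permutation recomputes
    the p-values under the permuted phenotype assignment and the same
    collapsing structure (MAF, hence the run structure, is invariant
    under permutation).  Windows without variants are skipped; windows
    whose variants are all untestable are reported with
    ``status='untested'``.

    ``external`` is an optional :class:`~goftscan.meta.ExternalPValueTable`
    whose records are merged into the observed p-value sets by position
    (duplicates of internally tested sites dropped).  Under each
    permutation the external p-values are resampled from Uniform(0,1)
    — the external genotypes are not available to permute — which is a
    declared approximation, flagged via ``n_external`` in the results.
    """
    if collapse is None:
        collapse = CollapseConfig()
    if M < 1:
        raise ValueError("M must be >= 1")
    ext_by_window: dict[int, np.ndarray] = {}
    if external is not None:
        from .meta import external_pvalues_by_window
        ext_by_window = external_pvalues_by_window(windows, genotypes.variants, external)

    Y_full = _permuted_traits(phenotype.values, M, seed)
    results: list[GoftResult] = []
    for s, w in enumerate(windows):
        if not w.variant_indices:
            continue
        D, _y, cov, labels = window_design(w, genotypes, phenotype, collapse, missing)
        ext_p = ext_by_window.get(s)
        if D.shape[1] == 0:
            results.append(GoftResult(window_id=w.label, G_observed=float("nan"),
                                      M=M, exceed_count=0, p_empirical=float("nan"),
                                      seed=seed, L=0, status="untested", window=w))
            continue
        keep = _window_keep(w, genotypes, missing)
        P, _ = association_pvalues(D, Y_full[keep], phenotype.trait_type,
                                   cov)
        if ext_p is not None and ext_p.size:
            n_ext = ext_p.size
            rng = np.random.default_rng([int(seed), _EXTERNAL_STREAM + s])
            ext_block = np.empty((n_ext, M + 1))
            ext_block[:, 0] = ext_p
            ext_block[:, 1:] = rng.uniform(size=(n_ext, M))
            P = np.vstack([P, ext_block])
        else:
            n_ext = 0
        P = np.maximum(P, p_floor)
        P.sort(axis=0)
        G = goft_statistic_columns(P)
        res = empirical_pvalue(G[0], G[1:], add_one=add_one,
                               window_id=w.label, seed=seed)
        res.L = P.shape[0]
        res.window = w
        res.n_external = n_ext
        res.observed_pvalues = P[:, 0].copy()
        results.append(res)
    return results


def _window_keep(w: Window, genotypes, missing: str) -> np.ndarray:
    """Boolean mask of samples retained for a window under the missing policy."""
    block = genotypes.dosage[:, w.variant_indices]
    if missing == "drop":
        return np.isfinite(block).all(axis=1)
    return np.ones(genotypes.n_samples, dtype=bool)
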