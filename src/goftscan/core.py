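"""Berk-Jones goodness-of-fit statistic for a set of p-values.

The scan treats each genomic window as a multiple-testing problem: under
the null of no association every per-variant p-value is Uniform(0,1), and
the window-level statistic measures the departure of the empirical
distribution of the sorted p-values ``p_1 <= ... <= p_L`` from uniformity,

    G = L * max_{1<=j<=L} 2 K(j/L, p_j),

where ``K(t, x)`` is the Kullback-Leibler divergence between Bernoulli(t)
and Bernoulli(x), restricted to the one-sided region ``x < t`` (small
p-values arriving earlier than uniformity predicts).  ``G`` is large when
a few p-values are unusually small for their rank, which makes the
statistic sensitive to weak, sparse signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Floor applied to p-values of exactly 0 (e.g. from permutation-derived
#: inputs) so that K and hence G stay finite.
DEFAULT_P_FLOOR = 1e-15

#: Sentinel for the +infinity branch of K.  Compares greater than any
#: finite statistic; never fed into downstream arithmetic.
INF_SENTINEL = math.inf


@dataclass(frozen=True)
class PValueSet:
    """Sorted per-variant p-values of one window.

    Parameters
    ----------
    values
        Probabilities in (0, 1].  Sorted ascending on construction;
        exact zeros are clamped to ``p_floor`` (the event is logged).
    window_id
        Opaque label identifying the window the p-values belong to.
    """

    values: np.ndarray
    window_id: object = None
    p_floor: float = DEFAULT_P_FLOOR

    def __init__(self, values: Sequence[float], window_id: object = None,
                 p_floor: float = DEFAULT_P_FLOOR) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("PValueSet requires a non-empty 1-D sequence")
        if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
            raise ValueError("p-values must lie in [0, 1]")
        n_zero = int(np.sum(arr == 0.0))
        if n_zero:
            logger.info("clamped %d zero p-value(s) to floor %.3g in window %r",
                        n_zero, p_floor, window_id)
            arr = np.maximum(arr, p_floor)
        arr = np.sort(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "window_id", window_id)
        object.__setattr__(self, "p_floor", p_floor)

    @property
    def L(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class GoftStatistic:
    """The window statistic ``G`` and the rank attaining the maximum."""

    G: float
    argmax_j: int  # 1-based rank j in 1..L

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("G must be non-negative")


def kl_term(t: float, x: float) -> float:
    """Bernoulli Kullback-Leibler divergence ``K(t, x)``, one-sided.

    Returns ``t*log(t/x) + (1-t)*log((1-t)/(1-x))`` when ``0 < x < t < 1``,
    0 when ``0 <= t <= x <= 1``, and the +infinity sentinel when ``x == 0``
    and ``t > 0``.  At ``t == 1`` with ``0 < x < 1`` the analytic limit
    ``-log(x)`` is used (the 0*log(0) = 0 convention), which is the
    standard Berk-Jones definition; without it the top rank ``j = L``
    would be degenerate for every window.
    """
    if not (0.0 <= t <= 1.0) or not (0.0 <= x <= 1.0):
        raise ValueError(f"kl_term arguments must lie in [0, 1]; got t={t}, x={x}")
    if t <= x:
        return 0.0
    # here x < t
    if x == 0.0:
        return INF_SENTINEL
    if t == 1.0:
        return -math.log(x)
    # log(t/x) as log t - log x: robust at extreme ratios
    return t * (math.log(t) - math.log(x)) + (1.0 - t) * (math.log1p(-t) - math.log1p(-x))


def goft_statistic(pvals: PValueSet | Sequence[float]) -> GoftStatistic:
    """Compute ``G = L * max_j 2 K(j/L, p_j)`` over the sorted p-values.

    Accepts a :class:`PValueSet` or any sequence of p-values (sorted
    internally, so the result is invariant to input order).
    """
    if not isinstance(pvals, PValueSet):
        pvals = PValueSet(pvals)
    p = pvals.values
    L = pvals.L
    terms = bj_terms(p[:, None])[:, 0]
    j = int(np.argmax(terms))  # first maximiser under ties
    return GoftStatistic(G=float(L * terms[j]), argmax_j=j + 1)


def bj_terms(sorted_p: np.ndarray) -> np.ndarray:
    """Vectorised ``2 K(j/L, p_j)`` for one or many sorted p-vectors.

    ``sorted_p`` has shape (L, m): m columns, each a sorted ascending
    p-vector of common length L.  Returns an (L, m) array of the
    doubled KL terms, with the t = 1 row evaluated at its ``-log x``
    limit.  Zeros in the input must already be clamped.
    """
    sorted_p = np.asarray(sorted_p, dtype=float)
    L = sorted_p.shape[0]
    t = (np.arange(1, L + 1, dtype=float) / L)[:, None]
    x = sorted_p
    with np.errstate(divide="ignore", invalid="ignore"):
        body = t * (np.log(t) - np.log(x)) + (1.0 - t) * (np.log1p(-t) - np.log1p(-x))
    # t == 1 (last row): limit -log(x)
    body[L - 1, :] = -np.log(x[L - 1, :])
    out = np.where(t > x, body, 0.0)
    return 2.0 * out


def goft_statistic_columns(sorted_p: np.ndarray) -> np.ndarray:
    """``G`` for each column of an (L, m) array of sorted p-vectors."""
    terms = bj_terms(sorted_p)
    return sorted_p.shape[0] * terms.max(axis=0)
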