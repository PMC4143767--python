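"""Fixed-width genome windows, rare/common classification, rare-run collapsing.

Variants are classified rare when their sample minor allele frequency is
strictly below a threshold (default 5%).  Within each window, maximal
runs of rare variants delimited by common variants are collapsed into a
single burden pseudo-variant whose per-sample dosage is the sum of the
run's dosages; runs before the first and after the last common variant
are collapsed as their own groups.  Collapsing never crosses a window
boundary — windows are the analysis unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_RARE_THRESHOLD = 0.05


@dataclass
class VariantInfo:
    """Per-variant metadata: coordinates, sample MAF and rarity class."""

    chrom: str
    position: int  # 1-based base pair
    id: str
    maf: float = float("nan")
    is_rare: bool = False

    def classify(self, rare_threshold: float) -> None:
        self.is_rare = bool(self.maf < rare_threshold)


@dataclass
class Window:
    """Half-open genomic interval [start, end) in 0-based coordinates."""

    chrom: str
    start: int
    end: int
    variant_indices: list[int] = field(default_factory=list)
    is_true: bool | None = None  # simulation truth label

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, position: int) -> bool:
        """Whether a 1-based position falls in this window."""
        return self.start <= position - 1 < self.end


@dataclass
class CollapseConfig:
    """Rare-variant collapsing switch and MAF threshold.

    ``rare_threshold`` uses a strict comparison (maf < threshold), so a
    threshold of 0 classifies nothing as rare and collapsing becomes a
    no-op.
    """

    enabled: bool = True
    rare_threshold: float = DEFAULT_RARE_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 <= self.rare_threshold <= 0.5):
            raise ValueError("rare_threshold must lie in [0, 0.5]")


@dataclass
class CollapsedColumn:
    """One testable design column: a common variant or a collapsed rare run."""

    dosages: np.ndarray
    label: str
    source_indices: list[int]  # column indices into the genotype matrix
    is_collapsed: bool


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from additive dosages in [0, 2].

    f = mean(dosage)/2 is the alternate-allele frequency; the MAF is
    min(f, 1-f).  Missing values (NaN) are ignored; an all-missing
    column is an error.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    mask = np.isfinite(d)
    if not mask.any():
        raise ValueError("all-missing dosage column")
    f = float(d[mask].mean()) / 2.0
    return min(f, 1.0 - f)


def make_windows(chrom: str, min_pos: int, max_pos: int, width: int) -> list[Window]:
    """Tile [0, ceil(max_pos/width)*width) with half-open windows.

    Windows are anchored at coordinate 0 rather than at ``min_pos`` so
    that boundaries are reproducible across datasets.  ``min_pos`` and
    ``max_pos`` are 1-based positions of the first and last variant.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if max_pos < min_pos:
        raise ValueError("max_pos must be >= min_pos")
    n = math.ceil(max_pos / width)
    if n == 0:  # max_pos == 0 would be invalid 1-based, but guard anyway
        n = 1
    return [Window(chrom=chrom, start=i * width, end=(i + 1) * width) for i in range(n)]


def assign_variants(windows: list[Window], variants: Sequence[VariantInfo]) -> None:
    """Fill ``variant_indices`` of each window (1-based position - 1 mapping).

    Every variant lands in exactly one window; windows are assumed to
    tile the chromosome from 0 with a common width.
    """
    if not windows:
        return
    width = windows[0].width
    by_key = {(w.chrom, w.start // width): w for w in windows}
    for idx, v in enumerate(variants):
        key = (v.chrom, (v.position - 1) // width)
        w = by_key.get(key)
        if w is not None:
            w.variant_indices.append(idx)
    for w in windows:
        w.variant_indices.sort(key=lambda i: variants[i].position)


def collapse_plan(window: Window, variants: Sequence[VariantInfo],
                  config: CollapseConfig) -> list[tuple[str, list[int], bool]]:
    """Grouping structure of a window's testable columns.

    Returns (label, source column indices, is_collapsed) triples in
    positional order: one entry per common variant and one per maximal
    run of rare variants delimited by common variants (runs before the
    first and after the last common variant included).  Monomorphic
    variants (maf == 0) are dropped before classification.  The plan
    depends only on variant MAFs, which are invariant under phenotype
    permutation, so it is computed once per window and reused.
    """
    plan: list[tuple[str, list[int], bool]] = []
    run: list[int] = []

    def flush_run() -> None:
        if run:
            label = f"burden:{variants[run[0]].position}-{variants[run[-1]].position}"
            plan.append((label, list(run), True))
            run.clear()

    n_mono = 0
    for idx in window.variant_indices:
        v = variants[idx]
        if v.maf == 0.0:
            n_mono += 1
            continue
        if config.enabled and v.maf < config.rare_threshold:
            run.append(idx)
        else:
            flush_run()
            plan.append((v.id or str(v.position), [idx], False))
    flush_run()
    if n_mono:
        logger.debug("window %s: dropped %d monomorphic variant(s)", window.label, n_mono)
    return plan


def collapse_rare(window: Window, dosage: np.ndarray,
                  variants: Sequence[VariantInfo],
                  config: CollapseConfig) -> list[CollapsedColumn]:
    """Build the window's testable design columns by rare-run collapsing.

    Each maximal run of rare variants between adjacent common variants
    becomes one pseudo-variant whose per-sample dosage is the sum of the
    run's dosages; common variants pass through unchanged.  ``dosage``
    is the full n_samples x n_variants matrix (columns indexed by
    ``window.variant_indices``).
    """
    return [CollapsedColumn(dosage[:, idxs].sum(axis=1) if collapsed
                            else dosage[:, idxs[0]].astype(float),
                            label, idxs, collapsed)
            for label, idxs, collapsed in collapse_plan(window, variants, config)]


def classification_table(variants: Sequence[VariantInfo]) -> pd.DataFrame:
    """Variant classification as a DataFrame (chrom, pos, id, maf, class)."""
    return pd.DataFrame({
        "chrom": [v.chrom for v in variants],
        "pos": [v.position for v in variants],
        "id": [v.id for v in variants],
        "maf": [v.maf for v in variants],
        "class": ["rare" if v.is_rare else "common" for v in variants],
    })


def windows_to_bed(windows: Iterable[Window], path) -> None:
    """Write window definitions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for w in windows:
            name = "true" if w.is_true else ("false" if w.is_true is not None else ".")
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{name}\n")
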