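"""p-value-level meta-analysis: merge a second source into the window sets.

Because the window statistic consumes only p-values, results from a
second study (e.g. a GWAS array analysed separately) can be added to
each window's p-value set before the statistic is computed, enlarging L
and borrowing strength across data sources.  External records are
assigned to windows by position; a record at a (chrom, position) already
tested internally is dropped (the sequencing-derived p-value wins), so
no site is double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PValueSet
from .segmentation import VariantInfo, Window

logger = logging.getLogger(__name__)


@dataclass
class ExternalPValueTable:
    """Per-variant p-values from a second source (chrom, position, id, p)."""

    chrom: np.ndarray
    position: np.ndarray
    id: np.ndarray
    p: np.ndarray
    source_label: str = "external"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.position = np.asarray(self.position, dtype=int)
        self.id = np.asarray(self.id, dtype=object)
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.size
        if not (self.chrom.size == self.position.size == self.id.size == n):
            raise ValueError("all columns must have equal length")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("external p-values must lie in [0, 1]")
        if np.any(self.position < 1):
            raise ValueError("positions must be 1-based positive integers")

    def __len__(self) -> int:
        return int(self.p.size)

    @classmethod
    def from_tsv(cls, path, source_label: str | None = None) -> "ExternalPValueTable":
        """Read a TSV with header columns chrom, pos, id, p."""
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "pos", "id", "p"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        return cls(df["chrom"].astype(str).to_numpy(), df["pos"].to_numpy(),
                   df["id"].astype(str).to_numpy(), df["p"].to_numpy(),
                   source_label or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"chrom": self.chrom, "pos": self.position,
                      "id": self.id, "p": self.p}).to_csv(path, sep="\t", index=False)


def external_pvalues_by_window(windows: Sequence[Window],
                               internal_variants: Sequence[VariantInfo],
                               external: ExternalPValueTable
                               ) -> dict[int, np.ndarray]:
    """Assign external p-values to windows, dropping internal duplicates.

    Returns a map from window index to the array of external p-values
    that fall inside that window at (chrom, position) pairs not already
    tested internally.  Records outside every window are counted and
    logged, not an error.
    """
    internal_sites = {(v.chrom, v.position) for v in internal_variants}
    by_key: dict[tuple, int] = {}
    for s, w in enumerate(windows):
        by_key[(w.chrom, w.start // w.width)] = s
    width = windows[0].width if windows else None
    assigned: dict[int, list[float]] = {}
    n_outside = n_dup = 0
    for chrom, pos, p in zip(external.chrom, external.position, external.p):
        if (chrom, int(pos)) in internal_sites:
            n_dup += 1
            continue
        s = by_key.get((chrom, (int(pos) - 1) // width)) if width else None
        if s is None:
            n_outside += 1
            continue
        assigned.setdefault(s, []).append(float(p))
    if n_dup:
        logger.info("meta: dropped %d external record(s) duplicating internal sites", n_dup)
    if n_outside:
        logger.info("meta: %d external record(s) fell outside all windows", n_outside)
    return {s: np.asarray(ps) for s, ps in assigned.items()}


def merge_sources(window_psets: dict, external: ExternalPValueTable,
                  windows: Sequence[Window],
                  internal_variants: Sequence[VariantInfo]) -> dict:
    """Merge external per-variant p-values into each window's p-value set.

    ``window_psets`` maps window index (or label) to :class:`PValueSet`;
    the returned map has the same keys with enlarged, re-sorted sets.
    L increases by the number of in-window external records that do not
    duplicate an internally tested site; re-applying the same table is
    idempotent because its sites are recorded as tested after the merge.
    """
    label_to_index = {w.label: s for s, w in enumerate(windows)}
    internal_sites = {(v.chrom, v.position) for v in internal_variants}
    merged = {}
    for key, pset in window_psets.items():
        s = key if isinstance(key, int) else label_to_index.get(key)
        if s is None:
            merged[key] = pset
            continue
        w = windows[s]
        seen = internal_sites | getattr(pset, "merged_sites", frozenset())
        add, sites = [], set()
        for chrom, pos, p in zip(external.chrom, external.position, external.p):
            site = (chrom, int(pos))
            if site in seen or not w.contains(int(pos)) or chrom != w.chrom:
                continue
            add.append(float(p))
            sites.add(site)
        if not add:
            merged[key] = pset
        else:
            out = PValueSet(np.concatenate([pset.values, add]),
                            window_id=pset.window_id)
            object.__setattr__(out, "merged_sites",
                               getattr(pset, "merged_sites", frozenset()) | frozenset(sites))
            merged[key] = out
    return merged
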