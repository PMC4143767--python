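"""Genotype/phenotype readers and result writers.

Supported genotype inputs:

* VCF 4.x (plain or bgzipped) via :mod:`cyvcf2`; GT fields become additive
  alternate-allele dosages, or the DS FORMAT field is used when present
  and preferred.
* A "dose" TSV: one row per variant with ``chrom``, ``pos``, ``id``
  metadata columns followed by one dosage column per sample, or the
  transposed dialect (one row per sample, variant columns labelled
  ``chrom:pos:id``).

Dosages may be fractional (imputed); values within 0.01 of the valid
[0, 2] range are clamped (imputation files commonly carry tiny numeric
spill), values further outside are an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import VariantInfo, compute_maf

logger = logging.getLogger(__name__)

DOSAGE_TOL = 1e-2


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with aligned variant metadata.

    ``dosage[i, j]`` is the additive alternate-allele dosage of sample i
    at variant j, a real in [0, 2]; missing calls are NaN.
    """

    sample_ids: list[str]
    dosage: np.ndarray
    variants: list[VariantInfo]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n, v = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids but {n} dosage rows")
        if v != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {v} dosage columns")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def compute_mafs(self, rare_threshold: float = 0.05) -> None:
        """Fill each variant's sample MAF and rarity class."""
        for j, v in enumerate(self.variants):
            v.maf = compute_maf(self.dosage[:, j])
            v.classify(rare_threshold)

    def drop_incomplete_samples(self) -> "GenotypeMatrix":
        """Keep only samples with no missing call (complete cases)."""
        keep = np.isfinite(self.dosage).all(axis=1)
        dropped = [s for s, k in zip(self.sample_ids, keep) if not k]
        if dropped:
            logger.info("dropped %d sample(s) with missing genotypes: %s",
                        len(dropped), ", ".join(dropped[:10]))
        return GenotypeMatrix(
            [s for s, k in zip(self.sample_ids, keep) if k],
            self.dosage[keep], self.variants, dict(self.meta),
        )


def _clamp_dosage(arr: np.ndarray, context: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    finite = np.isfinite(arr)
    bad = finite & ((arr < -DOSAGE_TOL) | (arr > 2 + DOSAGE_TOL))
    if bad.any():
        raise ValueError(f"{context}: dosage outside [{-DOSAGE_TOL}, {2 + DOSAGE_TOL}]")
    spill = finite & ((arr < 0) | (arr > 2))
    if spill.any():
        logger.warning("%s: clamped %d dosage value(s) into [0, 2]", context, int(spill.sum()))
    return np.clip(arr, 0.0, 2.0, out=np.where(finite, arr, np.nan))


def read_vcf(path, prefer_ds: bool = False, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    GT is converted to the count of ALT alleles; when ``prefer_ds`` is
    set and a DS FORMAT field is present it is used instead.
    Multiallelic records are skipped (with a log message) unless
    ``skip_multiallelic`` is False, in which case they are an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    cols: list[np.ndarray] = []
    variants: list[VariantInfo] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"{path}: multiallelic record at {rec.CHROM}:{rec.POS}")
        ds = rec.format("DS") if prefer_ds else None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(rec.genotype.array())  # (n, ploidy+1); last col is phasing
            alleles = gt[:, :-1].astype(float)
            alleles[alleles < 0] = np.nan  # missing call
            col = alleles.sum(axis=1)
        cols.append(_clamp_dosage(col, f"{path}:{rec.CHROM}:{rec.POS}"))
        variants.append(VariantInfo(chrom=rec.CHROM, position=rec.POS,
                                    id=rec.ID or f"{rec.CHROM}:{rec.POS}"))
    vcf.close()
    if n_multi:
        logger.info("%s: skipped %d multiallelic record(s)", path, n_multi)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic records")
    dosage = np.column_stack(cols)
    return GenotypeMatrix(samples, dosage, variants, meta={"source": str(path), "format": "vcf"})


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write integer-dosage genotypes as a minimal VCF 4.2 (GT + DS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = sorted({v.chrom for v in gm.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, v in enumerate(gm.variants):
            calls = []
            for d in gm.dosage[:, j]:
                if not np.isfinite(d):
                    calls.append("./.:.")
                    continue
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(round(d)), "./.")
                calls.append(f"{gt}:{d:g}")
            fh.write(f"{v.chrom}\t{v.position}\t{v.id}\tA\tG\t.\tPASS\t.\tGT:DS\t"
                     + "\t".join(calls) + "\n")


def read_dose_tsv(path, transposed: bool = False) -> GenotypeMatrix:
    """Read a dosage TSV.

    Default dialect: header ``chrom  pos  id  <sample1>  <sample2> ...``,
    one row per variant.  Transposed dialect (``transposed=True``):
    header ``sample_id  <chrom:pos:id> ...``, one row per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty dosage file")
    if transposed:
        if df.columns[0] != "sample_id":
            raise ValueError(f"{path}: transposed dialect requires a 'sample_id' first column")
        sample_ids = df["sample_id"].astype(str).tolist()
        variants = []
        for label in df.columns[1:]:
            parts = str(label).split(":")
            if len(parts) < 2:
                raise ValueError(f"{path}: variant column {label!r} not 'chrom:pos[:id]'")
            vid = parts[2] if len(parts) > 2 else label
            variants.append(VariantInfo(chrom=parts[0], position=int(parts[1]), id=vid))
        dosage = _parse_numeric(df.iloc[:, 1:], path)
    else:
        required = ["chrom", "pos", "id"]
        if list(df.columns[:3]) != required:
            raise ValueError(f"{path}: expected leading columns {required}, got {list(df.columns[:3])}")
        if df.shape[1] < 4:
            raise ValueError(f"{path}: no sample columns")
        sample_ids = [str(c) for c in df.columns[3:]]
        variants = [VariantInfo(chrom=str(r.chrom), position=int(r.pos), id=str(r.id))
                    for r in df.itertuples()]
        dosage = _parse_numeric(df.iloc[:, 3:], path).T
    dosage = _clamp_dosage(dosage, str(path))
    return GenotypeMatrix(sample_ids, dosage, variants,
                          meta={"source": str(path), "format": "dose_tsv",
                                "dialect": "transposed" if transposed else "variant-rows"})


def _parse_numeric(block: pd.DataFrame, path) -> np.ndarray:
    try:
        arr = block.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric dosage value ({exc})") from exc
    return arr


def write_dose_tsv(gm: GenotypeMatrix, path) -> None:
    """Write the variant-rows dosage dialect (chrom, pos, id, one column/sample)."""
    meta = pd.DataFrame({
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.position for v in gm.variants],
        "id": [v.id for v in gm.variants],
    })
    body = pd.DataFrame(gm.dosage.T, columns=list(gm.sample_ids))
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False,
                                           float_format="%.10g")


def read_phenotype_tsv(path) -> pd.DataFrame:
    """Phenotype TSV with header ``sample_id  trait  [covariate ...]``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.columns[0] != "sample_id" or df.columns[1] != "trait":
        raise ValueError(f"{path}: expected header 'sample_id\\ttrait[\\tcovariates...]'")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def results_to_frame(results) -> pd.DataFrame:
    """Scan results as a TSV-ready DataFrame (one row per window)."""
    rows = []
    for r in results:
        w = r.window
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "L": r.L, "G": r.G_observed, "exceed_count": r.exceed_count,
            "M": r.M, "p_empirical": r.p_empirical, "status": r.status,
        })
    return pd.DataFrame(rows)


def write_run_manifest(path, params: dict, input_paths: Sequence = ()) -> None:
    """Machine-readable record of a run: parameters, seed, input checksums."""
    checks = {}
    for p in input_paths:
        p = Path(p)
        checks[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(json.dumps({"params": params, "input_sha256": checks},
                                     indent=2, default=str) + "\n")
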