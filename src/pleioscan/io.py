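"""File formats, core containers, and phenotype preparation.

Genotypes travel as an individuals x variants expected-dosage matrix (0..2,
possibly fractional) together with a variant table.  External files keep
their native coordinate conventions (VCF positions are 1-based); window
arithmetic elsewhere in the package uses 0-based half-open intervals, and the
converters below are the single place the two conventions meet.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

RECORD_COLUMNS = ["animal_id", "trait", "record_index", "value", "weight"]


class PleioscanError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


@dataclasses.dataclass
class Genotypes:
    """Dosage matrix plus variant and sample metadata.

    dosages : (n_samples, n_variants) float array of ALT-allele dosages.
    variants : DataFrame with columns variant_id, chrom, pos (1-based),
        ref, alt and optionally maf / imputation_r2.
    samples : DataFrame with columns sample_id and optionally sire_id
        (empty string for founders/unrelated animals).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PleioscanError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise PleioscanError(
                f"shape mismatch: dosages {self.dosages.shape}, "
                f"{len(self.samples)} samples, {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise PleioscanError(f"variant table missing columns {missing}")
        if self.variants["variant_id"].duplicated().any():
            raise PleioscanError("duplicate variant_id in variant table")
        pos = self.variants.groupby("chrom", sort=False)["pos"]
        if not pos.apply(lambda s: s.is_monotonic_increasing).all():
            raise PleioscanError("positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Realized ALT-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_index(self, variant_ids) -> np.ndarray:
        """Column indices for the given variant ids (error when absent)."""
        lookup = pd.Index(self.variants["variant_id"])
        idx = lookup.get_indexer(np.atleast_1d(variant_ids))
        if (idx < 0).any():
            bad = np.atleast_1d(variant_ids)[idx < 0]
            raise PleioscanError(f"unknown variant id(s): {list(bad)}")
        return idx

    def subset_variants(self, mask_or_ids) -> "Genotypes":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.variant_index(arr)
        return Genotypes(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples,
        )


def vcf_pos_to_bed(pos):
    """1-based VCF position -> 0-based BED start of that base."""
    return np.asarray(pos) - 1


def bed_pos_to_vcf(start):
    """0-based BED start -> 1-based VCF position."""
    return np.asarray(start) + 1


# ---------------------------------------------------------------------------
# Genotype I/O


def write_vcf(geno: Genotypes, path, seed=None) -> None:
    """Write dosages as a VCF 4.2 with GT (rounded) and DS fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pleioscan\n")
        if seed is not None:
            fh.write(f"##pleioscan_seed={seed}\n")
        chroms = geno.variants["chrom"]
        for chrom in pd.unique(chroms):
            max_pos = int(geno.variants.loc[chroms == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected ALT dosage">\n'
        )
        samples = "\t".join(geno.samples["sample_id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        hard = np.clip(np.rint(geno.dosages), 0, 2).astype(int)
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                str(row.variant_id),
                str(row.ref),
                str(row.alt),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            cells = [
                f"{gt_codes[hard[i, j]]}:{geno.dosages[i, j]:.4f}"
                for i in range(geno.n_samples)
            ]
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path, dosage_field: str = "DS") -> Genotypes:
    """Load a VCF into a Genotypes container.

    Prefers the DS (expected dosage) FORMAT field and falls back to hard GT
    calls.  Multi-allelic sites are skipped (count logged); missing hard
    calls are mean-imputed per variant.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        if dosage_field:
            try:
                ds = v.format(dosage_field)
            except KeyError:
                ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan
                            for g in v.genotypes], dtype=float)
            if np.isnan(gts).any():
                gts = np.where(np.isnan(gts), np.nanmean(gts), gts)
            col = gts
        cols.append(col)
        rows.append(
            (v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0])
        )
    if n_multi:
        log.info("skipped %d multi-allelic site(s)", n_multi)
    if not rows:
        raise PleioscanError(f"no usable bi-allelic variants in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols)
    samples = pd.DataFrame({"sample_id": sample_ids})
    return Genotypes(dosages, variants, samples)


def write_dosage_tsv(geno: Genotypes, path) -> None:
    """Plain-text dosage table: one row per variant, one column per sample."""
    df = geno.variants[VARIANT_COLUMNS].copy()
    mat = pd.DataFrame(
        geno.dosages.T, columns=geno.samples["sample_id"].astype(str)
    )
    pd.concat([df.reset_index(drop=True), mat], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_dosage_tsv(path) -> Genotypes:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise PleioscanError(f"dosage table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    variants = df[VARIANT_COLUMNS].copy().reset_index(drop=True)
    samples = pd.DataFrame({"sample_id": sample_cols})
    return Genotypes(dosages, variants, samples)


def read_genotypes(path, format: str | None = None) -> Genotypes:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise PleioscanError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Phenotype records


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise PleioscanError(f"record table missing columns {missing}")
    if (records["weight"] <= 0).any():
        raise PleioscanError("record weights must be > 0")
    if records.duplicated(["animal_id", "trait", "record_index"]).any():
        raise PleioscanError("(animal_id, trait, record_index) must be unique")
    return records


def filter_min_records(records: pd.DataFrame, min_records: int = 2) -> pd.DataFrame:
    """Drop animals with fewer than ``min_records`` records of a trait.

    Mirrors the design where only cows with the full complement of repeated
    measurements (two, six weeks apart) enter the analysis.
    """
    if min_records < 1:
        raise PleioscanError("min_records must be >= 1")
    validate_records(records)
    counts = records.groupby(["animal_id", "trait"])["value"].transform("size")
    out = records[counts >= min_records].reset_index(drop=True)
    if out.empty:
        log.warning("filter_min_records: no animals retained")
    log.info(
        "filter_min_records: %d of %d (animal, trait) groups retained",
        out.groupby(["animal_id", "trait"]).ngroups if not out.empty else 0,
        records.groupby(["animal_id", "trait"]).ngroups,
    )
    return out


def average_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated records to one phenotype per animal and trait.

    The analysis phenotype is the arithmetic mean of the records, i.e. the
    mean of (permanent environment + additive genetic + residual) over the n
    records; weights are summed so that animals measured more often carry
    more information downstream.
    """
    validate_records(records)
    out = (
        records.groupby(["animal_id", "trait"], sort=False)
        .agg(value=("value", "mean"), weight=("weight", "sum"),
             n_records=("value", "size"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Run manifests


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed=None) -> None:
    """Record config hash, seed and library versions for reproducibility."""
    import scipy

    manifest = {
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "versions": {
            "pleioscan": __import__("pleioscan").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
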