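"""Local-GEBV window statistics and QTL calling.

The local genomic estimated breeding value of an individual in a window is
Wv — dosages of the window's SNPs times their estimated effects.  Windows
whose local GEBV varies strongly across individuals harbour QTL; QTL are
called as the top fraction of the genome by that variance (2 % for complex
milk-production-like traits, 0.1 % for genetically simple traits).

Coordinates are 0-based half-open [start, start + size), anchored at
multiples of the step from 0, matching BED conventions on output.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io import Genotypes, PleioscanError, vcf_pos_to_bed

WINDOW_COLUMNS = ["chrom", "start", "end", "n_variants", "local_var"]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    size_bp: int = 250_000
    step_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.size_bp <= 0 or self.step_bp <= 0:
            raise PleioscanError("window size and step must be > 0")
        if self.size_bp % self.step_bp != 0:
            raise PleioscanError("size_bp must be a multiple of step_bp")

    @property
    def n_phases(self) -> int:
        return self.size_bp // self.step_bp


@dataclasses.dataclass
class QTLCallSet:
    """Windows declared QTL for one trait at a stated genome fraction."""

    trait: str
    fraction: float
    windows: pd.DataFrame  # sorted by local_var descending
    n_total_windows: int


def make_windows(
    variants: pd.DataFrame, spec: WindowSpec, chrom_length: dict | int | None = None
) -> pd.DataFrame:
    """Sliding windows per chromosome with per-window variant counts.

    Windows start at multiples of ``step_bp`` from coordinate 0 and must lie
    fully inside the chromosome; zero-variant windows are retained with
    ``n_variants = 0`` so genome fractions stay interpretable.
    """
    frames = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos0 = vcf_pos_to_bed(sub["pos"].to_numpy())
        if not np.all(np.diff(pos0) >= 0):
            raise PleioscanError(f"positions unsorted on chromosome {chrom}")
        if isinstance(chrom_length, dict):
            L = chrom_length[chrom]
        elif chrom_length is not None:
            L = int(chrom_length)
        else:
            L = int(pos0[-1]) + 1 if len(pos0) else 0
        last_start = L - spec.size_bp
        if last_start < 0:
            continue
        starts = np.arange(0, last_start + 1, spec.step_bp)
        counts = np.searchsorted(pos0, starts + spec.size_bp) - np.searchsorted(
            pos0, starts
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + spec.size_bp,
                    "n_variants": counts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_variants"])
    return pd.concat(frames, ignore_index=True)


def local_gebv_variance(geno: Genotypes, effects, window) -> float:
    """Sample variance (denominator n-1) of Wv across individuals for one
    window; the variance is invariant to column shifts of W, so centering is
    immaterial."""
    if geno.n_samples < 2:
        raise PleioscanError("need at least 2 individuals for a variance")
    chrom, start, end = window[0], int(window[1]), int(window[2])
    v = np.asarray(
        effects.effect_mean if hasattr(effects, "effect_mean") else effects, float
    )
    if v.shape[0] != geno.n_variants:
        raise PleioscanError("effects do not align with the genotype matrix")
    pos0 = vcf_pos_to_bed(geno.variants["pos"].to_numpy())
    in_win = (geno.variants["chrom"].to_numpy() == chrom) & (pos0 >= start) & (
        pos0 < end
    )
    if not in_win.any():
        return 0.0
    wv = geno.dosages[:, in_win] @ v[in_win]
    return float(np.var(wv, ddof=1))


def window_variances(
    geno: Genotypes, effects, windows: pd.DataFrame
) -> pd.DataFrame:
    """local_gebv_variance for every window; adds a ``local_var`` column."""
    if geno.n_samples < 2:
        raise PleioscanError("need at least 2 individuals for a variance")
    v = np.asarray(
        effects.effect_mean if hasattr(effects, "effect_mean") else effects, float
    )
    out = windows.copy()
    out["local_var"] = 0.0
    pos0 = vcf_pos_to_bed(geno.variants["pos"].to_numpy())
    chroms = geno.variants["chrom"].to_numpy()
    for chrom, sub in windows.groupby("chrom", sort=False):
        mask = chroms == chrom
        cpos = pos0[mask]
        cidx = np.flatnonzero(mask)
        lo = np.searchsorted(cpos, sub["start"].to_numpy())
        hi = np.searchsorted(cpos, sub["end"].to_numpy())
        for row, (a, b) in zip(sub.index, zip(lo, hi)):
            if b > a:
                idx = cidx[a:b]
                wv = geno.dosages[:, idx] @ v[idx]
                out.at[row, "local_var"] = float(np.var(wv, ddof=1))
    return out


def call_qtl(stats: pd.DataFrame, fraction: float, trait: str = "trait") -> QTLCallSet:
    """Top ``ceil(fraction * N)`` windows by local GEBV variance.

    Ties are broken by (chrom, start) ascending so the call count never
    depends on the tie structure.
    """
    if stats is None or len(stats) == 0:
        raise PleioscanError("empty window statistics")
    if not (0.0 < fraction < 1.0):
        raise PleioscanError("fraction must lie in (0, 1)")
    n_top = math.ceil(fraction * len(stats))
    ranked = stats.sort_values(
        ["local_var", "chrom", "start"], ascending=[False, True, True],
        kind="mergesort",
    )
    return QTLCallSet(
        trait=trait,
        fraction=fraction,
        windows=ranked.head(n_top).reset_index(drop=True),
        n_total_windows=len(stats),
    )


def cumulative_variance_profile(
    stats: pd.DataFrame, top_fraction: float, spec: WindowSpec | None = None
) -> float:
    """Fraction of total window variance captured by the top windows.

    Computed on the offset-0 non-overlapping tiling (windows whose start is a
    multiple of the window size) to avoid double counting of overlapping
    sliding windows.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise PleioscanError("top_fraction must lie in (0, 1]")
    size = spec.size_bp if spec is not None else int(
        (stats["end"] - stats["start"]).iloc[0]
    )
    tiling = stats[stats["start"] % size == 0]
    total = tiling["local_var"].sum()
    if total <= 0:
        raise PleioscanError("zero total window variance")
    n_top = math.ceil(top_fraction * len(tiling))
    top = (
        tiling.sort_values("local_var", ascending=False)["local_var"]
        .head(n_top)
        .sum()
    )
    return float(top / total)


def write_window_tsv(stats: pd.DataFrame, path) -> None:
    """BED-like TSV (0-based half-open)."""
    stats.to_csv(path, sep="\t", index=False)


def read_window_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
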