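"""Testing co-location of QTL between trait pairs.

Because QTL are called on overlapping sliding windows, overlap is assessed
on the size/step non-overlapping tilings of the genome (phases of the
sliding grid): per tiling, every tile is classified as QTL / not-QTL for
each trait, the four cells of the resulting 2x2 table are averaged across
tilings, and a 1-df Pearson chi-squared test (no continuity correction)
asks whether traits share QTL tiles more often than independence predicts.
Significance is one-sided: the observed overlap must exceed expectation.

The chi-squared reference distribution is anti-conservative when expected
overlap counts are far below 1 (intrinsic to calling 0.1 % of the genome);
``rotation_p_value`` provides a permutation companion that calibrates the
overlap count by circularly rotating one trait's calls along the genome,
preserving the clustered structure of QTL windows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PleioscanError
from .windows import QTLCallSet, WindowSpec


@dataclasses.dataclass
class OverlapResult:
    trait_pair: tuple
    n_windows_per_tiling: float
    observed_overlap_avg: float
    expected_overlap: float
    chi2_stat: float
    p_value: float
    significant: bool
    cells: tuple  # averaged (both, A only, B only, neither)
    rotation_p: float | None = None


def nonoverlapping_tilings(windows: pd.DataFrame, spec: WindowSpec) -> list:
    """Split sliding windows into size/step phase classes, each a partition
    of the genome into non-overlapping windows."""
    if spec.size_bp % spec.step_bp != 0:
        raise PleioscanError("size_bp must be a multiple of step_bp")
    tilings = []
    starts = windows["start"].to_numpy()
    for phase in range(spec.n_phases):
        offset = phase * spec.step_bp
        tilings.append(
            windows[(starts % spec.size_bp) == offset].reset_index(drop=True)
        )
    return tilings


def expected_overlap(frac_a: float, frac_b: float, n_windows: int) -> float:
    """Windows expected to be QTL for both traits if placement is independent."""
    for f in (frac_a, frac_b):
        if not (0.0 < f < 1.0):
            raise PleioscanError("fractions must lie in (0, 1)")
    if n_windows < 1:
        raise PleioscanError("n_windows must be >= 1")
    return frac_a * frac_b * n_windows


def bonferroni_alpha(alpha: float, n_trait_pairs: int) -> float:
    if not (0.0 < alpha < 1.0):
        raise PleioscanError("alpha must lie in (0, 1)")
    if n_trait_pairs < 1:
        raise PleioscanError("n_trait_pairs must be >= 1")
    return alpha / n_trait_pairs


def _mark_tiles(tiling: pd.DataFrame, calls: pd.DataFrame) -> np.ndarray:
    """Boolean per tile: does any called (sliding) window intersect it >= 1 bp?"""
    hit = np.zeros(len(tiling), dtype=bool)
    for chrom, csub in calls.groupby("chrom", sort=False):
        tmask = (tiling["chrom"] == chrom).to_numpy()
        if not tmask.any():
            continue
        ts = tiling.loc[tmask, "start"].to_numpy()
        te = tiling.loc[tmask, "end"].to_numpy()
        cs = csub["start"].to_numpy()
        ce = csub["end"].to_numpy()
        # tiles are sorted and disjoint within a tiling: range-stab each call
        order = np.argsort(ts)
        lo = np.searchsorted(te[order], cs, side="right")
        hi = np.searchsorted(ts[order], ce, side="left")
        cover = np.zeros(len(ts) + 1, dtype=int)
        np.add.at(cover, lo, 1)
        np.add.at(cover, hi, -1)
        local = np.cumsum(cover[:-1]) > 0
        idx = np.flatnonzero(tmask)
        hit[idx[order]] |= local
    return hit


def _pearson_chi2(cells: np.ndarray) -> float:
    """1-df Pearson statistic on a (possibly fractional) 2x2 table."""
    t = cells.reshape(2, 2)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    expected = np.outer(rows, cols) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
    return float(contrib.sum())


def overlap_chi2(
    qtl_a: QTLCallSet,
    qtl_b: QTLCallSet,
    tilings: list,
    alpha: float = 0.05,
    n_rotations: int = 0,
    rotation_seed: int = 0,
) -> OverlapResult:
    """Chi-squared test for excess QTL co-location between two traits.

    Cell counts (both-QTL, A-only, B-only, neither) are averaged across the
    non-overlapping tilings before a single Pearson test.  ``significant``
    requires both p < alpha and observed overlap above the independence
    expectation ``frac_a * frac_b * n_windows``.
    """
    if qtl_a.n_total_windows != qtl_b.n_total_windows:
        raise PleioscanError("QTL call sets come from different window universes")
    if not tilings:
        raise PleioscanError("need at least one tiling")

    cells = np.zeros(4)
    hits = []
    for tiling in tilings:
        a = _mark_tiles(tiling, qtl_a.windows)
        b = _mark_tiles(tiling, qtl_b.windows)
        cells += np.array(
            [(a & b).sum(), (a & ~b).sum(), (~a & b).sum(), (~a & ~b).sum()],
            dtype=float,
        )
        hits.append((tiling, a, b))
    cells /= len(tilings)
    n_avg = cells.sum()

    chi2 = _pearson_chi2(cells)
    p = float(sps.chi2.sf(chi2, df=1))
    exp = expected_overlap(qtl_a.fraction, qtl_b.fraction, int(round(n_avg)))
    observed = cells[0]

    rotation_p = None
    if n_rotations > 0:
        rng = np.random.default_rng(rotation_seed)
        exceed = 0
        for _ in range(n_rotations):
            rot = 0.0
            for tiling, a, b in hits:
                shift = rng.integers(0, len(b))
                rot += (a & np.roll(b, shift)).sum()
            if rot / len(hits) >= observed:
                exceed += 1
        rotation_p = (1.0 + exceed) / (n_rotations + 1.0)

    return OverlapResult(
        trait_pair=(qtl_a.trait, qtl_b.trait),
        n_windows_per_tiling=float(n_avg),
        observed_overlap_avg=float(observed),
        expected_overlap=float(exp),
        chi2_stat=chi2,
        p_value=p,
        significant=bool(p < alpha and observed > exp),
        cells=tuple(cells),
        rotation_p=rotation_p,
    )


def results_to_frame(results: list) -> pd.DataFrame:
    """TSV-ready table: trait_A, trait_B, observed, expected, chi2, p, significant."""
    return pd.DataFrame(
        {
            "trait_A": [r.trait_pair[0] for r in results],
            "trait_B": [r.trait_pair[1] for r in results],
            "observed": [r.observed_overlap_avg for r in results],
            "expected": [r.expected_overlap for r in results],
            "chi2": [r.chi2_stat for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
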