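"""Expression-QTL association with structure covariates.

Expression phenotypes (already variance-stabilized) are regressed on variant
dosage together with multidimensional-scaling coordinates of the genetic
distance matrix — absorbing family/population structure — and a fixed effect
for collection cohort / sequencing facility.  Ten MDS axes are the default,
a practicable number that captures most of the genotypic structure.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Genotypes, PleioscanError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MDSCovariates:
    """Classical-MDS coordinates (columns ordered by decreasing eigenvalue,
    zero column means) and the eigenvalue share captured by each axis."""

    coords: np.ndarray  # (n, k)
    eigenvalue_share: np.ndarray

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def mds_covariates(K, k: int = 10) -> MDSCovariates:
    """Classical (Torgerson) MDS of the genetic distance D = 1 - IBS.

    Double-centers -D^2/2, takes the top-k eigenvectors scaled by
    sqrt(eigenvalue).  Coordinates are unique up to sign/rotation; compare
    distances, not raw axes.
    """
    K = np.asarray(K, float)
    n = K.shape[0]
    if k >= n:
        raise PleioscanError("k must be smaller than the number of individuals")
    D = 1.0 - K
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    lam, U = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    pos = np.clip(lam, 0.0, None)
    coords = U[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    share = pos[:k] / total if total > 0 else np.zeros(k)
    return MDSCovariates(coords=coords - coords.mean(axis=0), eigenvalue_share=share)


def _cohort_design(cohorts, n) -> np.ndarray:
    """Treatment-coded dummies; a single-level factor is dropped with a notice."""
    if cohorts is None:
        return np.empty((n, 0))
    codes, levels = pd.factorize(np.asarray(cohorts))
    if len(levels) < 2:
        log.info("cohort factor has a single level; dropped from the model")
        return np.empty((n, 0))
    dummies = np.zeros((n, len(levels) - 1))
    for j in range(1, len(levels)):
        dummies[codes == j, j - 1] = 1.0
    return dummies


def eqtl_scan(
    expression,
    genotypes,
    mds: MDSCovariates | None = None,
    cohorts=None,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Per-variant fixed-effects linear model: expression ~ dosage + MDS axes
    + cohort; t-test on the dosage term (df = n - p - 1).

    ``expression`` is a vector aligned with the genotype rows, or a tidy
    frame (sample_id, gene_id, value, cohort) matched against the genotype
    sample ids.  Run ``assoc.variant_qc`` beforehand with the eQTL
    thresholds (imputation R2 >= 0.70, MAF >= 0.001, HWE P >= 1e-10).
    """
    if isinstance(expression, pd.DataFrame):
        sub = expression
        if gene_id is not None:
            sub = sub[sub["gene_id"] == gene_id]
        if isinstance(genotypes, Genotypes):
            sub = sub.set_index("sample_id").loc[
                genotypes.samples["sample_id"].to_numpy()
            ]
        y = sub["value"].to_numpy(float)
        if cohorts is None and "cohort" in sub.columns:
            cohorts = sub["cohort"].to_numpy()
    else:
        y = np.asarray(expression, float)

    X = genotypes.dosages if isinstance(genotypes, Genotypes) else np.asarray(
        genotypes, float
    )
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n:
        raise PleioscanError("expression vector does not match genotype rows")

    parts = [np.ones((n, 1))]
    if mds is not None and mds.k > 0:
        parts.append(mds.coords)
    parts.append(_cohort_design(cohorts, n))
    C = np.column_stack(parts)

    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    rX = X - Q @ (Q.T @ X)
    xtx = (rX * rX).sum(axis=0)
    df = n - C.shape[1] - 1
    testable = xtx > 0
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        bh = (rX.T @ ry) / xtx
    rss = ry @ ry - bh**2 * xtx
    s2 = np.where(testable, rss / df, np.nan)
    beta[testable] = bh[testable]
    se[testable] = np.sqrt(s2[testable] / xtx[testable])
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df=df)

    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "n_used": n,
            "tested": testable,
        }
    )
    if isinstance(genotypes, Genotypes):
        out.insert(0, "variant_id", genotypes.variants["variant_id"].to_numpy())
        out.insert(1, "chrom", genotypes.variants["chrom"].to_numpy())
        out.insert(2, "pos", genotypes.variants["pos"].to_numpy())
    if gene_id is not None:
        out["gene_id"] = gene_id
    return out


def expression_outliers(expr_matrix, n_axes: int = 2, sd_threshold: float = 4.0):
    """Flag genome-wide expression outliers by principal-component distance.

    Samples farther than ``sd_threshold`` standard deviations from the
    centroid on any of the top ``n_axes`` PCs are flagged.  Returns a boolean
    keep-mask over rows (samples).
    """
    E = np.asarray(expr_matrix, float)
    if E.ndim == 1:
        E = E[:, None]
    Ec = E - E.mean(axis=0)
    u, s, _ = np.linalg.svd(Ec, full_matrices=False)
    k = min(n_axes, u.shape[1])
    scores = u[:, :k] * s[:k]
    sds = scores.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    z = np.abs(scores / sds)
    return (z <= sd_threshold).all(axis=1)
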