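"""Mixed-model association, conditioning, QC, and multi-analysis meta-test.

Single-variant association uses the two-stage EMMAX approximation: variance
components of ``y = Xb + g + e`` with ``g ~ N(0, sigma2_g K)`` are estimated
once under the null (no test variant) by REML on the eigendecomposition of
the kinship K, then every variant is tested by generalized least squares
with the variance ratio held fixed.  The kinship is identity-by-state allele
sharing by default (a centered GRM is available), which absorbs the strong
half-sib family covariance that would otherwise inflate naive OLS tests.

Analyses run separately on cohorts with heterogeneous error variance (e.g.
bull and cow phenotypes) are combined per variant as sum(t^2) over the n
contributing t-statistics, referred to a chi-squared distribution with n
degrees of freedom.  This assumes the analyses are independent; for
correlated traits measured on the same animals it is anti-conservative, and
a decorrelating variant (t' R^-1 t) is available via ``t_correlation``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .io import Genotypes, PleioscanError


def _dosage_matrix(genotypes) -> np.ndarray:
    if isinstance(genotypes, Genotypes):
        return genotypes.dosages
    X = np.asarray(genotypes, float)
    return X[:, None] if X.ndim == 1 else X


def ibs_matrix(genotypes) -> np.ndarray:
    """Identity-by-state kinship: mean over variants of 1 - |d_i - d_j| / 2."""
    X = _dosage_matrix(genotypes)
    n, m = X.shape
    if m == 0:
        raise PleioscanError("zero variants: cannot build an IBS matrix")
    if n < 2:
        raise PleioscanError("need at least 2 individuals")
    D = squareform(pdist(X, metric="cityblock")) / (2.0 * m)
    K = 1.0 - D
    np.fill_diagonal(K, 1.0)
    return K


def grm_matrix(genotypes, freqs=None) -> np.ndarray:
    """Centered genomic relationship matrix (VanRaden), Z Z' / sum 2 p q.

    ``freqs`` supplies reference allele frequencies (e.g. founder/population
    frequencies); with the default sample frequencies, strong family
    structure shrinks related-pair entries toward zero because the centering
    forces off-diagonals to average out.
    """
    X = _dosage_matrix(genotypes)
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    Z = X - 2.0 * p
    denom = (2.0 * p * (1.0 - p)).sum()
    if denom <= 0:
        raise PleioscanError("all variants monomorphic: GRM undefined")
    return Z @ Z.T / denom


@dataclasses.dataclass
class NullModelFit:
    """REML fit of the variance components under the no-variant null."""

    delta: float  # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    covariates: np.ndarray

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _reml_neg_loglik(log_delta, lam, Uty, UtX, xtx_logdet):
    delta = np.exp(log_delta)
    d = lam + delta
    n, p = UtX.shape
    XtViX = UtX.T @ (UtX / d[:, None])
    XtViy = UtX.T @ (Uty / d)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e300
    resid = Uty - UtX @ beta
    ypy = float(resid @ (resid / d))
    if ypy <= 0:
        return 1e300
    sigma2_g = ypy / (n - p)
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e300
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2_g) + 1.0)
        + np.log(d).sum()
        + logdet_XtViX
        - xtx_logdet
    )
    return -ll


def fit_null_mixed_model(y, covariates, K) -> NullModelFit:
    """REML estimation of delta = sigma2_e / sigma2_g by 1-D optimization on
    the kinship eigendecomposition; deterministic."""
    y = np.asarray(y, float)
    n = y.size
    X = np.atleast_2d(np.asarray(covariates, float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise PleioscanError("covariates do not match phenotype length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PleioscanError("singular covariate matrix")
    K = np.asarray(K, float)
    if K.shape != (n, n):
        raise PleioscanError("kinship does not match phenotype length")

    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)  # PSD adjustment of the IBS kernel
    Uty = U.T @ y
    UtX = U.T @ X
    _, xtx_logdet = np.linalg.slogdet(X.T @ X)

    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(np.log(1e-5), np.log(1e5)),
        args=(lam, Uty, UtX, xtx_logdet),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    d = lam + delta
    XtViX = UtX.T @ (UtX / d[:, None])
    beta = np.linalg.solve(XtViX, UtX.T @ (Uty / d))
    resid = Uty - UtX @ beta
    sigma2_g = float(resid @ (resid / d)) / (n - X.shape[1])
    return NullModelFit(
        delta=delta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_g * delta,
        loglik=-float(res.fun),
        eigvals=lam,
        eigvecs=U,
        covariates=X,
    )


def emmax_scan(
    genotypes,
    null: NullModelFit,
    y,
    condition_on=None,
    use_t: bool = True,
) -> pd.DataFrame:
    """GLS association test per variant with variance components fixed.

    Phenotype, covariates, and dosages are whitened by D^{-1/2} U' with
    D = diag(eigenvalues + delta); each variant is then an OLS regression in
    the rotated space.  ``condition_on`` lists variant ids whose dosages are
    added as covariates.  Monomorphic variants are flagged (tested = False),
    not tested.  Two-sided p-values come from the t distribution with
    n - p - 1 df (``use_t=False`` switches to the large-n normal).
    """
    y = np.asarray(y, float)
    if isinstance(genotypes, Genotypes):
        X = genotypes.dosages
        variant_ids = genotypes.variants["variant_id"].to_numpy()
        meta = genotypes.variants[["chrom", "pos"]].reset_index(drop=True)
    else:
        X = _dosage_matrix(genotypes)
        variant_ids = np.array([f"v{j}" for j in range(X.shape[1])])
        meta = None
    n = y.size
    if X.shape[0] != n:
        raise PleioscanError("dosage matrix does not match phenotype length")

    d = null.eigvals + null.delta
    W = null.eigvecs / np.sqrt(d)  # whitener transpose: W' y
    ty = W.T @ y
    C = null.covariates
    cond_ids: list = []
    if condition_on:
        if not isinstance(genotypes, Genotypes):
            raise PleioscanError("conditioning requires a Genotypes container")
        cond_ids = list(np.atleast_1d(condition_on))
        cidx = genotypes.variant_index(cond_ids)
        C = np.column_stack([C, X[:, cidx]])
    tC = W.T @ C
    tX = W.T @ X

    # residualize against whitened covariates (Frisch-Waugh)
    Q, _ = np.linalg.qr(tC)
    ry = ty - Q @ (Q.T @ ty)
    rX = tX - Q @ (Q.T @ tX)

    p_cov = C.shape[1]
    df = n - p_cov - 1
    xtx = (rX * rX).sum(axis=0)
    mono = np.ptp(X, axis=0) == 0
    testable = (~mono) & (xtx > 0)

    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        bh = (rX.T @ ry) / xtx
    rss = (ry @ ry) - bh**2 * xtx
    s2 = np.where(testable, rss / df, np.nan)
    beta[testable] = bh[testable]
    se[testable] = np.sqrt(s2[testable] / xtx[testable])
    t = beta / se
    if use_t:
        pvals = 2.0 * sps.t.sf(np.abs(t), df=df)
    else:
        pvals = 2.0 * sps.norm.sf(np.abs(t))

    out = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": pvals,
            "n_used": n,
            "tested": testable,
            "conditioned_on": ",".join(map(str, cond_ids)),
        }
    )
    if meta is not None:
        out.insert(1, "chrom", meta["chrom"])
        out.insert(2, "pos", meta["pos"])
    return out


def multi_trait_meta(t_stats, t_correlation=None) -> pd.DataFrame:
    """Combine per-analysis t-statistics per variant as sum(t^2) ~ chi2(n).

    ``t_stats``: (n_variants, n_analyses) array (or a single variant's
    vector).  ``t_correlation`` optionally decorrelates the statistics,
    stat = t' R^-1 t, for analyses on overlapping animals.
    """
    T = np.atleast_2d(np.asarray(t_stats, float))
    if T.size == 0:
        raise PleioscanError("empty t-statistic vector")
    n_analyses = T.shape[1]
    if t_correlation is not None:
        R = np.asarray(t_correlation, float)
        Rinv = np.linalg.inv(R)
        stat = np.einsum("ij,jk,ik->i", T, Rinv, T)
    else:
        stat = (T**2).sum(axis=1)
    p = sps.chi2.sf(stat, df=n_analyses)
    return pd.DataFrame({"stat": stat, "df": n_analyses, "p_value": p})


def hwe_test(dosages) -> np.ndarray:
    """1-df Pearson Hardy-Weinberg p-value per variant from hard calls."""
    X = np.clip(np.rint(_dosage_matrix(dosages)), 0, 2).astype(int)
    n = X.shape[0]
    counts = np.stack([(X == g).sum(axis=0) for g in (0, 1, 2)])  # (3, m)
    p = (2 * counts[2] + counts[1]) / (2.0 * n)
    expected = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            (p > 0) & (p < 1),
            np.nansum((counts - expected) ** 2 / expected, axis=0),
            0.0,
        )
    return sps.chi2.sf(chi2, df=1)


def variant_qc(
    variants: pd.DataFrame,
    dosages,
    maf_min: float | None = 0.001,
    r2_min: float | None = None,
    hwe_p_min: float | None = None,
):
    """Remove variants failing MAF / imputation-R2 / Hardy-Weinberg filters.

    Filters are applied as independent masks on the input, so the outcome is
    order-independent.  Returns ``(filtered_variants, kept_mask, log)`` with
    per-filter removal counts.
    """
    X = _dosage_matrix(dosages)
    if len(variants) != X.shape[1]:
        raise PleioscanError("variant table does not match the dosage matrix")
    keep = np.ones(len(variants), dtype=bool)
    removed = {}
    if maf_min is not None:
        freq = X.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        mask = maf >= maf_min
        removed["maf"] = int((~mask).sum())
        keep &= mask
    if r2_min is not None:
        if "imputation_r2" not in variants.columns:
            raise PleioscanError("imputation_r2 column required for the R2 filter")
        mask = variants["imputation_r2"].to_numpy() >= r2_min
        removed["imputation_r2"] = int((~mask).sum())
        keep &= mask
    if hwe_p_min is not None:
        mask = hwe_test(X) >= hwe_p_min
        removed["hwe"] = int((~mask).sum())
        keep &= mask
    log = {"n_in": len(variants), "n_out": int(keep.sum()), "removed": removed}
    return variants[keep].reset_index(drop=True), keep, log
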