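"""Bayesian four-component normal-mixture model for SNP effects (BayesR).

Each SNP effect is drawn from a mixture of normals with variances fixed at
(0, 0.00005, 0.0005, 0.005) x sigma2_P — a point mass at zero plus three
shells of increasing effect size — with a Dirichlet prior on the mixture
proportions.  Class variances are tied to the *phenotypic* variance of the
records, the appropriate anchor when trait heritabilities are unknown (as
for milk-composition traits measured on a strongly half-sib cohort).

Per-record weights accommodate heterogeneous accuracy: record k has residual
variance sigma2_e / w_k, so a bull phenotype backed by thousands of daughter
records can carry far more weight than a single cow record.

The Gibbs sampler cycles per sweep over the intercept, each SNP's mixture
class and effect (fixed column order, for reproducibility), the mixture
proportions (conjugate Dirichlet), and the residual variance (scaled inverse
chi-square with a flat prior, nu = -2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .io import Genotypes, PleioscanError

DEFAULT_CLASS_VARIANCES = (0.0, 0.00005, 0.0005, 0.005)


@dataclasses.dataclass(frozen=True)
class MixtureSpec:
    """Mixture-class variances as fractions of sigma2_P, plus Dirichlet prior."""

    class_variances: tuple = DEFAULT_CLASS_VARIANCES
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        cv = np.asarray(self.class_variances, float)
        if cv[0] != 0.0:
            raise PleioscanError("first mixture class variance must be exactly 0")
        if (np.diff(cv) < 0).any():
            raise PleioscanError("class variances must be nondecreasing")
        al = np.asarray(self.dirichlet_alpha, float)
        if len(al) != len(cv):
            raise PleioscanError("dirichlet_alpha length must match class_variances")
        if (al <= 0).any():
            raise PleioscanError("dirichlet_alpha entries must be > 0")


@dataclasses.dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise PleioscanError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise PleioscanError("thin must be >= 1")


@dataclasses.dataclass
class PosteriorEffects:
    """Posterior summaries of the SNP-effect mixture fit.

    ``effect_mean`` is the per-variant posterior mean effect — the v that
    enters the local genomic breeding value Wv downstream.
    """

    effect_mean: np.ndarray
    class_prob: np.ndarray  # (n_variants, n_classes)
    pi_mean: np.ndarray
    sigma2e_mean: float
    sigma2_P: float
    trace_summary: dict
    variant_ids: np.ndarray | None = None

    def to_frame(self, variants=None):
        import pandas as pd

        df = pd.DataFrame({"effect_mean": self.effect_mean})
        for k in range(self.class_prob.shape[1]):
            df[f"p_class{k}"] = self.class_prob[:, k]
        if variants is not None:
            df = pd.concat(
                [variants[["variant_id", "chrom", "pos"]].reset_index(drop=True), df],
                axis=1,
            )
        elif self.variant_ids is not None:
            df.insert(0, "variant_id", self.variant_ids)
        return df


def class_loglik(snp, residual, sigma2e, class_variance, weights=None):
    """Log marginal likelihood of the residual with the SNP effect integrated
    over its class prior N(0, class_variance).

    With D = diag(sigma2e / w), the marginal covariance is
    D + class_variance * x x'; the log density follows from the
    Sherman-Morrison identity and the matrix determinant lemma.  With
    class_variance = 0 this is the plain Gaussian log-likelihood of the
    residual.
    """
    if sigma2e <= 0:
        raise PleioscanError("sigma2e must be > 0")
    if class_variance < 0:
        raise PleioscanError("class_variance must be >= 0")
    x = np.asarray(snp, float)
    r = np.asarray(residual, float)
    w = np.ones_like(r) if weights is None else np.asarray(weights, float)
    n = r.size
    dinv = w / sigma2e  # D^{-1} diagonal
    base = -0.5 * (n * np.log(2 * np.pi) - np.log(dinv).sum() + (r * r * dinv).sum())
    if class_variance == 0.0:
        return base
    xtdx = (x * x * dinv).sum()
    xtdr = (x * r * dinv).sum()
    c = 1.0 + class_variance * xtdx
    return base - 0.5 * np.log(c) + 0.5 * class_variance * xtdr**2 / c


@njit(cache=True)
def _gibbs_kernel(
    Xt, y, w, class_var_abs, alpha, n_iter, burn_in, thin, seed
):  # pragma: no cover - exercised through fit_bayesr
    m, n = Xt.shape
    K = class_var_abs.shape[0]
    np.random.seed(seed)

    xtwx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += w[i] * Xt[j, i] * Xt[j, i]
        xtwx[j] = s
    wsum = w.sum()

    beta = np.zeros(m)
    mu = 0.0
    r = y.copy()  # r = y - mu - X beta
    pi = np.full(K, 1.0 / K)
    # initial residual variance: half the phenotypic variance
    ybar = 0.0
    for i in range(n):
        ybar += w[i] * y[i]
    ybar /= wsum
    s2 = 0.0
    for i in range(n):
        s2 += w[i] * (y[i] - ybar) ** 2
    sigma2e = 0.5 * s2 / (n - 1)

    beta_sum = np.zeros(m)
    class_count = np.zeros((m, K))
    pi_sum = np.zeros(K)
    sigma2e_trace = np.zeros((n_iter - burn_in + thin - 1) // thin)
    n_kept = 0

    logpi = np.log(pi)
    logp = np.empty(K)
    counts = np.empty(K)

    for it in range(n_iter):
        # intercept (flat prior)
        rhs_mu = 0.0
        for i in range(n):
            rhs_mu += w[i] * (r[i] + mu)
        new_mu = rhs_mu / wsum + np.random.normal() * np.sqrt(sigma2e / wsum)
        dmu = mu - new_mu
        for i in range(n):
            r[i] += dmu
        mu = new_mu

        for k in range(K):
            counts[k] = 0.0
            logpi[k] = np.log(pi[k])

        for j in range(m):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += Xt[j, i] * bj
            rhs = 0.0
            for i in range(n):
                rhs += w[i] * Xt[j, i] * r[i]
            # class log-probabilities (relative to the zero class)
            logp[0] = logpi[0]
            maxlp = logp[0]
            for k in range(1, K):
                v = class_var_abs[k]
                c = sigma2e + v * xtwx[j]
                logp[k] = (
                    logpi[k]
                    - 0.5 * np.log(c / sigma2e)
                    + 0.5 * v * rhs * rhs / (sigma2e * c)
                )
                if logp[k] > maxlp:
                    maxlp = logp[k]
            tot = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - maxlp)
                tot += logp[k]
            u = np.random.random() * tot
            acc = 0.0
            cls = K - 1
            for k in range(K):
                acc += logp[k]
                if u <= acc:
                    cls = k
                    break
            counts[cls] += 1.0
            if it >= burn_in and (it - burn_in) % thin == 0:
                class_count[j, cls] += 1.0
            if cls == 0:
                beta[j] = 0.0
            else:
                v = class_var_abs[cls]
                prec = xtwx[j] / sigma2e + 1.0 / v
                mean = rhs / sigma2e / prec
                newb = mean + np.random.normal() / np.sqrt(prec)
                beta[j] = newb
                for i in range(n):
                    r[i] -= Xt[j, i] * newb

        # mixture proportions | Dirichlet(alpha + counts)
        tot = 0.0
        for k in range(K):
            pi[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
            tot += pi[k]
        for k in range(K):
            pi[k] /= tot

        # residual variance | scaled inverse chi-square, flat prior nu = -2
        sse = 0.0
        for i in range(n):
            sse += w[i] * r[i] * r[i]
        sigma2e = sse / np.random.chisquare(n - 2)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                beta_sum[j] += beta[j]
            for k in range(K):
                pi_sum[k] += pi[k]
            sigma2e_trace[n_kept] = sigma2e
            n_kept += 1

    return beta_sum, class_count, pi_sum, sigma2e_trace, n_kept


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def fit_bayesr(
    genotypes,
    phenotypes,
    weights=None,
    mixture: MixtureSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorEffects:
    """Fit the SNP-effect mixture model by Gibbs sampling.

    ``genotypes`` may be a Genotypes container or a raw dosage matrix; one
    phenotype per individual (records already averaged).  Columns are
    centered internally.  Deterministic given ``mcmc.seed``.
    """
    mixture = mixture or MixtureSpec()
    mcmc = mcmc or MCMCConfig()
    variant_ids = None
    if isinstance(genotypes, Genotypes):
        variant_ids = genotypes.variants["variant_id"].to_numpy()
        X = genotypes.dosages
    else:
        X = np.asarray(genotypes, float)
        if X.ndim == 1:
            X = X[:, None]
    y = np.asarray(phenotypes, float)
    n, m = X.shape
    if y.shape != (n,):
        raise PleioscanError(
            f"phenotype length {y.shape} does not match {n} individuals"
        )
    if np.ptp(y) == 0:
        raise PleioscanError("constant phenotype: zero variance")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or (w <= 0).any():
            raise PleioscanError("weights must be positive, one per individual")
    if np.isnan(X).any():
        raise PleioscanError("missing dosages: mean-impute before fitting")

    sigma2_P = float(np.var(y, ddof=1))
    class_var_abs = np.asarray(mixture.class_variances, float) * sigma2_P
    Xt = np.ascontiguousarray((X - X.mean(axis=0)).T)

    beta_sum, class_count, pi_sum, s2e_trace, n_kept = _gibbs_kernel(
        Xt,
        y.astype(float),
        w.astype(float),
        class_var_abs,
        np.asarray(mixture.dirichlet_alpha, float),
        mcmc.n_iter,
        mcmc.burn_in,
        mcmc.thin,
        int(mcmc.seed) % (2**32),
    )
    class_prob = class_count / n_kept
    return PosteriorEffects(
        effect_mean=beta_sum / n_kept,
        class_prob=class_prob,
        pi_mean=pi_sum / n_kept,
        sigma2e_mean=float(s2e_trace[:n_kept].mean()),
        sigma2_P=sigma2_P,
        trace_summary={
            "n_kept": int(n_kept),
            "sigma2e_ess": _effective_sample_size(s2e_trace[:n_kept]),
            "sigma2e_trace": s2e_trace[:n_kept],
        },
        variant_ids=variant_ids,
    )
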