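"""Synthetic half-sib cattle cohorts: genotypes, traits, and expression.

The generator emulates the statistical structure of a dairy-cattle QTL study:
a cohort dominated by a handful of paternal half-sib families, LD-structured
SNP haplotypes, complex traits where a planted variant explains a tiny
fraction of phenotypic variance next to a polygenic background, genetically
simple secondary traits where the same variant has a large effect, repeated
records with permanent-environment and herd-year-season components and
heterogeneous record accuracy, and a cis-eQTL acting on a gene-expression
phenotype.

Haplotypes follow a first-order Markov copying model: a latent Gaussian
AR(1) process with lag-one correlation ``ld_rho`` is thresholded at the
allele-frequency quantile, so adjacent-marker LD decays geometrically along
the chromosome.  Daughters inherit a recombinant paternal gamete from their
sire (Haldane crossovers at 1 cM/Mb) and a fresh population haplotype from
an unrelated, non-genotyped dam.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import Genotypes, PleioscanError

RECOMBINATION_RATE_PER_BP = 1e-8  # 1 cM/Mb


@dataclasses.dataclass
class PopulationConfig:
    """Cohort layout and marker-panel parameters.

    Defaults give the simple-trait cohort: 444 cows, most from one of 8
    sire families.
    """

    n_sires: int = 8
    daughters_per_sire: int = 55
    n_unrelated: int = 4
    n_variants: int = 200
    chrom_length_bp: int = 10_000_000
    ld_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    focal_variant: int | None = None  # column index whose frequency is pinned
    focal_freq: float = 0.3
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires < 0 or self.daughters_per_sire < 0 or self.n_unrelated < 0:
            raise PleioscanError("counts must be non-negative")
        if self.n_sires * self.daughters_per_sire + self.n_unrelated <= 0:
            raise PleioscanError("population must contain at least one individual")
        if self.n_variants <= 0 or self.chrom_length_bp <= 0:
            raise PleioscanError("n_variants and chrom_length_bp must be positive")
        if not (0.0 < self.ld_rho < 1.0):
            raise PleioscanError("ld_rho must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise PleioscanError("maf_range must lie within (0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return self.n_sires * self.daughters_per_sire + self.n_unrelated


@dataclasses.dataclass
class TraitModel:
    """Generating model for one or more (possibly pleiotropic) traits.

    Per trait t the analysis-ready phenotype decomposes as
    ``sum_q a_qt * dosage_q + polygenic + PE + HYS + mean(residuals)``;
    fixed effects (breed, age and days-in-milk polynomials) are zero by
    construction because downstream stages consume pre-corrected phenotypes.

    ``qtl_var_fraction`` rows are traits, columns planted QTL, entries
    fractions of ``sigma2_P``.  The allele-substitution effect a solves
    2 p (1-p) a^2 = fraction * sigma2_P at the realized allele frequency,
    unless ``qtl_effects`` pins the effect in trait units directly (then the
    fraction is implied).  When ``residual_var`` is not given, the
    per-record residual variance is chosen as
    ``n_records * (1 - sum of fractions) * sigma2_P`` so that the
    record-averaged phenotype has variance sigma2_P in expectation.
    """

    trait_names: tuple = ("trait",)
    qtl_positions: tuple = ()
    qtl_var_fraction: np.ndarray | None = None  # (n_traits, n_qtl)
    qtl_effects: np.ndarray | None = None  # trait units per allele; overrides
    polygenic_h2: tuple = (0.25,)
    pe_var_fraction: tuple = (0.15,)
    hys_var_fraction: tuple = (0.10,)
    sigma2_P: tuple = (1.0,)
    residual_var: tuple | None = None  # per-record sigma2_e; derived if None
    n_records: int = 2
    frac_single_record: float = 0.0
    record_weight: float = 1.0
    hys_group_size: int = 20

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        nq = len(self.qtl_positions)
        if self.qtl_var_fraction is None:
            self.qtl_var_fraction = np.zeros((k, nq))
        self.qtl_var_fraction = np.atleast_2d(np.asarray(self.qtl_var_fraction, float))
        if self.qtl_var_fraction.shape != (k, nq):
            raise PleioscanError(
                f"qtl_var_fraction must be (n_traits={k}, n_qtl={nq})"
            )
        if self.qtl_effects is not None:
            self.qtl_effects = np.atleast_2d(np.asarray(self.qtl_effects, float))
            if self.qtl_effects.shape != (k, nq):
                raise PleioscanError("qtl_effects must be (n_traits, n_qtl)")
        for name in ("polygenic_h2", "pe_var_fraction", "hys_var_fraction", "sigma2_P"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), float), (k,))
            object.__setattr__(self, name, np.array(arr))
        if (self.qtl_var_fraction < 0).any():
            raise PleioscanError("variance fractions must be >= 0")
        total = (
            self.qtl_var_fraction.sum(axis=1)
            + self.polygenic_h2
            + self.pe_var_fraction
            + self.hys_var_fraction
        )
        if (total > 1.0 + 1e-12).any():
            raise PleioscanError("per-trait variance fractions must sum to <= 1")
        if self.n_records not in (1, 2):
            raise PleioscanError("n_records must be 1 or 2")
        if not (0.0 <= self.frac_single_record <= 1.0):
            raise PleioscanError("frac_single_record must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclasses.dataclass
class ExpressionModel:
    """Cis-eQTL acting on one gene's (variance-stabilized) expression."""

    gene_id: str = "geneA"
    gene_window: tuple = ("1", 0, 1_000_000)
    eqtl_variant: str | None = None
    eqtl_beta: float = 1.0
    covariate_confounding: float = 0.0  # SD units of the family-structure score
    cohort_effect: float = 0.0
    n_cohorts: int = 2
    noise_sd: float = 1.0


# ---------------------------------------------------------------------------


def _sample_haplotypes(rng, n_hap, thresholds, ld_rho):
    """Latent-AR(1) haplotypes; allele = 1 where the latent value is below
    the allele-frequency quantile, giving marginal frequency p per marker."""
    m = thresholds.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    innov = rng.standard_normal((n_hap, m))
    scale = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, m):
        z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j]
    return (z < thresholds).astype(np.int8)


def _recombine(rng, hap_a, hap_b, positions):
    """One gamete per row pair via Haldane crossovers (1 cM/Mb)."""
    n, m = hap_a.shape
    d = np.diff(positions).astype(float)
    switch_p = 0.5 * (1.0 - np.exp(-2.0 * RECOMBINATION_RATE_PER_BP * d))
    current = rng.integers(0, 2, size=n)
    source = np.empty((n, m), dtype=np.int8)
    source[:, 0] = current
    switches = rng.random((n, m - 1)) < switch_p
    for j in range(1, m):
        current = np.where(switches[:, j - 1], 1 - current, current)
        source[:, j] = current
    return np.where(source == 0, hap_a, hap_b)


def simulate_genotypes(config: PopulationConfig) -> Genotypes:
    """Half-sib cohort genotypes on a single chromosome.

    Each daughter receives a recombinant gamete from her sire and a fresh
    population haplotype from an unrelated dam; sires and ``n_unrelated``
    animals carry two fresh haplotypes.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False)
    )
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    if config.focal_variant is not None:
        # planted-QTL frequency is a study condition, not a random draw
        freqs[config.focal_variant] = config.focal_freq
    thresholds = norm.ppf(freqs)

    sire_h1 = _sample_haplotypes(rng, config.n_sires, thresholds, config.ld_rho)
    sire_h2 = _sample_haplotypes(rng, config.n_sires, thresholds, config.ld_rho)

    n_d = config.n_sires * config.daughters_per_sire
    sire_of = np.repeat(np.arange(config.n_sires), config.daughters_per_sire)
    paternal = _recombine(
        rng, sire_h1[sire_of], sire_h2[sire_of], positions
    ) if n_d else np.empty((0, m), dtype=np.int8)
    maternal = _sample_haplotypes(rng, n_d, thresholds, config.ld_rho)
    daughters = paternal + maternal

    unrelated = _sample_haplotypes(
        rng, config.n_unrelated, thresholds, config.ld_rho
    ) + _sample_haplotypes(rng, config.n_unrelated, thresholds, config.ld_rho)

    sires = sire_h1 + sire_h2
    dosages = np.vstack([daughters, unrelated, sires]).astype(float)

    sample_ids = (
        [f"d{i:05d}" for i in range(n_d)]
        + [f"u{i:05d}" for i in range(config.n_unrelated)]
        + [f"s{i:03d}" for i in range(config.n_sires)]
    )
    sire_ids = (
        [f"s{s:03d}" for s in sire_of]
        + [""] * config.n_unrelated
        + [""] * config.n_sires
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "sire_id": sire_ids})
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j:06d}" for j in range(m)],
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "freq": freqs,  # generating ALT frequency (haplotype marginal)
        }
    )
    return Genotypes(dosages, variants, samples)


def _qtl_effect_sizes(model: TraitModel, geno: Genotypes, qtl_idx):
    """Allele-substitution effects per (trait, qtl), and implied fractions."""
    k, nq = model.n_traits, len(qtl_idx)
    effects = np.zeros((k, nq))
    p = geno.allele_freq()[qtl_idx]
    het = 2.0 * p * (1.0 - p)
    if (het == 0).any() and nq:
        raise PleioscanError("planted QTL is monomorphic in this cohort")
    for t in range(k):
        for q in range(nq):
            if model.qtl_effects is not None and model.qtl_effects[t, q] != 0.0:
                effects[t, q] = model.qtl_effects[t, q]
            else:
                frac = model.qtl_var_fraction[t, q]
                if frac > 0:
                    effects[t, q] = np.sqrt(frac * model.sigma2_P[t] / het[q])
    return effects, het


def simulate_phenotypes(geno: Genotypes, model: TraitModel, seed: int = 0):
    """Repeated trait records for every genotyped animal.

    Returns ``(records, truth)``: a record table (animal_id, trait,
    record_index, value, weight) and a dict with the realized components
    (qtl effects, breeding values, per-animal PE/HYS draws) for testing.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    qtl_idx = (
        geno.variant_index(
            [
                geno.variants.loc[
                    (geno.variants["pos"] == pos), "variant_id"
                ].iloc[0]
                for pos in model.qtl_positions
            ]
        )
        if model.qtl_positions
        else np.array([], dtype=int)
    )
    effects, het = _qtl_effect_sizes(model, geno, qtl_idx)

    X = geno.dosages
    Xc = X - X.mean(axis=0)
    # per-animal record counts: a configurable fraction has a single record
    n_rec = np.full(n, model.n_records)
    if model.n_records == 2 and model.frac_single_record > 0:
        single = rng.random(n) < model.frac_single_record
        n_rec[single] = 1

    # herd-year-season groups cut across families, as in real herds
    hys_group = rng.permutation(n) // max(model.hys_group_size, 1)
    n_groups = hys_group.max() + 1

    frames = []
    truth = {"effects": effects, "qtl_idx": qtl_idx, "het": het, "traits": {}}
    for t, name in enumerate(model.trait_names):
        s2p = model.sigma2_P[t]
        frac_sum = (
            model.qtl_var_fraction[t].sum()
            + model.polygenic_h2[t]
            + model.pe_var_fraction[t]
            + model.hys_var_fraction[t]
        )
        if model.residual_var is not None:
            sigma2_e = float(np.broadcast_to(model.residual_var, (model.n_traits,))[t])
        else:
            sigma2_e = model.n_records * max(1.0 - frac_sum, 0.0) * s2p

        qtl_term = Xc[:, qtl_idx] @ effects[t] if len(qtl_idx) else np.zeros(n)
        if model.polygenic_h2[t] > 0:
            # small effects at every marker, scaled to the target variance
            b = rng.standard_normal(geno.n_variants)
            u = Xc @ b
            sd = u.std()
            u = (
                u / sd * np.sqrt(model.polygenic_h2[t] * s2p)
                if sd > 0
                else np.zeros(n)
            )
        else:
            u = np.zeros(n)
        pe = rng.standard_normal(n) * np.sqrt(model.pe_var_fraction[t] * s2p)
        hys_eff = rng.standard_normal(n_groups) * np.sqrt(
            model.hys_var_fraction[t] * s2p
        )
        hys = hys_eff[hys_group]
        base = qtl_term + u + pe + hys

        animal_ids = geno.samples["sample_id"].to_numpy()
        for rec in range(model.n_records):
            active = n_rec > rec
            e = rng.standard_normal(int(active.sum())) * np.sqrt(
                sigma2_e / model.record_weight
            )
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": animal_ids[active],
                        "trait": name,
                        "record_index": rec,
                        "value": base[active] + e,
                        "weight": model.record_weight,
                    }
                )
            )
        truth["traits"][name] = {
            "qtl_term": qtl_term,
            "polygenic": u,
            "pe": pe,
            "hys": hys,
            "sigma2_e": sigma2_e,
        }
    records = pd.concat(frames, ignore_index=True)
    return records, truth


def simulate_expression(geno: Genotypes, model: ExpressionModel, seed: int = 0):
    """Gaussian-scale expression phenotypes with a planted cis-eQTL.

    expression = beta * dosage + confounding * structure score
                 + cohort effect + noise.
    The structure score is the leading principal component of the centered
    dosage matrix (families separate along it), standing in for ancestry.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    if model.eqtl_variant is not None:
        j = int(geno.variant_index([model.eqtl_variant])[0])
        dos = geno.dosages[:, j] - geno.dosages[:, j].mean()
    else:
        dos = np.zeros(n)

    if model.covariate_confounding != 0.0:
        Xc = geno.dosages - geno.dosages.mean(axis=0)
        # leading left singular vector = top PC score
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        score = u[:, 0] * np.sqrt(n)
        structure = model.covariate_confounding * score
    else:
        structure = np.zeros(n)

    cohorts = np.array(
        [f"facility{i % model.n_cohorts}" for i in range(n)]
    )
    cohort_shift = model.cohort_effect * (
        pd.factorize(cohorts)[0] - (model.n_cohorts - 1) / 2.0
    )
    value = (
        model.eqtl_beta * dos
        + structure
        + cohort_shift
        + rng.standard_normal(n) * model.noise_sd
    )
    return pd.DataFrame(
        {
            "sample_id": geno.samples["sample_id"],
            "gene_id": model.gene_id,
            "value": value,
            "cohort": cohorts,
        }
    )
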