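# Methods

`pleioscan` implements a QTL-mapping strategy for complex traits whose
individual causal variants explain too little phenotypic variance (σ²P) to be
found directly: exploit *genetically simple* secondary traits — detailed milk
composition phenotypes, gene expression — on which the same variants have
much larger effects, and declare a locus interesting when QTL for the complex
and the simple trait co-locate. The canonical example the package is built
around is a variant that explains ~0.001 σ²P of milk yield but 0.11 σ²P of
milk phosphorus concentration (allele-substitution effect −41.8 mg/kg), with
a strong cis-eQTL on a phosphorus-antiporter gene at the same position.

## Models and procedures

### SNP-effect mixture model (BayesR)

Phenotypes y (one record-averaged value per animal) are modelled as
y = 1μ + Wβ + e, where W holds centered dosages and each βⱼ is drawn from a
four-component normal mixture with variances fixed at
(0, 0.00005, 0.0005, 0.005)·σ²P and a Dirichlet(1,1,1,1) prior on the
mixture proportions π. Anchoring the class variances to the *phenotypic*
variance (rather than the genetic variance) is deliberate: the secondary
traits are measured on a strongly half-sib cohort whose heritability cannot
be estimated reliably, while σ²P is always observable.

Heterogeneous record accuracy (bull progeny averages vs single cow records)
enters through per-record weights: record k has residual variance σ²e/wₖ.
Scaling all weights by a constant leaves the effect chain exactly invariant
(the residual variance absorbs the scale), which the tests exercise.

The Gibbs sampler cycles over μ, each SNP's class indicator and effect
(conjugate draws; the class indicator uses the marginal likelihood with the
effect integrated out), π (conjugate Dirichlet), and σ²e (scaled inverse
chi-square with a flat prior, ν = −2; the paper-level source is silent on
the prior). Defaults: 10,000 iterations, 5,000 burn-in, thinning 10. SNPs
are updated in fixed column order each sweep so a seed fully determines the
chain. The inner loop is compiled with numba; a fit of 2,000 animals ×
2,000 SNPs × 10,000 sweeps takes on the order of a minute.

Identifiability caveat: under a null trait the three smallest mixture
classes are mutually near-indistinguishable (log marginal-likelihood
differences of order 10⁻² per SNP at desk-scale n), so posterior class
probabilities for null SNPs spread over the small classes rather than
concentrating entirely on the point mass; the identifiable statements —
near-zero posterior effects and desertion of the detectable 0.005-class —
are what the tests assert.

### Local-GEBV window variance and QTL calling

For sliding windows of 250 kb advancing in 50 kb steps (anchored at
coordinate 0, half-open intervals, BED convention), the local genomic
estimated breeding value of each animal is Wv restricted to the window's
SNPs, with v the posterior mean effects. A window's statistic is the sample
variance (denominator n−1; the denominator convention affects reported
values, not rankings) of the local GEBV across animals. QTL are the top
⌈f·N⌉ windows by that statistic — f = 2 % for complex milk-production-like
traits, 0.1 % for genetically simple traits — with ties broken in genome
order so the call count never depends on tie structure. Zero-variant windows
carry a statistic of 0 and stay in the denominator, keeping genome fractions
interpretable. Cumulative-variance profiles (share of total window variance
captured by the top fraction) are computed on the offset-0 non-overlapping
tiling to avoid double counting.

### QTL-overlap chi-squared test

Because sliding windows overlap, co-location of two traits' QTL sets is
scored on the size/step = 5 non-overlapping tilings (phases) of the window
grid. Per tiling, each tile is marked QTL/not-QTL per trait if any called
sliding window intersects it by ≥ 1 bp; the four cells of the 2×2 table are
averaged over the tilings and a single 1-df Pearson chi-squared statistic
(no continuity correction) is computed on the averaged table. Averaging
cells before one test (rather than averaging five statistics) is a design
choice; the sentence-level description of the source procedure admits both
readings. Significance is one-sided: the observed overlap must also exceed
the independence expectation f_A·f_B·N. The worked expectation for the
study's scale is 0.02 × 0.001 × 10,015 = 0.2003 — under independence, less
than one shared window is expected genome-wide.

Pearson's reference distribution is asymptotic and the expected co-location
counts here are deliberately far below 1; a circular-rotation permutation
p-value (`n_rotations` in `overlap_chi2`) is available as a calibration
companion. Empirically the chi-squared decision is adequately calibrated at
these designs (measured type-I error 0.041 at nominal 0.05 over 1,000
placement replicates), which is what the acceptance checks assert.

### Mixed-model association and the Σt² meta-analysis

Single-variant association uses the two-stage EMMAX approximation:
variance components of y = Xb + g + e, g ~ N(0, σ²g K), are estimated once
by REML under the no-variant null via the eigendecomposition of K and 1-D
bounded optimization of the variance ratio δ = σ²e/σ²g; every variant is
then a generalized-least-squares regression with δ fixed, implemented by
whitening with D^(−1/2)U′ and Frisch–Waugh residualization. The kinship is
identity-by-state allele sharing (entry = mean over variants of
1 − |dᵢ − dⱼ|/2), matching the source design; a centered (VanRaden) GRM is
available as an option. Dosages may be fractional (expected dosages from
genotype probabilities — the standard EMMAX treatment). Two-sided p-values
use the t distribution with n − p − 1 df by default; the large-n normal is a
flag. Monomorphic variants are flagged, not tested. Conditioning on
candidate variants adds their dosages to the covariates; the kinship should
come from a genome-wide panel, not the tested region — building K from the
target region itself absorbs the regional signal (proximal contamination)
and the conditioning experiment constructs K from a second chromosome for
exactly this reason.

Analyses run separately per cohort (e.g. bulls and cows, to respect their
heterogeneous error variance) are combined per variant as Σt² referred to a
chi-squared distribution with df equal to the number of contributing
t-statistics. This assumes independent analyses; for correlated traits on
the same animals it is anti-conservative, and a decorrelated form t′R⁻¹t is
available via the `t_correlation` argument.

Variant QC applies independent masks — MAF ≥ 0.001, imputation R² ≥ 0.70,
Hardy-Weinberg exact-count chi-squared p ≥ 1 × 10⁻¹⁰ (thresholds
configurable, any filter can be disabled) — so the outcome is
order-independent; per-filter removal counts are logged.

### eQTL mapping

Expression phenotypes are taken as already variance-stabilized values.
Population structure is absorbed by classical (Torgerson) MDS of the genetic
distance 1 − IBS: double-center −D²/2, keep the top k = 10 eigenvectors
scaled by √eigenvalue (coordinates are unique up to sign/rotation; tests
compare distances, never signs). Each variant is tested in a fixed-effects
linear model: expression ~ dosage + 10 MDS axes + cohort (sequencing
facility) fixed effect; a single-level cohort factor is dropped with a log
notice. Genome-wide expression outliers can be removed by
principal-component distance (> 4 SD from the centroid on the top 2 axes by
default; the threshold is configurable since no canonical value exists).

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
cattle biology in mechanistic detail:

- **Pedigree.** Eight paternal half-sib families dominate the cohort
  (default 444 = 8 × 55 + 4 unrelated). Daughters inherit one recombinant
  gamete from their sire (Haldane crossovers, 1 cM/Mb) and one fresh
  population haplotype from an unrelated, non-genotyped dam.
- **LD.** Haplotypes come from a latent Gaussian AR(1) with lag-one
  correlation `ld_rho` (default 0.7), thresholded at each marker's
  allele-frequency quantile. Adjacent-marker dosage r² is therefore lower
  than `ld_rho` (thresholding attenuates the latent correlation) and decays
  geometrically with marker distance. This is a copying model, not a
  coalescent; it provides windows with internal structure and tunable proxy
  strength, nothing more.
- **Traits.** Per trait: planted QTL effects (either as variance fractions,
  converted via 2p(1−p)a² = fraction·σ²P at the realized frequency, or
  pinned in trait units), a polygenic term over all markers, permanent
  environment, herd-year-season (groups assigned by random permutation —
  herds cut across families), and per-record residuals. Fixed effects
  (breed, age and days-in-milk polynomials) are zero by construction:
  downstream stages consume pre-corrected phenotypes. Records default to 2
  per animal (a configurable fraction gets 1, to exercise the 2-record
  filter); when the residual variance is not given explicitly it is set to
  n_records·(1 − Σ fractions)·σ²P so the record-averaged analysis phenotype
  has variance σ²P.
- **Focal variant.** The planted variant's allele frequency is a pinned
  study condition (default 0.3) rather than a random draw, so its variance
  fraction and allele-substitution effect are mutually consistent across
  replicates.
- **Expression.** expression = β·dosage + confounding·(leading genotype PC)
  + cohort shift + Gaussian noise. Read counts, alignment, and
  count-to-Gaussian transformation are out of scope.

What the generator does *not* emulate — coalescent LD, multi-chromosome
maps, genotyping error, selection, breed admixture gradients — bounds what
green tests show: they validate the statistical machinery under the stated
structure, not performance on real cattle data.

## Scales used by the test suite

Simulation sizes are chosen so the full suite runs on a single CPU desk
machine in minutes:

- Planted-variant recovery: 200 replicates of 444-cow cohorts, 200 markers
  on 10 Mb. Mean single-variant R² carries a small upward drift relative to
  the planted 0.11 (finite-sample 1/n bias plus family-structure variance),
  well inside the ±0.02 acceptance band.
- End-to-end pipeline: 20 replicates, 500 markers on a 25 Mb chromosome,
  n = 2,000 with the 444-cow simple-trait subset drawn from the same cohort,
  BayesR 3,000 sweeps (1,000 burn-in). The 25 Mb chromosome stands for a
  ~1 % genome slice: regional polygenic variance is the genome-wide 0.25
  scaled by the slice share (0.0025), with off-slice polygenic variance
  entering as an animal-level component (it is unlinked to the slice's
  markers, so it is statistically a permanent-environment term). Without
  this scaling, a genome's worth of polygenic variance would be compressed
  into the slice and swamp window rankings in a way that has no analogue at
  full scale.
- Overlap calibration: placement-level replicates (no trait simulation) at
  2,000 windows (type-I error) and ~10,015 windows × 5 phases (negative
  control), matching the study's window universe.
- Conditioning: 2 Mb target region at `ld_rho` 0.995 (the source variants
  were in complete LD) with kinship from a 30 Mb background panel.

## Numerical choices and degenerate inputs

- Constant phenotypes are rejected (σ²P = 0 degenerates the mixture scale).
- Missing dosages must be mean-imputed before `fit_bayesr`; the loaders
  mean-impute missing hard calls.
- The IBS kernel is clipped to PSD (negative eigenvalues set to 0) before
  REML; δ is optimized on log scale in [10⁻⁵, 10⁵].
- With K = I the variance ratio is unidentified and only σ²g + σ²e is
  meaningful; it equals the OLS residual variance and the scan reduces
  exactly to OLS t-tests (a test asserts equality to 1e-8).
- Window calling uses ⌈fraction·N⌉; `call_qtl` on an empty table and
  fractions outside (0,1) are errors.
- Internal coordinates are 0-based half-open; VCF positions are converted on
  load and reconverted on write (a property test round-trips positions).

## Known limitations

- The Σt² meta-statistic is anti-conservative for correlated analyses
  unless decorrelated; the default matches the source procedure.
- The AR(1) copying model cannot produce long-range LD plateaus or
  complete-LD variant pairs at a distance; conditioning experiments use
  high `ld_rho` instead.
- No Bayes factors or credible intervals for QTL declaration; calling is by
  genome-fraction rank, as in the source design.
- Sequence imputation, read alignment/quantification, variant calling, and
  haplotype phasing are out of scope; genotypes enter as (possibly
  fractional) dosages via VCF or dosage TSV. PLINK binary fileset support
  is intentionally absent.
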