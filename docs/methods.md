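# Methods

`sowreact` implements a genetics pipeline for behavioral reactivity in
lactating sows under heat stress: ethogram-derived trait construction,
genomic animal models fitted by Gibbs sampling, and a GWAS that
back-solves genomic breeding values into SNP effects. This note
documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Ethogram traits

A shaving test yields, per sow: posture at three time points on the
four-level alertness scale LDL < LDS < SIT < STD; vocalization subsets
of {SGT, LGT, BRK} at three stages (four when the sow had to be
repositioned); shave time in seconds; touch counts and an intervention
indicator.

* **Posture-change score** = ordinal level difference of consecutive
  postures, in [−3, 3]. Positive means increased alertness.
* **Vocalization score (VS)** = sum over stages of the 0–7 ordinal
  subset score ({} → 0 up to {BRK} → 7, mixtures in between).
* **Responsiveness score (RS)** = VS + the sum of the two
  posture-change scores, unclipped. The observation protocol only says
  the two components are "combined" with posture increases counting
  positively; the additive rule is the simplest one consistent with a
  non-reactive, silent sow scoring exactly 0. Because sows rarely start
  the test standing, negative RS values are possible in principle but
  rare in practice. VS is the raw stage sum, not rescaled for 3- vs
  4-stage sessions; the intervention-moment systematic effect absorbs
  the stage-count difference in the model.
* **Shave time (ST)** is used as recorded.

Summary statistics remove continuous-trait records (ST) further than 3
SD from the trait mean before summarizing; the categorical scores keep
every record. Sessions with a missing posture observation are dropped
with a logged reason.

## Genotype QC

Filters run in the order: call rate < 0.90 (markers, then individuals;
exactly 0.90 is retained), MAF < 0.01, |observed − expected (2p(1−p))
heterozygosity| > 0.15, missing or duplicated (chromosome, position)
coordinates (first occurrence kept, a deterministic file-order rule),
and genotyped individuals without phenotypes. Frequencies are
recomputed after the missingness filter, the usual chip-QC convention.
Only the PLINK text dialect (.ped/.map) and a dosage CSV are read;
allele coding (the counted allele) is recorded in the marker map.

## Genomic relationship matrix

VanRaden method 1: G = ZZ′ / 2Σp(1−p) with Z the dosage matrix centered
at 2p, p computed from the analyzed sample, and missing dosages
mean-imputed at 2p. No pedigree exists in this population, so
invertibility is guaranteed by an explicit identity blend
G* = (1−ε)G + εI with ε = 0.01 by default, recorded in the matrix
provenance. ε = 0.01 perturbs diagonals by ≤1% while bounding the
smallest eigenvalue away from zero for the sampler and the GWAS
back-solve.

## Animal models and the Gibbs sampler

Single-record traits: y = Xβ + Za + e with a ~ N(0, G*σ²a),
e ~ N(0, Iσ²e). Repeated-record traits add Wpe with pe ~ N(0, Iσ²pe).
Heritability is σ²a/(σ²a+σ²e) per draw (single) or
σ²a/(σ²a+σ²pe+σ²e) (repeated), and repeatability
(σ²a+σ²pe)/(σ²a+σ²pe+σ²e) is reported for the latter. Two-trait models
share the G* kernel with a 2×2 genetic covariance matrix; the genetic
correlation is cov12/√(σ²a1·σ²a2) per draw, and the phenotypic
correlation sums the component covariances. The residual covariance is
estimated only when both traits are recorded on an identical record
structure; otherwise it is fixed at 0. A pair whose
genetic-correlation chain fails the Geweke criterion at p < 0.05 is
flagged as failed-to-converge (FTC) rather than summarized silently.

Sampling uses blocked location updates. Writing G* = UDU′ and solving
the generalized eigenproblem of (U′Z′ZU, D⁻¹) once per kernel yields
coordinates with an iid N(0, σ²a) prior in which the full conditional
of the additive effects is diagonal for every variance ratio, so a
sweep costs O(n²) rather than a fresh O(n³) factorization; the
decompositions are cached per kernel and reused across traits and
chains. Fixed effects are drawn jointly from their multivariate normal
full conditional (flat prior); variances from scaled inverse chi-square
full conditionals and covariance matrices from inverse Wisharts.

Priors default to flat (bounded improper) on variances — the posterior
is proper at the sample sizes this pipeline targets — with a
weakly-informative alternative (ν = 4, scale = phenotypic variance
split evenly across components) selectable in the chain config. The
weak prior is also what the dense-grid cross-check uses, because with a
flat prior and five observations the posterior mean of σ²a does not
exist. Chain defaults are 500,000 iterations, 150,000 burn-in,
thinning 80; the test suite and the recovery experiments use shorter,
config-driven chains (typically 2,500–3,000 iterations, burn-in
800–1,000, thinning 2–4 at n = 500–1,000), which the eigencoordinate
sampler mixes well enough to make parameter-recovery bias < 0.05 in h².
Retained draws number ⌊(iterations − burn-in)/thin⌋.

Systematic-effect selection mirrors the classical lm()/stepAIC
workflow: ordinary least squares on the full candidate model,
bidirectional AIC refinement, then removal of terms with partial-F
p ≥ 0.05 (type-II ANOVA). Ties are broken by term name so the
procedure is deterministic.

## Chain diagnostics

Geweke compares the means of the first 10% and last 50% of a chain,
standardized by spectral density estimates at frequency zero
(Bartlett-windowed autocovariances, window = 4% of the segment); a
chain passes at p > 0.05. The effective sample size uses FFT
autocovariances with Geyer's initial-positive-sequence truncation on
paired lags; for antithetic chains the estimate may exceed n and is
flagged rather than clipped.

## GWAS

Marker effects are recovered from each retained draw of the additive
effects as ĝ = Z′G*⁻¹u / 2Σp(1−p); the per-marker posterior mean and
SD are reported. For the test statistics, the package computes the
marker-effect BLUP and its exact sampling variance at the
posterior-mean variance components,
var(ĝ_j) = (σ²a/denom)² (Z′PZ)_jj, where P is the inverse phenotypic
covariance with fixed effects absorbed. Because this statistic is
linear in y it is calibrated under the null (genomic inflation λ ≈ 1 in
the calibration tests). Standardizing instead by the posterior SD of
the draws is available as a sensitivity mode but is strongly
conservative on 50K-scale panels — weakly informed markers retain most
of their prior uncertainty, which deflates λ far below 1 — so it is not
the default. An unshrunken single-marker GLS effect (same z-score,
interpretable allele-substitution scale) is reported alongside for
effect-size and variance-explained estimation.

Variance explained is 2p(1−p)ĝ²/σ²p with the phenotypic variance as
the default denominator (configurable). Chromosome-wise significance
uses Me = 2NeL/ln(NeL) with Ne = 100 and L the chromosome's bp span
converted at 1 cM/Mb (both configurable; the log base can be switched
for sensitivity); the threshold is α/Me with α = 0.05. The genomic
inflation factor is the median 1-df chi-square statistic over its null
median. Candidate windows are ±100 kb around significant markers,
0-based half-open, clamped at the chromosome start, merged when
overlapping.

## Synthetic data

The generator produces HWE genotypes (MAF drawn from 0.01–0.5 by
default, ~200 markers per 100 Mb chromosome at desk scale), polygenic
trait architectures with exact known truth (marker effects drawn
jointly across traits to honor a requested genetic correlation matrix,
optional planted QTL of fixed variance fractions, permanent-environment
variance for repeated records, categorical group effects), and an
ethogram observation layer: a latent reactivity value per sow is
thresholded into postures and stage vocalization scores, with a
log-normal shave time and touch/intervention covariates. The
observation-layer constants were fixed once so the derived scores
resemble the published descriptive pattern of this test (RS/VS means
near 5.7/4.5, ST near 55 s, ~44% of sows needing no intervention, of
the rest ~18% intervened before the first site) while retaining most of
the latent signal; with latent h² = 0.15 the realized heritability of
the derived RS is ≈ 0.11–0.12 because discretization and stage noise
attenuate the signal, which is why the end-to-end recovery test allows
a ±0.08 band around the latent value.

What the generator does **not** emulate: linkage disequilibrium
(markers are independent, so Me-based thresholds are if anything
anti-conservative relative to real chip data), selection or family
structure beyond what random mating induces, climate-driven
physiological dynamics, and observer effects. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to the full complexity of
field data.

## Problem sizes in the shipped tests

The recovery experiments run at n = 1,000 individuals × 1,500 markers
(20 replicates per heritability level), the GWAS calibration at
n = 800 × 3,000 (null) and n = 1,000 × 2,000 (power, 20 replicates),
and the integration test at n = 500 × 2,000 — sizes at which the
estimators' sampling error is small relative to the acceptance bands
while a full run of the suite stays in the tens of minutes on one CPU.

## Known limitations

* Two-trait fits require complete records per trait on the shared
  individual set; records with one trait missing are not imputed.
* The categorical scores are analyzed with linear (Gaussian) models,
  as in the source protocol; no threshold/liability model is provided.
* REML/EM estimation, pedigree and single-step evaluation, and
  gene/QTL annotation are out of scope.
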