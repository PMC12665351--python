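# sowreact

Genetics of behavioral reactivity in lactating sows under heat stress.

Commercial sow herds in hot climates need animals that cope with both
thermal load and routine human handling. A standardized handling event
— shaving a patch on each flank for skin-temperature measurement —
can be scored into three behavioral traits: the **responsiveness score
(RS)**, the **vocalization score (VS)** and the **shave time (ST)**.
`sowreact` is a pipeline for estimating the genetic basis of such
traits from SNP-chip data when no pedigree is recorded:

1. **ethogram** — score raw session records (postures at three time
   points on the LDL < LDS < SIT < STD alertness scale, per-stage
   vocalization subsets of {SGT, LGT, BRK}, shave seconds) into RS, VS
   and ST, with descriptive summaries and a 3-SD outlier rule for
   continuous traits;
2. **genotype_qc** — PLINK-text/CSV genotype input and chip QC (call
   rate 0.90, MAF 0.01, heterozygosity deviation 0.15, position
   filters, unphenotyped-animal removal) with exact removal
   bookkeeping;
3. **grm** — the VanRaden method-1 genomic relationship matrix
   G = ZZ′/2Σp(1−p), identity-stabilized for invertibility, plus the
   pairwise-relatedness distribution;
4. **mixed_models** — Bayesian animal models fitted by Gibbs sampling:
   y = Xβ + Za + e with a ~ N(0, Gσ²a) (plus Wpe for repeated
   records), single-, repeatability- and two-trait forms; per-draw
   heritability h² = σ²a/(σ²a + [σ²pe +] σ²e) and genetic correlation
   rg = cov₁₂/√(σ²a₁σ²a₂); stepwise (AIC + partial-F) selection of
   systematic effects;
5. **diagnostics** — Geweke convergence checks and effective sample
   sizes for the chains;
6. **gwas** — back-solve GEBVs into SNP effects
   ĝ = Z′G⁻¹û/2Σp(1−p), approximate p-values, variance explained,
   chromosome-wise Bonferroni thresholds from the effective number of
   independent segments Me = 2NeL/ln(NeL), the genomic inflation
   factor λ, and ±100 kb candidate windows;
7. **synthetic_data** — known-truth generators for genotypes,
   polygenic phenotypes (with planted QTL, genetic correlations,
   permanent environment) and ethogram sessions driven by a latent
   reactivity, so every stage is testable without real data.

See `docs/methods.md` for the models, priors, numerical choices and
limitations.

## Worked example

Simulate a 500-sow study whose latent reactivity has h² = 0.15, score
the generated shaving sessions, run QC, build the GRM, fit the RS
animal model and run the GWAS:

```python
import numpy as np
from sowreact import ethogram, genotype_qc, grm, mixed_models as mmod
from sowreact import gwas, synthetic_data as sd

cfg = sd.SimulationConfig(n_individuals=500, n_markers=2000,
                          h2={"react": 0.15}, seed=7)
geno = sd.simulate_genotypes(cfg)
_, truth = sd.simulate_phenotypes(geno, cfg)
rng = np.random.default_rng(8)
latent = truth["additive_values"]["react"].to_numpy()
latent = latent + rng.normal(0, np.sqrt(1 - 0.15), len(latent))
sessions = sd.simulate_ethogram_sessions(latent, cfg)

scores, summary = ethogram.score_sessions(
    ethogram.sessions_from_frame(sessions))
geno_qc, report = genotype_qc.run_qc(geno, phenotype_ids=scores["sow_id"])
G = grm.stabilize(grm.vanraden_g(geno_qc), epsilon=0.01)

spec = mmod.ModelSpec(response="rs", fixed_effects=["intervention_moment"],
                      covariates=["touches"])
X, rec, _ = mmod.build_design(scores, spec, G.individual_ids)
fit = mmod.gibbs_single_trait(
    scores["rs"].to_numpy(), X, rec, G,
    mmod.GibbsConfig(iterations=20_000, burn_in=5_000, thin=10, seed=1))
print(mmod.summarize_fit(fit).round(3).to_string(index=False))

res, scheme, lam, windows = gwas.run_gwas(
    fit, geno_qc, G, total_variance=float(np.var(scores["rs"])))
print(f"lambda = {lam:.2f}; significant markers: {int(res.significant.sum())}")
```

This prints:

```
parameter   mean   psd
 sigma_a2  2.065 1.669
 sigma_e2 15.905 1.819
       h2  0.114 0.090
lambda = 0.99; significant markers: 2
```

The posterior-mean h² of 0.11 ± 0.09 sits below the latent 0.15
because the ordinal scoring attenuates the signal (see the methods
note). λ = 0.99 indicates calibrated marker tests; the two "hits" on
this QTL-free simulation match the ~2.3 false positives expected from
the per-chromosome thresholds over 2,000 markers.

The same pipeline is scriptable from the shell (`sowreact simulate`,
`score`, `qc`, `grm`, `fit`, `diagnose`, `gwas`; see `--help`).

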