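# mavenpy

Localizing gene function to brain regions from **variegated transgene
expression** in larval zebrafish.

## The problem

Gal4/UAS rescue constructs in zebrafish often variegate: epigenetic
silencing of the UAS promoter gives every larva a different spatial
expression pattern, and consequently variable rescue of a mutant behavioral
phenotype. Instead of treating that variability as a nuisance, this package
exploits it. If larvae are sorted into two behavioral groups (e.g.
unrescued vs rescued, or typical vs shifted), the brain regions whose
construct expression *predicts* group membership are candidates for where
the gene acts — candidates that can then be validated with region-specific
Gal4 drivers, skipping a brute-force driver screen.

The pipeline consumes registered 3D brain stacks (one per larva, aligned to
a common atlas such as ZBrain), a region atlas (label volume or per-region
binary masks, overlaps allowed), and a subject table with a binary
phenotype and genotype class. It produces a short ranked list of candidate
regions with reliability and confirmatory statistics.

## The model

Let `x_ij` be the normalized mean fluorescence of subject `i` in region `j`
and `y_i ∈ {0,1}` the phenotype. The core fit is L1-penalized logistic
regression on standardized predictors with an unpenalized intercept:

```
min over (β0, β) of   (1/n) Σ_i [ log(1 + exp(η_i)) − y_i η_i ]  +  λ ‖β‖₁ ,
η_i = β0 + Σ_j β_j x̃_ij ,     x̃_ij = (x_ij − mean_j) / sd_j
```

The L1 penalty sets uninformative coefficients exactly to zero, so the fit
is simultaneously a classifier and a variable selector that tolerates the
strong positive multicollinearity variegation induces (larvae differ in
*global* silencing, so region signals share a latent factor). λ is chosen
by stratified k-fold cross-validated deviance with the one-standard-error
rule. Around this core:

- **Quantification** — per-region mean intensity over atlas mask voxels,
  normalized per brain (default: divide by the subject's whole-stack mean).
- **Collinearity diagnostics** — pairwise Pearson correlations with
  Ward-clustering display order; ranking of regions most correlated with a
  focal region, excluding regions that anatomically contain it.
- **Split-half bootstrap** — 100 random stratified half/half splits, a full
  CV + fit per split; models with >50% accuracy on both halves are kept and
  per-region signed-coefficient frequencies tallied over them.
- **Baselines** — bootstrapped unpenalized logistic fits on the whole-brain
  average signal, the candidate region, and both, to show the candidate is
  informative beyond global expression level.
- **Confirmatory statistics** — two-way ANOVA (phenotype × genotype, Type
  III, Šidák post-hoc within genotype) and exact/approximate Mann–Whitney U.
- **Synthetic data** — a generator for variegated-expression datasets with
  planted causal regions and tunable collinearity, plus voxel-level
  phantoms, so the whole pipeline is testable without any imaging data.

## Worked example

`examples/03_select_candidate_region.py` simulates the reference cohort
(50 subjects × 251 regions, one causal region `region_017` at +3 log-odds
per SD, a proxy `region_042` correlated with it at r ≈ 0.85) and runs the
selection:

```
planted causal effect: {'region_017': 3.0}

CV-selected penalty lambda = 0.0755
selected regions: ['region_017', 'region_076']
top region (largest |coefficient|): region_017
training accuracy: 0.96

after omitting region_017: top region becomes region_042
```

The sparse model names the planted region (plus one minor companion); when
the top candidate's column is removed — the fallback when a candidate fails
wet-lab validation — its correlated proxy surfaces, which is exactly how a
single lasso hit should be read: *this region, or something tightly
correlated with it*. The bootstrap (`examples/04_bootstrap_reliability.py`)
shows the same story as frequencies: `region_017` enters 100/100 accurate
models with a positive coefficient, the proxy 32/100. The baselines
(`examples/05_baselines_and_stats.py`) give 0.94 ± 0.004 test accuracy for
the region alone vs 0.53 ± 0.008 for the whole-brain average, and adding
the average does not improve on the region alone.

The other examples cover phantom quantification, correlation structure,
and the end-to-end YAML-configured pipeline (`maven run config.yaml out/`),
which also has a thin CLI: `maven simulate | quantify | correlate | select
| bootstrap | baselines | validate | render | run`.

## Documentation

The model, its assumptions, parameter defaults, numerical choices, and
known limitations are documented in [`docs/methods.md`](docs/methods.md).
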