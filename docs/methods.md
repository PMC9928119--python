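# Methods

## Scope and assumptions

The package starts *after* image registration: every input stack is assumed
to live in the same atlas space as the region masks, with finite,
non-negative intensities. Registration quality, staining artifacts,
background subtraction and deconvolution are out of scope. Atlas regions
may overlap (anatomical atlases nest regions inside super-regions); each
region is quantified independently from its own mask, so overlap never
couples estimates.

Coordinates are 0-based `(z, y, x)` voxel indices. Tabular formats are
plain UTF-8 CSV/TSV with mandatory headers; matrix CSVs round-trip floats
bit-exactly (values are written at `repr` precision and parsed with
correctly-rounded conversion — pandas' fast parser is off by one ulp often
enough to matter for byte-identical reruns). A matrix CSV carries its
normalization tag in a `.meta.json` sidecar so provenance survives the
round trip.

## Quantification and normalization

The per-region statistic is the **arithmetic mean** of stack intensities
over the mask voxels. Mean rather than integrated signal, so region size
does not dominate the downstream regression; `sum` and `median` are
available through `NormalizationSpec(statistic=...)` for sensitivity
checks.

Normalization options, applied when the matrix is built:

| method | effect | default |
|---|---|---|
| `per_brain_mean` | row ÷ subject's whole-stack mean | yes (stack input) |
| `none` | raw means | |
| `per_region_unit_interval` | column → [0, 1] | |
| `zscore_per_region` | column → mean 0, sd 1 | |

`per_brain_mean` absorbs per-subject staining/imaging gain: scaling a stack
by any k > 0 leaves its normalized row unchanged. It deliberately does
*not* remove biological whole-brain expression level, which the baseline
comparison (below) treats as its own predictor.

Regions with sample variance ≤ `min_variance` (default 0, with an exact
range==0 check so literally constant columns are caught despite float
round-off) are dropped before modeling: variegated constructs leave a few
regions always-on or always-off, and constant columns break per-region
standardization.

## Sparse logistic selection

Objective: `(1/n)·NLL + λ‖β‖₁` over predictors standardized to mean 0,
sd 1 (population sd), intercept unpenalized. Standardization makes λ
comparable across regions; the model stores the training moments so
predictions accept raw inputs.

The solver is a proximal-Newton scheme: each outer iteration forms the
IRLS quadratic (probabilities clipped to [1e-9, 1−1e-9]) and solves the
weighted lasso subproblem by cyclic coordinate descent with
soft-thresholding, iterating the active set between full passes. Warm
starts across a geometric penalty grid (`λ_max` down to `0.01·λ_max` when
n < p, `1e-4·λ_max` otherwise, 50 points) make whole paths cheap. Outer
convergence is relative objective change < 1e-11; a damped step guards the
rare quadratic overshoot near machine precision. Any solver meeting the
objective tolerance would be acceptable; the test suite checks this one
against a dense grid-search + polish oracle, an unpenalized Newton oracle,
and scikit-learn's saga solver at tight tolerance.

**Penalty choice**: stratified k-fold (default 5) cross-validated mean
binomial deviance over the grid; ties broken toward the larger penalty.
Default rule is **one-standard-error** — the largest λ whose mean deviance
is within one SE of the minimum — because the sparse end of the
statistically indistinguishable range is the scientifically useful one
here (`rule="min"` is available). On pure-noise data the one-SE rule
returns the intercept-only model.

**Known property, not a bug**: the lasso active set is not nested along
the path — as λ decreases a small coefficient occasionally crosses zero
and leaves the support (a documented feature of LARS/coordinate-descent
paths, reproduced identically by scikit-learn's saga at `tol=1e-13`).
Support size therefore *trends* upward as the penalty relaxes but can drop
by one at crossing events; nothing downstream assumes strict nesting.

**Accuracy** is the overall fraction correct at probability threshold 0.5
(strictly greater than 0.5 ⇒ class 1); balanced accuracy is available via
a flag. Splits are stratified by phenotype throughout so both classes
appear in every half/fold.

## Split-half bootstrap reliability

`bootstrap_lasso` draws `n_models` (default 100) stratified
`train_fraction` (default 0.5) splits; each training half gets its own CV
penalty selection and fit; a model is **accurate** iff training and test
accuracy both strictly exceed 0.5 (exactly 0.5 is inaccurate). Signed
coefficient frequencies are tallied over accurate models only — inaccurate
models' supports are noise. Per-model seeds descend from one
`SeedSequence`, so reports are byte-identical under a fixed seed.

Halving a 50-subject cohort costs real power: even on strongly-linked
synthetic data a fraction of halves yields chance-level models, which is
precisely why the accuracy filter exists.

## Baselines and confirmatory statistics

`baseline_comparison` fits unpenalized logistic models (damped Newton,
vanishing ridge 1e-10 for solvability; iteration-capped on separable
draws, which saturates predictions harmlessly) on three predictor sets —
whole-brain average signal, the focal region, both — over bootstrapped
stratified splits, reporting mean ± SEM test accuracy. The contrast reads:
if the focal region merely proxies global expression, the average matches
it; if not, the focal model wins and adding the average does not help.

`two_way_anova` uses Type III sums of squares (sum-to-zero contrasts via
statsmodels OLS) because behavior-sorted cohorts are unbalanced; on
balanced designs it coincides with the textbook decomposition (verified to
1e-10). Post-hoc: the phenotype contrast within each genotype, t-tests
pooling the ANOVA residual variance, **Šidák**-adjusted (Bonferroni via
flag). An empty cell degrades the model to main effects with a warning;
identically constant data yields F = 0, p = 1 rather than 0/0.

`mann_whitney_u` wraps the exact enumeration (tie-free, n_a+n_b ≤ 12 in
`auto` mode) or the normal approximation with midrank tie correction and
continuity correction; two-sided throughout. At α = 0.05 with n = 6 per
group the exact test's attainable level is 0.0411 — the discreteness of
the U distribution, visible in the type-I calibration test.

## Synthetic data generator

The generator reproduces the statistical signature of variegation with a
multiplicative latent model:

```
s_ij = clip( w_j·g_i + (1 − w_j)·a_ij + ε_ij , 0, ∞ )
```

- `g_i ~ Beta(2,2)`: subject i's global (anti-)silencing level — some
  larvae express nearly brain-wide, some barely at all;
- `a_ij ~ Beta(2,2)`: stochastic per-region activation;
- `w_j`: the region's loading on the global factor (collinearity dial);
- `ε_ij ~ N(0, 0.02)`: measurement noise;
- optional **block factors** mix a shared latent into chosen regions'
  activations, planting specific high-correlation pairs;
- phenotype: `y_i ~ Bernoulli(σ(intercept + Σ_c effect_c·z_ic))` with `z`
  the standardized signals of the planted causal regions (effects may be
  negative).

Reference conditions (`default_config`): 50 subjects × 251 regions;
loadings uniform on [0.2, 0.6], which realizes pairwise Pearson r with
mean ≈ 0.30 spanning ~0 to ~0.85 and no negative pairs beyond sampling
noise at n = 50; one causal region at **+3.0 log-odds per SD** (a strong
single-region effect — per-SD odds ratio ≈ 20 — chosen so a 50-subject
cohort is adequately powered, matching the regime in which a single-hit
selection is meaningful); one proxy region coupled to it through a block
factor with mixing 0.68, giving a pair correlation of 0.83 ± 0.04. The
causal/proxy pair sits at the low end of the loading range so its coupling
is pair-specific rather than inherited from global silencing — the
scenario the drop-the-top-candidate rerun is designed to resolve. Ground
truth (latents, effects, per-subject phenotype probabilities) is returned
alongside every dataset.

Voxel phantoms paint each subject's region signals into non-overlapping
cuboid masks (default 16×48×48 voxels, 4³-voxel regions, background 0.05,
optional Gaussian voxel noise; optionally one nested super-region to
exercise containment exclusion). End-to-end tests use 60-region phantoms —
large enough to exercise selection under collinearity, small enough that a
hundred seeded pipeline runs stay cheap.

**What the generator does not emulate**: real neuroanatomy (region shapes,
sizes, adjacency), point-spread functions, registration deformation,
left–right asymmetries, and any dependence of silencing on genotype.
Passing tests therefore demonstrate the statistical machinery — not that a
particular biological dataset satisfies the model's assumptions; on real
data the correlation structure should be inspected (`correlation_matrix`)
before trusting a single-region readout.

## Visualization and orchestration

`render_region_stack` is a pure function mapping a score-per-region onto
atlas voxels: sequential blue ramp for scored regions, reserved red for
the focal region, higher-score-on-top where masks overlap, z maximum
projection for the 2D view. Outputs are multi-page TIFF and PNG.

`run_pipeline` executes quantify (or load) → correlate → select →
bootstrap → validate → render from one YAML config into a run directory,
logging every stage's parameters, seeds and input hashes in
`manifest.json`. All outputs are byte-reproducible under a fixed config;
the manifest's wall-clock timestamp is the only varying field. A stage
failure halts the run naming the stage. When all subjects share one
genotype the validate stage reports the Mann–Whitney test alone, since the
two-factor ANOVA needs ≥ 2 genotype classes.

## Numerical choices, degenerate inputs, limitations

- CV deviance ties → larger λ; ranking ties → region-table order;
  predicted probability exactly 0.5 → class 0.
- Zero-variance columns: rejected at correlation and standardization,
  dropped by `drop_uninformative_regions`; within CV folds a
  locally-constant column gets unit scale and contributes nothing.
- Containment exclusion threshold: overlap fraction ≥ 0.99 of the focal
  mask inside the candidate (full containment up to a stray voxel);
  "physically contains" has no unique quantitative reading, so the
  threshold is exposed.
- Ward clustering runs on dissimilarity 1 − r; the leaf order is a display
  convention, not an inference.
- The pipeline's statistical guarantees are conditional on the binary
  phenotype being a faithful sorting; label noise directly erodes the
  bootstrap's accurate-model fraction.
- With extreme collinearity (pairs at r → 1) no method can attribute
  signal within a correlated block; the package surfaces this through the
  proxy-promotion rerun and the correlation ranking rather than pretending
  to resolve it.
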