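# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Preference-index randomization tests

A trial is a count pair (N_E, N_C) out of `flies_loaded` (default 20).
PI = (N_E − N_C)/(N_E + N_C) is undefined when no fly chooses; such trials
are excluded from summaries and tests, never imputed as zero. Replicates
are summarised by the chooser-weighted mean, so a trial in which 18 flies
chose counts more than one in which 6 did.

The two-group statistic is a chooser-weighted Welch-style t: group means are
weighted means of trial PIs, and standard errors use the effective sample
size n_eff = (Σw)²/Σw² with an n_eff/(n_eff−1) small-sample correction. An
unweighted variant is available (`weighted=False`); the weighted form is the
default because the reported group means are weighted. The multi-group
statistic is the weighted between-group mean square over the weighted
within-group mean square.

The null permutes trial-level (PI, weight) pairs across group labels,
within blocks when block labels are present; every block must contain both
groups or the test refuses to run. When the number of distinct assignments
(∏ per-block C(n_b, n_ab)) is at most `n_permutations`, the null is
enumerated exhaustively and the exact tie-inclusive fraction is reported;
otherwise Monte-Carlo sampling is used with add-one smoothing
p = (b+1)/(m+1), which keeps p strictly positive. "Equal or more extreme"
includes ties, so a zero observed statistic gives p = 1. Two-sided is the
default; one-sided available on request.

A consequence worth knowing: with full participation all weights are equal
and trial PIs sit on a lattice, so tie classes among assignments can be
large and the tie-inclusive p is conservative (stochastically larger than
uniform). With realistic incomplete participation the weighted statistic is
essentially tie-free and null p-values are uniform. Both behaviours are
asserted in the test suite.

## Metabolome pipeline

Processing order is enforced (filter → log → impute → standardize → PCA);
calling a step out of order raises `PipelineOrderError`, because the steps
are only meaningful in this order (imputation distances assume log scale;
standardization assumes completeness).

* **Missingness filter** — a metabolite is dropped when its missing count
  strictly exceeds floor(f · n_samples), f = 5/32 by default, so on 32
  samples "missing in 6" is dropped and "missing in 5" retained.
* **Log transform** — natural log; the base is irrelevant downstream
  because standardization rescales each column.
* **kNN imputation** — neighbours are metabolites; the distance between two
  metabolites is the plain (unscaled) Euclidean distance over the samples
  where both are observed; a missing entry becomes the mean of the target
  sample's values for the k = 10 nearest metabolites that are observed in
  that sample. Hand-rolled deliberately: sklearn's `KNNImputer` rescales
  its nan-Euclidean metric by missingness, which can rank neighbours
  differently from this rule. Deterministic; ties break by distance then
  column order; fewer than k usable neighbours falls back to all available
  with a warning.
* **Standardization** — per-column z-score with the n−1 variance; a
  zero-variance column is an error naming the metabolite.
* **PCA** — full-rank covariance PCA (min(n−1, p) components) so explained
  variances sum to the total variance; each loading vector's sign is fixed
  so its largest-magnitude entry is positive, making outputs reproducible
  across BLAS implementations.

### Z separation and its permutation null

For one component's projections, Z = between/within with
between = Σ n_k (Mean_total − Mean_k)² and within the pooled within-group
sum of squared deviations. The paper-style formula fixes only the
numerator; the pooled-SS denominator is the default and a mean-square
denominator (divide by Σ(n_k−1)) is available — for fixed group sizes the
two differ by a constant factor, so permutation p-values are identical.
Z is invariant to affine transforms of the projections.

The null shuffles sample labels; since PCA of an unchanged matrix is
unchanged by a label shuffle, projections are computed once and only Z is
recomputed, which makes the 10,000-permutation default cheap. Per-component
p is upper-tail with add-one smoothing. Each result also carries a
family-wise p calibrated against the per-permutation maximum of Z across
components, for users who want control over the component family; the
per-component p is the primary quantity and no cross-component correction
is applied by default.

The default grouping is the composite genotype × exposure factor (four
cells): an exposure response present only in the sighted genotype moves the
exposure and genotype *marginal* means identically, so marginal tests
cannot distinguish the two factors even in principle. Attribution is
instead done by `stratified_pc_test`: the exposure Z test re-run within
each genotype stratum (and vice versa), taking the better stratum's p. The
pipeline calls a component exposure-separating when it is significant under
the composite test and separates exposure within some genotype.

### Candidate screen

Per metabolite, one-sided Student's t tests of exposed vs unexposed within
each genotype, the direction fixed by the sign of the control-genotype
effect; flagged when p_control < α and p_mutant ≥ α (α = 0.05). The screen
asks for an effect that *depends on perception*, hence the asymmetric
criterion; it applies no multiple-testing correction across metabolites, so
with ~119 metabolites a handful of null flags per run is expected and the
flag list should be read as a shortlist, not an inference.

## Survival

Kaplan–Meier estimation and the two-sample log-rank test are delegated to
lifelines. The interaction between exposure and genotype is estimated
either by Cox regression (statsmodels PHReg) with exposure, genotype and
product terms — Breslow tie handling by default, Efron optional — or, when
every age at death is observed and proportional hazards is doubtful, by the
interaction term of a two-way OLS ANOVA on age at death (for this 1-df term
the coefficient t test equals the ANOVA F test). The choice between the
two is the analyst's; `proportional_hazards_check` provides a
Schoenfeld-residual diagnostic. Flies lost or escaped should be entered as
right-censored at their last census.

## Synthetic-data generator

The generator produces data with the structure the analyses assume, with
ground truth attached, so recovery and calibration are testable end to end.

* **Trials** — participants ~ Binomial(flies_loaded, participation_rate),
  then exposed-arm count ~ Binomial(participants, p_exposed_arm). Default
  participation 0.8 reflects the >50% participation typical of the assay.
  It does not model the within-trial time course (counts at 3/6/9/12 min);
  each simulated count pair is one snapshot.
* **Metabolome** — 2 genotypes × 2 exposures × 8 replicates = 32 samples,
  119 metabolites, log-normal abundances (base_log_mean 8, base_log_sd 0.5
  on the natural-log scale). Latent structure lives on an orthonormal basis
  of min(rank+5, n−1, p) directions with strictly decreasing variances;
  the exposure effect is a mean shift of `effect_size` (default 3) SD along
  the direction of variance rank `planted_pc_rank` (default 10), applied to
  the exposed samples of the affected genotype (default control) only.

  Three design choices matter for recoverability and are deliberate. The
  variance profile gives the planted direction variance 24 against a noise
  floor near 1, with the 9 stronger directions set 8× the planted
  direction's post-shift variance (the shift inflates it by
  1 + 3·effect²/16), so the planted eigenvector stays spectrally isolated
  from both sides after the shift. The basis is rotated (Bendel–Mickey
  Givens sweeps) until the population covariance has an exactly constant
  diagonal, so every metabolite has the same population variance and
  per-column standardization is a near-scalar operation — without this,
  heterogeneous column variances leak high-variance structure into the
  residual space and the planted direction is no longer identifiable at
  n = 32. And missingness (completely at random, default 3%, capped at 5
  per metabolite so the matrix emulates a post-filter panel) is kept modest
  because imputation noise directly erodes direction recovery.

  What it does not emulate: intensity-dependent (non-random) missingness,
  technical full-rank measurement noise (the latent model concentrates
  variance in ~15 directions; real matrices are full rank), batch effects,
  or a genotype main effect. Passing recovery tests on this generator shows
  the machinery is correct and calibrated, not that real head-metabolome
  effects of any particular size are detectable.
* **Cohorts** — event times by inverse-transform sampling from an
  exponential or Gompertz baseline (default Gompertz a = 2e-4/day,
  b = 0.12/day, median ≈ 50 days, the classical shape for adult fly
  mortality; exponential retained for analytic checks), hazards multiplied
  by exp of the exposure/genotype/interaction log-hazard effects, optional
  fixed-time right-censoring.

All generators are bit-reproducible under a fixed seed.

## Reproducibility and numerics

All randomness in a pipeline run derives from one master seed through named
substreams (`SeedSequence([seed, crc32(stage_name)])`), so adding or
reordering stages cannot silently change another stage's results, and two
runs with the same config and seed write byte-identical `summary.json`
files. Floats in the summary are rounded to 6 decimals purely for
readability; CSVs keep full precision, and the survival reader parses
floats in round-trip mode so write→read is lossless.

Simulation-study sizes in the test suite and acceptance script (for
example 399–499 permutations inside 100–1,000-replicate calibration loops)
are chosen so the whole suite runs in a couple of minutes on one CPU; the
analysis defaults themselves (100,000 randomizations for preference tests,
10,000 permutations for PC selection) match the study protocol.

## Known limitations

* The permutation PC test assumes exchangeable samples under the null;
  block or batch structure in the matrix is not modelled.
* The candidate screen's one-sided direction is estimated from the same
  data it tests (control-genotype effect sign), a mild selection effect
  shared by the original procedure.
* `stratified_pc_test` takes the minimum p across strata without
  correction; with two strata its per-component null rate is nearer 0.1
  than 0.05, which the pipeline accepts because it is applied only to
  components already significant under the composite test.
* Cox fitting assumes proportional hazards; the diagnostic is advisory,
  not a gate.
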