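# Methods

## The problem

Amyloid-beta deposition in the brain, measured regionally by amyloid-PET
SUVR, does not accumulate uniformly: cross-sectional cohorts of cognitively
normal (CN) and mildly impaired (MCI) individuals mix people at different
points along possibly several distinct regional progression patterns.
`amysustain` implements the full analysis for recovering those patterns
from a single cross-sectional SUVR table: region-specific abnormality
cutoffs, a z-score event-based subtype-and-stage mixture model, MCMC
uncertainty over event orderings, cross-validated selection of the number
of subtypes, probabilistic subject assignment with exclusion rules, and
downstream clinical/biomarker/survival characterisation of the recovered
subtypes.

## Model

Let z_ni be the covariate-adjusted, CN-referenced z-score of subject n in
region i, with E = 11 regions. Each latent subtype c has an event sequence
S_c — a permutation of the 11 regions — and a mixture fraction f_c. A
subject at stage k has experienced the first k events of its subtype's
sequence. The expected z-score of region i at stage k is piecewise linear:

- rising from 0 at stage 0 to z_cut_i at the stage equal to region i's
  position in S_c (the event: the region crosses its abnormality
  threshold), then
- rising from z_cut_i to z_max_i at stage E.

Observations are the expected trajectory plus independent Gaussian noise
with SD sigma_i (default 1, appropriate for z-scored inputs). With a
uniform prior over stages 0..E, the data likelihood is

    L = prod_n sum_c f_c * (1/(E+1)) * sum_k prod_i
        N(z_ni ; g_i(k; S_c), sigma_i)

computed throughout in log space with log-sum-exp. Stage 0 means no region
is abnormal; stage E means all are.

### Fitting

- **Sequences** are fitted by greedy coordinate ascent: from a random
  permutation, each event in turn is removed and re-inserted at the
  position that maximises the (responsibility-weighted) log-likelihood,
  until a full pass yields no improvement; the best of `n_restarts`
  random starts is kept. All insertion slots for one event are scored in a
  single vectorised batch. Ties keep the earliest insertion slot so
  refits are bit-reproducible.
- **Subtypes** are fitted hierarchically: the (C−1)-subtype solution is
  split by hard-assigning subjects to their most likely cluster, randomly
  bipartitioning one cluster, fitting a sequence to each half, and
  refining the resulting C-subtype model by EM (responsibilities →
  fraction update → per-subtype weighted greedy re-optimisation). The best
  split over clusters and restarts is kept. EM stops when the
  log-likelihood improves by less than 1e-6 or after 100 iterations
  (capped lower, at 30 by default and 15 in the cross-validation loop,
  where dozens of fits are needed and the remaining improvements do not
  affect model ranking). An emptied component is re-seeded from the
  worst-fit subjects. Fitted subtypes are relabelled in order of
  decreasing mixture fraction so labels are reproducible; labels remain
  arbitrary with respect to any external naming, and comparisons between
  models always go through the similarity-maximising matcher.
- **Uncertainty** is quantified by Metropolis–Hastings MCMC over
  (sequences, fractions): with probability 1/2 one uniformly chosen event
  of one subtype moves to a uniformly chosen position, otherwise the
  fraction vector is perturbed with Gaussian noise (SD 0.02), clipped at
  0 and renormalised; proposals are accepted with probability
  min(1, exp(Δ log L)). Every post-move state is recorded. Positional
  variance diagrams are the empirical frequency of each region occupying
  each position across samples.
- **The number of subtypes** (1..4) is chosen by ten-fold cross-validation:
  CVIC(C) = −2 × Σ held-out log scores, where a held-out subject's score
  is the log of its mixture likelihood averaged over the training-fold
  MCMC samples (an ML-only mode is available via
  `use_mcmc_average=False`). The selected C minimises CVIC.

### Preprocessing and cutoff calibration

Input SUVRs are first adjusted for age, gender and education by per-region
OLS over the whole dataset (residual plus the fitted value at the
covariate means, which preserves each region's mean), then z-scored
against the CN subset (mean 0, SD 1 over CN by construction; SD uses
ddof=1). The global amyloid-positivity ratio p is the fraction of subjects
whose cortical-composite SUVR (unweighted mean of frontal, temporal,
parietal and cingulate; configurable) exceeds 1.1. Each region's
abnormality threshold z_cut_i is then the (1−p) empirical quantile of its
z-score distribution (linear interpolation between order statistics), so
every region's supra-threshold fraction matches the global ratio.

Two numerical choices matter here. First, z_max_i is not identified by the
cutoff scheme; it defaults to max(95th percentile of region i's z-scores,
z_cut_i + 0.5), anchoring the late-stage trajectory in the observed upper
tail. Second, regions whose events come late in every sequence can have a
(1−p) quantile at or below the CN bulk — a threshold at or below the
normal mean is vacuous — so calibrated cutoffs are floored at 0.05 z units
(`min_cut`, configurable; 0 disables the floor and makes a non-positive
quantile an error). This reflects a genuine weakness of transferring one
global positivity ratio to all regions: thresholds for late, low-signal
regions are intrinsically less reliable.

### Assignment and exclusions

Each subject's posterior over (subtype, stage) is proportional to
f_c × stage likelihood, normalised over all C × (E+1) cells. The hard
assignment is the posterior mode, with ties broken toward the lower stage
and then the lower subtype index. Subjects whose most likely stage is 0
carry no subtype information (no abnormal region) and get no subtype;
subjects at stage 0 or stage E are flagged excluded and are removed from
every downstream characterisation analysis.

### Sequence agreement

Kendall's tau between two orderings is (concordant − discordant) pairs
over all 55 pairs; the consistency percentage reported across folds and
datasets is the concordant-pair share, 100 × (1 + tau)/2. Subtype labels
being arbitrary, any cross-model comparison first finds the label pairing
maximising total similarity.

### Characterisation

Continuous profiles are compared between subtypes by an F-test on the
group factor in `profile ~ group + age + gender + education` with
continuous variables centred and scaled; the F statistic is computed by
nested-model residual-sum-of-squares comparison (verified against
statsmodels' type-II ANOVA in the test suite). Categorical profiles (APOE
e4 allele count) use the Pearson chi-square on the raw contingency table
without continuity correction and without covariate adjustment. The
family of profile tests within one dataset is Benjamini–Hochberg
FDR-corrected. Stage–profile associations are Spearman correlations of
covariate-residualised stage and profile. Conversion risk uses Cox
proportional-hazards models (lifelines; Efron ties) with follow-up
truncated at 6 years, adjusted for age, gender and education; survival
curves are emitted both as Kaplan–Meier step functions per group and as
Cox-adjusted curves evaluated at the covariate means.

## Synthetic cohort generator

Because the motivating data are restricted, the package ships a
first-class generator that emulates the assumed data structure and emits
ground-truth labels. Per subject: subtype ~ fractions (default 0.5/0.5
over a subcortex-priority and a cortex-priority sequence, both ending in
the cerebellum); stage ~ a prior with P(stage 0) = 0.3 and the remaining
mass uniform over stages 1..11 (a mixed CN/MCI cohort with a sizeable
amyloid-negative group); z-scores are the subtype trajectory at the true
stage plus N(0, 1) noise; SUVR_i = 1.0 + 0.1·z_i plus linear covariate
terms in (age−72), gender, (education−16). Defaults that the data do not
pin down were fixed once, on realism grounds:

- Trajectory amplitude z_cut = 1.0, z_max = 3.0 (generator z units) per
  region, chosen so the default cohort's global positivity at the 1.1
  cutoff lands in the mid-40s percent, matching the positivity regime of
  the real mixed CN/MCI cohorts this emulates.
- Diagnosis tracks stage, P(MCI) = min(0.10 + 0.07·stage, 0.9), so the CN
  reference is dominated by low-stage subjects.
- CSF and cognitive outcomes are linear in stage with subtype offsets and
  Gaussian noise; directions (not magnitudes) mirror the contrasts the
  analysis is meant to expose: the cortex-priority subtype has lower CSF
  amyloid-beta, higher t-tau/p-tau, worse cognitive composites, and APOE
  e4 carriage enriched (allele-count probabilities (0.46, 0.42, 0.12) vs
  (0.71, 0.26, 0.03)).
- Conversion times are exponential with rate
  0.02 × 3.0^[subtype 2] × 1.2^stage per year, observed if within the
  6-year horizon, else censored there.

What the generator does **not** emulate: longitudinal visits, scanner or
site effects, non-Gaussian or heteroscedastic regional noise, missing
data beyond optional per-column missingness, and spatial correlation
between regions beyond what the shared stage induces. Passing recovery
tests therefore demonstrates that the fitting machinery inverts its own
generative assumptions at realistic noise — not that those assumptions
hold in any particular PET cohort.

## Problem sizes used in tests and the acceptance script

Sequence recovery uses ten cohorts of n = 600 with 10 greedy restarts and
a 20,000-sample MCMC; model-order recovery uses cohorts of n = 450 with
ten folds, 2 restarts, 500 MCMC samples per fold and the EM cap of 15;
calibration checks use 1,000 null ANOVA simulations, 200 Cox-coverage
simulations, and 10–20 hazard-recovery cohorts of n = 800. These sizes
were chosen to make the full battery runnable on a single CPU in minutes
while keeping every check's expected margin wide (the two-subtype CVIC
margin is hundreds of nats; recovery taus are ≥ 0.9 with margin).

## Known limitations

- The MCMC proposal (single-event move plus fraction jitter) is one
  faithful Metropolis–Hastings choice; fine structure of positional
  variance diagrams can differ from other samplers.
- CVIC contrasts of nearly-equivalent models (e.g. C = 2 on truly
  one-subtype data) sit within sampling noise by construction; selection
  there is expected to be noise-driven, and parsimony holds only in the
  majority of replicates.
- The subtype hazard ratio fitted from a marginal Cox model is attenuated
  relative to the generator's conditional value because stage, an
  independent risk factor, is marginalised out; the recovery check
  accounts for this.
- Subjects at stage 0 or the final stage are unassignable or
  uninformative by construction; with the default generator stage prior
  the excluded fraction is large (≈ a quarter), much larger than in a
  cohort pre-screened for amyloid positivity.
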