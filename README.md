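# amysustain

Spatiotemporal subtyping and staging of regional amyloid burden from
cross-sectional amyloid-PET SUVR data, using a z-score event-based
subtype-and-stage mixture model.

## Who this is for

Researchers analysing regional amyloid-PET tables from mixed cognitively
normal / MCI cohorts who want to (a) recover distinct regional progression
patterns (subtypes) and a per-subject disease stage from a single visit,
and (b) characterise the recovered subtypes against genetics, CSF
biomarkers, cognition and conversion risk. Because the motivating cohort
data are access-restricted, the package also ships a first-class synthetic
cohort generator with ground-truth labels, so the whole pipeline is
testable end to end.

## The model

Each of C latent subtypes is an ordered sequence S_c of E = 11 regional
events — a region's covariate-adjusted, CN-referenced z-score crossing its
abnormality threshold z_cut_i. A subject at stage k has passed the first k
events of its subtype's sequence; the expected z-score of region i rises
piecewise linearly from 0 (stage 0) to z_cut_i at the event's position and
on to z_max_i at stage E. With Gaussian residuals and a uniform stage
prior, the likelihood is

    L = prod_n  sum_c f_c (1/(E+1)) sum_k prod_i N(z_ni ; g_i(k; S_c), sigma_i)

Sequences are fitted by greedy coordinate ascent with restarts, subtypes
by hierarchical splitting with EM, ordering uncertainty by
Metropolis–Hastings MCMC, and the number of subtypes by ten-fold
cross-validation (CVIC). Regional thresholds are calibrated from the
global amyloid-positivity ratio at the conventional 1.1 SUVR cutoff: each
region's z_cut is the (1−p) quantile of its z distribution. Details,
defaults and numerical choices are in `docs/methods.md`.

## Worked example

```python
import amysustain as am

cfg = am.default_config(seed=11, n_subjects=600)   # two latent subtypes
cohort, truth = am.generate_cohort(cfg)

adjusted = am.adjust_covariates(cohort)            # age/gender/education OLS
zmat = am.cn_zscore(adjusted)                      # CN-referenced z-scores
p = am.global_positivity(adjusted, suvr_cutoff=1.1)
cuts = am.regional_cutoffs(zmat, p)
print(f"global positivity: {p:.3f}")

Z = zmat.values
est = am.SubtypeStageModel(n_subtypes=2, z_cut=cuts.as_array(),
                           n_restarts=10, random_state=0).fit(Z)
for c, (seq, f) in enumerate(zip(est.sequences_, est.fractions_), 1):
    print(f"subtype {c} (fraction {f:.2f}): {' -> '.join(seq[:4])} ...")

res = am.assign_subjects(Z, est.model_, subject_ids=cohort["subject_id"])
print(f"excluded: {res.n_excluded}/{len(cohort)}")

report = am.characterize_subtypes(cohort, res.table)
row = report.set_index("profile").loc["apoe_e4"]
print(f"APOE chi2 = {row['statistic']:.2f}, p_FDR = {row['p_fdr']:.2e}")
```

Output:

```
global positivity: 0.432
subtype 1 (fraction 0.51): basal_ganglia -> thalamus -> hippocampus -> amygdala ...
subtype 2 (fraction 0.49): parietal -> frontal -> temporal -> occipital ...
excluded: 253/600
APOE chi2 = 15.02, p_FDR = 1.64e-03
```

Reading it: 43% of the simulated cohort is amyloid-positive at the 1.1
composite cutoff; the fitted two-subtype model recovers one
subcortical-first and one cortical-first ordering (the generator's two
latent patterns); 253 subjects sit at stage 0 or the terminal stage and
are excluded from characterisation; among the rest, APOE e4 allele
distribution differs significantly between subtypes, as built into the
generator.

The same workflow is available from the shell:

```sh
amysustain simulate --n-subjects 600 --seed 11 --out cohort.csv
amysustain run --input cohort.csv --out-dir out --max-subtypes 2 \
    --mcmc-samples 20000 --seed 11
```

`amysustain run` writes calibrated cutoffs, the CVIC table, the fitted
model, MCMC positional-variance matrices, per-subject assignments, the
characterisation report, and a manifest with SHA-256 digests of every
artifact (reruns with the same seed reproduce identical model digests).

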