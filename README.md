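# fndconn

Voxel-wise resting-state connectivity graph metrics and brain–behavior
inference for longitudinal cohorts with functional neurological disorder
(FND), packaged with a synthetic phantom-cohort generator so the entire
pipeline can be exercised, calibrated and stress-tested against known
ground truth.

It is aimed at researchers who analyze longitudinal resting-state fMRI in
small clinical samples and want the full inferential chain — graph
metrics, mass-univariate models, Monte-Carlo cluster correction, seed
post-hocs, clinical statistics — as tested, reusable code rather than a
one-off script stack.

## The analysis

Per participant and session, pairwise Pearson correlations between
grey-matter voxel time series (negatives removed) define weights
`adj(i,j) ∈ [0,1]`, summarized per voxel by three graph metrics:

- weighted-degree `WD_i = Σ_j adj(i,j)` — global centrality;
- integration `INT_i = Σ_{j: net(j) ≠ net(i)} adj(i,j)` — between-network
  connectivity over isocortical voxels with a Yeo-style seven-network
  parcellation;
- segregation `SEG_i = Σ_{j: net(j) = net(i)} adj(i,j)` — within-network
  connectivity.

At every voxel, the symptom-change score Δy (follow-up − baseline
questionnaire total; negative = improvement) is modelled as

    Δy ~ metric + age + sex + SSRI/SNRI + mean FD + interval + baseline score,

with the metric term's t converted to z and thresholded at |z| > 1.96;
suprathreshold clusters survive only if larger than the (1 − α) quantile
of a Monte-Carlo max-extent null built from smoothness-matched Gaussian
fields (α = 0.05). Significant integration voxels are characterized by
seed-to-voxel Fisher-z maps tested against zero, between-network voxel
counts, and baseline vs follow-up comparisons; clinical tables get
Wilcoxon / paired-t / McNemar / Mann-Whitney statistics with
Benjamini-Hochberg FDR, and overlap voxels are contextualized against
healthy controls. `docs/methods.md` documents every convention.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study and
write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_brain_behavior_glm.py
```

which prints, for the seed-1 cohort:

```
phantom: 800 grey voxels, 600 isocortical, 7 networks
cohort: 32 FND (28 with follow-up scan), 50 HC
core symptom change (SOMS:CD): mean +0.8, sd 4.1, range [-9, +10]
planted effect: 12 voxels in network 3
...
baseline_predictor_integration: extent threshold 7, 1 cluster(s), 14 significant voxel(s)
  sensitivity: affective_baseline=held, childhood_trauma=held, phenotype=held
```

Reading this: the generator planted a 12-voxel region in network 3 whose
cross-network coupling varies across subjects and drives their symptom
change. The baseline integration analysis recovers it — one surviving
cluster of 14 voxels (the planted blob plus fringe) against a 7-voxel
extent threshold — and the finding holds under every post-hoc covariate
set. `03_seed_posthoc.py` then labels the significant voxels by network
and runs the seed analyses, `04_cohort_stats.py` reproduces the clinical
table statistics, and `05_calibration_and_recovery.py` reports, at seed 1:
family-wise error 4.5% (nominal 5%), planted-effect recovery 88% with
false regions in 4% of replicates, and one of 100 null cohorts showing a
significant cluster.

A thin CLI wraps the same pipeline (`fndconn simulate`, `fndconn glm`,
`fndconn run-all --seed 3`), and the library surface (`fndconn.metrics`,
`fndconn.glm`, `fndconn.seeds`, `fndconn.cohort_stats`,
`fndconn.simulate`) is importable directly.

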