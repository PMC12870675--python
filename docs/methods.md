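# Methods

This note documents the models, conventions and numerical choices behind
`fndconn`: a pipeline that relates longitudinal change in self-reported
symptoms of functional neurological disorder (FND) to voxel-wise
resting-state functional-connectivity (rsFC) graph metrics, exercised end
to end on synthetic phantom cohorts with known ground truth.

## Graph metrics

Per participant and session, an rsFC matrix is built from pairwise Pearson
correlations between grey-matter voxel time series. Negative correlations
are set to zero (removed, not absolute-valued or shifted) and the diagonal
is excluded; weights therefore lie in [0, 1]. Three per-voxel sums over
this matrix are computed:

- **weighted-degree** `WD_i = Σ_j adj(i,j)` over all grey-matter voxels
  (global centrality, whole-grey matrix);
- **integration** — the same sum restricted to isocortical voxels in
  *different* functional networks (between-network connectivity);
- **segregation** — restricted to voxels in the *same* network
  (within-network connectivity).

Integration and segregation use an isocortical-only matrix with each voxel
assigned to one of seven networks. Because Pearson correlation between two
series does not depend on which other voxels are present, the isocortical
matrix is taken as a submatrix of the whole-grey matrix. By construction
integration + segregation equals the isocortical row sum exactly; this
partition identity is enforced by test at 1e-9 relative tolerance.

Subjects whose grey-mean weighted-degree is a gross outlier are screened
with a leave-one-out rule: subject `i` is flagged when it deviates from
the mean of the *other* subjects by more than `k` (default 3) of their
standard deviations. The leave-one-out form is used because a single gross
outlier inflates a cohort-inclusive SD enough to mask itself.

## Brain–behavior GLMs

At every voxel, the symptom-change score (follow-up minus baseline total;
negative = improvement) is regressed on the voxel's metric (baseline map,
or follow-up-minus-baseline change map) plus nuisance covariates: age, sex
(female = 1), SSRI/SNRI use, session mean framewise displacement,
inter-session interval, and the baseline score of the outcome. Continuous
covariates are mean-centered (this affects only the intercept). Covariates
with zero variance across the sample (e.g. an all-female draw) are dropped
with a warning. The voxel loop is vectorized with the
Frisch–Waugh–Lovell identity and is numerically identical to per-voxel
full OLS; the metric term's t is converted to z by tail-probability
matching (`z = Φ⁻¹(F_t(t))`), capped at ±8.2 with a flag for numerically
perfect fits. The t statistic of the term of interest is invariant to
exchanging the outcome and metric roles (partial-correlation identity);
this is tested to 1e-8.

## Cluster-extent correction

Voxel-forming threshold |z| > 1.96, two-sided, with positive and negative
clusters labeled separately under 26-connectivity (6/18 configurable).
The null distribution of the maximum cluster extent is simulated by Monte
Carlo: white Gaussian fields on the grid, smoothed to the estimated
per-axis FWHM, re-standardized within the mask (so the voxel threshold
keeps its nominal rate), thresholded, and the maximum component extent
recorded per iteration (10,000 iterations by default; reduced in the
bundled experiments, see below). Smoothness is estimated from the GLM
residual maps with the classical gradient-variance estimator
`FWHM = sqrt(−2 ln 2 / ln(1 − var(∂e) / 2 var(e)))` per axis, floored at
1 voxel. FWHM is interpreted as total smoothness including the intrinsic
one-voxel floor of a discrete grid: the null-field kernel is
`sqrt(max(FWHM² − 1, 0)) / 2.3548` voxels per axis, so spatially white
residuals reproduce unsmoothed white null fields.

The surviving-extent threshold is the smallest integer strictly above the
empirical (1 − α) quantile of the max-extent null, i.e. the smallest
extent whose estimated cluster-level p is ≤ α. On a small phantom this
discrete rule is mildly conservative; at FWHM 1 the max-extent
distribution is so coarse that no integer threshold attains exactly 5%
(the exceedance probability jumps from ≈8.6% to ≈3.6% across one voxel of
extent on the 800-voxel phantom), which is why the family-wise-error
calibration experiment is run at FWHM 2, where the realized error is
≈ 4–4.5%.

Post-hoc covariate-sensitivity re-fits add each extra covariate set
(phenotype; baseline affective scores; childhood-trauma scores; for
longitudinal models also change in depression and anxiety scores), re-run
the full correction with smoothness and null re-derived from the new
residuals, and call a primary cluster "held" when at least one surviving
voxel overlaps it — the weakest overlap reading; stricter fractions are a
parameter away.

## Seed post-hocs

Significant integration voxels are histogrammed by network label; the top
three networks (ties broken by ascending index, zero-count networks never
selected) define seed ROIs as the average time series of their
significant voxels. Seed-to-voxel Pearson maps are Fisher r-to-z
transformed (r clipped to ±(1 − 1e-7) first), tested against zero across
subjects with age, sex, SSRI/SNRI and mean FD as centered covariates
(the intercept is then the adjusted group mean), and cluster-corrected
identically to the primary models. Significant voxels are counted per
*other* network (within-network links are excluded — they do not measure
integration); baseline vs follow-up comparisons express counts as percent
of each target network's isocortical voxel count, which is the chosen
denominator convention.

## Cohort statistics

CGI-I categories aggregate to improved (much improved + improved),
unchanged, and worsened (worse + much worse). Improved and unchanged
percents are rounded half-up to one decimal; the worsened percent is the
complement to 100.0, so the three categories partition the cohort exactly
(19/10/3 of 32 prints as 59.4 / 31.3 / 9.3 — independent rounding of
3/32 would give 9.4 and a 100.1 total). Pre–post tests use Wilcoxon
signed-rank (zeros dropped, midranks, normal approximation, signed z
reported) for skewed scores and paired t for approximately normal ones;
paired binary traits use McNemar (exact binomial below 25 discordant
pairs); group comparisons use Mann-Whitney U with midranks and
tie-corrected normal approximation, U reported for the first sample.
Multiple tests are corrected with Benjamini-Hochberg FDR within each
family. Extreme responders are the `k = floor(n·fraction)` most negative
(improved) and most positive (worsened) change scores — floor because
0.2 × 28 must select 5 — with ties broken by subject order under a
warning. Healthy-control contextualization intersects the
baseline-predictor and longitudinal-change significance masks and
compares per-subject mean metric values over the overlap voxels between
each FND stratum (full, most improved, most worsened) × timepoint and the
HC sample: six Mann-Whitney tests.

## Synthetic cohort generator

One scanning session is a latent-factor block model. Voxel `v` in network
`L(v)` observes

    x_v = κ_v [ √rb·g + √(rw−rb)·f_L(v) + β_v·c_v ] + (noise term),

with `g` a global factor, `f_k` per-network factors (the unlabeled
subcortical band forms its own block), `rw`/`rb` the within- and
between-network correlation targets (defaults 0.35 / 0.10), and the noise
loading chosen per voxel so the series has unit variance. Two choices are
deliberate and load-bearing:

- **Factors are orthonormalized within each session** (zero mean, unit
  variance, exactly zero mutual correlation in-sample). Raw factor draws
  leave O(1/√T) empirical correlations among factors that act as a global
  connectivity confound shared by every voxel pair — each replicate's
  whole z-map shifts together and cluster inference is badly
  miscalibrated. Orthonormalization emulates nuisance-cleaned data, which
  is what the pipeline consumes in practice (preprocessing is out of
  scope and time series are taken as given).
- **Per-voxel signal-amplitude jitter** `κ_v ~ 1 + N(0, 0.15)` per
  session supplies the between-subject metric-map noise. Without it the
  maps are so clean that correlation-based inference saturates: because a
  correlation is scale-free, even the faint genuine shift that the
  planted effect induces in its connection partners becomes significant
  everywhere.

The planted effect gives `effect_region` voxels (a compact 12-voxel blob
in one network) an extra cross-network loading `β_v = boost`: on a single
target network's factor when `target_network` is set, otherwise spread
uniformly over all other networks' factors (the default, which raises the
region's integration without creating a concentrated secondary region).
Per-subject boosts are `max(0, N(0.4, 0.2))` at baseline with an
independent `N(0, 0.2)` longitudinal change. The symptom-change score is

    change = 12.5·(−(boost − 0.4)) + 12.5·(−Δboost) + N(0, 3),

then written into bounded integer questionnaire totals, so higher baseline
integration and integration decreases map to improvement. The slope,
boost spread and noise place the realized region-mean partial correlation
(given the nuisance covariates) near 0.6 at n = 32, the regime the
recovery study is designed around. Covariate and score distributions
(age 42.4 ± 13.3; 28F:4M; SSRI/SNRI 13/32; FND-seizure 10/32; interval
6.8 ± 0.8 months; FD ≈ 0.073–0.076; questionnaire means/SDs and ranges)
follow the modelled study's clinical table. Each subject draws from an
RNG stream derived from the master seed by fixed offsets, so enlarging
the cohort never perturbs existing subjects.

What the generator does **not** emulate: scanner/physiological noise
spectra, motion-corrupted frames, anatomy, spatially smooth activation
fields (maps are spatially white up to the block structure, so estimated
FWHM ≈ 1), item-level questionnaires, or the global FC fluctuations of
un-cleaned real data. Passing tests therefore validate the statistical
machinery under a clean, known-truth data-generating process — not
robustness to real-world artifacts.

## Validation experiments and problem sizes

Bundled experiments (also re-run by `scripts/acceptance.py`) use a
(12, 12, 10) phantom — 800 grey / 600 isocortical voxels — 32-subject
cohorts at 200 timepoints, and reduced Monte-Carlo iteration counts
(600–2000 instead of 10,000), sizes at which the full set completes in a
few minutes:

1. **Family-wise error** — derive the extent threshold from 2000 null
   iterations at FWHM 2, then measure the rate of surviving clusters on
   200 fresh null fields. Observed ≈ 4.5% at seed 1.
2. **Null pipeline** — 100 cohorts with zero planted effects through
   time-series → metrics → GLM → correction. Observed 1% of cohorts with
   a significant cluster at seed 1; the discrete extent rule and the
   white-map floor make the pipeline conservative rather than
   anticonservative.
3. **Recovery** — 25 cohorts with the planted baseline effect; a
   replicate is recovered when ≥ 50% of region voxels fall in surviving
   clusters, and counts as a false flag when a surviving cluster is
   *disjoint* from the region dilated by the smoothness margin. Observed
   88% recovery, 4% false regions at seed 1. The cluster-level false
   criterion is deliberate: a genuine anchor cluster accretes chance
   26-connected fringe voxels beyond any fixed margin in a large share of
   replicates, and correlation symmetry necessarily gives the region's
   connection partners a small genuine shift, so voxel-exact localization
   is not a meaningful error measure for correlation-generated effects.

## Known limitations

- The longitudinal-change pathway is underpowered at the default
  conditions: change maps carry two sessions of metric noise, so at the
  default slopes the demo longitudinal analyses typically detect nothing
  (the baseline-predictor analyses do). Raising
  `longitudinal_effect_size` or lowering `noise_sd` shifts power between
  the two pathways.
- Cluster inference assumes stationary Gaussian-field-like nulls; the
  generator was designed to satisfy that assumption, and the calibration
  results do not speak to violations of it.
- The Wilcoxon/Mann-Whitney tie and continuity conventions are fixed
  choices among several defensible ones; exact small-sample variants are
  not exposed.
- Phantom voxel coordinates are reported 0-based in native grid order;
  there is no world-space geometry.
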