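# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `hippopls`.

## 1. Synthetic study design

The generator (`hippopls.synthgen`) emulates a two-condition task fMRI
experiment: autobiographical-memory retrieval trials (AM) interleaved with
mental-arithmetic control trials (MA).

**Trial schedule.** A run holds `n_trials` (default 40, half per
condition, randomly ordered) trials of exactly 17 s, the last 8 s of which
form the *elaboration window* — the period the analysis models.  A
selection button press is drawn per trial (normal, mean 3.53 s AM / 3.66 s
MA, SD 0.98 s, clipped to the pre-elaboration period), a post-trial rating
is drawn with the emulated vivid/easy proportions (89 % / 70 %), and
trials are separated by an ISI drawn uniformly from 1-4 s.  The run begins
with a 17 s waiting period covered by `n_discard = 5` leading volumes at
TR = 3.4 s; runs are capped at 264 volumes.

**Label volumes.** Each subject's segmentation assigns two hippocampi on
the shared grid.  The long-axis extent is drawn near 40 slices
(SD 2.57) with ~8 pre-DG slices (SD 2.01); every slice carries one band
per applicable subfield (pre/parasubiculum, subiculum, CA1, CA3/2, and
DG/CA4 in the body or the uncus anteriorly).  The uncus is labelled but
never analyzed.  A fixed neocortical slab, shared across subjects (the
synthetic "group space"), hosts the planted AM network
(`n_network_voxels`, default 150, chosen uniformly at random from the
slab once per cohort).

**Signal model.** A brain voxel's time series is

```
y_v(t) = B * (1 + s_v(t)/100) + drift_v(t) + e_v(t) + g(t)
```

with baseline `B = 1000`.  `s_v(t)` sums HRF-convolved boxcars over the
elaboration windows, scaled by per-condition amplitudes in percent signal
change:

* hippocampal (subfield × portion) cells take their AM amplitude from
  `effect_map` plus a per-cell, per-condition between-subject draw;
* neocortical voxels draw independent per-voxel subject amplitudes;
* the seed cell (default: anterior-body pre/parasubiculum) and the
  network voxels realize their subject variability through a latent
  scalar per elaboration window shared between them.

`subject_sd_pct` (default 0.35 %) parameterizes the between-subject SD of
the AM-minus-MA differential, so each condition's draw uses SD
`subject_sd_pct/√2`.  The latent amplitude is set analytically to
`subject_sd_pct/√2 · √n_trials`, which makes the seed's subject-level SD
equal the per-condition SD and yields an expected across-subject
seed-network correlation of `seed_network_r_am` (default 0.5) under AM and
`seed_network_r_ma` (default 0) under MA when extraction noise is small;
extraction noise attenuates the realized correlation slightly.

The default `effect_map` plants 0.2 % AM-minus-MA in every cell and
0.6 % in the anterior-body pre/parasubiculum, i.e. all subfields engage
during AM with one cell engaging over and above the rest.

**Noise.**  Voxelwise AR(1) noise (stationary SD `noise_sd = 5`,
`ar1_coef = 0.3`); a shared global AR(1) fluctuation
(`global_noise_sd = 1`, i.e. 0.1 % of baseline) emulating scanner-level
intensity variation — without it the global-mean series would be
unrealistically quiet and the QC screen degenerate; low-frequency drift
built from the three slowest cosines below 1/192 Hz with per-voxel gains
(amplitude 10); and optional global-intensity spike volumes
(`spike_volumes`, `spike_factor`) for exercising the QC stage.

**What the generator does not emulate.** No k-space physics, no spatial
displacement from head motion (only intensity-level artifacts), no
distortion or registration error (subjects share one grid, so group-space
"normalization" is the identity), no spatial noise autocorrelation, and no
physiological noise structure beyond AR(1).  Passing tests therefore show
that the analysis chain is correct and calibrated under this model — not
that it is robust to registration error or spatially structured noise in
real acquisitions.

**Group-level shortcuts.** Replicate-heavy validation uses two summary
simulators drawing directly from the same truth: subject × cell
differential tables (planted mean + N(0, `subject_sd_pct`)) and subject ×
voxel group matrices with the same latent-correlation construction.  They
represent the voxelwise pipeline's output distribution when within-subject
estimation noise is negligible.

## 2. First-level analysis

**HRF.** Canonical double gamma (gamma shapes 6 and 16, undershoot ratio
6, no derivatives), sampled at dt = 0.1 s.  Regressors are the
continuous-time convolution (discrete convolution × dt) of the 8 s
elaboration boxcars with the *area-normalized* response, so a sustained
block plateaus at the boxcar amplitude and planted percent signal change
round-trips through the GLM exactly in the noiseless case.  The generator
and the analysis share this code path deliberately.

**High-pass.** Realized inside the model as discrete-cosine regressors —
all cosines with frequency `j/(2·N·TR) ≤ 1/128 Hz` — rather than by
pre-filtering, preserving the residual degrees of freedom.  A drift
composed of in-band cosines is removed to numerical precision; a linear
ramp (not exactly in-band) is captured to better than 99.9 % of its
energy.

**Design.** Columns: AM and MA elaboration regressors, six mean-centered
motion parameters, the drift set, and an intercept.  The baseline is
implicit (unmodelled inter-trial intervals).  Rank-deficient designs are
rejected with a diagnostic.

**Fitting.** Ordinary least squares per voxel; residual df =
volumes − rank(X).  No autocorrelation whitening (a noted limitation: with
AR(1) noise the t-statistics are slightly optimistic; the package's
inferences rest on the resampling stages, not on first-level t values).
T-contrasts report `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`; voxels whose residual
variance is indistinguishable from rounding error (exact interpolation)
keep their contrast estimate with the t value masked.  Extracted signal
intensities are beta contrasts scaled to percent of the voxel's intercept
(`100·β/β₀`), making them comparable across subjects; raw t maps are also
available.

**Motion / intensity QC.** A volume is flagged when its detrended global
mean (intercept + drift set projected out) deviates more than the central
97 % normal band (|z| > 2.17, z standardized by the residual SD), or when
any motion parameter jumps more than 1 mm / 0.02 rad between volumes; the
two sub-criteria are OR-combined.  A run is excluded when flagged volumes
exceed 10 % of retained volumes.  Detrending is what lets slow scanner
drift pass while spikes are caught.

**Smoothing.** Isotropic Gaussian, σ = FWHM/2.3548 per axis in voxel
units, reflect padding (preserves the mean near edges): 1 mm FWHM in
native space before extraction, 6 mm before group-space stacking.

**tSNR.** Temporal mean over residual SD after projecting out the
intercept and drift set; zero-variance voxels are excluded from ROI means
and logged.

## 3. ROI rules

**Long-axis partition.** Per hemisphere, the *anterior* portion runs from
the first hippocampus-bearing slice to the slice before the first DG/CA4
slice; the remaining slices are split into three contiguous near-equal
parts (anterior body, posterior body, tail).  When the remainder of the
three-way split is nonzero the extra slices go to the rostral-most parts
first, so part sizes are non-increasing rostral → caudal and never differ
by more than one.

**Extraction.** Mean contrast intensity over each (subfield × portion ×
hemisphere) voxel set, for `whole` plus the four portions; empty sets
(e.g. DG/CA4 in the anterior) yield NaN with a logged warning.
Whole-hippocampus analyses include the anterior portion; portion-wise
analyses use only the three body/tail portions (the anterior is short,
lacks DG/CA4, and is excluded from portion-wise statistics).

**Laterality.** A paired t-test across subjects compares hemispheric mean
whole-hippocampus differentials; when non-significant (p ≥ 0.05)
hemispheres are collapsed by voxel-count-weighted averaging (equal to the
pooled-voxel mean — the collapse rule is a package choice, the weighting
being the variant that commutes with pooling voxels).  A significant
lateralization leaves hemispheres separate with a warning.

**DICE.** `2|A∩B|/(|A|+|B|)`; two empty masks are defined as similarity 1
with a warning.

## 4. Group univariate statistics

One-way repeated-measures ANOVA in the univariate formulation:
`F = MS_levels / MS_(levels×subjects)` with df `(k−1)` and `(k−1)(n−1)`;
subjects with missing cells are dropped listwise and logged.  No
sphericity correction is applied by default (matching common practice for
these designs); the F test is exact under compound symmetry.  Tukey HSD
follow-ups use the studentized range with the RM error term and its df;
Dunnett comparisons against a declared control level use two-sided
equicoordinate probabilities of the equicorrelated (ρ = 1/2) multivariate
t, evaluated numerically to ~1e-3 (cross-checked against a Monte-Carlo
oracle in the tests).  Bonferroni adjustment is `min(1, p·m)`.

## 5. Partial least squares

**Mean-centered PLS.** Rows = condition means over subjects, centered by
the unweighted grand mean across conditions; SVD gives design saliences
(U), singular values (S) and voxel saliences (V).  With two conditions the
matrix is rank one and LV1's voxel salience is proportional to the
AM-minus-MA mean difference map.  Sign convention: each LV is oriented so
its largest-magnitude design salience is positive.

**Seed PLS.** Rows = within-condition across-subject Pearson correlations
between a seed ROI's extracted intensity and every voxel.  The matrix is
*not* centered across conditions (the direct correlation reading);
zero-variance seeds or voxels yield a zero entry with a log record.  The
portion-wise omnibus stacks the correlation rows of all five subfields
(seed-major, 10 rows for two conditions); follow-ups analyze one subfield
at a time.

**Permutation inference.** p-values use the add-one estimator
`p_i = (1 + #{s_perm,i ≥ s_obs,i}) / (1 + n_perm)` with permuted singular
values matched to observed LVs by rank; defaults `n_perm = 500`
(validation experiments use 200).  Exchange schemes differ by method:

* *mean-centered*: condition labels are shuffled within subject — the
  standard task-PLS null of exchangeable conditions;
* *seed*: seed values are permuted across subjects within each condition
  (one subject permutation per condition, applied to all seeds jointly so
  inter-seed structure is preserved), breaking the seed-brain pairing
  while leaving the brain rows and the seed's condition means intact.
  Shuffling condition labels jointly for seed and brain rows was
  implemented first and rejected: when both the seed region and the
  network carry a condition-mean activation difference (as planted, and
  as any co-activated network would), the joint shuffle mixes those means
  into the permuted within-group correlations, inflating the null above
  the observed singular value and driving power to zero.

When fewer distinct permutations exist than requested (tiny designs) the
group is sampled with replacement and a warning is issued; a one-subject
design degenerates gracefully to p = 1.

**Bootstrap ratios.** Subjects are resampled with replacement, keeping
each subject's full condition set (and their seed values).  Each
bootstrap's voxel saliences are aligned to the original solution by the
orthogonal Procrustes rotation of its design saliences, preventing
sign/axis flips from inflating the SE; `BSR = salience / SD(bootstrap
saliences)` with `n_boot = 100` by default.  SEs indistinguishable from
rounding error mask the BSR (NaN) with a log record.  Under the default
conditions a voxel with true seed correlation r has expected
`BSR ≈ r / ((1−r²)/√(n−3))` — about 3.1 at r = 0.5 with 24 subjects — so
|BSR| > 3 marks voxels at or beyond that reliability, not a generous
margin above it.

**Clusters.** Supra-threshold voxels (|BSR| > 3 by default, two-sided,
positive and negative clustered separately) are grouped by 6-neighbor
face connectivity in 3D; clusters of ≥ 50 voxels are reported with size,
sign, peak |BSR| and peak coordinate.

**Battery.** Three portion-wise omnibus analyses at α = 0.05; where
significant, five per-subfield follow-ups at the Bonferroni-corrected
α = 0.01, with bootstrap ratios for each surviving subfield.  In the
pipeline the battery's brain matrix is restricted to the neocortex mask:
the question is hippocampal-neocortical connectivity, and including the
hippocampus would let each seed correlate trivially with its own ROI
voxels through shared extraction noise.  Mean-centered PLS keeps the
whole brain mask.

## 6. Pipeline and reproducibility

`run_all` executes simulate → QC → GLM → extraction → laterality collapse
→ paired t (Bonferroni over five subfields) → portion-wise RM-ANOVA with
Tukey → mean-centered PLS → seed-PLS battery, and summarizes recovered
vs planted effects.  All randomness descends from the configuration's
`rng_seed` through named streams (schedule, labels, network, BOLD, group),
so identical configurations give byte-identical summaries; the config
hash is embedded in every output.  A stage failure aborts with a
stage-tagged diagnostic.

**Problem sizes.** The default lattice is a reduced 40×40×48 grid at
2 mm voxels rather than an acquisition-sized matrix; tests and the
validation experiments use a 20×12×30 grid with 21-slice hippocampi,
12-trial runs and 6-24 subjects, and the replicate counts 100 (null
calibration), 50 (ANOVA recovery) and 25 (connectivity recovery).  These
sizes are the package's desk-scale choices; every experiment is a function
of its seed and scales up by argument.

## 7. Known limitations

* OLS without whitening leaves first-level t values slightly optimistic
  under AR(1) noise; group inference relies on resampling.
* The seed-PLS permutation tests "no seed-voxel association", not "no
  condition difference in association"; with the uncentered correlation
  matrix a connectivity pattern common to both conditions would also be
  detected.  Condition-centering of the seed matrix is the natural
  variant for a pure difference test and can be composed from the public
  builders.
* Voxel noise is spatially independent, which makes whole-matrix
  singular-value nulls harsher than for smoothed real data, where spatial
  correlation reduces the effective voxel count; detection of a planted
  network in a large matrix is correspondingly conservative at desk scale.
* Synthetic hemispheres are statistically identical by construction, so
  the laterality branch that refuses collapse is exercised only by
  constructed tables in the tests.
* The generator's response amplitudes are condition-locked scalings of a
  single canonical HRF; no HRF variability across regions or subjects.
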