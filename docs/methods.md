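# Methods

This document records the models, parameter choices and numerical
decisions behind each module, and the known limits of the synthetic
phantoms.

## Phantom model (`neuropipe.phantom`)

The structural phantom is a nested-ellipsoid head: an outer brain
ellipsoid (default semi-axes 58 × 72 × 56 mm) containing concentric
grey-matter (92 % of the outer radius) and white-matter (75 %) shells, a
central CSF ventricular system, and 15 subcortical structures
(brainstem plus 7 left/right pairs) placed as small ellipsoids at fixed
anatomical offsets. Tissue intensities are CSF 30, GM 60, WM 90
(arbitrary units) with partial-volume fractions stored per tissue. The
default grid is 48 × 56 × 48 voxels at 3 mm — chosen once so that one
bundle generates and featurises in well under a second while all 13
atlas regions, every subcortical structure and the ventricles remain
several voxels across. A multiplicative smooth bias field (peak
deviation `bias_amplitude`, default 0.05) and additive Gaussian noise
(`noise_sigma`, default 1.5) complete the forward model. The bundle
carries everything downstream stages need: the noiseless template, an
affine to a standard space, a warp-magnitude map, brain mask, two
alternative brain extractions (dilated and eroded), a lobe atlas and a
lesion mask.

Artifact injection maps each problem code (0–10) and imperfection code
(1–7) to one or more injectors — k-space ringing, bias, field-of-view
truncation, ventricle enlargement, white-matter lesions, and three
kinds of brain-mask error — with effect linear in a severity in [0, 1].
Severity is a toolkit construct (the study conditions use severities
drawn U(0.4, 1.0) for the unusable class); code 0 and severity 0 are
no-ops recorded in the truth ledger.

Realism limits: the phantom has no gyrification, no real registration
step (the affine and warp map are synthesised), no motion model beyond
ringing, and intensities are not quantitative. It is designed so that
every pipeline property under test is *true by construction and
checkable against ground truth*, not so that images look realistic.

## Protocol conformance (`neuropipe.conformance`)

The reference protocol fixes, per modality, the matrix (e.g. T1
208 × 256 × 256 at 1 mm; resting fMRI 88 × 88 × 64 × 490 at 2.4 mm;
diffusion 104 × 104 × 72 with 5 b=0 plus 50 directions each at
b = 1000 and b = 2000 s/mm²). Voxel sizes compare with tolerance 1e-3 mm
(header rounding); b ≤ 50 counts as b = 0 and shells match within
±100 s/mm². Each failed check contributes one human-readable reason.
Routing moves an unusable modality's files into an `unusable/`
subfolder (idempotently, ordered by mtime then name); an unusable T1
marks every other modality non-processable but leaves its files in
place.

## Defacing (`neuropipe.deface`)

Face and ear boxes are defined in standard-space millimetres as
half-open axis-aligned intervals (minimum inclusive). Rasterisation
maps each native voxel centre through the native affine to world space
and through the inverse of the standard-to-native affine into standard
space; a voxel is removed iff its centre falls in a box. The default
boxes were placed once, outside the default brain ellipsoid with margin
covering the benchmark's ±5 % anatomical variation, and the overlap
report (voxels removed inside the brain mask) provides the audit.

## Bias transfer (`neuropipe.bias`)

Correction divides by the bias field inside the mask (non-positive bias
inside the mask is an error). The quality statistic is the IQR of
WM voxel intensities after division by their median — scale-invariant,
with percentiles computed by linear interpolation, requiring ≥ 4
voxels.

## swMRI (`neuropipe.swmri`)

Phase highpass is homodyne-style: the complex image is multiplied by
the conjugate of a Gaussian low-pass of itself (in-plane only, sigma =
kernel/6 with default kernel 33 voxels, so smooth coil/background phase
cancels exactly while fine phase survives). Coils combine per echo as
Σ|image|·exp(i·filtered phase); the final phase is taken from the
second echo. The venogram multiplies second-echo magnitude by
(1 − clamp(s·φ, 0, π)/π)⁴ — diamagnetic phase (opposite the
paramagnetic sign s) never attenuates. R2* = ln(S1/S2)/ΔTE (TE 9.4 and
20 ms) reported in s⁻¹, T2* = 1/R2* in ms; non-invertible voxels
(non-positive or non-decaying magnitudes) are flagged missing, median
filtered with a 3 × 3 × 1 in-plane kernel (slices are thick), then at
most two dilation passes fill holes from valid 8-neighbourhoods;
anything left stays missing rather than being invented. On the
noiseless single-coil phantom this chain inverts the forward model to
machine precision, which is the headline correctness gate.

## b=0 selection (`neuropipe.b0select`)

Score of volume i = mean of its off-diagonal correlations against all
co-aligned b=0 volumes. The first volume is preferred whenever its
score reaches 0.98 (boundary inclusive) because it is acquired closest
in time to the neighbouring series; otherwise the argmax wins with
lowest-index tie-breaking. AP and PA series are selected independently.
The built-in aligner searches integer shifts only; pre-aligned input
from a full rigid registration is accepted.

## fMRI networks (`neuropipe.fmrinet`)

* **Highpass**: at each timepoint a straight line is fitted to the
  whole series with Gaussian weights (sigma 50 s, TR 0.735 s) and
  subtracted; the column mean is added back. Implemented as a T × T
  smoother matrix — exact, and fine at desk scale.
* **MIGP**: a running stack of weighted spatial eigenvectors is
  concatenated with each subject in turn and reduced by
  eigendecomposition of the small T × T covariance; the working
  dimension defaults to twice the kept components. Noiselessly this
  matches batch PCA of the temporal concatenation to < 1e-6 rad
  principal angle.
* **Dual regression stage 1** is `data @ pinv(maps)` with a rank check.
* **Cleanup** residualises non-artefact node timeseries against the
  artefact nodes (with intercept) and drops them, e.g. 25 → 21 nodes.
* **Partial netmats** use the ridge convention of scaling the
  covariance so its squared diagonal has mean 1 before adding ρI
  (ρ = 0.5 by default), making ρ comparable across datasets;
  r = −P_ij/√(P_ii P_jj).
* **r-to-z** multiplies arctanh(r) by √(df_eff − 3), where df_eff is a
  Bartlett-style correction T/(1 + 2Σρ̂_l²) summed to min(T/4, 50)
  lags — white noise gives df_eff ≈ T, autocorrelation strictly fewer.
* **Vectorisation** walks the strictly-upper triangle column-major
  ((1,2), (1,3), (2,3), (1,4), …), giving 210 values for 21 nodes;
  `rewrap_netmat` inverts it.
* **Task chain**: Gaussian smoothing with sigma = FWHM/2.3548 per axis
  (time axis untouched), and ROI summaries of percent signal change
  (relative to the overall-image-mean baseline) and z, each by median
  and 90th percentile.

## QC features (`neuropipe.qcfeatures`)

The manifest holds exactly 190 uniquely named features in 16
categories, sized 12, 5, 8, 30, 7, 4, 45, 2, 6, 6, 6, 5, 4, 7, 4, 39:
template discrepancy (NCC and mean |difference| globally and in 10
lobes), SNR/CNR, global tissue volumes, subcortical volumes raw and as
brain-volume fractions, bilateral asymmetries, global asymmetry,
subcortical intensity statistics, GM outside the mask, tissue on the
mask border, Canny edge counts per tissue (slice-wise, sigma 1,
thresholds 0.1/0.2, excluding the mask border shell), agreement with
the two alternative brain extractions (Dice, volume ratio, symmetric
difference), mask-border intensities, GM/WM holes, warp statistics
(including a Jacobian proxy from the warp gradient), lesion loads
(periventricular = within 10 mm of deep CSF), and border-distance
statistics per atlas region. All intensity-derived features are ratios
or median-normalised, hence invariant to global intensity rescaling.
Missing values are NaN, handled downstream by imputation. Degenerate
inputs yield NaN rather than errors.

## QC classification (`neuropipe.qcclassify`)

Continuous features are median-imputed and discretised into 10
equal-frequency bins (edges learned on training folds only). Three
classifiers are trained: a Gaussian naive Bayes on the continuous
features; a discrete Bayesian-network classifier with the class at the
root, greedy structure search adding at most one feature parent per
feature scored by the Dirichlet (BDeu-style) marginal likelihood with
per-cell prior α = 0.5 (vectorised with gammaln lookup tables over
integer counts, which is what makes 190-feature structure search fast);
and a MetaCost wrapper around a second Bayes network — bagged
probability estimates (out-of-bag where possible), relabelling each
training point to the class of minimum expected cost under a 20:1
false-negative:false-positive cost matrix, then retraining. Posteriors
fuse by the Minimum-Probability rule: per-class minimum across models,
renormalised; exact ties go to the positive (flag-for-review) class.
The asymmetric cost and positive tie-break both serve the operating
goal: missing an unusable subject is far worse than flagging a usable
one. Evaluation is stratified 10-fold cross-validation with pooled
confusion counts; metrics with zero denominators are reported missing
rather than as 0 or 1.

## Benchmark (`neuropipe.benchmark`)

240 phantoms: 200 clean with natural variation (radii ±5 %, ventricle
scale ±10 %, bias 0.02–0.08, noise 1.0–2.5) and 40 with one problem
code drawn from {3, 4, 5, 6, 8, 9, 10} at severity U(0.4, 1.0). These
generator settings define the study conditions and were fixed once, up
front. Cross-validated performance on this benchmark (sensitivity
0.975, flagged rate 0.16 at seed 1) is the classifier's acceptance
gate.

## Numerical conventions

Percentiles use linear interpolation throughout. Random number use is
exclusively `numpy.random.default_rng` with explicit seeds; derived
seeds stay below 2³¹. Matrix inversions are guarded (singular affines
raise; rank-deficient map matrices raise; constant volumes raise with
the offending index named).
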