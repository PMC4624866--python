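# Methods

## What the pipeline computes

Spontaneous low-frequency oscillations (LFO) of the resting-state BOLD signal
are quantified per voxel by two amplitude indices:

* **ALFF** — the mean of the one-sided FFT amplitude spectrum over a frequency
  band. With the convention amp_k = 2|X_k|/N (interior bins), a sinusoid of
  amplitude A centred on bin k contributes exactly A to that bin, so ALFF is in
  the signal's own units and is linear in signal scale: ALFF(c·x) = c·ALFF(x).
  For group analysis each subject's ALFF map is divided by its in-mask mean
  ("normalized ALFF"), removing global scale differences between subjects.
* **fALFF** — the band's amplitude sum divided by the amplitude sum over the
  whole detectable spectrum (0–0.25 Hz at TR = 2 s), a dimensionless fraction
  in [0, 1]. It is scale-invariant, so no further normalization is applied.

Both indices are computed in the five canonical LFO sub-bands — slow-6
[0, 0.01), slow-5 [0.01, 0.027), slow-4 [0.027, 0.073), slow-3 [0.073, 0.198)
and slow-2 [0.198, 0.25] Hz — half-open on the right with slow-2 closed at the
Nyquist frequency, so the bands partition (0, 0.25] and the five fALFF values
of any voxel sum to exactly 1. Bin membership is decided by bin-centre
frequency; the 0.027 Hz boundary belongs to slow-4. The DC bin is excluded
everywhere (series are detrended, so DC ≈ 0 regardless). slow-6, slow-3 and
slow-2 are computed but excluded from group analysis: they are dominated by
scanner drift, white-matter signal and physiological noise respectively, and
only slow-4 and slow-5 carry the grey-matter LFO of interest.

### Preprocessing and its deliberate deviation

Per run: the first 10 volumes are discarded (magnetization equilibration;
240 → 230 volumes), each voxel's series is linearly detrended (OLS line
removal; idempotent), and volumes are smoothed with a normalized separable 3D
Gaussian kernel (FWHM 6 mm; sigma = FWHM/(2√(2 ln 2)) per axis in voxel units;
nearest-edge boundaries).

The broad 0.01–0.08 Hz temporal band-pass customary in resting-state
preprocessing is **not** applied. Filtering first would truncate slow-4
content near its 0.073 Hz upper edge's neighbourhood and, more importantly,
destroy the slow-3/slow-2 spectrum that the fALFF denominator requires (fALFF
is defined over the full 0–0.25 Hz range). Band restriction is therefore
performed in the spectral domain per sub-band, and the fALFF denominator uses
the unfiltered, detrended spectrum. This is the standard resolution of a known
internal tension in band-specific ALFF pipelines.

### Quality control

A run is excluded iff any single translation axis exceeds 2.0 mm or any
rotation axis exceeds 2.0° in absolute value at any timepoint, applied to
parameters relative to the reference volume (not frame-to-frame deltas).
The rule is a strict ">": a trace touching exactly 2.0 is kept. Motion traces
are defined over the retained 230 volumes, since realignment in the emulated
pipeline follows volume discarding.

### Group statistics

The design is a 2 (group, between-subject) × 2 (band: slow-4 vs slow-5,
within-subject) mixed ANOVA per voxel. With only two within-subject levels
every effect reduces exactly to a t statistic on per-subject summaries
(m_i = (y4_i + y5_i)/2, d_i = y4_i − y5_i):

* group: pooled-variance two-sample t on {m_i};
* interaction: pooled-variance two-sample t on {d_i};
* band: t for the unweighted mean of the two group means of d against zero,
  SE = s_d·√((1/n1 + 1/n2)/4).

All three use df = n1 + n2 − 2 and satisfy t² = F of the classical split-plot
ANOVA (verified against an independently coded cell-means oracle and against
pingouin's implementation). Effects are reported as signed t maps (group =
group1 − group2, band = slow4 − slow5); F is recoverable as t². Under
imbalance the unweighted band mean matches Type-III conventions. Zero-variance
voxels are masked out of the t maps rather than raised as errors.

Regional follow-up uses cluster-mean extraction (both bands extracted for each
significant cluster, the larger-|t| band flagged), Pearson correlation with
clinical scores, and partial correlation after OLS residualization of both
variables on age, sex (0/1) and education (df = n − 2 − k). A voxelwise OLS
slope-t regression on a covariate (e.g. age) is available with df = n − 2.

### Cluster-extent correction

Family-wise error of the lenient voxel-level threshold (two-tailed p < 0.05)
is controlled by an AlphaSim-style Monte Carlo procedure: per iteration, fill
the mask's bounding box with white Gaussian noise, smooth at the analysis
FWHM, standardize to zero mean/unit variance in-mask, threshold two-tailed at
the voxel p, form clusters separately within each sign (default 26-neighbour
connectivity, configurable to 6/18), and record the maximum cluster size
across signs. The extent threshold is the smallest k whose simulated
exceedance frequency P(max ≥ k) is ≤ alpha. Clusters at least that large are
retained and reported with extent (voxels and mm³), signed peak t, and peak
location (0-based index and mm = origin + index·voxel size). When a threshold
is instead supplied in mm³ under a strict ">" convention, the voxel threshold
is floor(V/voxel volume) + 1 (e.g. 3591 mm³ at 27 mm³/voxel → 134 voxels).

Simulated smoothness equals the applied analysis smoothing (6 mm) rather than
a residual-estimated smoothness — no smoothness estimate is available for the
emulated data, and the simulation should match what was actually applied to
the maps; a residual-based estimator could be slotted in where the config
takes its FWHM.

## The synthetic cohort generator

Real patient scans for this design are not publicly deposited, so the pipeline
ships a generator that emulates the acquisition at desk scale and provides
exact ground truth. Defaults (chosen once as realistic resting-BOLD
magnitudes, in arbitrary scanner units):

| parameter | default | meaning |
|---|---|---|
| grid | 24×28×24 voxels, 3 mm isotropic | ~1/8 the voxel count of a full MNI grid; full method coverage at desk cost |
| n_timepoints / TR | 240 / 2.0 s | 10 volumes later discarded → 230 analyzed |
| baseline | 1000 | mean signal level |
| band signal SD | 10 (≈1% of baseline) | typical relative LFO amplitude |
| noise_sd | 10 | broadband white noise, same order as the signal |
| drift_slope_sd | 0.02 /volume | ≈5 units of linear drift over a run |
| subject_amplitude_sd | 0.3 | lognormal sigma of the per-subject amplitude factor |

Construction per subject: baseline + per-voxel linear drift (slope ~
N(0, drift_slope_sd)) + white noise + the ROI band signal. The band signal is
white noise FFT-masked to the ROI's band, inverse-transformed and rescaled so
its sample SD is exact — broadband within its band, like real LFO, not a sum
of sinusoids. The *shape* is drawn once per ROI and shared across subjects;
each subject scales it by base_amplitude × group multiplier × a lognormal
subject factor. Sharing the shape makes group amplitude ratios exact in band
ALFF (the noiseless group-1/group-2 ALFF ratio equals the multiplier ratio to
1e-6), at the cost of unrealistically perfect between-subject signal
correlation; between-subject amplitude variance comes from the lognormal
factor. Covariate couplings attach a clinical score to the *noiseless* planted
amplitude x via y = r·z(x) + √(1−r²)·e, so recovery error measures only the
pipeline, then map y to the score's clinical scale (THQ 43.5 ± 21.3 clipped to
[0, 100]; duration 36.9 ± 36.4 months clipped below at 1). Uncoupled
covariates are drawn from the same clinical moments (age 41.5 ± 14.6 /
46.0 ± 12.2 years, education ≥ 8 years, sex ≈ 60%/51% male for
patients/controls).

Motion traces are smoothed random walks re-anchored at the reference volume;
non-outlier axes peak at 0.1–1.2 mm/°, designated outliers exceed the limit on
one axis (2.2–3.5). Outlier designation: k = round(fraction × n) per group,
assigned to the first k after a seeded shuffle. All randomness flows from one
cohort seed through named substreams, so identical spec ⇒ bit-identical
cohort.

What the generator does **not** emulate: slice-timing offsets, realignment
residuals, field inhomogeneity, cardiac/respiratory waveforms, spatial
autocorrelation of the noise, or 1/f noise spectra. Passing tests therefore
show the *estimator chain* is correct and calibrated under a white-noise null;
they do not certify behaviour under physiological confounds.

### Two instructive artifacts the synthetic analyses exhibit

* **Global-normalization redistribution.** Dividing ALFF by the in-mask mean
  makes a focal planted increase appear alongside a diffuse, opposite-signed
  background change (the planted ROI inflates the global mean, depressing all
  other voxels). The analysis scripts' cluster tables show exactly this: a
  compact positive cluster at the ROI plus a large negative background
  cluster. This is a genuine property of global-mean normalization, not a bug.
* **Truncation leakage.** The band signal is exactly band-limited on the
  240-sample grid, but discarding 10 volumes breaks bin alignment, leaking a
  small amplitude-proportional component into neighbouring bands — which is
  why slow-5 regional values can correlate with a covariate coupled only to
  slow-4 amplitude. Real pipelines have the same property.

## Numerical choices

* Amplitude convention 2|X_k|/N; DC carries |X_0|/N and the Nyquist bin (even
  N) |X_{N/2}|/N, both flagged; any fixed positive rescaling cancels in
  normalized ALFF and fALFF. Energy identity under this convention:
  Σ_t x² = (N/2)·Σ_interior amp² + N·(amp_DC² + amp_Nyq²).
* fALFF at voxels with zero total amplitude is NaN (undefined marker), not an
  exception; normalization with a non-positive in-mask mean is an error.
* Voxelwise degenerate cases: zero-variance ANOVA voxels → NaN; a perfect
  regression fit → ±inf slope t (flagged); scalar entry points raise instead.
* Cluster labels follow the lexicographic scan order of `scipy.ndimage.label`;
  reports are sorted by descending extent with a stable tie-break.
* I/O: NIfTI-1 volumes (float32, TR in pixdim[4]), 6-column whitespace motion
  text (translations mm, rotations °), tab-separated phenotype with columns
  subject_id, group, age, sex, education_years, thq, duration_months.

## Validation experiments and problem sizes

`bandalff.experiments` re-derives the pipeline's guarantees from scratch at
sizes a laptop handles in minutes (the same sizes the acceptance script and
tests use): null p-value calibration on a 20+20 noise cohort (24×28×24 grid,
binomial 99% band around 0.05); realized FWER of the extent threshold (1000
calibration iterations, 200 fresh nulls, target 0.05 ± 0.04); detection of a
planted slow-4 interaction (group-1 multiplier 1.5, n = 20+20, 10 replicate
cohorts, detection = corrected interaction cluster with Dice > 0.5 against the
ROI); recovery of a planted r = 0.5 THQ coupling at n = 39 patients (20
replicates on a 16×18×16 grid, coverage of the Fisher-z 95% interval, and the
partial-correlation shift under independent covariates); and the
motion-exclusion arithmetic (2 of 41 patient runs over the limit → 39
retained).

## Known limitations

* The 2×2 closed form does not generalize to more bands or factors; no
  REML/mixed-effects machinery is included.
* No nonparametric correlations, no multiple-testing correction across the
  correlation table (none is applied in the emulated analysis), no
  Gaussian-random-field or permutation cluster inference.
* The simulated null for the extent threshold assumes stationary Gaussian
  smoothness equal to the applied kernel; real BOLD smoothness varies
  spatially.
* Anatomical labelling of cluster peaks is out of scope; the region column of
  report tables is left to the user.
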