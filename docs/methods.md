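# Methods

This note documents the models, conventions and design choices behind
`betalat`, in the spirit of the methods documentation of packages such as
`mne` or `statsmodels`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Analysis model

The pipeline estimates hemispheric language dominance from the
event-related desynchronization (ERD) of beta-band oscillations during a
covert verb-generation task. Its statistical object is, per subject, the
per-voxel contrast of narrowband source power between a pre-stimulus
baseline (−700–0 ms) and an active window (300–1000 ms), both 700 ms long
so spectral estimates are directly comparable.

**Cross-spectra.** Each window of each trial is demeaned with its own mean
and tapered with DPSS sequences; the taper count follows
K = ⌊2·T·W⌋ − 1 (T segment duration, W = 11 Hz half-bandwidth; 14 tapers
at the defaults). Fourier coefficients are taken at the bin of the
next-power-of-two frequency grid nearest 24 Hz, evaluated by direct DFT at
that single bin (identical to zero-padding and selecting the bin, without
allocating the full FFT). Tapering is applied per trial segment and
cross-spectra averaged over tapers and trials rather than tapering a
concatenation of trials; the expectation is the same and boundary
artifacts are avoided. The CSD diagonal is normalised so a sinusoid of
amplitude A at the centre frequency reads A²/2 (band-limited variance);
all downstream quantities (filters, percent change, t statistics) are
invariant to this constant. Condition CSDs combine into the pooled CSD by
the trial-count-weighted mean.

**Forward model.** Sources are current dipoles in a homogeneous conducting
sphere; sensor readings follow Sarvas' closed-form magnetometer field
projected on the coil normal. Radially oriented dipoles are exactly
silent, so the per-voxel 3-column leadfield has rank 2; the grid point at
the sphere centre is silent altogether and is carried with zero gain. An
anatomy-dependent realistic conductor is deliberately out of scope: the
sphere model is closed-form, testable against its analytic properties, and
standard for magnetometer arrays.

**DICS beamformer.** The spatial filter uses the real part of the pooled
CSD (the standard convention for power mapping), regularised as
C_r = Re(C) + λ·tr(Re C)/n_chan·I with λ = 0.1 by default. The filter is
scalar (orientation-optimised) rather than vector: per voxel the
orientation is the generalized eigendirection maximising output power —
equivalently minimising l'C_r⁻¹l — computed inside the numerically
non-silent column space of the local leadfield (singular directions below
1e−8 of the leading singular value are projected out, which removes the
sphere's radial null direction). Weights are the unit-gain minimum-variance
solution w = C_r⁻¹l / (l'C_r⁻¹l). The *common* filter is built once from
the pooled conditions and applied unchanged to the baseline and active
per-trial CSDs, so condition contrasts are not biased by
condition-specific filters. Percent change is 100·(active − baseline)/
baseline per voxel; zero-baseline voxels are flagged invalid rather than
propagated as infinities.

**Inference.** The per-voxel statistic is the paired t of
(baseline − active) over trials, df = n − 1, so a power decrease yields
positive t; one-tailed critical t = 1.65 (p = 0.05). Family-wise error over
the ROI-restricted voxel set is controlled by a cluster-mass permutation
test: suprathreshold voxels form connected clusters (6-connectivity on the
cubic grid by default; configurable, as is the sensor-space variant via
k-nearest-neighbour adjacency extended over ±1 time sample), each cluster
is scored by the sum of its t values, and observed masses are referred to
the maximum-mass distribution over random sign flips of the per-trial
differences. Sign-flip t values are recomputed exactly but cheaply using
the invariance of Σd² under sign flips. p-values include the observed draw
((b+1)/(n_perm+1)), so min p = 1/(n_perm+1). "Not enough surviving voxels"
is operationalised as *zero clusters at p ≤ α*, in which case the map falls
back to the uncorrected one-tailed threshold t = 1.97 (p = 0.025) and is
marked uncorrected in its metadata. The sensor-level exploratory path
(z-scored evoked RMS per hemisphere, pointwise sign-flip randomization
with Benjamini–Hochberg FDR) shares the same engine and conventions but is
two-sided.

**Laterality and categories.** LI = (S_L − S_R)/(S_L + S_R) with S either
the sum of surviving t values or the surviving voxel count; both variants
are always computed, with sum-t as the reporting default (on flat maps they
coincide; the cohort tables print sum-t). LI is undefined — not zero — when
both sides are empty. Cutoffs are ±0.1 (MEG) and ±0.2 (fMRI), boundary
inclusive toward the lateralized category; dichotomization maps left→Left
and right/bilateral→Atypical. fMRI maps are thresholded at t = 3.13 with a
10-voxel minimum extent under 18-connectivity (the convention of the
originating volumetric ecosystem; configurable), or by the top 10% of
positive voxels with ties at the cut retained.

**Agreement.** Unweighted Cohen's κ from the marginal-product chance
expectation, with a permutation p-value and a Bonferroni-style ×3
correction across ROIs (capped at 1 by default; uncapped available).
Matthews correlation for 2×2 tables, defined 0 when a margin vanishes.
Peak coordinates are the maximum-statistic surviving voxel per ROI side,
ties broken by lowest voxel index; an alternative centroid-of-peaks
reading exists in the literature but is not implemented. When both series
are constant and equal, κ is reported as 1 with a degeneracy flag. For
fMRI-vs-Wada in the reference cohort, κ recomputed from the cohort's own
tables is 0.34 (WA) and 0.46 (TIMP); the package always reports values
recomputed from the data rather than any externally stated κ.

## Synthetic data

The generator emulates the study conditions rather than any particular
recording: stimulus-locked epochs from −1.0 to +1.5 s; oscillatory dipole
sources at 24 Hz with trial-random phase and tangential orientation
(near-radial orientations are rejected — they are magnetically silent in a
sphere); an amplitude envelope of 1 at baseline and `ratio` during the ERD
window, with 50-ms raised-cosine ramps placed just *outside* the window so
the plateau spans it exactly (this makes the active/baseline narrowband
power ratio equal ratio² analytically, which the tests exploit); a 1/f
background (default exponent 1) and white sensor noise added after forward
projection.

Defaults: 160 trials (the usable-trial count of the emulated recordings is
about 167), amplitude ratio 0.89 — i.e. a ~21% power decrease, inside the
−14% to −23% decrement range reported for healthy speakers, since no SNR
is published for the patient data — dipole moment 50 nAm, sensor noise
2e−13 T and background 1e−13 T RMS, which puts peak-channel amplitude SNR
near 10. The toy anatomy places magnetometers on rings over the upper
hemisphere of a 12-cm sphere, mirror-symmetric in x, around a 9-cm head
sphere; the cubic grid (10 mm default spacing) carries 18 pseudo-regions
(terciles of y × terciles of z per hemisphere) that are exact mirror
images across the midsagittal plane, so a symmetric map yields LI = 0 by
construction. Coordinates: x<0 left, origin at the sphere centre, mm in
source space, m in sensor space.

What the generator does **not** emulate: realistic cortical geometry and
conductor anatomy, eye-blink/cardiac/dental artifacts, heteroscedastic or
spatially correlated sensor noise, evoked (phase-locked) components, and
hemodynamics (the fMRI arm synthesises t-maps directly as Gaussian blobs
plus noise, not BOLD time series). Passing tests therefore demonstrate the
correctness and calibration of the *computation* — localization, error
control, LI recovery — not clinical performance on real recordings.

## Numerical choices and edge cases

- Regularised CSDs with condition number above 1e12 raise a numeric
  failure with the advice to raise λ (λ = 0 on rank-deficient data is the
  typical trigger).
- Zero-variance difference voxels get t = ±∞ with the sign of the mean
  (0 when the mean is also 0); permutation t values recompute under the
  same rule.
- Morlet time–frequency cells whose wavelet half-support
  (n_cycles/(2f)) exceeds the distance to an epoch edge are flagged
  invalid (NaN), never zero-filled; relative power change flags
  zero-baseline cells the same way.
- The band-power helpers normalise wavelet rows by their own peak response
  and equivalent-noise bandwidth (both measured from the transform's
  response to unit sinusoids), making the integrated Morlet band power
  directly comparable to the single-bin multitaper estimate; on clean
  in-band sinusoids the two agree within a few percent.
- Eigendecomposition sign ambiguity in the filter orientation is fixed by
  making the largest-magnitude component positive.
- Peak-coordinate ties resolve to the lowest voxel index; top-percent ties
  at the cut are all retained.

## Problem sizes in the test suite

Tests run on scaled-down problems chosen once: a 32-sensor array on a
20-mm grid (≈250 inside voxels), 40–120 trials at 480 Hz, and 500–1000
permutations where the default 10,000 would add nothing to the property
under test. The family-wise-error check uses 200 null simulations of a
4×4×4 lattice at 1,000 permutations; the exhaustive-enumeration check uses
8 trials (2⁸ sign patterns) against 10,000 Monte Carlo draws; end-to-end
recovery uses 40 subjects at the generator's default effect size and
noise. The full suite runs in about a minute on one CPU.

## Known limitations

- The spherical forward model ignores conductor anatomy; absolute source
  amplitudes and fields are not comparable to realistic head models, only
  spatial contrast structure is.
- Scalar DICS with a real-part CSD is one of several defensible
  conventions (vector DICS, magnitude CSD); the choices are configurable
  at the filter level but only the defaults are exercised by the
  acceptance checks.
- The cluster statistic is mass (sum of t); extent-based clustering is not
  implemented for the MEG path (it is, in effect, what the fMRI extent
  rule does).
- Laterality confidence intervals (bootstrap LI curves) and weighted κ are
  out of scope.
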