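# Methods

This note records the models, estimators, numerical conventions, and
design choices behind `evquant`, and what the synthetic-data generator
does and does not emulate.

## Image model and quantification pipeline

**Point-spread function.** Spots are rendered as isotropic 2-D Gaussians
parameterized by *integrated* intensity (total photon count above
background), truncated at 4σ; the truncation keeps ≥ 99.97% of the mass,
which is why conservation checks carry a 1% tolerance. The default grid is
512 × 512 px for an 80 µm field (≈ 0.156 µm/px). Detector resolution, bit
depth, and pixel pitch are not properties the assay defines, so all three
are configurable and the defaults are declared, not inferred.

**Noise.** Poisson shot noise on (background + signal) plus Gaussian read
noise (default SD 2 counts on a background of 100). The EMCCD
excess-noise factor is deliberately omitted: it rescales the variance
without changing any property the quantifier is tested on. The background
carries a gentle planar gradient (default 5 counts across the field) to
exercise the local-background machinery.

**Denoising.** Stationary (undecimated) wavelet transform, `sym4`, 3
levels, soft-thresholding all detail levels at `k·σ̂` with `σ̂` the MAD of
the finest diagonal detail and `k = 4` by default. Frames are
reflect-padded to a multiple of `2^levels` and cropped back.

**Detection.** The smooth background is a per-block median (32 px blocks)
bilinearly upsampled — a large-kernel median at a fraction of the cost,
adequate for backgrounds that vary over tens of pixels. Candidates are
4-connected components of pixels strictly above `background + k·σ̂`
(`k = 4`). When denoising is enabled, the threshold still uses the *raw*
frame's MAD noise SD: denoising suppresses the noise floor roughly
tenfold while leaving spot tails intact, so thresholding the denoised
frame at its own residual SD would grow every mask to the kernel
truncation radius and misstate spot sizes.

**Measurement.** The measurement aperture is the detected mask dilated by
3 px (`aperture_pad_px`): a super-threshold mask alone misses the
sub-threshold tails of the PSF and underestimates integrated intensity by
tens of percent, while padded pixels sitting at the background level
contribute zero net intensity, so the pad recovers the tails without
bias. The local background is a 10%-trimmed mean of an annulus beyond the
aperture (gap 1 px, width 3 px), excluding pixels within a pad of any
other candidate; a fully occluded annulus is widened once, then the spot
is dropped with a warning. Intensities are measured on the raw frame by
default (`measure_on="raw"`) because soft-thresholding shrinks summed
intensities; the mean-type background estimator makes net intensity
exactly invariant to a constant offset. Negative net intensities are kept
through measurement and removed only by the histogram cutoff — clipping
them at zero would bias blank wells upward.

**Size filter and cutoff.** Equivalent diameter is `2·sqrt(area/π)`;
bounds (6–20 px) are inclusive; out-of-range spots are tagged
`aggregate-or-noise`. The histogram cutoff is strict (`>`), with the
automatic choice being the 99.9th percentile of blank-control net
intensities. Histogram bins follow the half-open convention with the last
bin closed.

**TFI.** The well statistic divides the summed net spot intensity by the
number of *effective* images; frames with more than 1% saturated pixels
(when a saturation level is configured) are dropped and `l` reduced. A
sample's marker level is the arithmetic mean over its replicate wells.

## Calibration

Ordinary least squares on log10(TFI) vs log10(concentration) — noise in
fluorescence dilution series is multiplicative, so the log–log line is
the natural scale and weighting is unnecessary by default. Non-positive
TFIs (possible after an aggressive cutoff) are floored at a configurable
ε with a warning rather than dropped. The LOD is the inverse-predicted
concentration at blank mean + 3 SD (the conventional 3σ rule; the
multiplier is a parameter, e.g. 3.3, or 10 for an LOQ); a critical TFI
more than one decade below the fitted range raises an extrapolation
warning.

## Biomarker calls

"H" on a marker means strictly above the cutoff, so the
maximum-of-controls rule reproduces 100% specificity on its deriving
controls exactly. A sample is positive unless both markers are low (OR
rule), which guarantees dual sensitivity ≥ each single-marker sensitivity
and dual specificity ≤ each single-marker specificity at the same
cutoffs. For continuous dual/triple-marker ROC curves the default
combiner is the linear predictor of an unpenalized logistic regression on
log10 markers (CA19-9 enters on log10 scale; its clinical 37 U/mL
threshold is available as a fixed cutoff); a control-standardized max-z
score is provided as a label-free alternative. Whether a rule-based or
model-based combiner is used upstream of an ROC matters little for the
dominance properties tested, but both are exposed.

**Youden cutoffs.** Two estimators are provided. The default scans
observed values and maximizes sensitivity + specificity − 1, breaking
ties toward higher specificity; this is the common empirical rule but its
argmax converges at the cube-root rate, wandering ~0.1 SD units around
the population cutpoint even at n = 1000 per class. The `kernel` method
maximizes J over kernel-smoothed class CDFs (Gaussian kernel, Silverman
bandwidths) and localizes the population cutpoint far more precisely on
continuous data; it is the right choice when the cutoff itself, rather
than the achieved operating point, is the quantity of interest.

## Cohort statistics

Mann–Whitney U delegates to scipy with the exact (enumeration)
distribution for combined n ≤ 12 without ties and the tie-corrected
normal approximation otherwise. The ROC curve is the empirical curve over
all distinct thresholds; its trapezoidal AUC satisfies the U/(n₁n₂)
identity exactly, ties included; the standard error is Hanley–McNeil.
Correlated AUCs are compared with DeLong's structural-components z-test
(midrank formulation). Two-sample power uses the two-sided normal
approximation `Φ(|d|·√(n₁n₂/(n₁+n₂)) − z_{1−α/2}) + Φ(−… − z_{1−α/2})`.

Kaplan–Meier and the two-group log-rank test are implemented in-package
(product-limit with Greenwood variance; hypergeometric variance with
Breslow handling of tied event times) and cross-checked against lifelines
in the test suite — keeping them local makes the maximally selected scan
below cheap. Survival dichotomization maximizes the log-rank statistic
over candidate thresholds restricted to the inner 10–90% marker
quantiles, breaking ties toward the lowest threshold; the reported
p-value is *not* adjusted for the scan and the result carries a
multiplicity warning flag. Exact recovery of a latent group boundary is
not statistically identifiable at moderate hazard ratios: under a 4×
exponential rate difference each boundary subject has probability
`P(T < ln 4 / (h₂−h₁)) ≈ 0.37` of resembling the other group, so
recovery is asserted as near-complete agreement with the latent
dichotomy, not an exact split.

## Synthetic cohorts and survival

Marker levels are log10-normal per cohort with configurable inter-marker
correlation (default 0.3). Cases are elevated (default 10×, i.e. 4
control SDs) in both markers, mRNA only, or protein only, in fractions
0.5/0.25/0.25 — mirroring the quadrant structure of dual-marker-positive
disease. Survival times are exponential with log-linear hazard in the
control-standardized log markers (baseline 0.08 events/month ≈ 8.7-month
median; 0.5 log-hazard per SD per marker); censoring is uniform over a
36-month horizon with probability `censoring_rate`, plus administrative
censoring at the horizon. The imaging bridge (`simulate_imaging_sample`)
converts a target TFI into an expected spot count per frame
(target / median spot intensity), capped at 40% footprint coverage the
way a physical capture surface saturates.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optics-accurate evanescent-field excitation
and its depth-dependent intensity, camera gain and EMCCD excess noise,
spot shape anisotropy and focus drift, non-specific binding structure
beyond a constant speck rate, batch effects between wells or hospitals,
and any biological covariance between marker level and survival beyond
the log-linear hazard. Recovery and linearity results transfer to real
images only to the extent that spots are diffraction-limited, background
varies slowly, and noise is shot-plus-read.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite in minutes on one CPU: 200 frames of 512 × 512 for detection
benchmarks (12 EV-sized spots/frame, lognormal amplitudes with effective
SNR ≥ 8, no aggregates — aggregates deliberately swallow neighbours and
are benchmarked separately by the size filter), 4-image wells for
linearity at 10/30/100/300 spots per image (σ = 1.3 px with a wide 4–60
px size window so chance merges stay retained; TFI is conserved under
mask merging, only the size filter breaks linearity), 6-level dilution
series, and a 20 + 20 sample imaging cohort at 256 × 256 with 2 wells ×
2 frames per channel. Coordinates are 0-based (row, col); equivalent
diameters use the equal-area circle; all generators are deterministic
given their config and a single integer seed, with per-frame seeds
spawned from the well seed.

## Known limitations

Touching spots are not deconvolved — merged components are retained if
the merged size stays in range, otherwise discarded, which is the
dominant detection-error mode at high density. The background block
median biases slightly upward at very high spot coverage. The logistic
combiner is fit and evaluated on the same samples (as is usual for
discovery-cohort AUCs); no cross-validation is performed. Cox regression,
competing risks, and multi-gene classifiers are out of scope.
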