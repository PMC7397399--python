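# Methods

## The retention plane and folding

A GC×GC modulator reinjects first-column effluent onto the second
column every *P*<sub>M</sub> seconds (default 2.5 s), so a detector
trace is a concatenation of short second-dimension chromatograms.
Folding cuts the trace into consecutive *P*<sub>M</sub>-long columns:
column *c* covers first-dimension retention ¹t<sub>R</sub> =
c·*P*<sub>M</sub> (assigned at modulation start, no apex correction)
and row *r* covers ²t<sub>R</sub> = r/rate seconds from modulation
start, with no hold-up-time subtraction. Compounds eluting past
*P*<sub>M</sub> wrap around into the next column and are represented
as-is.

When samples-per-modulation *P*<sub>M</sub>·rate is an integer (FID:
2.5 s × 120 Hz = 300) folding is an exact reshape and
`unfold(fold(x)) == x` bit-for-bit. When it is not (MS TIC: 2.5 s ×
41.49 Hz ≈ 103.7), each modulation is linearly interpolated onto a
fixed grid of ⌈*P*<sub>M</sub>·rate⌉ rows so all columns share one
second-dimension axis. Interpolation (rather than truncation) preserves
apex positions to sub-sample accuracy and is deterministic, so folded
planes are bit-reproducible.

## Baseline correction

Two operators, both applied to the unfolded 1-D signal so each
channel's own sampling rate governs the window sizes. Both annihilate
constant offsets exactly and are idempotent once the baseline is flat
(a second application is a no-op); on a *sloped* baseline any local
minimum-based estimator leaves residuals of order slope × peak width
near peaks, because a peak blocks the estimation window from reaching
the lower baseline beside it — an inherent property, not an
implementation artifact.

**DBC (MS channel).** The baseline is a flat morphological opening —
centered moving minimum followed by a matched moving maximum, window
= `dbc_window_factor` (default 10) × the expected second-dimension peak
width × rate — smoothed by a centered moving average one peak width
wide, then subtracted. The min/max pair is deliberate: a moving minimum
alone lags a drifting baseline by half its window, which both distorts
recovered peak heights and breaks idempotence; the opening tracks
linear drift exactly. The peak-width parameter (default **0.35 s**) is
the operator's sensitive knob: too small and the baseline eats peaks,
too large and it ignores real background structure.

**TopHat (FID channel).** Subtraction of a flat grey opening with a
structuring element `tophat_factor` (default 5) × peak width × rate
samples, forced odd. Narrow peaks pass through unchanged; the slowly
rising column-bleed ramp is removed.

**Peak-width estimation.** Because volatile profiles span several
orders of magnitude in abundance, a single fixed width is a compromise.
`estimate_peak_width` formalizes the practice of averaging widths
across the dynamic range: detected candidates are stratified into
`n_peaks` (default 10) log-spaced height bins between the smallest and
largest candidate; the candidate nearest each bin's geometric-mean
height contributes its second-dimension FWHM (half-height crossings
found by linear interpolation); the estimate is the arithmetic mean.
FWHM was chosen as the width measure because it is insensitive to the
integration floor.

## Peak detection and integration

Detection operates on a Gaussian-smoothed copy (σ = 1 modulation along
the first dimension, a quarter peak width along the second); local
maxima above `snr_min` (default 10) × noise seed flood fills on the
*unsmoothed* plane down to max(5% of apex, the SNR floor). Noise is
estimated robustly as 1.4826 × the median absolute deviation from the
plane-wide median, computed over the below-median half of the cells —
the half least contaminated by peaks; measuring deviations from the
plane median (not the subset's own median) keeps the estimator unbiased
for Gaussian noise. Maxima whose footprints touch are merged keeping
the tallest cell (ties break toward earlier first-, then
second-dimension retention), so footprints of distinct peaks are
disjoint and results are reproducible to the bit. Volumes are footprint
cell sums × dwell time (1/rate), negative cells clipped.

A 5%-of-apex boundary captures exactly 95% of a 2-D Gaussian's mass in
the continuum; discretization moves the captured fraction a few tenths
of a percent either way depending on how σ₁ aligns with the modulation
grid. Co-eluting peak deconvolution and rejoining of wraparound peaks
split across the column edge are out of scope: the workflow targets
well-modulated peaks.

## Stencils

A stencil region is an axis-aligned retention-window rectangle with a
stable id, an editable compound name (default `Unknown_<id>`), the
apex-scan mass spectrum (max-normalized, restricted to the configured
scan range) and the id of the sample it came from. Rectangles keep the
JSON schema simple and the inclusion test trivial; freeform outlines
can be approximated by editing the JSON. The apex scan is used rather
than a footprint average because baseline has already been removed and
the apex maximizes analyte purity. No spectral-library search is
performed.

Autostencils pad each footprint bounding box by 1 modulation and
0.05 s. Merging a further sample matches each of its peaks against
existing regions — apex inside the region, or within (1 modulation,
0.1 s) of the region center with spectral cosine ≥ 0.8 on the union of
integer m/z when both spectra exist — and appends regions only for
unmatched peaks, so duplicate markers are filtered and region count
converges to the compound union across samples. Merging is idempotent
and never removes or shrinks existing regions.

## Cross-channel registration

The qMS runs under vacuum and the FID at atmospheric pressure, so the
FID pattern is slightly offset in both retention dimensions. The offset
is well modeled as rigid: `estimate_shift` resamples the MS plane onto
the FID second-dimension grid, rank-transforms both planes (robust to
the ~4.5:1 intensity split and dynamic-range differences), and
exhaustively scores integer shifts within ±5 modulations and ±0.25 s by
normalized cross-correlation of the overlap, preferring the smallest
shift on ties. For same-grid planes the planted shift is recovered
exactly; across channels the second-dimension estimate is limited by
the coarser MS grid (1/41.5 s ≈ 24 ms). An optional per-region snap
re-centers a region on the tallest cell of its tolerance-expanded
window for residual peak-shape differences.

## Quantification, batch tables, pretreatment, PCA

For each region the tallest cell inside the rectangle is the candidate
apex; below the SNR floor the region's volume is recorded as **0**
(zero-filling — a deliberate statement that nothing was detected, not a
missing value), otherwise the apex seeds a flood fill clipped to the
region and the footprint is integrated as in detection. Reports align
into a samples × regions table in stencil order; a transposed view is
available for spreadsheet-style workflows.

Pretreatment order is **row unit-vector normalization first, then
column autoscaling** (mean center, divide by sample SD, ddof = 1).
The order matters and is fixed deliberately: column statistics are only
meaningful after per-sample intensity differences have been normalized
out. Zero-variance columns are centered and left unscaled with a
warning. PCA is a singular value decomposition of the pretreated
matrix — scores = U·S, loadings = V — with the sign convention that
each loading column's largest-magnitude element is positive, making
results invariant (up to row permutation of scores) to sample order.
PCA here is a visualization of the processed batch, not an inference
procedure.

## The synthetic generator

Peaks are pure 2-D Gaussians in (modulation, ²t) coordinates, so every
planted peak has the exact analytic volume 2π·A·σ₁·σ₂ (σ₁ in
modulations, σ₂ in seconds — a rate-independent quantity matching the
cell-sum × dwell-time integrator). Defaults mirror the acquisition
configuration: 2.5 s modulation, 41.5 scans/s MS over m/z 40–300,
120 Hz FID, FID amplitudes 4.5× the MS TIC amplitudes (the effluent
split), a small inter-channel shift (1 modulation, 0.05 s), σ₁ = 1
modulation and σ₂ = 0.15 s (FWHM ≈ 0.35 s, the default baseline
width). The MS channel gets per-line Poisson counting noise plus a
Poisson background line per scan (mean 5 counts); the FID channel gets
linear drift (100 counts full scale), an exponential bleed ramp
(50 counts) and Gaussian noise (σ = 2 counts). Batch designs plant
shared plus class-specific compounds on a coarse slot grid spaced so
that 5%-of-apex footprints stay disjoint across a 100× amplitude range
(8 modulations × 1.0 s); replicate amplitudes are jittered log-normally
(sd 0.1). Everything derives from one seed, bit-for-bit.

Synthetic runs default to a 6-minute extent — long enough for ~30
well-separated compounds — so the full suite and the acceptance script
complete in seconds while exercising every stage at the real sampling
rates. What the generator does **not** emulate: peak tailing and
asymmetry (an optional concern the Gaussian model sidesteps to keep
volumes analytic), retention-time drift between samples, co-elution,
spectral overlap between compounds, and detector saturation. Passing
tests therefore demonstrate correctness of the processing chain under
its stated model, not robustness to every pathology of real
chromatograms; the stencil-merge tolerances and the per-region snap
exist precisely for the retention variability the generator leaves
out.

## Numerical and design notes

- Intensities are 64-bit floats throughout; times inside files are
  seconds, minutes appear only in report columns.
- Readers reject malformed files rather than repairing them; all
  writer/reader pairs round-trip exactly. netCDF output is NetCDF-3
  classic, the ANDI/AIA interchange dialect.
- All tie-breaks (merged maxima, shift ties, bin selection) are fully
  specified so outputs are byte-identical across reruns; the pipeline
  log contains no timestamps for the same reason.
- The second-dimension flow split (~4.5:1) and its derivation are
  stored as metadata only; flow calculations are out of scope.
- Stencil-building samples default to the whole manifest; for large
  batches a subset (e.g. one replicate per class) can be configured and
  is recorded in the log, since the sampling plan affects which
  compounds the stencil can contain.
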