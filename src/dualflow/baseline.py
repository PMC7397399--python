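"""Baseline correction for the two detection channels.

Two operators, both acting on the unfolded 1-D signal so each channel's
own sampling rate is respected:

* **Dynamic baseline correction (DBC)** for the MS total-ion-current
  trace. The baseline is a flat morphological opening (centered moving
  minimum, then a matched moving maximum) whose window is a multiple of
  the expected second-dimension peak width, smoothed by a centered
  moving average one peak width wide, and subtracted. The peak width is
  the operator's key parameter: windows much wider than a peak track
  the drifting background without eating into peaks.
* **TopHat** for the FID trace: subtraction of a flat morphological
  opening (erosion then dilation). The structuring element is several
  peak widths wide so genuine peaks survive while the slowly varying
  bleed ramp is removed.

Both default to a 0.35 s second-dimension peak width — a compromise
value across the dynamic range of typical runs — and
:func:`estimate_peak_width` re-derives it per dataset by averaging the
full width at half maximum of peaks sampled across the plane's dynamic
range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dualflow.chrom_io import RawTrace
from dualflow.errors import ParameterError, ProcessingError
from dualflow.folding import Chromatogram2D

__all__ = ["BaselineParams", "dbc", "tophat", "estimate_peak_width"]


@dataclass(frozen=True)
class BaselineParams:
    """Parameters shared by both baseline operators.

    peak_width_2d : expected second-dimension peak width, seconds.
    dbc_window_factor : moving-minimum window, in peak widths.
    tophat_factor : structuring-element width, in peak widths.
    """

    peak_width_2d: float = 0.35
    dbc_window_factor: float = 10.0
    tophat_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.peak_width_2d <= 0:
            raise ParameterError("peak_width_2d must be > 0")
        if self.dbc_window_factor < 1 or self.tophat_factor < 1:
            raise ParameterError("window factors must be >= 1")


def dbc(trace: RawTrace, params: BaselineParams = BaselineParams()) -> RawTrace:
    """Dynamic baseline correction of a 1-D trace.

    baseline = centered moving minimum followed by a matched moving
    maximum (a flat morphological opening, window ``dbc_window_factor ×
    peak_width``), smoothed by a moving average one peak width wide; the
    corrected trace is the input minus this baseline. The min/max pair —
    rather than the minimum alone — makes the baseline track drifting
    background without the half-window lag, so the operator is
    idempotent and recovers apex heights on sloped baselines. Edges use
    nearest-value padding; the output length equals the input length.
    """
    rate = trace.sampling_rate
    w_min = round(params.dbc_window_factor * params.peak_width_2d * rate)
    if w_min < 3:
        raise ParameterError(
            f"DBC moving-minimum window {w_min} samples is < 3; "
            "increase peak_width_2d or dbc_window_factor"
        )
    w_avg = max(round(params.peak_width_2d * rate), 1)
    baseline = ndimage.minimum_filter1d(trace.intensities, size=w_min, mode="nearest")
    baseline = ndimage.maximum_filter1d(baseline, size=w_min, mode="nearest")
    baseline = ndimage.uniform_filter1d(baseline, size=w_avg, mode="nearest")
    return RawTrace(
        channel=trace.channel,
        sampling_rate=rate,
        start_time=trace.start_time,
        intensities=trace.intensities - baseline,
    )


def tophat(trace: RawTrace, params: BaselineParams = BaselineParams()) -> RawTrace:
    """TopHat baseline correction: subtract a flat morphological opening.

    The structuring element is ``tophat_factor × peak_width`` samples,
    rounded and forced odd so the operator is centered.
    """
    rate = trace.sampling_rate
    size = round(params.tophat_factor * params.peak_width_2d * rate)
    if size < 3:
        raise ParameterError(
            f"TopHat structuring element {size} samples is < 3; "
            "increase peak_width_2d or tophat_factor"
        )
    if size % 2 == 0:
        size += 1
    opened = ndimage.grey_opening(trace.intensities, size=size, mode="nearest")
    return RawTrace(
        channel=trace.channel,
        sampling_rate=rate,
        start_time=trace.start_time,
        intensities=trace.intensities - opened,
    )


def _fwhm_2d(plane: Chromatogram2D, row: int, col: int) -> float:
    """Full width at half maximum (seconds) along the second dimension
    through a peak apex."""
    from dualflow.peakdetect import fwhm_profile

    return fwhm_profile(plane.values[:, col], row) / plane.rate


def estimate_peak_width(plane: Chromatogram2D, n_peaks: int = 10,
                        snr_min: float = 10.0) -> float:
    """Average second-dimension FWHM of ``n_peaks`` peaks spanning the
    plane's dynamic range.

    Candidate peaks (SNR >= ``snr_min``) are stratified into ``n_peaks``
    log-spaced height bins between the smallest and largest candidate
    height; from each bin the candidate nearest the bin's geometric-mean
    height is taken (ties broken toward earlier first-dimension
    retention), its FWHM measured along the second dimension, and the
    arithmetic mean of the widths returned, in seconds.
    """
    from dualflow.peakdetect import DetectParams, detect_peaks

    if n_peaks < 1:
        raise ParameterError("n_peaks must be >= 1")
    peaks = detect_peaks(plane, DetectParams(snr_min=snr_min))
    if len(peaks) < n_peaks:
        raise ProcessingError(
            f"only {len(peaks)} candidate peaks detected; "
            f"try n_peaks <= {len(peaks)}"
        )
    heights = np.array([p.height for p in peaks])
    lo, hi = heights.min(), heights.max()
    if lo <= 0:
        lo = np.min(heights[heights > 0])
    edges = np.logspace(np.log10(lo), np.log10(hi), n_peaks + 1)
    widths = []
    for b in range(n_peaks):
        gm = np.sqrt(edges[b] * edges[b + 1])
        dist = np.abs(np.log(heights) - np.log(gm))
        order = sorted(
            range(len(peaks)),
            key=lambda k: (dist[k], peaks[k].apex_col, peaks[k].apex_row),
        )
        chosen = peaks[order[0]]
        widths.append(_fwhm_2d(plane, chosen.apex_row, chosen.apex_col))
    return float(np.mean(widths))
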