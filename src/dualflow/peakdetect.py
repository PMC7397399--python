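"""2-D peak detection and delineation on baseline-corrected planes.

Detection runs on a lightly smoothed copy of the plane (Gaussian, one
modulation along the first dimension, a quarter peak width along the
second); local maxima above an SNR threshold seed flood fills on the
*unsmoothed* plane down to a floor of ``boundary_fraction`` of the apex
(or the noise threshold, whichever is higher). Maxima whose footprints
touch are merged, keeping the tallest, so footprints of distinct peaks
are disjoint and results are bit-reproducible. Overlap splitting and
wraparound rejoining are deliberately out of scope: the workflow targets
well-modulated peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dualflow.errors import ParameterError
from dualflow.folding import Chromatogram2D, index_to_retention

__all__ = [
    "Peak2D",
    "DetectParams",
    "estimate_noise",
    "detect_peaks",
    "integrate_volume",
    "fwhm_profile",
]

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


@dataclass
class Peak2D:
    """A detected 2-D peak with its apex, size metrics and footprint."""

    apex_1tR: float  # minutes, modulation start
    apex_2tR: float  # seconds from modulation start
    apex_row: int
    apex_col: int
    height: float  # counts at apex
    volume: float  # counts·s (cell sum × dwell time)
    fwhm_1d: float  # modulations
    fwhm_2d: float  # seconds
    footprint: frozenset = field(repr=False)  # of (row, col)


@dataclass(frozen=True)
class DetectParams:
    """Detection thresholds; defaults suit clean, well-modulated data."""

    snr_min: float = 10.0
    min_volume: float = 0.0
    smooth_sigma_2d: float = 0.0875  # seconds; a quarter of the 0.35 s default width
    boundary_fraction: float = 0.05  # of apex height

    def __post_init__(self) -> None:
        if self.snr_min <= 0:
            raise ParameterError("snr_min must be > 0")
        if not 0 < self.boundary_fraction < 1:
            raise ParameterError("boundary_fraction must be in (0, 1)")


def estimate_noise(plane: Chromatogram2D) -> float:
    """Robust noise level: scaled MAD of the plane's below-median cells.

    Deviations are measured from the plane-wide median over the cells
    below it (the half of the plane least contaminated by peaks); the
    1.4826 factor makes the estimate consistent with the standard
    deviation of Gaussian noise.
    """
    med = float(np.median(plane.values))
    below = plane.values[plane.values < med]
    if below.size == 0:
        return 0.0
    return 1.4826 * float(np.median(med - below))


def fwhm_profile(profile: np.ndarray, apex: int) -> float:
    """Full width at half maximum around ``apex``, in samples, with
    linear interpolation at the half-height crossings; truncated at the
    profile edges."""
    half = profile[apex] / 2.0
    i = apex
    while i > 0 and profile[i - 1] > half:
        i -= 1
    if i == 0:
        lo = 0.0
    else:
        y1, y0 = profile[i], profile[i - 1]
        lo = (i - 1) + (half - y0) / (y1 - y0)
    i = apex
    n = profile.size
    while i < n - 1 and profile[i + 1] > half:
        i += 1
    if i == n - 1:
        hi = float(n - 1)
    else:
        y0, y1 = profile[i], profile[i + 1]
        hi = i + (y0 - half) / (y0 - y1)
    return hi - lo


def _flood_footprint(values: np.ndarray, seed: tuple[int, int], floor: float) -> frozenset:
    """4-connected component of ``values >= floor`` containing ``seed``."""
    mask = values >= floor
    labels, _ = ndimage.label(mask, structure=_FOUR_CONN)
    lab = labels[seed]
    if lab == 0:  # seed itself below floor (degenerate): footprint is the seed
        return frozenset([seed])
    rows, cols = np.nonzero(labels == lab)
    return frozenset(zip(rows.tolist(), cols.tolist()))


def detect_peaks(plane: Chromatogram2D, params: DetectParams = DetectParams()) -> list[Peak2D]:
    """Detect peaks on a baseline-corrected plane.

    Returns peaks sorted by (apex column, apex row); an empty list is a
    valid result.
    """
    values = plane.values
    noise = estimate_noise(plane)
    thr = params.snr_min * noise
    sigma_rows = params.smooth_sigma_2d * plane.rate
    smoothed = ndimage.gaussian_filter(values, sigma=(sigma_rows, 1.0), mode="nearest")
    is_max = smoothed == ndimage.maximum_filter(smoothed, size=3, mode="nearest")
    candidates = is_max & (smoothed > thr) & (smoothed > 0)
    seeds = list(zip(*np.nonzero(candidates)))
    if not seeds:
        return []

    footprints = []
    for seed in seeds:
        apex_val = values[seed]
        floor = max(params.boundary_fraction * apex_val, thr)
        footprints.append(_flood_footprint(values, seed, floor))

    # merge maxima whose footprints overlap (union-find over seeds)
    parent = list(range(len(seeds)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    owner: dict[tuple[int, int], int] = {}
    for k, fp in enumerate(footprints):
        for cell in fp:
            if cell in owner:
                ra, rb = find(owner[cell]), find(k)
                if ra != rb:
                    parent[rb] = ra
            else:
                owner[cell] = k

    groups: dict[int, list[int]] = {}
    for k in range(len(seeds)):
        groups.setdefault(find(k), []).append(k)

    peaks: list[Peak2D] = []
    for members in groups.values():
        # merged maxima keep the tallest cell; ties → smaller col, then row
        fp = frozenset().union(*(footprints[k] for k in members))
        fp_idx = (np.array([c[0] for c in fp]), np.array([c[1] for c in fp]))
        in_fp = values[fp_idx]
        order = np.lexsort((fp_idx[0], fp_idx[1], -in_fp))
        apex_row = int(fp_idx[0][order[0]])
        apex_col = int(fp_idx[1][order[0]])
        height = float(values[apex_row, apex_col])
        volume = float(np.clip(in_fp, 0.0, None).sum()) / plane.rate
        if volume < params.min_volume or volume <= 0:
            continue
        t1, t2 = index_to_retention(plane, apex_row, apex_col)
        peaks.append(
            Peak2D(
                apex_1tR=t1,
                apex_2tR=t2,
                apex_row=apex_row,
                apex_col=apex_col,
                height=height,
                volume=volume,
                fwhm_1d=fwhm_profile(values[apex_row, :], apex_col),
                fwhm_2d=fwhm_profile(values[:, apex_col], apex_row) / plane.rate,
                footprint=fp,
            )
        )
    peaks.sort(key=lambda p: (p.apex_col, p.apex_row))
    return peaks


def integrate_volume(plane: Chromatogram2D, footprint) -> float:
    """Sum of the plane over a footprint × dwell time (1/rate), in
    counts·s; negative cells are clipped to zero."""
    cells = list(footprint)
    if not cells:
        raise ParameterError("footprint must contain at least one cell")
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= plane.n_rows or cols.max() >= plane.n_cols):
        raise ParameterError("footprint cell out of plane range")
    return float(np.clip(plane.values[rows, cols], 0.0, None).sum()) / plane.rate
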