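"""Registration of the MS-derived stencil onto the FID plane.

The two detection channels see the same separation through different
plumbing: the quadrupole runs under vacuum, the FID at atmospheric
pressure, so the FID pattern is slightly shifted in both retention
dimensions relative to the MS pattern. The shift is rigid to a good
approximation, so a single plane-wide translation — estimated by
exhaustive normalized cross-correlation on rank-transformed planes —
aligns the stencil, with an optional per-region snap to the local
intensity maximum for residual width/quality differences. The rank
transform makes the correlation robust to the channels' very different
intensity scales (the effluent split is roughly 4.5:1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from dualflow.errors import ProcessingError
from dualflow.folding import Chromatogram2D
from dualflow.stencil import Stencil, StencilRegion

__all__ = ["ShiftTransform", "resample_to_grid", "estimate_shift",
           "apply_shift", "local_snap"]


@dataclass(frozen=True)
class ShiftTransform:
    """A rigid retention-plane translation MS → FID."""

    d1t: float  # minutes (signed)
    d2t: float  # seconds (signed)
    score: float  # correlation at the optimum, in [-1, 1]

    def inverse(self) -> "ShiftTransform":
        return ShiftTransform(d1t=-self.d1t, d2t=-self.d2t, score=self.score)


def resample_to_grid(plane_ms: Chromatogram2D, target_rate: float) -> Chromatogram2D:
    """Linearly interpolate each column onto a second-dimension grid at
    ``target_rate``; the column count is unchanged."""
    if target_rate <= 0:
        raise ProcessingError("target_rate must be > 0")
    n_rows = int(round(plane_ms.pm * target_rate))
    src_t = np.arange(plane_ms.n_rows) / plane_ms.rate
    dst_t = np.arange(n_rows) / (n_rows / plane_ms.pm)
    out = np.empty((n_rows, plane_ms.n_cols))
    for j in range(plane_ms.n_cols):
        out[:, j] = np.interp(dst_t, src_t, plane_ms.values[:, j])
    return Chromatogram2D(
        values=out, pm=plane_ms.pm, rate=n_rows / plane_ms.pm,
        channel=plane_ms.channel, sample_id=plane_ms.sample_id,
    )


def _rank(plane: np.ndarray) -> np.ndarray:
    r = rankdata(plane, method="average").reshape(plane.shape)
    return r - r.mean()


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_shift(plane_ms: Chromatogram2D, plane_fid: Chromatogram2D,
                   max_d1t: int = 5, max_d2t: float = 0.25) -> ShiftTransform:
    """Estimate the rigid shift taking the MS plane onto the FID plane.

    Exhaustive search over integer (column, row) shifts within
    ``±max_d1t`` modulations and ``±max_d2t`` seconds, scoring each by
    normalized cross-correlation of the rank-transformed overlapping
    sub-planes; ties prefer the smallest shift magnitude, then the
    smaller first-dimension shift.
    """
    if plane_ms.n_rows != plane_fid.n_rows:
        plane_ms = resample_to_grid(plane_ms, plane_fid.rate)
    a = plane_ms.values
    b = plane_fid.values
    if float(a.max() - a.min()) == 0 or float(b.max() - b.min()) == 0:
        raise ProcessingError("cannot register a constant plane")
    ra, rb = _rank(a), _rank(b)
    max_drow = int(round(max_d2t * plane_fid.rate))
    n_rows = min(ra.shape[0], rb.shape[0])
    n_cols = min(ra.shape[1], rb.shape[1])
    best = None
    for dcol in range(-max_d1t, max_d1t + 1):
        for drow in range(-max_drow, max_drow + 1):
            # overlap of a shifted by (drow, dcol) with b
            a_r0, b_r0 = max(0, -drow), max(0, drow)
            a_c0, b_c0 = max(0, -dcol), max(0, dcol)
            h = n_rows - abs(drow)
            w = n_cols - abs(dcol)
            if h < 2 or w < 2:
                continue
            score = _ncc(ra[a_r0:a_r0 + h, a_c0:a_c0 + w],
                         rb[b_r0:b_r0 + h, b_c0:b_c0 + w])
            key = (-score, drow * drow + dcol * dcol, abs(dcol), abs(drow))
            if best is None or key < best[0]:
                best = (key, dcol, drow, score)
    assert best is not None
    _, dcol, drow, score = best
    at_edge = abs(dcol) == max_d1t or abs(drow) == max_drow
    if at_edge and (abs(dcol) > 0 or abs(drow) > 0):
        warnings.warn(
            "best shift lies on the search boundary; the true shift may be "
            "outside the configured bounds", stacklevel=2,
        )
    return ShiftTransform(
        d1t=dcol * plane_fid.pm / 60.0,
        d2t=drow / plane_fid.rate,
        score=score,
    )


def apply_shift(stencil: Stencil, t: ShiftTransform,
                plane: Chromatogram2D | None = None) -> Stencil:
    """Translate every region by (d1t, d2t), preserving ids, names and
    spectra.

    When ``plane`` is given, regions are clipped to its extent; a region
    losing more than half its area triggers a warning and a region
    falling entirely outside the plane is an error.
    """
    out = []
    for r in stencil.regions:
        moved = replace(r, t1_lo=r.t1_lo + t.d1t, t1_hi=r.t1_hi + t.d1t,
                        t2_lo=r.t2_lo + t.d2t, t2_hi=r.t2_hi + t.d2t)
        if plane is not None:
            t1_max = (plane.n_cols - 1) * plane.pm / 60.0
            t2_max = (plane.n_rows - 1) / plane.rate
            lo1, hi1 = max(moved.t1_lo, 0.0), min(moved.t1_hi, t1_max)
            lo2, hi2 = max(moved.t2_lo, 0.0), min(moved.t2_hi, t2_max)
            if lo1 >= hi1 or lo2 >= hi2:
                raise ProcessingError(
                    f"region {r.id} falls entirely outside the plane after shifting"
                )
            area0 = (moved.t1_hi - moved.t1_lo) * (moved.t2_hi - moved.t2_lo)
            area1 = (hi1 - lo1) * (hi2 - lo2)
            if area1 < 0.5 * area0:
                warnings.warn(f"region {r.id} clipped by more than 50% of its area",
                              stacklevel=2)
            moved = replace(moved, t1_lo=lo1, t1_hi=hi1, t2_lo=lo2, t2_hi=hi2)
        out.append(moved)
    return Stencil(regions=out, source_channel=stencil.source_channel)


def local_snap(region: StencilRegion, plane_fid: Chromatogram2D,
               tol_1t: float = 1.0, tol_2t: float = 0.1) -> StencilRegion:
    """Re-center a region on the tallest cell of its tolerance-expanded
    window when that cell lies outside the region; size is preserved."""
    pm, rate = plane_fid.pm, plane_fid.rate
    tol1_min = tol_1t * pm / 60.0
    c0 = max(int(np.floor((region.t1_lo - tol1_min) * 60.0 / pm)), 0)
    c1 = min(int(np.ceil((region.t1_hi + tol1_min) * 60.0 / pm)), plane_fid.n_cols - 1)
    r0 = max(int(np.floor((region.t2_lo - tol_2t) * rate)), 0)
    r1 = min(int(np.ceil((region.t2_hi + tol_2t) * rate)), plane_fid.n_rows - 1)
    if c0 > c1 or r0 > r1:
        raise ProcessingError(f"region {region.id} does not overlap the plane")
    window = plane_fid.values[r0:r1 + 1, c0:c1 + 1]
    if float(window.max()) <= 0:
        return region
    flat = int(np.argmax(window))
    row = r0 + flat // window.shape[1]
    col = c0 + flat % window.shape[1]
    t1, t2 = col * pm / 60.0, row / rate
    if region.contains(t1, t2):
        return region
    h1 = (region.t1_hi - region.t1_lo) / 2.0
    h2 = (region.t2_hi - region.t2_lo) / 2.0
    return replace(region, t1_lo=t1 - h1, t1_hi=t1 + h1,
                   t2_lo=t2 - h2, t2_hi=t2 + h2)
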