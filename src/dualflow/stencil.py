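"""Stencil regions: the unit of cross-sample and cross-channel identity.

A stencil is an ordered set of named rectangular regions in the
(1tR, 2tR) retention plane, each optionally carrying the mass spectrum
of the peak it was built from. Regions are generated automatically from
peaks detected on the MS plane (*autostencils*), enriched incrementally
by merging further samples — adding regions only for compounds not
already covered, so duplicate peak markers are filtered out — and
finally transferred onto FID data, where they locate and (tentatively)
identify compounds that carry no spectra of their own.

Regions are axis-aligned rectangles: the inclusion test is trivial and
the JSON file can be refined by hand. No spectral-library search is
performed; names default to ``Unknown_<id>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dualflow.chrom_io import ScanStream
from dualflow.errors import ProcessingError
from dualflow.folding import Chromatogram2D, index_to_retention
from dualflow.peakdetect import Peak2D

__all__ = [
    "StencilRegion",
    "Stencil",
    "region_spectrum",
    "autostencil",
    "spectral_cosine",
    "merge_stencil",
]

Spectrum = list[tuple[float, float]]  # (m/z, relative intensity), max-normalized


@dataclass
class StencilRegion:
    """A named rectangular retention-plane region."""

    id: str
    t1_lo: float  # minutes
    t1_hi: float
    t2_lo: float  # seconds
    t2_hi: float
    name: str = ""
    spectrum: Spectrum | None = None
    origin_sample: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"Unknown_{self.id}"
        if not (self.t1_lo < self.t1_hi and self.t2_lo < self.t2_hi):
            raise ValueError(f"region {self.id}: empty retention window")
        if self.spectrum is not None:
            ints = [i for _, i in self.spectrum]
            if any(i <= 0 or i > 1 + 1e-12 for i in ints):
                raise ValueError(
                    f"region {self.id}: spectrum intensities must be in (0, 1]"
                )

    def contains(self, t1: float, t2: float) -> bool:
        return self.t1_lo <= t1 <= self.t1_hi and self.t2_lo <= t2 <= self.t2_hi

    @property
    def center(self) -> tuple[float, float]:
        return (self.t1_lo + self.t1_hi) / 2.0, (self.t2_lo + self.t2_hi) / 2.0


@dataclass
class Stencil:
    """Ordered collection of regions from one source channel."""

    regions: list[StencilRegion] = field(default_factory=list)
    source_channel: str = "MS"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("stencil region ids must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def ids(self) -> list[str]:
        return [r.id for r in self.regions]


def region_spectrum(scans: ScanStream, peak: Peak2D, plane: Chromatogram2D,
                    mz_range: tuple[int, int] | None = None) -> Spectrum:
    """Spectrum of the scan nearest the peak apex, max-normalized to 1.

    The apex retention is converted back to absolute run time
    (modulation start + second-dimension offset, plus the stream's own
    start time) and the nearest scan's spectrum taken as-is: baseline
    correction has already been applied upstream and the apex scan
    maximizes analyte purity.
    """
    apex_time = scans.scan_times[0] + peak.apex_1tR * 60.0 + peak.apex_2tR
    if not (scans.scan_times[0] - 1e-9 <= apex_time <= scans.scan_times[-1] + 1e-9):
        raise ProcessingError(
            f"apex time {apex_time:.2f} s outside scan-time range "
            f"[{scans.scan_times[0]:.2f}, {scans.scan_times[-1]:.2f}]"
        )
    k = int(np.argmin(np.abs(scans.scan_times - apex_time)))
    mz, inten = scans.mz[k], scans.intensities[k]
    if mz_range is not None:
        keep = (mz >= mz_range[0]) & (mz <= mz_range[1])
        mz, inten = mz[keep], inten[keep]
    if mz.size == 0 or float(inten.max()) <= 0:
        raise ProcessingError(f"scan {k} at apex has an empty spectrum")
    rel = inten / float(inten.max())
    keep = rel > 0
    return [(float(m), float(i)) for m, i in zip(mz[keep], rel[keep])]


def _region_from_peak(peak: Peak2D, plane: Chromatogram2D, region_id: str,
                      pad_1t: float, pad_2t: float,
                      spectrum: Spectrum | None, origin: str) -> StencilRegion:
    rows = [c[0] for c in peak.footprint]
    cols = [c[1] for c in peak.footprint]
    t1_lo, t2_lo = index_to_retention(plane, min(rows), min(cols))
    t1_hi, t2_hi = index_to_retention(plane, max(rows), max(cols))
    pad1 = pad_1t * plane.pm / 60.0  # modulations → minutes
    t1_max, t2_max = index_to_retention(plane, plane.n_rows - 1, plane.n_cols - 1)
    return StencilRegion(
        id=region_id,
        t1_lo=max(t1_lo - pad1, 0.0),
        t1_hi=min(t1_hi + pad1, t1_max),
        t2_lo=max(t2_lo - pad_2t, 0.0),
        t2_hi=min(t2_hi + pad_2t, t2_max),
        spectrum=spectrum,
        origin_sample=origin,
    )


def autostencil(peaks: list[Peak2D], scans: ScanStream, plane: Chromatogram2D,
                pad_1t: float = 1.0, pad_2t: float = 0.05,
                mz_range: tuple[int, int] | None = None,
                sample_id: str = "") -> Stencil:
    """Build a stencil with one region per detected MS peak.

    Each region is the peak footprint's bounding box padded by
    ``pad_1t`` modulations and ``pad_2t`` seconds, clipped to the plane
    extent; the apex-scan spectrum is attached. Ids run ``R0001``… in
    detection order.
    """
    origin = sample_id or (plane.sample_id if plane is not None else "")
    regions = []
    for k, peak in enumerate(peaks, start=1):
        spectrum = region_spectrum(scans, peak, plane, mz_range=mz_range)
        regions.append(
            _region_from_peak(peak, plane, f"R{k:04d}", pad_1t, pad_2t,
                              spectrum, origin)
        )
    channel = plane.channel if plane is not None and plane.channel else "MS"
    return Stencil(regions=regions, source_channel=channel)


def spectral_cosine(a: Spectrum, b: Spectrum) -> float:
    """Cosine similarity of two spectra on the union of integer m/z."""
    if not a or not b:
        raise ProcessingError("cannot compare an empty spectrum")
    va: dict[int, float] = {}
    vb: dict[int, float] = {}
    for m, i in a:
        va[round(m)] = va.get(round(m), 0.0) + i
    for m, i in b:
        vb[round(m)] = vb.get(round(m), 0.0) + i
    keys = sorted(set(va) | set(vb))
    xa = np.array([va.get(k, 0.0) for k in keys])
    xb = np.array([vb.get(k, 0.0) for k in keys])
    denom = float(np.linalg.norm(xa) * np.linalg.norm(xb))
    if denom == 0:
        return 0.0
    return float(np.dot(xa, xb) / denom)


def merge_stencil(base: Stencil, peaks: list[Peak2D], scans: ScanStream,
                  plane: Chromatogram2D, rt_tol_1t: float = 1.0,
                  rt_tol_2t: float = 0.1, cos_min: float = 0.8,
                  pad_1t: float = 1.0, pad_2t: float = 0.05,
                  mz_range: tuple[int, int] | None = None,
                  sample_id: str = "") -> Stencil:
    """Merge a sample's peaks into an existing stencil.

    A peak matches an existing region if its apex lies inside the
    region, or lies within (``rt_tol_1t`` modulations, ``rt_tol_2t``
    seconds) of the region center and — when both spectra exist — the
    spectral cosine is at least ``cos_min``. Matched peaks add nothing
    (duplicate-marker filtering); unmatched peaks append fresh regions.
    Base regions are never removed or shrunk.
    """
    if base.source_channel and plane.channel and base.source_channel != plane.channel:
        raise ProcessingError(
            f"channel mismatch: stencil from {base.source_channel!r}, "
            f"plane from {plane.channel!r}"
        )
    tol1_min = rt_tol_1t * plane.pm / 60.0
    origin = sample_id or plane.sample_id
    next_idx = len(base.regions) + 1
    new_regions = list(base.regions)
    existing_ids = set(base.ids())
    for peak in peaks:
        spectrum = region_spectrum(scans, peak, plane, mz_range=mz_range)
        matched = False
        for region in new_regions:
            if region.contains(peak.apex_1tR, peak.apex_2tR):
                matched = True
                break
            c1, c2 = region.center
            near = (abs(peak.apex_1tR - c1) <= tol1_min
                    and abs(peak.apex_2tR - c2) <= rt_tol_2t)
            if near:
                if region.spectrum is not None and spectrum:
                    if spectral_cosine(region.spectrum, spectrum) >= cos_min:
                        matched = True
                        break
                else:
                    matched = True
                    break
        if not matched:
            while f"R{next_idx:04d}" in existing_ids:
                next_idx += 1
            rid = f"R{next_idx:04d}"
            next_idx += 1
            existing_ids.add(rid)
            new_regions.append(
                _region_from_peak(peak, plane, rid, pad_1t, pad_2t,
                                  spectrum, origin)
            )
    return Stencil(regions=new_regions, source_channel=base.source_channel)
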