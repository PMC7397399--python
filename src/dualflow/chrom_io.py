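"""File I/O for the chromatographic interchange formats.

Two ANDI/AIA netCDF dialects are supported, both NetCDF-3 classic:

* chromatography (single-channel FID): an ``ordinate_values`` vector plus
  either a stored sampling interval or an abscissa vector;
* mass spectrometry: a scan index into flattened ``mass_values`` /
  ``intensity_values`` arrays plus per-scan acquisition times.

Only the minimal common variable sets are read; vendor extensions are
ignored. Intensities are promoted to 64-bit floats regardless of the
stored type, and all times inside files are seconds. Readers reject
malformed input rather than silently repairing it; every writer/reader
pair is an exact round-trip on valid objects.

The module also owns the artifact's own formats: stencil JSON, sample
report CSV, and the folded-plane netCDF grid container.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import netcdf_file

from dualflow.errors import FormatError

__all__ = [
    "RawTrace",
    "ScanStream",
    "SampleReport",
    "read_fid_cdf",
    "write_fid_cdf",
    "read_ms_cdf",
    "write_ms_cdf",
    "read_report_csv",
    "write_report_csv",
    "read_stencil",
    "write_stencil",
    "read_plane_cdf",
    "write_plane_cdf",
]


@dataclass
class RawTrace:
    """A single-channel detector trace sampled at a fixed rate."""

    channel: str
    sampling_rate: float  # Hz
    start_time: float  # seconds
    intensities: np.ndarray  # detector counts

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.intensities.ndim != 1 or self.intensities.size < 1:
            raise ValueError("intensities must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from ``start_time``."""
        return self.start_time + np.arange(self.intensities.size) / self.sampling_rate


@dataclass
class ScanStream:
    """A scan-based MS acquisition: ragged per-scan spectra plus times."""

    scan_times: np.ndarray  # seconds, strictly increasing
    mz: list[np.ndarray]  # per-scan m/z, each sorted ascending
    intensities: list[np.ndarray]  # per-scan intensities, same lengths as mz
    total_intensity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=np.float64)
        self.mz = [np.asarray(m, dtype=np.float64) for m in self.mz]
        self.intensities = [np.asarray(i, dtype=np.float64) for i in self.intensities]
        n = self.scan_times.size
        if len(self.mz) != n or len(self.intensities) != n:
            raise ValueError("scan_times, mz and intensities must have equal length")
        if n > 1 and not np.all(np.diff(self.scan_times) > 0):
            raise ValueError("scan_times must be strictly increasing")
        for k, (m, i) in enumerate(zip(self.mz, self.intensities)):
            if m.size != i.size:
                raise ValueError(f"scan {k}: m/z and intensity lengths differ")
            if m.size > 1 and not np.all(np.diff(m) > 0):
                raise ValueError(f"scan {k}: m/z values must be sorted ascending")
            if np.any(i < 0):
                raise ValueError(f"scan {k}: intensities must be >= 0")
        if self.total_intensity is None:
            self.total_intensity = np.array(
                [float(i.sum()) for i in self.intensities], dtype=np.float64
            )
        else:
            self.total_intensity = np.asarray(self.total_intensity, dtype=np.float64)

    @property
    def n_scans(self) -> int:
        return self.scan_times.size


#: Column order of the sample-report CSV.
REPORT_COLUMNS = ("region_id", "compound_name", "apex_1tR_min", "apex_2tR_s", "volume")


@dataclass
class SampleReport:
    """Per-sample quantification: one row per stencil region."""

    sample_id: str
    rows: list[tuple]  # (region_id, compound_name, apex_1tR_min, apex_2tR_s, volume)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("region_ids must be unique within a report")
        for r in self.rows:
            if float(r[4]) < 0:
                raise ValueError(f"volume must be >= 0 (region {r[0]})")

    def volumes(self) -> dict[str, float]:
        return {r[0]: float(r[4]) for r in self.rows}


# ---------------------------------------------------------------------------
# ANDI chromatography (FID)
# ---------------------------------------------------------------------------

def read_fid_cdf(path) -> RawTrace:
    """Read a single-channel ANDI/AIA chromatogram into a :class:`RawTrace`.

    The sampling rate comes from the file's stored sampling interval when
    present, otherwise from the median spacing of the abscissa vector;
    abscissa jitter beyond 1% of that spacing is a format error.
    """
    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:  # scipy raises bare exceptions on truncation
        raise FormatError(f"{path}: not a readable netCDF-3 file ({exc})") from exc
    with nc:
        if "ordinate_values" not in nc.variables:
            raise FormatError(f"{path}: missing variable 'ordinate_values'")
        y = np.array(nc.variables["ordinate_values"][:], dtype=np.float64)
        start = 0.0
        if "actual_delay_time" in nc.variables:
            start = float(np.asarray(nc.variables["actual_delay_time"][...]))
        if "actual_sampling_interval" in nc.variables:
            dt = float(np.asarray(nc.variables["actual_sampling_interval"][...]))
            if dt <= 0:
                raise FormatError(f"{path}: non-positive sampling interval {dt}")
        elif "raw_data_retention" in nc.variables:
            t = np.array(nc.variables["raw_data_retention"][:], dtype=np.float64)
            if t.size != y.size:
                raise FormatError(f"{path}: abscissa/ordinate length mismatch")
            spacing = np.diff(t)
            dt = float(np.median(spacing))
            if dt <= 0 or np.any(np.abs(spacing - dt) > 0.01 * dt):
                raise FormatError(f"{path}: non-uniform abscissa beyond 1% jitter")
            start = float(t[0])
        else:
            raise FormatError(
                f"{path}: no 'actual_sampling_interval' or 'raw_data_retention'"
            )
        channel = "FID"
        if hasattr(nc, "detector_name"):
            channel = bytes(nc.detector_name).decode("ascii", "replace") or "FID"
    return RawTrace(channel=channel, sampling_rate=1.0 / dt, start_time=start, intensities=y)


def write_fid_cdf(trace: RawTrace, path) -> None:
    """Write a :class:`RawTrace` as an ANDI chromatography netCDF file."""
    with netcdf_file(str(path), "w") as nc:
        nc.detector_name = trace.channel.encode("ascii", "replace")
        nc.createDimension("point_number", trace.intensities.size)
        v = nc.createVariable("ordinate_values", "d", ("point_number",))
        v[:] = trace.intensities
        si = nc.createVariable("actual_sampling_interval", "d", ())
        si.data[()] = 1.0 / trace.sampling_rate
        dl = nc.createVariable("actual_delay_time", "d", ())
        dl.data[()] = trace.start_time


# ---------------------------------------------------------------------------
# ANDI mass spectrometry
# ---------------------------------------------------------------------------

def read_ms_cdf(path, warn_tic_rel=0.01) -> ScanStream:
    """Read an ANDI/MS netCDF file into a :class:`ScanStream`.

    The ragged spectra are reassembled from ``scan_index`` offsets into
    the flattened ``mass_values``/``intensity_values`` arrays. The total
    ion current is recomputed as the per-scan spectrum sum; if a stored
    TIC differs by more than ``warn_tic_rel`` relative it is reported via
    :mod:`warnings`.
    """
    import warnings

    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable netCDF-3 file ({exc})") from exc
    with nc:
        for name in ("scan_index", "mass_values", "intensity_values", "scan_acquisition_time"):
            if name not in nc.variables:
                raise FormatError(f"{path}: missing variable '{name}'")
        idx = np.array(nc.variables["scan_index"][:], dtype=np.int64)
        mass = np.array(nc.variables["mass_values"][:], dtype=np.float64)
        inten = np.array(nc.variables["intensity_values"][:], dtype=np.float64)
        times = np.array(nc.variables["scan_acquisition_time"][:], dtype=np.float64)
        stored_tic = None
        if "total_intensity" in nc.variables:
            stored_tic = np.array(nc.variables["total_intensity"][:], dtype=np.float64)
        stored_counts = None
        if "point_count" in nc.variables:
            stored_counts = np.array(nc.variables["point_count"][:], dtype=np.int64)
    if idx.size != times.size:
        raise FormatError(f"{path}: scan_index/scan_acquisition_time length mismatch")
    if stored_counts is not None:
        if stored_counts.size != idx.size or np.any(stored_counts < 0):
            raise FormatError(f"{path}: invalid point_count")
        ends = idx + stored_counts
    else:
        ends = np.append(idx[1:], mass.size)
    if (np.any(np.diff(idx) < 0) or np.any(ends < idx)
            or np.any(ends > mass.size) or np.any(idx < 0)):
        raise FormatError(f"{path}: inconsistent scan_index offsets")
    mz = [mass[idx[k]:ends[k]] for k in range(idx.size)]
    ints = [inten[idx[k]:ends[k]] for k in range(idx.size)]
    stream = ScanStream(scan_times=times, mz=mz, intensities=ints)
    if stored_tic is not None and stored_tic.size == stream.n_scans:
        denom = np.maximum(np.abs(stored_tic), 1e-30)
        rel = np.abs(stream.total_intensity - stored_tic) / denom
        mask = stored_tic > 0
        if np.any(rel[mask] > warn_tic_rel):
            warnings.warn(
                f"{path}: stored TIC differs from per-scan sums by more than "
                f"{warn_tic_rel:.0%}", stacklevel=2,
            )
    return stream


def write_ms_cdf(stream: ScanStream, path) -> None:
    """Write a :class:`ScanStream` as an ANDI/MS netCDF file."""
    counts = np.array([m.size for m in stream.mz], dtype=np.int64)
    idx = np.concatenate(([0], np.cumsum(counts)[:-1])) if counts.size else np.array([], dtype=np.int64)
    total_points = int(counts.sum())
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", stream.n_scans)
        # netCDF-3 forbids zero-length dimensions other than the record one
        nc.createDimension("point_number", max(total_points, 1))
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = idx.astype(np.int32)
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = counts.astype(np.int32)
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = stream.scan_times
        v = nc.createVariable("total_intensity", "d", ("scan_number",))
        v[:] = stream.total_intensity
        mv = nc.createVariable("mass_values", "d", ("point_number",))
        iv = nc.createVariable("intensity_values", "d", ("point_number",))
        if total_points:
            mv[:] = np.concatenate(stream.mz)
            iv[:] = np.concatenate(stream.intensities)
        else:
            mv[:] = np.zeros(1)
            iv[:] = np.zeros(1)
        if counts.size == 0 or total_points == 0:
            # padding point not referenced by any scan
            pass


# ---------------------------------------------------------------------------
# Sample report CSV
# ---------------------------------------------------------------------------

def write_report_csv(report: SampleReport, path) -> None:
    """Write a sample report as UTF-8 RFC-4180 CSV with a header row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("sample_id",) + REPORT_COLUMNS)
        for region_id, name, t1, t2, vol in report.rows:
            w.writerow([report.sample_id, region_id, name, repr(float(t1)),
                        repr(float(t2)), repr(float(vol))])


def read_report_csv(path) -> SampleReport:
    """Read a sample report CSV written by :func:`write_report_csv`."""
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh)
        try:
            header = next(r)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        if tuple(header) != ("sample_id",) + REPORT_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header!r}")
        sample_id = ""
        rows = []
        seen = set()
        for line in r:
            if len(line) != 6:
                raise FormatError(f"{path}: row with {len(line)} fields, expected 6")
            sample_id = line[0]
            if line[1] in seen:
                raise FormatError(f"{path}: duplicate region_id {line[1]!r}")
            seen.add(line[1])
            rows.append((line[1], line[2], float(line[3]), float(line[4]), float(line[5])))
    if not rows:
        sample_id = Path(path).stem
    return SampleReport(sample_id=sample_id, rows=rows)


# ---------------------------------------------------------------------------
# Stencil JSON
# ---------------------------------------------------------------------------

STENCIL_SCHEMA_VERSION = 1


def write_stencil(stencil, path) -> None:
    """Write a stencil to JSON (schema: version, source_channel, regions)."""
    doc = {
        "version": STENCIL_SCHEMA_VERSION,
        "source_channel": stencil.source_channel,
        "regions": [
            {
                "id": r.id,
                "name": r.name,
                "t1_min_lo": r.t1_lo,
                "t1_min_hi": r.t1_hi,
                "t2_s_lo": r.t2_lo,
                "t2_s_hi": r.t2_hi,
                "spectrum": None if r.spectrum is None
                else [[float(m), float(i)] for m, i in r.spectrum],
                "origin_sample": r.origin_sample,
            }
            for r in stencil.regions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _require(doc, key, types, where):
    if key not in doc:
        raise FormatError(f"stencil JSON: missing {where}/{key}")
    if types is not None and not isinstance(doc[key], types):
        raise FormatError(f"stencil JSON: {where}/{key} has wrong type")
    return doc[key]


def read_stencil(path):
    """Read a stencil JSON file, validating the schema field by field."""
    from dualflow.stencil import Stencil, StencilRegion

    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top-level value must be an object")
    _require(doc, "version", int, "")
    channel = _require(doc, "source_channel", str, "")
    raw_regions = _require(doc, "regions", list, "")
    regions = []
    for k, rr in enumerate(raw_regions):
        where = f"regions[{k}]"
        if not isinstance(rr, dict):
            raise FormatError(f"stencil JSON: {where} must be an object")
        spec_raw = _require(rr, "spectrum", (list, type(None)), where)
        spectrum = None
        if spec_raw is not None:
            spectrum = []
            for j, pair in enumerate(spec_raw):
                if (not isinstance(pair, list)) or len(pair) != 2:
                    raise FormatError(
                        f"stencil JSON: {where}/spectrum[{j}] must be [mz, rel_int]"
                    )
                spectrum.append((float(pair[0]), float(pair[1])))
        regions.append(
            StencilRegion(
                id=_require(rr, "id", str, where),
                name=_require(rr, "name", str, where),
                t1_lo=float(_require(rr, "t1_min_lo", (int, float), where)),
                t1_hi=float(_require(rr, "t1_min_hi", (int, float), where)),
                t2_lo=float(_require(rr, "t2_s_lo", (int, float), where)),
                t2_hi=float(_require(rr, "t2_s_hi", (int, float), where)),
                spectrum=spectrum,
                origin_sample=_require(rr, "origin_sample", (str, type(None)), where),
            )
        )
    return Stencil(regions=regions, source_channel=channel)


# ---------------------------------------------------------------------------
# Folded-plane container (netCDF grid)
# ---------------------------------------------------------------------------

def write_plane_cdf(plane, path) -> None:
    """Write a folded retention plane as a small netCDF grid."""
    with netcdf_file(str(path), "w") as nc:
        nc.channel = plane.channel.encode("ascii", "replace")
        nc.sample_id = plane.sample_id.encode("ascii", "replace")
        nc.createDimension("row", plane.values.shape[0])
        nc.createDimension("col", plane.values.shape[1])
        v = nc.createVariable("intensity", "d", ("row", "col"))
        v[:] = plane.values
        p = nc.createVariable("modulation_period", "d", ())
        p.data[()] = plane.pm
        r = nc.createVariable("rate", "d", ())
        r.data[()] = plane.rate


def read_plane_cdf(path):
    """Read a folded retention plane written by :func:`write_plane_cdf`."""
    from dualflow.folding import Chromatogram2D

    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable netCDF-3 file ({exc})") from exc
    with nc:
        for name in ("intensity", "modulation_period", "rate"):
            if name not in nc.variables:
                raise FormatError(f"{path}: missing variable '{name}'")
        values = np.array(nc.variables["intensity"][:], dtype=np.float64)
        pm = float(np.asarray(nc.variables["modulation_period"][...]))
        rate = float(np.asarray(nc.variables["rate"][...]))
        channel = bytes(getattr(nc, "channel", b"")).decode("ascii", "replace")
        sample_id = bytes(getattr(nc, "sample_id", b"")).decode("ascii", "replace")
    return Chromatogram2D(values=values, pm=pm, rate=rate, channel=channel, sample_id=sample_id)
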