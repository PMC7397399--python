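"""Round-trip and rejection behaviour of all readers and writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualflow import chrom_io
from dualflow.chrom_io import (
    RawTrace,
    SampleReport,
    ScanStream,
    read_fid_cdf,
    read_ms_cdf,
    read_report_csv,
    read_stencil,
    write_fid_cdf,
    write_ms_cdf,
    write_report_csv,
    write_stencil,
)
from dualflow.errors import FormatError
from dualflow.stencil import Stencil, StencilRegion


# ------------------------------------------------------------------- FID ---

def test_fid_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    trace = RawTrace("FID", 120.0, 0.0, rng.uniform(0, 100, 300))
    path = tmp_path / "fid.cdf"
    write_fid_cdf(trace, path)
    back = read_fid_cdf(path)
    assert back.intensities.size == 300
    assert back.sampling_rate == pytest.approx(120.0)
    np.testing.assert_array_equal(back.intensities, trace.intensities)


def test_fid_synthetic_sample_exact(clean_sample, cfg, tmp_path):
    _, fid_trace, _ = clean_sample
    path = tmp_path / "synth_fid.cdf"
    write_fid_cdf(fid_trace, path)
    back = read_fid_cdf(path)
    np.testing.assert_array_equal(back.intensities, fid_trace.intensities)


def test_fid_truncated_file_rejected(tmp_path):
    path = tmp_path / "trunc.cdf"
    write_fid_cdf(RawTrace("FID", 120.0, 0.0, np.arange(1000.0)), path)
    data = path.read_bytes()
    path.write_bytes(data[: len(data) // 2])
    with pytest.raises(FormatError):
        read_fid_cdf(path)


def test_fid_missing_ordinate_rejected(tmp_path):
    from scipy.io import netcdf_file

    path = tmp_path / "noord.cdf"
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("point_number", 5)
        v = nc.createVariable("something_else", "d", ("point_number",))
        v[:] = np.zeros(5)
    with pytest.raises(FormatError, match="ordinate_values"):
        read_fid_cdf(path)


# -------------------------------------------------------------------- MS ---

def _small_stream():
    return ScanStream(
        scan_times=[0.0, 0.1, 0.2],
        mz=[np.array([50.0, 60.0]), np.array([]), np.array([70.0])],
        intensities=[np.array([1.0, 2.0]), np.array([]), np.array([5.0])],
    )


def test_ms_round_trip_with_empty_scan(tmp_path):
    stream = _small_stream()
    path = tmp_path / "ms.cdf"
    write_ms_cdf(stream, path)
    back = read_ms_cdf(path)
    assert back.n_scans == 3
    np.testing.assert_array_equal(back.scan_times, stream.scan_times)
    for a, b in zip(back.mz, stream.mz):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(back.intensities, stream.intensities):
        np.testing.assert_array_equal(a, b)
    assert back.total_intensity[1] == 0.0  # empty scan preserved


def test_ms_per_scan_sums_match_generator(clean_sample, cfg, tmp_path):
    scans, _, _ = clean_sample
    path = tmp_path / "synth_ms.cdf"
    write_ms_cdf(scans, path)
    back = read_ms_cdf(path)
    np.testing.assert_allclose(back.total_intensity, scans.total_intensity)


def test_ms_inconsistent_scan_index_rejected(tmp_path):
    from scipy.io import netcdf_file

    path = tmp_path / "bad.cdf"
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", 2)
        nc.createDimension("point_number", 3)
        si = nc.createVariable("scan_index", "i", ("scan_number",))
        si[:] = np.array([2, 0], dtype=np.int32)  # not non-decreasing
        for name in ("mass_values", "intensity_values"):
            v = nc.createVariable(name, "d", ("point_number",))
            v[:] = np.zeros(3)
        t = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        t[:] = np.array([0.0, 1.0])
    with pytest.raises(FormatError, match="scan_index"):
        read_ms_cdf(path)


@st.composite
def scan_streams(draw):
    n = draw(st.integers(min_value=1, max_value=5))
    times = np.cumsum(draw(st.lists(
        st.floats(min_value=0.01, max_value=2.0), min_size=n, max_size=n)))
    mz, ints = [], []
    for _ in range(n):
        k = draw(st.integers(min_value=0, max_value=6))
        mzs = draw(st.lists(st.integers(min_value=40, max_value=300),
                            min_size=k, max_size=k, unique=True))
        mzs = np.array(sorted(mzs), dtype=float)
        vals = np.array(draw(st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=k, max_size=k)))
        mz.append(mzs)
        ints.append(vals)
    return ScanStream(scan_times=times, mz=mz, intensities=ints)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scan_streams())
def test_ms_round_trip_property(stream):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "s.cdf"
        write_ms_cdf(stream, path)
        back = read_ms_cdf(path)
    assert back.n_scans == stream.n_scans
    np.testing.assert_array_equal(back.scan_times, stream.scan_times)
    for a, b in zip(back.mz, stream.mz):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(back.intensities, stream.intensities):
        np.testing.assert_array_equal(a, b)


# ----------------------------------------------------------- report CSV ---

def test_report_round_trip_empty(tmp_path):
    path = tmp_path / "empty.csv"
    write_report_csv(SampleReport("empty", []), path)
    back = read_report_csv(path)
    assert back.rows == []


def test_report_round_trip_with_comma_in_name(tmp_path):
    report = SampleReport("s1", [
        ("R0001", "2-methylbutanal, branched", 1.25, 0.8, 123.5),
        ("R0002", "limonene", 3.0, 1.1, 0.0),
        ("R0003", 'says "hi"', 4.5, 0.2, 7.25),
    ])
    path = tmp_path / "r.csv"
    write_report_csv(report, path)
    back = read_report_csv(path)
    assert back.sample_id == "s1"
    assert back.rows == report.rows


def test_report_duplicate_region_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "sample_id,region_id,compound_name,apex_1tR_min,apex_2tR_s,volume\n"
        "s,R0001,x,1.0,0.5,10.0\n"
        "s,R0001,y,2.0,0.5,20.0\n"
    )
    with pytest.raises(FormatError, match="duplicate"):
        read_report_csv(path)


# ---------------------------------------------------------- stencil JSON ---

def test_stencil_round_trip_empty(tmp_path):
    path = tmp_path / "s.json"
    write_stencil(Stencil(regions=[], source_channel="MS"), path)
    back = read_stencil(path)
    assert len(back) == 0
    assert back.source_channel == "MS"


def test_stencil_round_trip_with_spectrum(tmp_path):
    region = StencilRegion(
        id="R0001", t1_lo=1.0, t1_hi=1.5, t2_lo=0.4, t2_hi=0.9,
        name="unknown terpene",
        spectrum=[(55.0, 0.25), (70.0, 1.0), (91.0, 0.5), (120.0, 0.1), (150.0, 0.05)],
        origin_sample="sample_A",
    )
    path = tmp_path / "s.json"
    write_stencil(Stencil(regions=[region], source_channel="MS"), path)
    back = read_stencil(path)
    assert back.regions[0] == region


def test_stencil_schema_violation_names_path(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(
        '{"version": 1, "source_channel": "MS", "regions": '
        '[{"id": "R0001", "name": "x", "t1_min_lo": 0.1, "t1_min_hi": 0.2, '
        '"t2_s_lo": 0.1, "spectrum": null, "origin_sample": null}]}'
    )
    with pytest.raises(FormatError, match=r"regions\[0\]"):
        read_stencil(path)


# ------------------------------------------------------------ plane grid ---

def test_plane_cdf_round_trip(clean_planes, tmp_path):
    ms, _ = clean_planes
    path = tmp_path / "plane.cdf"
    chrom_io.write_plane_cdf(ms, path)
    back = chrom_io.read_plane_cdf(path)
    np.testing.assert_array_equal(back.values, ms.values)
    assert back.pm == ms.pm
    assert back.rate == pytest.approx(ms.rate)
    assert back.channel == ms.channel
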