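"""Region quantification, batch assembly, pretreatment and PCA."""

import numpy as np
import pandas as pd
import pytest

from dualflow.chrom_io import SampleReport
from dualflow.errors import ParameterError, ProcessingError
from dualflow.quantify_batch import (
    BatchTable,
    align_reports,
    autoscale,
    pca,
    quantify_stencil,
    read_batch_csv,
    unit_vector_normalize,
    write_batch_csv,
)
from dualflow.register import apply_shift, estimate_shift
from dualflow.stencil import Stencil, StencilRegion


def _table(matrix, samples=None, regions=None, **flags):
    matrix = np.asarray(matrix, dtype=float)
    samples = samples or [f"s{i}" for i in range(matrix.shape[0])]
    regions = regions or [f"R{j:04d}" for j in range(matrix.shape[1])]
    return BatchTable(data=pd.DataFrame(matrix, index=samples, columns=regions),
                      **flags)


# ---------------------------------------------------------------- quantify ---

def test_quantify_empty_stencil(clean_planes):
    _, fid = clean_planes
    report = quantify_stencil(fid, Stencil(regions=[], source_channel="MS"))
    assert report.rows == []


def test_quantify_blank_region_zero_filled(clean_planes):
    _, fid = clean_planes
    blank = StencilRegion(id="R0001", t1_lo=5.7, t1_hi=5.9, t2_lo=2.2, t2_hi=2.4)
    report = quantify_stencil(fid, Stencil(regions=[blank], source_channel="MS"))
    assert report.rows[0][4] == 0.0


def test_quantified_volumes_and_split_ratio(clean_truth, clean_sample,
                                            clean_planes, cfg):
    """FID volumes land within 5% of the analytic Gaussian integrals and
    the quantified FID:MS volume ratio reflects the ~4.5:1 split."""
    from dualflow.peakdetect import detect_peaks
    from dualflow.stencil import autostencil

    scans, _, table = clean_sample
    ms, fid = clean_planes
    peaks = detect_peaks(ms)
    st = autostencil(peaks, scans, ms, mz_range=(cfg.mz_min, cfg.mz_max))
    shift = estimate_shift(ms, fid)
    moved = apply_shift(st, shift, plane=fid)
    report = quantify_stencil(fid, moved)
    vols = report.volumes()
    assert len(vols) == len(clean_truth.peaks)
    ratios = []
    for _, row in table.iterrows():
        region = min(st.regions,
                     key=lambda r: abs(r.center[0] - row.t1_ms_min)
                     + abs(r.center[1] - row.t2_ms_s) / 60.0)
        v = vols[region.id]
        assert v == pytest.approx(row.volume_fid, rel=0.05)
        # MS volume from the detected MS peak
        ms_peak = min(peaks, key=lambda p: abs(p.apex_1tR - row.t1_ms_min)
                      + abs(p.apex_2tR - row.t2_ms_s) / 60.0)
        ratios.append(v / ms_peak.volume)
    assert np.mean(ratios) == pytest.approx(4.5, rel=0.1)


# ------------------------------------------------------------------- align ---

def _stencil(ids):
    return Stencil(regions=[
        StencilRegion(id=i, t1_lo=k + 0.0, t1_hi=k + 0.5, t2_lo=0.1, t2_hi=0.5)
        for k, i in enumerate(ids)
    ], source_channel="MS")


def test_align_single_sample():
    st = _stencil(["R0001", "R0002"])
    rep = SampleReport("s1", [("R0001", "a", 0.1, 0.2, 10.0),
                              ("R0002", "b", 1.1, 0.2, 20.0)])
    table = align_reports([rep], st)
    assert table.data.shape == (1, 2)
    np.testing.assert_array_equal(table.values, [[10.0, 20.0]])


def test_align_zero_fills_missing_regions():
    st = _stencil(["R0001", "R0002", "R0003", "R0004"])
    rep = SampleReport("s1", [("R0002", "b", 1.1, 0.2, 7.0)])
    table = align_reports([rep], st)
    np.testing.assert_array_equal(table.values, [[0.0, 7.0, 0.0, 0.0]])


def test_align_rejects_unknown_region():
    st = _stencil(["R0001"])
    rep = SampleReport("s1", [("R9999", "x", 0.1, 0.2, 1.0)])
    with pytest.raises(ProcessingError, match="R9999"):
        align_reports([rep], st)


def test_align_batch_matches_design(pipeline_result, batch_truths):
    """The 6 × 25 zero-fill pattern mirrors the class design: class-
    specific compounds quantify to zero in the other class's samples and
    shared compounds are present in every sample."""
    truths, design = batch_truths
    table = pipeline_result.batch
    assert table.data.shape == (6, len(design))
    centers = {r.id: r.center for r in pipeline_result.stencil.regions}
    for rid in table.data.columns:
        c1, c2 = centers[rid]
        comp = design.iloc[((design.t1 - c1).abs()
                            + (design.t2 - c2).abs() / 60.0).idxmin()]
        col = table.data[rid]
        assert col.min() >= 0.0
        if comp["class"] == "shared":
            assert (col > 0.0).all()
        else:
            present = col[[s for s in col.index if s.startswith(comp["class"])]]
            absent = col[[s for s in col.index if not s.startswith(comp["class"])]]
            assert (present > 0.0).all()
            # other-class cells are zero-filled up to tiny noise/tail leakage
            assert absent.max() <= 0.02 * present.min()


def test_align_transposed_view():
    table = _table([[1.0, 2.0], [3.0, 4.0]])
    assert table.transposed().shape == (2, 2)
    np.testing.assert_array_equal(table.transposed().values, [[1.0, 3.0], [2.0, 4.0]])


# ------------------------------------------------------------ pretreatment ---

def test_unit_vector_normalize_row():
    out = unit_vector_normalize(_table([[3.0, 4.0]]))
    np.testing.assert_allclose(out.values, [[0.6, 0.8]])
    assert out.normalized


def test_unit_vector_idempotent_on_unit_rows():
    t = unit_vector_normalize(_table([[3.0, 4.0], [1.0, 0.0]]))
    again = unit_vector_normalize(t)
    np.testing.assert_allclose(again.values, t.values, atol=1e-12)


def test_unit_vector_random_rows_norm_one():
    rng = np.random.default_rng(0)
    out = unit_vector_normalize(_table(rng.uniform(0.1, 100, (8, 12))))
    np.testing.assert_allclose(np.linalg.norm(out.values, axis=1), 1.0, atol=1e-9)


def test_unit_vector_zero_row_rejected():
    with pytest.raises(ProcessingError, match="s1"):
        unit_vector_normalize(_table([[1.0, 2.0], [0.0, 0.0]], samples=["s0", "s1"]))


def test_autoscale_two_value_column():
    out = autoscale(_table([[1.0], [3.0]]))
    np.testing.assert_allclose(out.values, [[-0.70710678], [0.70710678]], atol=1e-6)
    assert out.centered and out.scaled


def test_autoscale_constant_column_warns_and_centers():
    with pytest.warns(UserWarning, match="zero-variance"):
        out = autoscale(_table([[5.0, 1.0], [5.0, 2.0]]))
    np.testing.assert_allclose(out.values[:, 0], [0.0, 0.0])


def test_autoscale_column_statistics():
    rng = np.random.default_rng(1)
    out = autoscale(_table(rng.uniform(0, 50, (10, 6))))
    np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_autoscale_needs_two_samples():
    with pytest.raises(ProcessingError):
        autoscale(_table([[1.0, 2.0]]))


# --------------------------------------------------------------------- PCA ---

def _pretreated(matrix, **kw):
    return _table(matrix, normalized=True, centered=True, scaled=True, **kw)


def test_pca_single_axis_data():
    x = np.outer([1.0, -1.0, 2.0, -2.0], [0.5, 0.5, 0.70710678])
    res = pca(_pretreated(x), k=1)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_reconstruction():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(6, 10))
    x -= x.mean(axis=0)
    res = pca(_pretreated(x), k=5)  # full rank after centering
    recon = res.scores.values @ res.loadings.values.T
    np.testing.assert_allclose(recon, x, atol=1e-8)
    # loadings orthonormal, ratios non-increasing
    np.testing.assert_allclose(res.loadings.values.T @ res.loadings.values,
                               np.eye(5), atol=1e-8)
    assert all(np.diff(res.explained_variance_ratio) <= 1e-12)


def test_pca_row_order_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(5, 8))
    a = pca(_pretreated(x), k=2)
    perm = [3, 1, 4, 0, 2]
    b = pca(_pretreated(x[perm]), k=2)
    np.testing.assert_allclose(b.scores.values, a.scores.values[perm], atol=1e-9)
    np.testing.assert_allclose(b.loadings.values, a.loadings.values, atol=1e-9)


def test_pca_requires_pretreatment_flags():
    x = np.random.default_rng(4).normal(size=(4, 5))
    with pytest.raises(ProcessingError):
        pca(_table(x), k=2)
    pca(_table(x), k=2, force=True)  # explicit override allowed


def test_pca_k_out_of_range():
    x = np.random.default_rng(5).normal(size=(4, 5))
    with pytest.raises(ParameterError):
        pca(_pretreated(x), k=4)  # k > samples - 1


def test_pca_separates_synthetic_classes(pipeline_result):
    """Class-specific compounds drive a PC1 separation of more than 3×
    the pooled within-class spread."""
    scores = pipeline_result.pca.scores["PC1"]
    c1 = scores[[s for s in scores.index if s.startswith("class1")]]
    c2 = scores[[s for s in scores.index if s.startswith("class2")]]
    pooled = np.sqrt((c1.var(ddof=1) + c2.var(ddof=1)) / 2.0)
    assert abs(c1.mean() - c2.mean()) > 3.0 * pooled


# --------------------------------------------------------------- batch CSV ---

def test_batch_csv_round_trip(tmp_path):
    table = _table([[1.5, 0.0], [2.25, 3.75]], samples=["a", "b"])
    table.region_names = {"R0000": "alpha", "R0001": "beta, gamma"}
    path = tmp_path / "batch.csv"
    write_batch_csv(table, path)
    back = read_batch_csv(path)
    np.testing.assert_array_equal(back.values, table.values)
    assert list(back.data.index) == ["a", "b"]
    assert back.region_names == table.region_names
    assert not back.normalized
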