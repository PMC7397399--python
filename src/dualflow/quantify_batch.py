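"""Region quantification, batch-table assembly, pretreatment and PCA.

Each stencil region is searched on the baseline-corrected FID plane: the
tallest cell inside the region is the candidate apex; below the SNR
threshold the region's volume is recorded as zero (zero-filling, so the
batch table is complete), otherwise the apex seeds a flood fill clipped
to the region and the footprint is integrated exactly as in peak
detection. Per-sample reports are aligned into a samples × regions
table, pretreated — row unit-vector normalization first, then column
autoscaling; row normalization must precede the column statistics for
those statistics to be meaningful — and decomposed by PCA for
visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dualflow.chrom_io import SampleReport
from dualflow.errors import ParameterError, ProcessingError
from dualflow.folding import Chromatogram2D
from dualflow.peakdetect import DetectParams, _flood_footprint, estimate_noise
from dualflow.stencil import Stencil

__all__ = [
    "BatchTable",
    "PCAResult",
    "quantify_stencil",
    "align_reports",
    "unit_vector_normalize",
    "autoscale",
    "pca",
    "write_batch_csv",
    "read_batch_csv",
]


@dataclass
class BatchTable:
    """Samples × regions quantification matrix with pretreatment flags.

    ``data`` rows are sample ids; columns are region ids. Flags are
    monotone: once set by a pretreatment step they are never unset.
    """

    data: pd.DataFrame
    region_names: dict[str, str] = field(default_factory=dict)
    normalized: bool = False
    centered: bool = False
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("batch table must be zero-filled, not contain NaN")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    def transposed(self) -> pd.DataFrame:
        """Regions × samples view (the spreadsheet-transpose step)."""
        return self.data.T


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a PCA decomposition."""

    scores: pd.DataFrame  # samples × k
    loadings: pd.DataFrame  # variables × k, columns orthonormal
    explained_variance_ratio: np.ndarray  # k values, non-increasing, sum <= 1


def quantify_stencil(plane_fid: Chromatogram2D, stencil: Stencil,
                     params: DetectParams = DetectParams(),
                     sample_id: str | None = None) -> SampleReport:
    """Quantify every stencil region on a corrected FID plane.

    Regions whose apex falls below ``snr_min × noise`` get volume 0;
    otherwise the apex seeds a flood fill (floor as in peak detection)
    clipped to the region rectangle, and the footprint volume is the
    clipped cell sum × dwell time. Region order is preserved.
    """
    pm, rate = plane_fid.pm, plane_fid.rate
    noise = estimate_noise(plane_fid)
    thr = params.snr_min * noise
    rows_out = []
    for region in stencil.regions:
        c0 = max(int(np.ceil(region.t1_lo * 60.0 / pm - 1e-9)), 0)
        c1 = min(int(np.floor(region.t1_hi * 60.0 / pm + 1e-9)), plane_fid.n_cols - 1)
        r0 = max(int(np.ceil(region.t2_lo * rate - 1e-9)), 0)
        r1 = min(int(np.floor(region.t2_hi * rate + 1e-9)), plane_fid.n_rows - 1)
        if c0 > c1 or r0 > r1:
            rows_out.append((region.id, region.name, region.center[0],
                             region.center[1], 0.0))
            continue
        window = plane_fid.values[r0:r1 + 1, c0:c1 + 1]
        flat = int(np.argmax(window))
        arow = r0 + flat // window.shape[1]
        acol = c0 + flat % window.shape[1]
        apex = float(plane_fid.values[arow, acol])
        if apex <= thr or apex <= 0:
            rows_out.append((region.id, region.name, region.center[0],
                             region.center[1], 0.0))
            continue
        floor = max(params.boundary_fraction * apex, thr)
        fp = _flood_footprint(window, (arow - r0, acol - c0), floor)
        fp_rows = np.array([c[0] for c in fp])
        fp_cols = np.array([c[1] for c in fp])
        volume = float(np.clip(window[fp_rows, fp_cols], 0.0, None).sum()) / rate
        rows_out.append((region.id, region.name, acol * pm / 60.0,
                         arow / rate, volume))
    return SampleReport(sample_id=sample_id or plane_fid.sample_id, rows=rows_out)


def align_reports(reports: list[SampleReport], stencil: Stencil) -> BatchTable:
    """Combine per-sample reports into a zero-filled batch table.

    Rows follow input sample order; columns follow stencil region
    order; (sample, region) pairs absent from a report are filled with
    zero. Report values are never altered.
    """
    region_ids = stencil.ids()
    id_set = set(region_ids)
    matrix = []
    sample_ids = []
    for report in reports:
        vols = report.volumes()
        extra = set(vols) - id_set
        if extra:
            raise ProcessingError(
                f"report {report.sample_id!r} contains region ids absent "
                f"from the stencil: {sorted(extra)}"
            )
        matrix.append([vols.get(rid, 0.0) for rid in region_ids])
        sample_ids.append(report.sample_id)
    data = pd.DataFrame(matrix, index=sample_ids, columns=region_ids, dtype=np.float64)
    names = {r.id: r.name for r in stencil.regions}
    return BatchTable(data=data, region_names=names)


def write_batch_csv(table: BatchTable, path) -> None:
    """Write a batch table: header row of region ids, second header row
    of region names, then one row per sample (full float precision)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        cols = list(table.data.columns)
        w.writerow(["sample_id"] + cols)
        w.writerow(["name"] + [table.region_names.get(c, "") for c in cols])
        w.writerow(["flags", f"normalized={table.normalized}",
                    f"centered={table.centered}", f"scaled={table.scaled}"]
                   + [""] * max(len(cols) - 3, 0))
        for sid, row in table.data.iterrows():
            w.writerow([sid] + [repr(float(v)) for v in row])


def read_batch_csv(path) -> BatchTable:
    """Read a batch table written by :func:`write_batch_csv`."""
    import csv

    from dualflow.errors import FormatError

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3 or rows[0][0] != "sample_id" or rows[1][0] != "name":
        raise FormatError(f"{path}: not a batch-table CSV")
    cols = rows[0][1:]
    names = dict(zip(cols, rows[1][1:]))
    flags = {}
    for cell in rows[2][1:4]:
        if "=" in cell:
            k, v = cell.split("=", 1)
            flags[k] = v == "True"
    index, matrix = [], []
    for line in rows[3:]:
        index.append(line[0])
        matrix.append([float(v) for v in line[1:]])
    data = pd.DataFrame(matrix, index=index, columns=cols, dtype=np.float64)
    return BatchTable(data=data, region_names=names,
                      normalized=flags.get("normalized", False),
                      centered=flags.get("centered", False),
                      scaled=flags.get("scaled", False))


def unit_vector_normalize(table: BatchTable) -> BatchTable:
    """Scale every sample row to Euclidean norm 1."""
    values = table.values
    norms = np.linalg.norm(values, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ProcessingError(
            f"cannot normalize all-zero sample row(s): "
            f"{[table.data.index[k] for k in zero]}"
        )
    out = table.data.div(norms, axis=0)
    return BatchTable(data=out, region_names=dict(table.region_names),
                      normalized=True, centered=table.centered, scaled=table.scaled)


def autoscale(table: BatchTable) -> BatchTable:
    """Mean-center each column and divide by its sample SD (ddof=1).

    Zero-variance columns are centered and left unscaled, with a
    warning.
    """
    if table.data.shape[0] < 2:
        raise ProcessingError("autoscaling needs at least 2 samples")
    values = table.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance column(s) centered but not scaled",
            stacklevel=2,
        )
    scale = np.where(flat, 1.0, sd)
    out = pd.DataFrame((values - mean) / scale, index=table.data.index,
                       columns=table.data.columns)
    return BatchTable(data=out, region_names=dict(table.region_names),
                      normalized=table.normalized, centered=True, scaled=True)


def pca(table: BatchTable, k: int = 2, force: bool = False) -> PCAResult:
    """PCA of the pretreated batch table via singular value decomposition.

    scores = U·S, loadings = V (columns orthonormal); each loading
    column's largest-magnitude element is made positive so the sign is
    reproducible. ``force`` skips the pretreatment-flag check.
    """
    if not force and not (table.normalized and table.centered and table.scaled):
        raise ProcessingError(
            "table is not fully pretreated (normalize, center, scale); "
            "pass force=True to decompose anyway"
        )
    n, p = table.data.shape
    if not 1 <= k <= min(n - 1, p):
        raise ParameterError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    x = table.values
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|.| element of each loading column positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total = float((s ** 2).sum())
    ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=table.data.index, columns=comp)
    loadings = pd.DataFrame(vt[:k].T, index=table.data.columns, columns=comp)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio)
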