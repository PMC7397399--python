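"""End-to-end batch workflow orchestration.

Stages, in order: read both channels → TIC from the MS scan stream →
baseline correction on the 1-D traces (DBC for MS, TopHat for FID) →
fold into retention planes → peak detection on the MS planes →
sequential stencil build/merge over the stencil-building samples →
per-sample shift estimation and stencil transfer onto the FID plane →
region quantification → zero-filled batch table → pretreatment (row
unit-vector normalization, then column autoscaling) → PCA.

Every intermediate is written to the output directory and every
parameter is recorded in a JSON-lines log, so a rerun with identical
inputs is byte-identical. Stencil-building samples default to the whole
manifest (sensible for small batches); for large batches pass a subset
— e.g. one or two replicates per class — and the log records which.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from dualflow import __version__
from dualflow.baseline import BaselineParams, dbc, tophat
from dualflow.chrom_io import (
    read_fid_cdf,
    read_ms_cdf,
    write_plane_cdf,
    write_report_csv,
    write_stencil,
)
from dualflow.errors import ConfigurationError, ProcessingError
from dualflow.folding import compute_tic, fold
from dualflow.method_meta import AcquisitionConfig, OvenProgram
from dualflow.peakdetect import DetectParams, detect_peaks
from dualflow.quantify_batch import (
    align_reports,
    autoscale,
    pca,
    quantify_stencil,
    unit_vector_normalize,
    write_batch_csv,
)
from dualflow.register import apply_shift, estimate_shift, local_snap
from dualflow.stencil import Stencil, autostencil, merge_stencil

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything the batch pipeline needs, in one validated object."""

    acquisition: AcquisitionConfig
    manifest: list[tuple[str, str, str]]  # (sample_id, ms_path, fid_path)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    detect: DetectParams = field(default_factory=DetectParams)
    stencil_samples: list[str] | None = None  # default: all samples
    pad_1t: float = 1.0  # modulations
    pad_2t: float = 0.05  # seconds
    rt_tol_1t: float = 1.0
    rt_tol_2t: float = 0.1
    cos_min: float = 0.8
    max_d1t: int = 5  # shift search bound, modulations
    max_d2t: float = 0.25  # seconds
    snap: bool = False
    pca_components: int = 2

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.manifest]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("manifest sample ids must be unique")
        if self.stencil_samples is not None:
            unknown = set(self.stencil_samples) - set(ids)
            if unknown:
                raise ConfigurationError(
                    f"stencil_samples not in manifest: {sorted(unknown)}"
                )


@dataclass
class PipelineResult:
    """Handles on everything the pipeline produced."""

    stencil: Stencil
    reports: list
    batch: "object"
    pretreated: "object"
    pca: "object"
    shifts: dict
    out_dir: Path


def load_config(path) -> PipelineConfig:
    """Read a pipeline TOML config; manifest paths resolve relative to
    the config file."""
    import tomllib

    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    acq_doc = dict(doc.get("acquisition", {}))
    oven_doc = acq_doc.pop("oven", None)
    if oven_doc is not None:
        acq_doc["oven"] = OvenProgram(**oven_doc)
    acquisition = AcquisitionConfig(**acq_doc)
    baseline = BaselineParams(**doc.get("baseline", {}))
    detect = DetectParams(**doc.get("detect", {}))
    manifest = []
    for entry in doc.get("samples", []):
        manifest.append((
            entry["id"],
            str(path.parent / entry["ms"]),
            str(path.parent / entry["fid"]),
        ))
    pipe = dict(doc.get("pipeline", {}))
    return PipelineConfig(acquisition=acquisition, manifest=manifest,
                          baseline=baseline, detect=detect, **pipe)


def _log_entry(fh, stage: str, **fields) -> None:
    fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")


def _params_doc(cfg: PipelineConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    doc["version"] = __version__
    return json.loads(json.dumps(doc, default=str, sort_keys=True))


def run_pipeline(cfg: PipelineConfig, out_dir) -> PipelineResult:
    """Run the full batch workflow; see the module docstring for stages.

    Any stage error is re-raised annotated with the stage name and the
    sample id being processed.
    """
    if not cfg.manifest:
        raise ConfigurationError("manifest is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pm = cfg.acquisition.modulation_period
    mz_range = (cfg.acquisition.mz_min, cfg.acquisition.mz_max)

    stencil_ids = cfg.stencil_samples or [m[0] for m in cfg.manifest]
    log_path = out_dir / "log.jsonl"
    with open(log_path, "w", encoding="utf-8") as log:
        _log_entry(log, "config", params=_params_doc(cfg),
                   stencil_samples=stencil_ids)

        planes = {}  # sample_id -> (ms_plane, fid_plane, scans)
        for sample_id, ms_path, fid_path in cfg.manifest:
            try:
                scans = read_ms_cdf(ms_path)
                fid_raw = read_fid_cdf(fid_path)
                tic = compute_tic(scans)
                tic_corr = dbc(tic, cfg.baseline)
                fid_corr = tophat(fid_raw, cfg.baseline)
                ms_plane = fold(tic_corr, pm)
                fid_plane = fold(fid_corr, pm)
                ms_plane.channel, fid_plane.channel = "MS", "FID"
                ms_plane.sample_id = fid_plane.sample_id = sample_id
            except Exception as exc:
                raise ProcessingError(
                    f"stage=fold sample={sample_id}: {exc}"
                ) from exc
            planes[sample_id] = (ms_plane, fid_plane, scans)
            write_plane_cdf(ms_plane, out_dir / f"{sample_id}_ms_plane.cdf")
            write_plane_cdf(fid_plane, out_dir / f"{sample_id}_fid_plane.cdf")
            _log_entry(log, "fold", sample=sample_id,
                       ms_shape=list(ms_plane.values.shape),
                       fid_shape=list(fid_plane.values.shape))

        stencil: Stencil | None = None
        for sample_id in stencil_ids:
            ms_plane, _, scans = planes[sample_id]
            try:
                peaks = detect_peaks(ms_plane, cfg.detect)
                if stencil is None:
                    stencil = autostencil(
                        peaks, scans, ms_plane, pad_1t=cfg.pad_1t,
                        pad_2t=cfg.pad_2t, mz_range=mz_range,
                        sample_id=sample_id,
                    )
                else:
                    stencil = merge_stencil(
                        stencil, peaks, scans, ms_plane,
                        rt_tol_1t=cfg.rt_tol_1t, rt_tol_2t=cfg.rt_tol_2t,
                        cos_min=cfg.cos_min, pad_1t=cfg.pad_1t,
                        pad_2t=cfg.pad_2t, mz_range=mz_range,
                        sample_id=sample_id,
                    )
            except Exception as exc:
                raise ProcessingError(
                    f"stage=stencil sample={sample_id}: {exc}"
                ) from exc
            _log_entry(log, "stencil", sample=sample_id,
                       peaks=len(peaks), regions=len(stencil))
        assert stencil is not None
        write_stencil(stencil, out_dir / "stencil.json")

        reports = []
        shifts = {}
        for sample_id, _, _ in cfg.manifest:
            ms_plane, fid_plane, _ = planes[sample_id]
            try:
                shift = estimate_shift(ms_plane, fid_plane,
                                       max_d1t=cfg.max_d1t, max_d2t=cfg.max_d2t)
                local = apply_shift(stencil, shift, plane=fid_plane)
                if cfg.snap:
                    local = Stencil(
                        regions=[local_snap(r, fid_plane, tol_1t=cfg.rt_tol_1t,
                                            tol_2t=cfg.rt_tol_2t)
                                 for r in local.regions],
                        source_channel=local.source_channel,
                    )
                report = quantify_stencil(fid_plane, local, cfg.detect,
                                          sample_id=sample_id)
            except Exception as exc:
                raise ProcessingError(
                    f"stage=quantify sample={sample_id}: {exc}"
                ) from exc
            shifts[sample_id] = shift
            reports.append(report)
            write_report_csv(report, out_dir / f"{sample_id}_report.csv")
            _log_entry(log, "transfer", sample=sample_id, d1t_min=shift.d1t,
                       d2t_s=shift.d2t, score=shift.score)

        try:
            batch = align_reports(reports, stencil)
            write_batch_csv(batch, out_dir / "batch.csv")
            pre = autoscale(unit_vector_normalize(batch))
            write_batch_csv(pre, out_dir / "batch_pretreated.csv")
            k = min(cfg.pca_components, batch.data.shape[0] - 1,
                    batch.data.shape[1])
            result = pca(pre, k=k)
        except Exception as exc:
            raise ProcessingError(f"stage=batch sample=-: {exc}") from exc
        result.scores.to_csv(out_dir / "scores.csv", index_label="sample_id")
        result.loadings.to_csv(out_dir / "loadings.csv", index_label="region_id")
        with open(out_dir / "variance.csv", "w", encoding="utf-8") as fh:
            fh.write("component,explained_variance_ratio\n")
            for j, r in enumerate(result.explained_variance_ratio, start=1):
                fh.write(f"PC{j},{r!r}\n")
        _log_entry(log, "pca", components=k,
                   explained=[float(r) for r in result.explained_variance_ratio])

    return PipelineResult(stencil=stencil, reports=reports, batch=batch,
                          pretreated=pre, pca=result, shifts=shifts,
                          out_dir=out_dir)
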