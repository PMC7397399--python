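"""Shared fixtures: synthetic samples and end-to-end pipeline runs.

Everything is generated programmatically from fixed seeds; the batch
fixtures are session-scoped because generating and processing a
six-sample batch dominates the suite's runtime.
"""

from pathlib import Path

import numpy as np
import pytest

from dualflow import chrom_io
from dualflow.baseline import dbc, tophat
from dualflow.folding import compute_tic, fold
from dualflow.method_meta import AcquisitionConfig
from dualflow.pipeline import PipelineConfig, run_pipeline
from dualflow.synth import PlantedPeak, SyntheticTruth, synth_batch, synth_sample


def _spectrum(*lines):
    return tuple((float(m), float(i)) for m, i in lines)


DEFAULT_SPECTRUM = _spectrum((55, 0.4), (70, 1.0), (91, 0.7), (120, 0.2), (150, 0.1))


@pytest.fixture(scope="session")
def cfg() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_truth(cfg) -> SyntheticTruth:
    """20 well-separated clean Gaussians spanning a 100× amplitude range."""
    rng = np.random.default_rng(42)
    cols = np.arange(6, 146, 7)[:20]
    t2s = np.tile([0.4, 1.5], 10)
    amps = np.logspace(3, 5, 20)
    rng.shuffle(amps)
    peaks = tuple(
        PlantedPeak(
            t1=float(c) * cfg.modulation_period / 60.0,
            t2=float(t2),
            sigma1=1.0,
            sigma2=0.15,
            amplitude_ms=float(a),
            spectrum=DEFAULT_SPECTRUM,
        )
        for c, t2, a in zip(cols, t2s, amps)
    )
    return SyntheticTruth(
        peaks=peaks, duration_min=6.0, poisson_ms=False, ms_background=0.0,
        noise_sigma_fid=0.0, drift_total_fid=100.0, bleed_amp_fid=50.0, seed=42,
    )


@pytest.fixture(scope="session")
def clean_sample(clean_truth, cfg):
    """(scans, fid_trace, truth_table) for the clean 20-peak sample."""
    return synth_sample(clean_truth, cfg)


@pytest.fixture(scope="session")
def clean_planes(clean_sample, cfg):
    """Baseline-corrected (ms_plane, fid_plane) for the clean sample."""
    scans, fid_trace, _ = clean_sample
    ms = fold(dbc(compute_tic(scans)), cfg.modulation_period)
    fid = fold(tophat(fid_trace), cfg.modulation_period)
    ms.channel, fid.channel = "MS", "FID"
    ms.sample_id = fid.sample_id = "clean"
    return ms, fid


@pytest.fixture(scope="session")
def batch_truths(cfg):
    """2 classes × 3 replicates, 15 shared + 5 per-class compounds."""
    return synth_batch(n_classes=2, n_per_class=3, shared_compounds=15,
                       class_compounds=5, seed=1, cfg=cfg)


@pytest.fixture(scope="session")
def batch_dir(batch_truths, cfg, tmp_path_factory) -> Path:
    """The batch written out as *.cdf pairs, ready for the pipeline."""
    truths, design = batch_truths
    out = tmp_path_factory.mktemp("batch")
    for truth in truths:
        scans, fid, table = synth_sample(truth, cfg)
        chrom_io.write_ms_cdf(scans, out / f"{truth.sample_id}_ms.cdf")
        chrom_io.write_fid_cdf(fid, out / f"{truth.sample_id}_fid.cdf")
        table.to_csv(out / f"{truth.sample_id}_truth.csv", index=False)
    design.to_csv(out / "design.csv", index=False)
    return out


@pytest.fixture(scope="session")
def pipeline_config(batch_truths, batch_dir, cfg) -> PipelineConfig:
    truths, _ = batch_truths
    manifest = [
        (t.sample_id, str(batch_dir / f"{t.sample_id}_ms.cdf"),
         str(batch_dir / f"{t.sample_id}_fid.cdf"))
        for t in truths
    ]
    return PipelineConfig(acquisition=cfg, manifest=manifest)


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config, tmp_path_factory):
    return run_pipeline(pipeline_config, tmp_path_factory.mktemp("results"))
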