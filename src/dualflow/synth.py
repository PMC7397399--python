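"""Synthetic dual-channel GC×GC samples with exact ground truth.

Every pipeline stage is testable without instrument data: peaks are
pure 2-D Gaussians over the (modulation, second-dimension time) grid, so
their analytic volumes (2π·A·σ₁·σ₂ in grid units) are exact oracles.
The MS channel is a scan stream at the quadrupole rate whose per-scan
spectra are each peak's fragment pattern scaled by the 2-D Gaussian at
that scan's folded coordinates, with optional Poisson counting noise and
a small Poisson background line per scan. The FID channel is a fast
fixed-rate trace of the same Gaussians scaled by the effluent-split gain
(default 4.5), translated by a small inter-channel retention shift, over
a linear drift plus an exponential column-bleed ramp with Gaussian
noise.

Amplitudes can span several orders of magnitude, as volatile-compound
profiles from biological sources do; replicate batches jitter amplitudes
log-normally. Everything is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from dualflow.chrom_io import RawTrace, ScanStream
from dualflow.errors import ParameterError
from dualflow.method_meta import AcquisitionConfig

__all__ = ["PlantedPeak", "SyntheticTruth", "synth_sample", "synth_batch"]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PlantedPeak:
    """Ground-truth description of one planted compound peak."""

    t1: float  # minutes, first-dimension retention (modulation start)
    t2: float  # seconds, second-dimension retention
    sigma1: float  # modulations
    sigma2: float  # seconds
    amplitude_ms: float  # TIC counts at apex
    spectrum: tuple  # ((mz, rel_intensity), ...), max intensity 1
    fid_gain: float = 4.5  # FID:MS effluent split
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ParameterError("sigmas must be > 0")
        if self.amplitude_ms <= 0:
            raise ParameterError("amplitude must be > 0")

    def analytic_volume_ms(self) -> float:
        """Exact TIC volume in counts·s per modulation-grid conventions:
        2π·A·σ₁[modulations]·σ₂[seconds] (independent of sampling rate)."""
        return TWO_PI * self.amplitude_ms * self.sigma1 * self.sigma2

    def analytic_volume_fid(self) -> float:
        return self.fid_gain * self.analytic_volume_ms()


@dataclass(frozen=True)
class SyntheticTruth:
    """Full recipe for one synthetic sample; same seed → same bytes."""

    peaks: tuple  # of PlantedPeak
    duration_min: float = 6.0
    channel_shift: tuple = (2.5 / 60.0, 0.05)  # FID − MS: (minutes, seconds)
    poisson_ms: bool = True
    ms_background: float = 5.0  # mean background counts per scan
    noise_sigma_fid: float = 2.0  # counts
    drift_total_fid: float = 100.0  # counts, linear 0 → this
    bleed_amp_fid: float = 50.0  # counts at end of run
    bleed_rate: float = 3.0  # exponential shape of the bleed ramp
    seed: int = 0
    sample_id: str = "synthetic"


def _gauss2d(peak_amp_pairs, cols, t2s, pm):
    """Sum of planted Gaussians at folded coordinates (vectorized over
    the sample axis)."""
    out = np.zeros_like(t2s, dtype=np.float64)
    for p, amp in peak_amp_pairs:
        col_p = p.t1 * 60.0 / pm
        out += amp * np.exp(
            -0.5 * ((cols - col_p) / p.sigma1) ** 2
            - 0.5 * ((t2s - p.t2) / p.sigma2) ** 2
        )
    return out


def synth_sample(truth: SyntheticTruth, cfg: AcquisitionConfig
                 ) -> tuple[ScanStream, RawTrace, pd.DataFrame]:
    """Generate one paired MS/FID sample plus its truth table.

    Returns ``(scan_stream, fid_trace, truth_table)`` where the truth
    table lists, per peak, the planted retentions on both channels and
    the analytic per-channel volumes.
    """
    pm = cfg.modulation_period
    run_s = truth.duration_min * 60.0
    d1t, d2t = truth.channel_shift
    for p in truth.peaks:
        for t1, t2 in ((p.t1, p.t2), (p.t1 + d1t, p.t2 + d2t)):
            if not (0.0 <= t1 * 60.0 <= run_s - pm):
                raise ParameterError(
                    f"peak at 1tR={t1:g} min outside run extent"
                )
            if not (0.0 <= t2 < pm):
                raise ParameterError(
                    f"peak at 2tR={t2:g} s outside the modulation period"
                )
    rng = np.random.default_rng(truth.seed)

    # ---- MS scan stream -------------------------------------------------
    n_scans = int(math.floor(run_s / cfg.ms_scan_time))
    scan_times = np.arange(n_scans) * cfg.ms_scan_time
    cols = np.floor(scan_times / pm)
    t2s = scan_times - cols * pm
    # per-peak apex-normalized spectra: lines scaled to sum to 1 so the
    # per-scan spectrum sum (TIC) equals the planted Gaussian amplitude
    peak_lines = []
    for p in truth.peaks:
        mzs = np.array([m for m, _ in p.spectrum], dtype=np.float64)
        rel = np.array([i for _, i in p.spectrum], dtype=np.float64)
        peak_lines.append((mzs, rel / rel.sum()))
    weights = np.zeros((len(truth.peaks), n_scans))
    for k, p in enumerate(truth.peaks):
        col_p = p.t1 * 60.0 / pm
        weights[k] = p.amplitude_ms * np.exp(
            -0.5 * ((cols - col_p) / p.sigma1) ** 2
            - 0.5 * ((t2s - p.t2) / p.sigma2) ** 2
        )
    cutoff = 1e-9
    mz_list: list[np.ndarray] = []
    int_list: list[np.ndarray] = []
    mz_lo, mz_hi = cfg.mz_min, cfg.mz_max
    for s in range(n_scans):
        acc: dict[float, float] = {}
        for k in range(len(truth.peaks)):
            w = weights[k, s]
            if w <= cutoff:
                continue
            mzs, frac = peak_lines[k]
            for m, f in zip(mzs, frac):
                acc[m] = acc.get(m, 0.0) + w * f
        if truth.ms_background > 0:
            bg_mz = float(rng.integers(mz_lo, mz_hi + 1))
            bg = float(rng.poisson(truth.ms_background))
            if bg > 0:
                acc[bg_mz] = acc.get(bg_mz, 0.0) + bg
        if not acc:
            mz_list.append(np.empty(0))
            int_list.append(np.empty(0))
            continue
        mz_arr = np.array(sorted(acc), dtype=np.float64)
        int_arr = np.array([acc[m] for m in mz_arr], dtype=np.float64)
        if truth.poisson_ms:
            int_arr = rng.poisson(int_arr).astype(np.float64)
            keep = int_arr > 0
            mz_arr, int_arr = mz_arr[keep], int_arr[keep]
        mz_list.append(mz_arr)
        int_list.append(int_arr)
    scans = ScanStream(scan_times=scan_times, mz=mz_list, intensities=int_list)

    # ---- FID trace ------------------------------------------------------
    n_fid = int(math.floor(run_s * cfg.fid_rate))
    t = np.arange(n_fid) / cfg.fid_rate
    fcols = np.floor(t / pm)
    ft2 = t - fcols * pm
    shifted = [
        (replace(p, t1=p.t1 + d1t, t2=p.t2 + d2t), p.amplitude_ms * p.fid_gain)
        for p in truth.peaks
    ]
    fid = _gauss2d(shifted, fcols, ft2, pm)
    if truth.drift_total_fid:
        fid = fid + truth.drift_total_fid * t / run_s
    if truth.bleed_amp_fid:
        fid = fid + truth.bleed_amp_fid * (
            np.expm1(truth.bleed_rate * t / run_s) / math.expm1(truth.bleed_rate)
        )
    if truth.noise_sigma_fid:
        fid = fid + rng.normal(0.0, truth.noise_sigma_fid, size=n_fid)
    fid_trace = RawTrace(channel="FID", sampling_rate=cfg.fid_rate,
                         start_time=0.0, intensities=fid)

    rows = []
    for k, p in enumerate(truth.peaks, start=1):
        rows.append({
            "peak": k,
            "name": p.name or f"compound_{k:03d}",
            "t1_ms_min": p.t1,
            "t2_ms_s": p.t2,
            "t1_fid_min": p.t1 + d1t,
            "t2_fid_s": p.t2 + d2t,
            "sigma1_mod": p.sigma1,
            "sigma2_s": p.sigma2,
            "amplitude_ms": p.amplitude_ms,
            "amplitude_fid": p.amplitude_ms * p.fid_gain,
            "volume_ms": p.analytic_volume_ms(),
            "volume_fid": p.analytic_volume_fid(),
        })
    table = pd.DataFrame(rows)
    return scans, fid_trace, table


def _random_spectrum(rng: np.random.Generator, mz_lo: int, mz_hi: int) -> tuple:
    n_lines = int(rng.integers(5, 16))
    mzs = rng.choice(np.arange(mz_lo, mz_hi + 1), size=n_lines, replace=False)
    rel = rng.uniform(0.05, 1.0, size=n_lines)
    rel[rng.integers(0, n_lines)] = 1.0  # base peak
    order = np.argsort(mzs)
    return tuple((float(m), float(i)) for m, i in zip(mzs[order], rel[order]))


def _compound_slots(duration_min: float, pm: float, n: int,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    """Well-separated (t1, t2) positions on a coarse slot grid.

    Spacing (8 modulations × 1.0 s for σ₁ = 1 modulation, σ₂ = 0.15 s)
    keeps 5%-of-apex footprints disjoint even across a 100× amplitude
    range, so flood-fill delineation never merges neighbours."""
    n_cols = int(duration_min * 60.0 / pm)
    col_slots = np.arange(6, n_cols - 6, 8)
    t2_slots = np.arange(0.3, pm - 0.4, 1.0)
    all_slots = [(c * pm / 60.0, float(s)) for c in col_slots for s in t2_slots]
    if n > len(all_slots):
        raise ParameterError(
            f"cannot place {n} well-separated compounds in a "
            f"{duration_min:g} min run (max {len(all_slots)})"
        )
    pick = rng.choice(len(all_slots), size=n, replace=False)
    return [all_slots[int(k)] for k in pick]


def synth_batch(n_classes: int = 2, n_per_class: int = 3,
                shared_compounds: int = 15, class_compounds: int = 5,
                seed: int = 0, cfg: AcquisitionConfig | None = None,
                duration_min: float = 6.0,
                amplitude_range: tuple[float, float] = (1e3, 1e5),
                rep_jitter_sd: float = 0.1,
                **truth_overrides) -> tuple[list[SyntheticTruth], pd.DataFrame]:
    """Generate a replicate batch design: shared + class-specific compounds.

    Every class's samples contain the shared compounds plus that class's
    own; replicate amplitudes are jittered log-normally (sd
    ``rep_jitter_sd``). Returns the per-sample truths (feed each to
    :func:`synth_sample`) and a compound design table. Deterministic per
    seed.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ParameterError("counts must be >= 1")
    cfg = cfg or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    n_compounds = shared_compounds + n_classes * class_compounds
    slots = _compound_slots(duration_min, cfg.modulation_period, n_compounds, rng)
    compounds = []
    lo, hi = amplitude_range
    for k, (t1, t2) in enumerate(slots):
        amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        compounds.append({
            "name": f"compound_{k + 1:03d}",
            "t1": t1,
            "t2": t2,
            "sigma1": 1.0,
            "sigma2": 0.15,
            "amplitude": amp,
            "spectrum": _random_spectrum(rng, cfg.mz_min, cfg.mz_max),
            "class": "shared" if k < shared_compounds
            else f"class{(k - shared_compounds) // class_compounds + 1}",
        })
    design = pd.DataFrame(
        [{k: v for k, v in c.items() if k != "spectrum"} for c in compounds]
    )
    truths = []
    for c in range(1, n_classes + 1):
        members = [cc for cc in compounds
                   if cc["class"] in ("shared", f"class{c}")]
        for r in range(1, n_per_class + 1):
            peaks = []
            for cc in members:
                jitter = float(np.exp(rng.normal(0.0, rep_jitter_sd)))
                peaks.append(PlantedPeak(
                    t1=cc["t1"], t2=cc["t2"], sigma1=cc["sigma1"],
                    sigma2=cc["sigma2"],
                    amplitude_ms=cc["amplitude"] * jitter,
                    spectrum=cc["spectrum"], name=cc["name"],
                ))
            child_seed = int(rng.integers(0, 2**31 - 1))
            truths.append(SyntheticTruth(
                peaks=tuple(peaks), duration_min=duration_min,
                seed=child_seed, sample_id=f"class{c}_rep{r}",
                **truth_overrides,
            ))
    return truths, design
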