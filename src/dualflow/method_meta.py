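"""Acquisition-method metadata and derived quantities.

The GC oven program and detector settings parameterize everything
downstream: the modulation period defines the folding of the 1D signal
into the retention plane, the detector rates define the second-dimension
grids, and the oven program fixes the total run time and hence the
expected number of complete modulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from dualflow.errors import ConfigurationError


@dataclass(frozen=True)
class OvenProgram:
    """Single-ramp GC oven program.

    Parameters
    ----------
    initial_temp : float
        Starting oven temperature, °C.
    initial_hold : float
        Hold at the starting temperature, minutes.
    ramp_rate : float
        Heating rate, °C/min. Must be positive.
    final_temp : float
        Final temperature, °C. Must exceed ``initial_temp``.
    final_hold : float
        Hold at the final temperature, minutes.
    """

    initial_temp: float
    initial_hold: float
    ramp_rate: float
    final_temp: float
    final_hold: float

    def __post_init__(self) -> None:
        if self.final_temp <= self.initial_temp:
            raise ConfigurationError(
                "final_temp must exceed initial_temp "
                f"({self.final_temp} <= {self.initial_temp})"
            )
        if self.ramp_rate <= 0:
            raise ConfigurationError(f"ramp_rate must be > 0, got {self.ramp_rate}")
        if self.initial_hold < 0 or self.final_hold < 0:
            raise ConfigurationError("hold times must be >= 0")


def _default_oven() -> OvenProgram:
    return OvenProgram(
        initial_temp=60.0,
        initial_hold=1.0,
        ramp_rate=5.0,
        final_temp=250.0,
        final_hold=10.0,
    )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Dual-channel GC×GC-qMS/FID acquisition settings.

    Defaults mirror a typical qMS/FID method: 2.5 s modulation period
    with a 100 ms flush, FID sampled at 120 Hz, quadrupole scanning
    m/z 40-300 in 0.0241 s (41.5 scans/s), and an effluent split of
    roughly 4.5:1 between the FID and the MS.
    """

    modulation_period: float = 2.5  # seconds
    flush_time: float = 100.0  # milliseconds; acquisition detail, not used in processing
    fid_rate: float = 120.0  # Hz
    ms_scan_time: float = 0.0241  # seconds per full scan
    mz_min: int = 40
    mz_max: int = 300
    oven: OvenProgram = field(default_factory=_default_oven)
    split_ratio_fid_to_ms: float = 4.5

    def __post_init__(self) -> None:
        if self.modulation_period <= 0:
            raise ConfigurationError("modulation_period must be > 0")
        if self.fid_rate <= 0:
            raise ConfigurationError("fid_rate must be > 0")
        if self.ms_scan_time <= 0:
            raise ConfigurationError("ms_scan_time must be > 0")
        if self.mz_min >= self.mz_max:
            raise ConfigurationError("mz_min must be < mz_max")

    @property
    def ms_rate(self) -> float:
        """MS acquisition rate in scans/s (full precision)."""
        return acquisition_rate(self.ms_scan_time)


def total_run_time(oven: OvenProgram) -> float:
    """Total oven-program run time in minutes.

    initial hold + ramp duration + final hold; the ramp duration is the
    temperature span divided by the ramp rate.
    """
    return (
        oven.initial_hold
        + (oven.final_temp - oven.initial_temp) / oven.ramp_rate
        + oven.final_hold
    )


def acquisition_rate(scan_time: float) -> float:
    """Acquisition rate in Hz for a given full-scan time in seconds.

    Stored at full precision; round only when reporting.
    """
    if scan_time <= 0:
        raise ConfigurationError(f"scan_time must be > 0, got {scan_time}")
    return 1.0 / scan_time


def expected_modulations(cfg: AcquisitionConfig) -> int:
    """Number of complete modulation cycles in the run.

    A partial final cycle has no complete second-dimension trace and is
    discarded, so the count is the floor of run time over modulation
    period.
    """
    run_s = total_run_time(cfg.oven) * 60.0
    return int(math.floor(run_s / cfg.modulation_period))
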