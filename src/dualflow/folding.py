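"""Folding of 1-D detector signals into the 2-D retention plane.

The modulator reinjects effluent onto the second column every
``pm`` seconds (the modulation period), so a detector trace is a
concatenation of short second-dimension chromatograms. Folding cuts the
trace into consecutive ``pm``-long blocks: columns index modulations
(first-dimension retention, assigned at modulation start) and rows index
samples within a modulation (second-dimension retention, measured from
modulation start). Peaks eluting past ``pm`` wrap around to the bottom
of the next column; no unwrapping is attempted.

When the samples-per-modulation count ``pm × rate`` is not an integer
(e.g. 41.5 Hz × 2.5 s = 103.75), each modulation is linearly
interpolated onto a fixed grid of ``ceil(pm × rate)`` rows so every
column shares one second-dimension axis; in the integer case folding is
an exact reshape and ``unfold(fold(x)) == x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dualflow.chrom_io import RawTrace, ScanStream
from dualflow.errors import ParameterError, ProcessingError

__all__ = [
    "Chromatogram2D",
    "compute_tic",
    "fold",
    "unfold",
    "index_to_retention",
    "retention_to_index",
]


@dataclass
class Chromatogram2D:
    """A folded retention-plane intensity matrix for one channel.

    ``values[row, col]``: row = second-dimension sample index, col =
    modulation index. ``rate`` is the effective sampling rate along the
    second-dimension axis (rows per second).
    """

    values: np.ndarray
    pm: float  # modulation period, seconds
    rate: float  # second-dimension sampling rate, Hz
    channel: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("plane must be a 2-D matrix")
        if self.pm <= 0 or self.rate <= 0:
            raise ValueError("pm and rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("plane values must be finite")
        if abs(self.values.shape[0] - self.pm * self.rate) > 0.5 + 1e-9:
            raise ValueError(
                f"row count {self.values.shape[0]} inconsistent with "
                f"pm × rate = {self.pm * self.rate:g}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def compute_tic(scans: ScanStream) -> RawTrace:
    """Total ion current trace: per-scan spectrum sums.

    The sampling rate is inferred as the reciprocal of the median scan
    spacing; at least two scans are required.
    """
    if scans.n_scans < 2:
        raise ProcessingError("need at least 2 scans to infer a scan rate")
    dt = float(np.median(np.diff(scans.scan_times)))
    tic = np.array([float(i.sum()) for i in scans.intensities])
    return RawTrace(
        channel="MS-TIC",
        sampling_rate=1.0 / dt,
        start_time=float(scans.scan_times[0]),
        intensities=tic,
    )


def _is_integer_grid(n: float) -> bool:
    return abs(n - round(n)) <= 1e-9 * max(1.0, abs(n))


def fold(trace: RawTrace, pm: float) -> Chromatogram2D:
    """Fold a 1-D trace into a :class:`Chromatogram2D` with period ``pm``.

    Integer samples-per-modulation: exact reshape into consecutive
    blocks. Non-integer: per-modulation linear interpolation onto a
    ``ceil(pm × rate)``-row grid. The trailing partial modulation is
    discarded in both cases.
    """
    if pm <= 0:
        raise ParameterError(f"modulation period must be > 0, got {pm}")
    rate = trace.sampling_rate
    n = pm * rate  # samples per modulation
    m = trace.intensities.size
    if m < n - 1e-9:
        raise ProcessingError(
            f"trace of {m} samples is shorter than one modulation ({n:g} samples)"
        )
    if _is_integer_grid(n):
        ni = round(n)
        n_cols = m // ni
        mat = trace.intensities[: n_cols * ni].reshape(n_cols, ni).T.copy()
        return Chromatogram2D(
            values=mat, pm=pm, rate=rate,
            channel=trace.channel, sample_id="",
        )
    n_rows = math.ceil(n)
    n_cols = int(math.floor(m / n + 1e-12))
    eff_rate = n_rows / pm
    t_samples = np.arange(m) / rate  # trace-relative seconds
    mat = np.empty((n_rows, n_cols), dtype=np.float64)
    row_offsets = np.arange(n_rows) / eff_rate
    for j in range(n_cols):
        mat[:, j] = np.interp(j * pm + row_offsets, t_samples, trace.intensities)
    return Chromatogram2D(
        values=mat, pm=pm, rate=eff_rate,
        channel=trace.channel, sample_id="",
    )


def unfold(plane: Chromatogram2D) -> RawTrace:
    """Concatenate the plane's columns back into a 1-D trace.

    Exact inverse of :func:`fold` on integer-grid planes.
    """
    flat = plane.values.T.reshape(-1).copy()
    return RawTrace(
        channel=plane.channel,
        sampling_rate=plane.rate,
        start_time=0.0,
        intensities=flat,
    )


def index_to_retention(plane: Chromatogram2D, row: int, col: int) -> tuple[float, float]:
    """Map a (row, col) cell to retentions (1tR minutes, 2tR seconds).

    1tR is the modulation start time; 2tR is measured from modulation
    start with no hold-up-time subtraction.
    """
    if not (0 <= row < plane.n_rows and 0 <= col < plane.n_cols):
        raise ParameterError(f"index ({row}, {col}) out of range for "
                             f"{plane.n_rows}×{plane.n_cols} plane")
    return col * plane.pm / 60.0, row / plane.rate


def retention_to_index(plane: Chromatogram2D, t1_min: float, t2_s: float) -> tuple[int, int]:
    """Map retentions back to the nearest (row, col) cell."""
    col = round(t1_min * 60.0 / plane.pm)
    row = round(t2_s * plane.rate)
    if not (0 <= row < plane.n_rows and 0 <= col < plane.n_cols):
        raise ParameterError(
            f"retention ({t1_min} min, {t2_s} s) outside plane extent"
        )
    return int(row), int(col)
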