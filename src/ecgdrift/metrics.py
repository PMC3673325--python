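"""Evaluation metrics: baseline-agreement errors and error-reduction rates.

error1 measures the mean squared difference between the raw extracted
baseline (before adjustment) and a reference baseline; error2 the same after
shift/elevation/gain adjustment. The per-record reduction is
(error1 - error2)/error1 and the suite-level figure is its arithmetic mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import periodogram

from .errors import InputError
from .signal import Signal

__all__ = [
    "ErrorReport",
    "baseline_error",
    "error_reduction",
    "average_error_reduction",
    "band_power",
    "band_power_reduction",
    "write_reports",
    "read_reports",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(getattr(x, "samples", x), dtype=np.float64)


@dataclass(frozen=True)
class ErrorReport:
    """Per-record evaluation: errors are mean squared differences;
    ``percentage`` is the fractional reduction (error1 - error2)/error1."""

    error1: float
    error2: float
    percentage: float
    n_samples: int

    def __post_init__(self):
        if self.error1 < 0 or self.error2 < 0:
            raise InputError("errors must be nonnegative")

    @classmethod
    def from_errors(cls, error1: float, error2: float, n_samples: int) -> "ErrorReport":
        return cls(error1, error2, error_reduction(error1, error2), n_samples)


def baseline_error(candidate, reference, *, root: bool = False) -> float:
    """Mean squared difference sum_k (c_k - r_k)^2 / n (RMS if ``root``)."""
    c = _as_array(candidate)
    r = _as_array(reference)
    if c.shape != r.shape:
        raise InputError(f"length mismatch: {c.shape} vs {r.shape}")
    if c.size < 1:
        raise InputError("need at least one sample")
    mse = float(np.mean((c - r) ** 2))
    return float(np.sqrt(mse)) if root else mse


def error_reduction(error1: float, error2: float) -> float:
    """(error1 - error2) / error1; undefined for error1 == 0."""
    if not error1 > 0:
        raise InputError(f"error1 must be > 0, got {error1}")
    return (error1 - error2) / error1


def average_error_reduction(reports) -> float:
    """Arithmetic mean of per-report reductions over a non-empty list."""
    reports = list(reports)
    if not reports:
        raise InputError("need at least one report")
    return float(np.mean([r.percentage for r in reports]))


def band_power(signal: Signal, f_lo: float, f_hi: float) -> float:
    """Spectral power in (f_lo, f_hi] Hz (Hann periodogram, mean removed)."""
    f, p = periodogram(
        signal.samples, fs=signal.fs, window="hann", detrend="constant"
    )
    mask = (f > f_lo) & (f <= f_hi)
    return float(np.sum(p[mask]))


def band_power_reduction(before: Signal, after: Signal, f_hi: float = 0.5) -> float:
    """Fractional reduction of sub-``f_hi`` power from ``before`` to ``after``."""
    p0 = band_power(before, 0.0, f_hi)
    if not p0 > 0:
        raise InputError("reference record has no power in the band")
    return 1.0 - band_power(after, 0.0, f_hi) / p0


def write_reports(reports, path) -> None:
    """Serialize reports as JSON lines (one object per record)."""
    with Path(path).open("w") as fh:
        for r in reports:
            fh.write(json.dumps(asdict(r)) + "\n")


def read_reports(path) -> list[ErrorReport]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ErrorReport(**json.loads(line)))
    return out
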