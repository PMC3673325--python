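"""Uniformly sampled single-channel signal: the currency of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, InputError


@dataclass(frozen=True)
class Signal:
    """A finite, uniformly sampled 1-D time series.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units). Coerced to a float64 array.
    fs
        Sampling rate in Hz; must be positive and constant over the record.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise InputError(f"samples must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise InputError("signal must contain at least one sample")
        fs = float(self.fs)
        if not np.isfinite(fs) or fs <= 0:
            raise InputError(f"sampling rate must be positive, got {fs}")
        if not np.all(np.isfinite(arr)):
            raise DataError("signal contains non-finite samples")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", fs)

    @property
    def T(self) -> float:
        """Sampling interval in seconds (1/fs)."""
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self) / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self)) / self.fs

    def __len__(self) -> int:
        return self.samples.size
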