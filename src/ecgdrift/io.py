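"""CSV reading/writing of single-channel signals.

The interchange format is a comma-separated file with '.' decimals and an
optional single header line: either two columns (time in seconds, amplitude)
or one column (amplitude) accompanied by an explicit sampling rate. Two-column
input is verified to be uniformly sampled.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, InputError
from .signal import Signal

__all__ = ["read_signal", "write_signal"]

#: maximum allowed deviation of any sampling interval from the median, relative
_UNIFORMITY_TOL = 0.01


def _load_numeric(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, header=None, dtype=np.float64)
    except (ValueError, TypeError):
        pass
    try:
        df = pd.read_csv(path, header=0)
        return df.astype(np.float64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: could not parse numeric CSV ({exc})") from exc


def read_signal(path, fs: float | None = None) -> Signal:
    """Read a signal from CSV.

    One column: amplitudes; ``fs`` is required. Two columns: (time, value);
    the time column must be uniformly sampled (interval deviations below 1% of
    the median) and supplies the rate unless ``fs`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = _load_numeric(path)
    if df.shape[1] == 1:
        if fs is None:
            raise ConfigError(
                f"{path}: single-column input needs an explicit sampling rate"
            )
        return Signal(df.iloc[:, 0].to_numpy(), fs)
    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy()
        v = df.iloc[:, 1].to_numpy()
        if t.size < 2:
            raise FormatError(f"{path}: need at least two rows to infer the rate")
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise FormatError(f"{path}: time column is not increasing")
        if np.max(np.abs(dt - med)) > _UNIFORMITY_TOL * med:
            raise FormatError(
                f"{path}: non-uniform sampling (interval deviation exceeds "
                f"{_UNIFORMITY_TOL:.0%} of the median)"
            )
        return Signal(v, fs if fs is not None else 1.0 / med)
    raise FormatError(
        f"{path}: expected 1 or 2 columns, got {df.shape[1]} "
        "(ground-truth record files are read with synth.read_record)"
    )


def write_signal(signal: Signal, path, include_time: bool = True) -> None:
    """Write a signal as CSV; lossless round-trip with :func:`read_signal`."""
    path = Path(path)
    if include_time:
        df = pd.DataFrame({"t": signal.time(), "value": signal.samples})
    else:
        df = pd.DataFrame({"value": signal.samples})
    df.to_csv(path, index=False, float_format="%.17g")
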