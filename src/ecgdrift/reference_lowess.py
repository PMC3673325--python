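"""Robust locally weighted regression (LOWESS) baseline estimator.

This is the comparator method for the ICA pipeline: at each sample a local
polynomial is fitted by weighted least squares over the ``span`` nearest
samples with tricube distance weights, followed by robustness iterations that
bisquare-downweight residuals scaled by 6 * median |residual|. The fitted
trend is the baseline; subtracting it yields the drift-free signal.

The default span of 1500 samples corresponds to 3 s at a 500 Hz sampling
rate, a window long enough to straddle individual beats while tracking
respiratory-band drift.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._kernels import lowess_kernel
from .errors import ConfigError, InputError
from .signal import Signal

__all__ = ["LowessConfig", "lowess_baseline", "remove_baseline_reference"]


@dataclass(frozen=True)
class LowessConfig:
    """Smoother parameters.

    span: window size in samples (default 1500 = 3 s at 500 Hz).
    degree: local polynomial degree (default 1).
    robust_iters: bisquare robustness iterations (default 2).
    """

    span: int = 1500
    degree: int = 1
    robust_iters: int = 2

    def __post_init__(self):
        if self.degree < 0:
            raise ConfigError(f"degree must be >= 0, got {self.degree}")
        if self.span < self.degree + 2:
            raise ConfigError(
                f"span must be >= degree + 2 = {self.degree + 2}, got {self.span}"
            )
        if self.robust_iters < 0:
            raise ConfigError(f"robust_iters must be >= 0, got {self.robust_iters}")


def lowess_baseline(signal: Signal, cfg: LowessConfig = LowessConfig()) -> Signal:
    """Fitted LOWESS trend of ``signal``, same length as the input.

    Interior windows are symmetric; at the edges the window slides to stay
    in-bounds (no reflection or padding).
    """
    n = len(signal)
    if cfg.span > n:
        raise InputError(f"span {cfg.span} exceeds signal length {n}")
    fit = lowess_kernel(signal.samples, int(cfg.span), int(cfg.degree), int(cfg.robust_iters))
    return Signal(fit, signal.fs)


def remove_baseline_reference(
    signal: Signal, cfg: LowessConfig = LowessConfig()
) -> tuple[Signal, Signal]:
    """(clean, baseline) where clean = signal - lowess_baseline(signal)."""
    baseline = lowess_baseline(signal, cfg)
    clean = Signal(signal.samples - baseline.samples, signal.fs)
    return clean, baseline
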