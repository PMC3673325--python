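"""Adaptive LMS notch / noise-cancelling filter with design analytics.

The filter is an N-stage tapped-delay-line LMS canceller whose reference input
is a sinusoid x(k) = C cos(w_r k T + theta) at the frequency to be excluded.
Per-sample recursion (weights start at zero):

    y_k = w_k^T x_k,   e_k = d_k - y_k,   w_{k+1} = w_k + step * e_k * x_k

In steady state the canceller behaves like a sharp linear notch at w_r whose
transfer function is

    H(z) = (z^2 - 2 z cos(w_r T) + 1)
           / (z^2 - 2 (1 - N*step*C^2/4) z cos(w_r T) + (1 - N*step*C^2/2))

with approximate -3 dB bandwidth BW = N*step*C^2 / (2T) rad/s. With w_r = 0
the notch sits at DC and the filter acts as a drift-removing high-pass; the
cancelled path (the interference estimate y) is then the low-frequency
sub-signal used downstream by the ICA stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import matmul_toeplitz
from scipy.signal import csd, welch

from ._kernels import lms_kernel
from .errors import ConfigError, DataError, DivergenceError, InputError, PoleError
from .signal import Signal

__all__ = [
    "NotchConfig",
    "NotchResult",
    "DC_MODE",
    "POWERLINE_60HZ",
    "make_reference",
    "lms_cancel",
    "notch_filter",
    "transfer_magnitude",
    "beta",
    "design_bandwidth",
    "stability_limit",
    "empirical_response",
    "measured_bandwidth",
    "steady_state_skip",
]


@dataclass(frozen=True)
class NotchConfig:
    """Parameter set of the adaptive notch filter.

    n_taps
        Tap count N of the delay line.
    step
        Adaptation constant (>= 0; 0 freezes the weights so the filter passes
        the input through). Stability requires step < 1/lambda_max of the
        reference correlation matrix; see :func:`stability_limit`.
    amplitude
        Reference amplitude C (>= 0).
    omega
        Reference angular frequency w_r in rad/s (>= 0; 0 selects DC mode).
    phase
        Reference phase theta in radians.
    """

    n_taps: int
    step: float
    amplitude: float = 0.1
    omega: float = 0.0
    phase: float = 0.0

    def __post_init__(self):
        if int(self.n_taps) < 1:
            raise ConfigError(f"n_taps must be >= 1, got {self.n_taps}")
        object.__setattr__(self, "n_taps", int(self.n_taps))
        if self.step < 0:
            raise ConfigError(f"step must be >= 0, got {self.step}")
        if self.amplitude < 0:
            raise ConfigError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.omega < 0:
            raise ConfigError(f"omega must be >= 0, got {self.omega}")


#: Drift-removal (high-pass) configuration: notch at DC.
DC_MODE = NotchConfig(n_taps=10_000, step=1e-4, amplitude=0.1, omega=0.0)

#: Powerline-interference configuration: notch at 60 Hz.
POWERLINE_60HZ = NotchConfig(n_taps=2048, step=1e-3, amplitude=0.1, omega=2 * np.pi * 60.0)


@dataclass(frozen=True)
class NotchResult:
    """Output of one adaptive-cancellation run.

    ``output`` is the error sequence e (the cleaned signal),
    ``interference_estimate`` is the cancelled path y, and the exact identity
    output + interference_estimate == primary holds sample-wise.
    ``final_weights`` is the length-N weight vector, most-recent tap first.
    """

    output: Signal
    interference_estimate: Signal
    final_weights: np.ndarray


def make_reference(n: int, fs: float, cfg: NotchConfig, first_index: int = 0) -> Signal:
    """Sinusoidal reference x(k) = C cos(w_r k T + theta) for k starting at
    ``first_index`` (negative values give the analytic pre-history)."""
    if n < 1:
        raise InputError(f"reference length must be >= 1, got {n}")
    k = np.arange(first_index, first_index + n, dtype=np.float64)
    samples = cfg.amplitude * np.cos(cfg.omega * k / fs + cfg.phase)
    return Signal(samples, fs)


def stability_limit(reference: Signal, n_taps: int, iters: int = 40) -> float:
    """Estimate the LMS stability bound 1/lambda_max for this reference.

    lambda_max is the largest eigenvalue of the N x N correlation (Toeplitz)
    matrix of the reference, estimated by power iteration with FFT-based
    Toeplitz matvecs. The adaptation constant must stay below the returned
    value for the mean weight recursion to converge.
    """
    x = reference.samples
    n = x.size
    m = min(n_taps, n)
    # biased autocorrelation, lags 0 .. m-1
    f = np.fft.rfft(x, 2 * n)
    r = np.fft.irfft(f * np.conj(f), 2 * n)[:m] / n
    if r[0] <= 0:
        return np.inf
    rng = np.random.default_rng(0)
    v = rng.standard_normal(m)
    v /= np.linalg.norm(v)
    lam = r[0]
    for _ in range(iters):
        w = matmul_toeplitz((r, r), v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return np.inf
        lam = nrm
        v = w / nrm
    return 1.0 / lam


def lms_cancel(
    primary: Signal,
    reference: Signal,
    n_taps: int,
    step: float,
    *,
    guard: float = 1e12,
    reference_history: np.ndarray | None = None,
    check_stability: bool = True,
) -> NotchResult:
    """Run the LMS recursion of ``primary`` against ``reference``.

    The tapped-delay-line vector holds the ``n_taps`` most recent reference
    samples; pre-history defaults to zeros (an explicit ``reference_history``
    of length n_taps-1, oldest first, may be supplied instead). Weights start
    at zero, so output + interference_estimate == primary exactly from sample
    0. A weight norm above ``guard`` raises :class:`DivergenceError`.
    """
    if len(primary) != len(reference):
        raise InputError(
            f"primary and reference lengths differ: {len(primary)} vs {len(reference)}"
        )
    if primary.fs != reference.fs:
        raise InputError(f"sampling rates differ: {primary.fs} vs {reference.fs}")
    n_taps = int(n_taps)
    if n_taps < 1:
        raise InputError(f"n_taps must be >= 1, got {n_taps}")
    if step < 0:
        raise InputError(f"step must be >= 0, got {step}")
    d = primary.samples
    x = reference.samples
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(x))):
        raise DataError("non-finite sample encountered in primary or reference")
    if reference_history is None:
        hist = np.zeros(n_taps - 1)
    else:
        hist = np.asarray(reference_history, dtype=np.float64)
        if hist.shape != (n_taps - 1,):
            raise InputError(
                f"reference_history must have length n_taps-1={n_taps - 1}, got {hist.size}"
            )
    if check_stability and step > 0:
        limit = stability_limit(reference, n_taps)
        if step >= limit:
            warnings.warn(
                f"step={step:g} is at or above the stability bound "
                f"1/lambda_max~={limit:g}; the recursion is expected to diverge",
                stacklevel=2,
            )
    xfull = np.concatenate([hist, x])
    y, e, w, diverged_at = lms_kernel(d, xfull, n_taps, float(step), float(guard), 64)
    if diverged_at >= 0:
        raise DivergenceError(
            f"adaptive weights diverged at sample {diverged_at} "
            f"(norm guard {guard:g}); reduce step below the stability bound",
            diverged_at,
        )
    return NotchResult(
        output=Signal(e, primary.fs),
        interference_estimate=Signal(y, primary.fs),
        final_weights=w[::-1].copy(),
    )


def notch_filter(signal: Signal, cfg: NotchConfig = DC_MODE, *, guard: float = 1e12) -> NotchResult:
    """Apply the adaptive notch described by ``cfg`` to ``signal``.

    The sinusoidal reference is synthesized internally; because it is a known
    deterministic waveform, the delay line is pre-filled with its analytic
    continuation (samples k = -(N-1)..-1) so no tap-fill transient occurs —
    only the weight-adaptation transient (on the order of 1/BW seconds)
    remains.
    """
    n = len(signal)
    if n < cfg.n_taps:
        warnings.warn(
            f"signal length {n} is below the tap count {cfg.n_taps}; "
            "the filter will not reach its design bandwidth",
            stacklevel=2,
        )
    ref = make_reference(n, signal.fs, cfg)
    hist = (
        make_reference(cfg.n_taps - 1, signal.fs, cfg, first_index=-(cfg.n_taps - 1)).samples
        if cfg.n_taps > 1
        else None
    )
    return lms_cancel(
        signal, ref, cfg.n_taps, cfg.step, guard=guard, reference_history=hist
    )


def transfer_magnitude(cfg: NotchConfig, fs: float, freq) -> float | np.ndarray:
    """|H| of the converged notch at ``freq`` Hz (scalar or array).

    Evaluates the closed-form transfer function at z = exp(j 2 pi f T).
    """
    freq = np.asarray(freq, dtype=np.float64)
    if np.any(freq < 0) or np.any(freq > fs / 2):
        raise InputError("freq must lie in [0, fs/2]")
    T = 1.0 / fs
    z = np.exp(2j * np.pi * freq * T)
    c = np.cos(cfg.omega * T)
    k = cfg.n_taps * cfg.step * cfg.amplitude**2
    num = z * z - 2 * z * c + 1
    if k == 0:
        # numerator and denominator coincide: |H| = 1 identically
        out = np.ones_like(freq, dtype=np.float64)
        return float(out) if out.ndim == 0 else out
    den = z * z - 2 * (1 - k / 4) * z * c + (1 - k / 2)
    if np.any(np.abs(den) < 1e-15):
        raise PoleError("transfer-function denominator is numerically zero")
    out = np.abs(num / den)
    return float(out) if out.ndim == 0 else out


def beta(n_taps: int, omega: float, T: float) -> float:
    """Time-varying-component factor beta = sin(N w_r T) / sin(w_r T).

    At singular points of the closed form (w_r T a multiple of pi) the
    L'Hopital limit N cos(N w_r T)/cos(w_r T) is returned; at w_r T -> 0 this
    is N.
    """
    x = omega * T
    s = np.sin(x)
    if abs(s) < 1e-9:
        return n_taps * np.cos(n_taps * x) / np.cos(x)
    return float(np.sin(n_taps * x) / s)


def design_bandwidth(cfg: NotchConfig, T: float) -> float:
    """Approximate notch bandwidth BW = N * step * C^2 / (2T), in rad/s."""
    if not T > 0:
        raise InputError(f"sampling interval must be > 0, got {T}")
    return cfg.n_taps * cfg.step * cfg.amplitude**2 / (2.0 * T)


def steady_state_skip(cfg: NotchConfig, fs: float) -> int:
    """Samples to discard before treating the filter as converged
    (max of the tap count and 2 seconds)."""
    return max(cfg.n_taps, int(round(2.0 * fs)))


def empirical_response(
    cfg: NotchConfig,
    fs: float,
    duration: float = 60.0,
    seed: int = 0,
    nperseg: int = 5000,
):
    """Measure the steady-state frequency response with a white-noise probe.

    Filters ``duration`` seconds of unit-variance white noise, discards the
    start-up region, and estimates |H| with the cross-spectral (H1) estimator
    csd(x, e) / psd(x). Returns (freqs_hz, magnitude).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(round(duration * fs)))
    res = notch_filter(Signal(x, fs), cfg)
    skip = steady_state_skip(cfg, fs)
    if skip >= x.size - nperseg:
        raise InputError("probe too short for the requested steady-state region")
    xin = x[skip:]
    xout = res.output.samples[skip:]
    f, pxx = welch(xin, fs=fs, nperseg=nperseg)
    _, pxy = csd(xin, xout, fs=fs, nperseg=nperseg)
    return f, np.abs(pxy) / pxx


def measured_bandwidth(freqs: np.ndarray, mag: np.ndarray, center_hz: float) -> float:
    """-3 dB notch width (rad/s) from a measured magnitude response.

    Finds, by linear interpolation, the frequencies nearest ``center_hz`` on
    each side at which |H| crosses 1/sqrt(2).
    """
    thr = 1.0 / np.sqrt(2.0)
    ic = int(np.argmin(np.abs(freqs - center_hz)))
    lo = None
    for i in range(ic, 0, -1):
        if mag[i - 1] >= thr > mag[i]:
            lo = freqs[i - 1] + (freqs[i] - freqs[i - 1]) * (mag[i - 1] - thr) / (
                mag[i - 1] - mag[i]
            )
            break
    hi = None
    for i in range(ic, freqs.size - 1):
        if mag[i] < thr <= mag[i + 1]:
            hi = freqs[i] + (freqs[i + 1] - freqs[i]) * (thr - mag[i]) / (
                mag[i + 1] - mag[i]
            )
            break
    if lo is None or hi is None:
        raise InputError("could not locate both -3 dB crossings around the notch")
    return 2 * np.pi * (hi - lo)


def dc_design(n_taps: int = 10_000, step: float = 1e-4, amplitude: float = 0.1) -> NotchConfig:
    """Convenience constructor for a DC (drift-removal) configuration."""
    return replace(DC_MODE, n_taps=n_taps, step=step, amplitude=amplitude)
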