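"""Synthetic single-lead ECG with ground-truth baseline wander.

Each record is an exact sum of four independently generated parts —

    mixture = ecg_clean + wander_true + powerline_true + noise

— so every stage of the removal pipeline can be scored against a known truth.
Beats are sums of five Gaussian bumps (P, Q, R, S, T) placed at RR intervals
derived from the heart rate (with optional beat-to-beat jitter); the clean
ECG is mean-removed per record, mirroring AC-coupled acquisition. Baseline
wander is a sparse sum of sinusoids confined to the respiratory/motion band
0.05-0.5 Hz, optionally shaped by a piecewise-linear amplitude envelope to
emulate slowly drifting wander strength. Powerline interference is a 60 Hz
sinusoid; measurement noise is white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .signal import Signal

__all__ = [
    "Wave",
    "SynthSpec",
    "SynthRecord",
    "default_waves",
    "default_wander",
    "generate",
    "lbnp_like_suite",
    "standard_suite",
    "write_record",
    "read_record",
]

WANDER_BAND = (0.05, 0.5)  # Hz; respiratory / electrode-motion drift band


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude, center offset from the R peak (s), width (s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if not self.width > 0:
            raise ConfigError(f"wave width must be > 0, got {self.width}")


def default_waves() -> tuple[Wave, ...]:
    """Textbook lead-II-like P-QRS-T morphology, R amplitude 1.0."""
    return (
        Wave(0.12, -0.200, 0.025),  # P
        Wave(-0.10, -0.035, 0.010),  # Q
        Wave(1.00, 0.000, 0.012),  # R
        Wave(-0.15, 0.035, 0.010),  # S
        Wave(0.35, 0.300, 0.050),  # T
    )


def default_wander(amplitude: float = 1.0) -> tuple[tuple[float, float, float], ...]:
    """Three in-band sinusoids whose absolute amplitudes sum to ``amplitude``."""
    return (
        (0.08, 0.6 * amplitude, 0.0),
        (0.21, 0.3 * amplitude, 1.3),
        (0.45, 0.1 * amplitude, 2.1),
    )


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic record (deterministic given seed)."""

    fs: float = 500.0
    duration: float = 60.0
    heart_rate: float = 72.0
    hr_jitter: float = 0.02  # fractional beat-to-beat RR jitter
    waves: tuple[Wave, ...] = field(default_factory=default_waves)
    wander: tuple[tuple[float, float, float], ...] = field(
        default_factory=default_wander
    )  # (freq Hz, amplitude, phase)
    envelope: tuple[tuple[float, float], ...] | None = None  # (time s, gain)
    powerline: tuple[float, float, float] = (0.0, 60.0, 0.0)  # (amp, freq, phase)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (self.fs > 0 and self.duration > 0):
            raise ConfigError("fs and duration must be positive")
        if not self.heart_rate > 0:
            raise ConfigError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for f, _a, _p in self.wander:
            if not WANDER_BAND[0] <= f <= WANDER_BAND[1]:
                raise ConfigError(
                    f"wander frequency {f} Hz outside band {WANDER_BAND}"
                )
        if self.envelope is not None and len(self.envelope) < 2:
            raise ConfigError("envelope needs at least two (time, gain) breakpoints")

    @property
    def r_amplitude(self) -> float:
        return max(abs(w.amplitude) for w in self.waves)


@dataclass(frozen=True)
class SynthRecord:
    """Generated record; mixture == ecg_clean + wander_true + powerline_true + noise."""

    mixture: Signal
    ecg_clean: Signal
    wander_true: Signal
    powerline_true: Signal
    noise: Signal
    spec: SynthSpec


def _beat_centers(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    rr = 60.0 / spec.heart_rate
    centers = []
    c = 0.3  # first R peak at 0.3 s
    while c < spec.duration + 0.3:
        centers.append(c)
        step = rr * (1.0 + spec.hr_jitter * rng.standard_normal())
        c += max(step, 0.3 * rr)
    return np.asarray(centers)


def generate(spec: SynthSpec = SynthSpec()) -> SynthRecord:
    """Build one record; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    ecg = np.zeros(n)
    for c in _beat_centers(spec, rng):
        for w in spec.waves:
            mu = c + w.center
            lo = max(0, int((mu - 6 * w.width) * spec.fs))
            hi = min(n, int((mu + 6 * w.width) * spec.fs) + 1)
            if hi > lo:
                tt = t[lo:hi] - mu
                ecg[lo:hi] += w.amplitude * np.exp(-tt * tt / (2 * w.width**2))
    ecg -= ecg.mean()  # AC-coupled front end: recorded ECG is zero-mean

    wander = np.zeros(n)
    for f, a, ph in spec.wander:
        wander += a * np.cos(2 * np.pi * f * t + ph)
    if spec.envelope is not None:
        bt = np.asarray([p[0] for p in spec.envelope])
        bg = np.asarray([p[1] for p in spec.envelope])
        wander *= np.interp(t, bt, bg)

    pamp, pfreq, pph = spec.powerline
    powerline = pamp * np.cos(2 * np.pi * pfreq * t + pph)

    noise = spec.noise_sd * rng.standard_normal(n)

    fs = spec.fs
    return SynthRecord(
        mixture=Signal(ecg + wander + powerline + noise, fs),
        ecg_clean=Signal(ecg, fs),
        wander_true=Signal(wander, fs),
        powerline_true=Signal(powerline, fs),
        noise=Signal(noise, fs),
        spec=spec,
    )


def _subject_seeds(n: int, seed: int) -> np.ndarray:
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    # enforce distinctness deterministically
    seen = set()
    for i in range(n):
        while int(seeds[i]) in seen:
            seeds[i] = (seeds[i] + 1) % (2**31)
        seen.add(int(seeds[i]))
    return seeds


def _random_spec(
    rng: np.random.Generator,
    sub_seed: int,
    duration: float,
    amp: float,
    drifting: bool,
) -> SynthSpec:
    freqs = np.sort(rng.uniform(*WANDER_BAND, size=3))
    rel = rng.dirichlet(np.ones(3))
    phases = rng.uniform(0, 2 * np.pi, size=3)
    wander = tuple(
        (float(f), float(amp * r), float(p)) for f, r, p in zip(freqs, rel, phases)
    )
    envelope = None
    if drifting:
        g0, g1 = rng.uniform(0.5, 1.5, size=2)
        envelope = ((0.0, float(g0)), (duration, float(g1)))
    return SynthSpec(
        duration=duration,
        heart_rate=float(rng.uniform(60.0, 90.0)),
        wander=wander,
        envelope=envelope,
        seed=int(sub_seed),
    )


def lbnp_like_suite(
    n_subjects: int,
    seed: int = 0,
    duration: float = 60.0,
    amp_range: tuple[float, float] = (0.2, 3.0),
    drifting: bool = True,
) -> list[SynthRecord]:
    """Randomized cohort emulating a lower-body-negative-pressure study.

    Wander amplitudes span ``amp_range`` times the R amplitude with drifting
    (piecewise-linear) envelopes; at least one record has wander amplitude
    above the R amplitude by construction.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = _subject_seeds(n_subjects, seed)
    amps = rng.uniform(*amp_range, size=n_subjects)
    amps[0] = max(amps[0], 1.2)  # guarantee a strong-wander record
    return [
        generate(_random_spec(rng, s, duration, a, drifting))
        for s, a in zip(seeds, amps)
    ]


def standard_suite(
    n_subjects: int = 20, seed: int = 0, duration: float = 60.0, drifting: bool = False
) -> list[SynthRecord]:
    """Default evaluation suite.

    Each record keeps the default beat template, heart rate, and wander
    spectral shape; across records the summed wander amplitude spans 0.5-2x
    the R amplitude, the sinusoid phases are randomized, and the record seed
    (beat jitter, noise) varies. ``drifting`` adds a piecewise-linear
    amplitude envelope per record.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = _subject_seeds(n_subjects, seed)
    amps = rng.uniform(0.5, 2.0, size=n_subjects)
    out = []
    for s, a in zip(seeds, amps):
        base = default_wander(float(a))
        phases = rng.uniform(0, 2 * np.pi, size=len(base))
        wander = tuple((f, amp, float(p)) for (f, amp, _), p in zip(base, phases))
        envelope = None
        if drifting:
            g0, g1 = rng.uniform(0.5, 1.5, size=2)
            envelope = ((0.0, float(g0)), (duration, float(g1)))
        out.append(
            generate(
                SynthSpec(
                    duration=duration, wander=wander, envelope=envelope, seed=int(s)
                )
            )
        )
    return out


_COLUMNS = ("t", "mixture", "ecg_clean", "wander_true", "powerline_true", "noise")


def write_record(record: SynthRecord, path) -> None:
    """Write all ground-truth columns as CSV (t, mixture, components)."""
    df = pd.DataFrame(
        {
            "t": record.mixture.time(),
            "mixture": record.mixture.samples,
            "ecg_clean": record.ecg_clean.samples,
            "wander_true": record.wander_true.samples,
            "powerline_true": record.powerline_true.samples,
            "noise": record.noise.samples,
        }
    )
    df.to_csv(path, index=False)


def read_record(path) -> dict[str, Signal]:
    """Read a ground-truth CSV back as a dict of Signals (keyed by column)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"record file {path} missing columns {missing}")
    t = df["t"].to_numpy()
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt))
    return {c: Signal(df[c].to_numpy(), fs) for c in _COLUMNS if c != "t"}
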