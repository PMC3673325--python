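import numpy as np
import pytest
from hypothesis import settings

import ecgdrift as ed

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ecg_record():
    """One default 60-s synthetic record with known wander."""
    return ed.generate(ed.SynthSpec(duration=60.0, seed=7))


@pytest.fixture(scope="session")
def zero_wander_record():
    """A drift-free record (wander, powerline both absent)."""
    return ed.generate(ed.SynthSpec(duration=60.0, seed=11, wander=()))


@pytest.fixture(scope="session")
def pipeline_run(ecg_record):
    """Blind-mode pipeline output on the default record."""
    clean, est, report = ed.remove_baseline(ecg_record.mixture)
    return ecg_record, clean, est, report


def lowess_oracle(y, span, degree, robust_iters):
    """Brute-force robust locally weighted regression.

    Explicitly forms and solves each local weighted least-squares system with
    a square-root-weighted Vandermonde design and numpy's lstsq; tricube
    distance weights over the span nearest samples (window slides in-bounds
    at the edges), then bisquare reweighting by residual/(6 median |residual|).
    Independent of the production kernel.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    fit = np.zeros(n)
    delta = np.ones(n)
    for it in range(robust_iters + 1):
        for i in range(n):
            lo = min(max(i - span // 2, 0), n - span)
            hi = lo + span
            idx = np.arange(lo, hi)
            dmax = max(i - lo, hi - 1 - i)
            d = np.abs(idx - i) / dmax
            w = np.clip(1 - d**3, 0, None) ** 3 * delta[lo:hi]
            X = np.vander(idx - i, degree + 1, increasing=True)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y[lo:hi] * sw, rcond=None)
            fit[i] = coef[0]
        if it < robust_iters:
            r = np.abs(y - fit)
            s = np.median(r)
            if s <= 0:
                delta = np.ones(n)
            else:
                delta = np.clip(1 - (r / (6 * s)) ** 2, 0, None) ** 2
    return fit
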