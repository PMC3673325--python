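"""Numba inner loops for the LMS recursion and the robust LOWESS smoother.

These are the only per-sample loops in the package; everything else is
vectorized numpy. Both kernels are pure functions of their array arguments so
the surrounding modules own all validation and error reporting.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lms_kernel(d, xfull, n_taps, step, guard, check_every):
    """LMS adaptive canceller.

    d : desired/primary sequence, length n.
    xfull : reference including n_taps-1 samples of pre-history, length
        n + n_taps - 1; xfull[i] is the reference at time i - (n_taps - 1).
    Returns (y, e, w_oldest_first, diverged_at); diverged_at is -1 on success,
    otherwise the sample index at which the weight norm crossed ``guard``.
    """
    n = d.size
    w = np.zeros(n_taps)  # w[i] multiplies the tap that is (n_taps-1-i) old
    y = np.zeros(n)
    e = np.zeros(n)
    guard2 = guard * guard
    diverged_at = -1
    for k in range(n):
        acc = 0.0
        for i in range(n_taps):
            acc += w[i] * xfull[k + i]
        y[k] = acc
        ek = d[k] - acc
        e[k] = ek
        if not np.isfinite(ek):
            diverged_at = k
            break
        g = step * ek
        for i in range(n_taps):
            w[i] += g * xfull[k + i]
        if (k % check_every) == 0:
            ss = 0.0
            for i in range(n_taps):
                ss += w[i] * w[i]
            if ss > guard2:
                diverged_at = k
                break
    return y, e, w, diverged_at


@njit(cache=True)
def lowess_kernel(y, span, degree, robust_iters):
    """Robust locally weighted polynomial regression on a unit integer grid.

    At each point i a degree-``degree`` polynomial is fitted by weighted least
    squares over the ``span`` nearest samples (window slides to stay in-bounds
    at the edges) with tricube distance weights; ``robust_iters`` rounds of
    bisquare reweighting by residual / (6 * median |residual|) follow.
    """
    n = y.size
    fit = np.empty(n)
    delta = np.ones(n)
    half = span // 2
    p = degree + 1
    M = np.zeros((p, p))
    b = np.zeros(p)
    pw = np.empty(2 * p - 1)
    for it in range(robust_iters + 1):
        for i in range(n):
            lo = i - half
            if lo < 0:
                lo = 0
            if lo > n - span:
                lo = n - span
            hi = lo + span
            dmax = float(max(i - lo, hi - 1 - i))
            for a in range(p):
                b[a] = 0.0
                for c in range(p):
                    M[a, c] = 0.0
            npos = 0
            wsum = 0.0
            wysum = 0.0
            for j in range(lo, hi):
                dist = abs(j - i) / dmax
                if dist >= 1.0:
                    w = 0.0
                else:
                    t = 1.0 - dist * dist * dist
                    w = t * t * t
                w *= delta[j]
                if w <= 0.0:
                    continue
                npos += 1
                wsum += w
                wysum += w * y[j]
                xx = float(j - i)
                v = 1.0
                for q in range(2 * p - 1):
                    pw[q] = v
                    v *= xx
                for a in range(p):
                    for c in range(p):
                        M[a, c] += w * pw[a + c]
                    b[a] += w * pw[a] * y[j]
            if npos >= p:
                coef = np.linalg.solve(M, b)
                fit[i] = coef[0]
            elif wsum > 0.0:
                # too few robust-weighted points for the polynomial: local mean
                fit[i] = wysum / wsum
            else:
                fit[i] = y[i]
        if it < robust_iters:
            r = np.abs(y - fit)
            s = np.median(r)
            if s <= 0.0:
                for j in range(n):
                    delta[j] = 1.0
            else:
                for j in range(n):
                    u = r[j] / (6.0 * s)
                    if u >= 1.0:
                        delta[j] = 0.0
                    else:
                        t = 1.0 - u * u
                        delta[j] = t * t
    return fit
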