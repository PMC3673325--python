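"""Fixed-point (negentropy-based) independent component analysis, from scratch.

The estimator follows the classical fixed-point scheme: center the mixtures,
whiten them through the eigendecomposition of the covariance matrix
(z = D V^{-1/2} D^T y), then extract one unit vector at a time by the
iteration

    w' = E{z g(w^T z)} - E{g'(w^T z)} w,   w = w' / ||w'||

with deflation (Gram-Schmidt against previously found rows). Convergence is
directional: |<w_new, w_old>| > 1 - tol. Non-Gaussianity is measured through
the standard contrast functions g1 = tanh(a1 y), g2 = y exp(-a2 y^2/2),
g3 = y^3, and the negentropy approximation J(y) = [E G(y) - E G(v)]^2 with v
standard Gaussian.

Components are identifiable only up to sign, scale, and permutation; the
returned mixing estimate maps unit-variance components back onto the centered
mixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, InputError, RankDeficiencyWarning, RankError

__all__ = [
    "MixtureMatrix",
    "WhiteningModel",
    "ICAModel",
    "center",
    "whiten",
    "contrast",
    "negentropy_approx",
    "fastica_one_unit",
    "fastica",
]


@dataclass(frozen=True)
class MixtureMatrix:
    """n_channels x n_samples matrix of mixture signals (one row per channel)."""

    data: np.ndarray
    fs: float
    offsets: np.ndarray | None = None  # per-channel alignment offsets, in samples

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2:
            raise InputError(f"data must be 2-D, got shape {arr.shape}")
        n_ch, n_s = arr.shape
        if n_s <= n_ch:
            raise InputError(
                f"need more samples than channels, got {n_ch} channels x {n_s} samples"
            )
        if not np.all(np.isfinite(arr)):
            raise DataError("mixture matrix contains non-finite entries")
        object.__setattr__(self, "data", arr)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WhiteningModel:
    """Whitening transform derived from the covariance eigendecomposition.

    ``transform`` maps centered channels to unit-covariance coordinates. At
    full rank it is the symmetric form D V^{-1/2} D^T (n x n); when
    eigenvalues fall below the variance floor the reduced rectangular form
    V_r^{-1/2} D_r^T (rank x n) is used instead.
    """

    means: np.ndarray
    transform: np.ndarray
    eigvecs: np.ndarray
    eigvals: np.ndarray

    @property
    def rank(self) -> int:
        return self.transform.shape[0]


@dataclass(frozen=True)
class ICAModel:
    """Result of a full ICA fit.

    unmixing: rows are the unit-norm weight vectors in whitened coordinates
    (n_components x rank). components: n_components x n_samples, unit variance.
    mixing_estimate: least-squares map from components back to the centered
    mixtures (n_channels x n_components).
    """

    whitening: WhiteningModel
    unmixing: np.ndarray
    components: np.ndarray
    mixing_estimate: np.ndarray
    iterations: tuple[int, ...]
    converged: tuple[bool, ...]
    fs: float = field(default=1.0)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def center(X: MixtureMatrix) -> tuple[MixtureMatrix, np.ndarray]:
    """Remove each channel's mean; returns the centered matrix and the means."""
    means = X.data.mean(axis=1)
    return MixtureMatrix(X.data - means[:, None], X.fs, X.offsets), means


def whiten(
    X: MixtureMatrix,
    var_floor: float = 1e-12,
    means: np.ndarray | None = None,
    n_keep: int | None = None,
) -> tuple[np.ndarray, WhiteningModel]:
    """Whiten centered mixtures via the covariance eigendecomposition.

    Eigenvalues below ``var_floor`` times the largest are dropped with a
    :class:`RankDeficiencyWarning`; ``n_keep`` additionally truncates to the
    leading eigen-directions (PCA dimension reduction). Returns (Z, model)
    with sample covariance of Z equal to the identity.
    """
    Y = X.data
    n = X.n_samples
    cov = (Y @ Y.T) / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    if vals[0] <= 0:
        raise RankError("covariance has no positive eigenvalue (all-zero input?)")
    keep = vals > var_floor * vals[0]
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} of {vals.size} dimensions below the "
            "variance floor",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    rank = int(keep.sum())
    if n_keep is not None:
        if n_keep > rank:
            raise RankError(f"requested {n_keep} dimensions but rank is {rank}")
        rank = n_keep
    if means is None:
        means = np.zeros(X.n_channels)
    if rank == X.n_channels:
        transform = vecs @ np.diag(vals**-0.5) @ vecs.T
    else:
        transform = np.diag(vals[:rank] ** -0.5) @ vecs[:, :rank].T
    Z = transform @ Y
    model = WhiteningModel(means=means, transform=transform, eigvecs=vecs, eigvals=vals)
    return Z, model


_CONTRASTS = ("g1", "g2", "g3")


def contrast(u, kind: str = "g1", a1: float = 1.0, a2: float = 1.0):
    """Evaluate the contrast derivative pair (g(u), g'(u)).

    g1(y) = tanh(a1 y), g2(y) = y exp(-a2 y^2/2), g3(y) = y^3, with exact
    first derivatives. ``a1`` conventionally lies in [1, 2]; ``a2`` near 1.
    """
    u = np.asarray(u, dtype=np.float64)
    if kind == "g1":
        g = np.tanh(a1 * u)
        gp = a1 * (1.0 - g * g)
    elif kind == "g2":
        e = np.exp(-a2 * u * u / 2.0)
        g = u * e
        gp = (1.0 - a2 * u * u) * e
    elif kind == "g3":
        g = u**3
        gp = 3.0 * u * u
    else:
        raise ConfigError(f"unknown contrast kind {kind!r}; expected one of {_CONTRASTS}")
    return g, gp


def _contrast_G(u, kind: str, a1: float, a2: float):
    """Antiderivative G used by the negentropy approximation."""
    u = np.asarray(u, dtype=np.float64)
    if kind == "g1":
        # log cosh via logaddexp for overflow safety
        au = a1 * u
        return (np.logaddexp(au, -au) - np.log(2.0)) / a1
    if kind == "g2":
        return -np.exp(-a2 * u * u / 2.0) / a2
    if kind == "g3":
        return u**4 / 4.0
    raise ConfigError(f"unknown contrast kind {kind!r}; expected one of {_CONTRASTS}")


def _gaussian_expectation_G(kind: str, a1: float, a2: float, order: int = 96) -> float:
    """E{G(v)} for standard-Gaussian v, by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    vals = _contrast_G(np.sqrt(2.0) * nodes, kind, a1, a2)
    return float(np.sum(weights * vals) / np.sqrt(np.pi))


def negentropy_approx(y, kind: str = "g1", a1: float = 1.0, a2: float = 1.0) -> float:
    """Nonnegative negentropy approximation [E G(y) - E G(v)]^2.

    ``y`` is standardized to zero mean, unit variance internally; a
    zero-variance input is rejected. The value tends to 0 for Gaussian data
    and grows with departure from Gaussianity.
    """
    y = np.asarray(y, dtype=np.float64)
    sd = y.std()
    if not sd > 0:
        raise DataError("negentropy is undefined for zero-variance input")
    ys = (y - y.mean()) / sd
    ey = float(np.mean(_contrast_G(ys, kind, a1, a2)))
    return (ey - _gaussian_expectation_G(kind, a1, a2)) ** 2


def fastica_one_unit(
    Z: np.ndarray,
    w0: np.ndarray,
    kind: str = "g1",
    a1: float = 1.0,
    a2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    decorrelate_against: np.ndarray | None = None,
) -> tuple[np.ndarray, int, bool]:
    """One-unit fixed-point iteration on whitened data ``Z`` (rank x n).

    Starting from unit vector ``w0``, iterates the negentropy fixed point,
    Gram-Schmidt-decorrelates against previously found rows, and normalizes.
    Stops on direction convergence |<w_new, w_old>| > 1 - tol or at
    ``max_iter`` with a non-convergence flag (no exception; the caller
    decides).
    """
    n = Z.shape[1]
    w = np.asarray(w0, dtype=np.float64)
    w = w / np.linalg.norm(w)
    B = decorrelate_against
    if B is not None and B.size == 0:
        B = None
    for it in range(1, max_iter + 1):
        u = w @ Z
        g, gp = contrast(u, kind, a1, a2)
        w_new = (Z @ g) / n - gp.mean() * w
        if B is not None:
            w_new = w_new - B.T @ (B @ w_new)
        nrm = np.linalg.norm(w_new)
        if nrm < 1e-12:
            return w, it, False
        w_new /= nrm
        if abs(w_new @ w) > 1.0 - tol:
            return w_new, it, True
        w = w_new
    return w, max_iter, False


def fastica(
    X: MixtureMatrix,
    n_components: int | None = None,
    kind: str = "g1",
    a1: float = 1.0,
    a2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    restarts: int = 3,
    var_floor: float = 1e-12,
) -> ICAModel:
    """Full ICA fit: center, whiten, then deflationary one-unit extraction.

    ``n_components`` (at most the rank after whitening) selects the leading
    eigen-directions kept at the whitening step — where most signal variance
    lives — and one unit is extracted per retained dimension, sequentially,
    with seeded random unit-vector initializations. A unit that fails to
    converge is restarted up to ``restarts`` times with fresh initializations
    before being flagged. The result is fully reproducible for a fixed seed.
    """
    Xc, means = center(X)
    Z, wm = whiten(Xc, var_floor=var_floor, means=means)
    rank = wm.rank
    if n_components is None:
        n_components = rank
    if not 1 <= n_components <= rank:
        raise ConfigError(
            f"n_components={n_components} outside [1, rank={rank}] after whitening"
        )
    if n_components < rank:
        Z, wm = whiten(Xc, var_floor=var_floor, means=means, n_keep=n_components)
        rank = wm.rank
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    iterations: list[int] = []
    converged: list[bool] = []
    for _ in range(n_components):
        B = np.array(rows) if rows else None
        best = None
        total_it = 0
        for _attempt in range(restarts + 1):
            w0 = rng.standard_normal(rank)
            if B is not None:
                w0 = w0 - B.T @ (B @ w0)
            nrm = np.linalg.norm(w0)
            if nrm < 1e-12:
                continue
            w, it, ok = fastica_one_unit(
                Z, w0 / nrm, kind, a1, a2, tol, max_iter, decorrelate_against=B
            )
            total_it += it
            best = (w, ok)
            if ok:
                break
        if best is None:
            raise RankError("could not initialize a direction orthogonal to prior rows")
        w, ok = best
        rows.append(w)
        iterations.append(total_it)
        converged.append(ok)
    W = np.array(rows)
    S = W @ Z
    A, *_ = np.linalg.lstsq(S.T, Xc.data.T, rcond=None)
    return ICAModel(
        whitening=wm,
        unmixing=W,
        components=S,
        mixing_estimate=A.T,
        iterations=tuple(iterations),
        converged=tuple(converged),
        fs=X.fs,
    )
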