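import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.signal import square

import ecgdrift as ed
from ecgdrift.fastica import fastica_one_unit

FS = 500.0


def _mix(seed=0, n=5000):
    """Random 3x3 mixing of a slow sine, a square wave, and Laplace noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS
    S = np.vstack(
        [np.sin(2 * np.pi * 0.3 * t), square(2 * np.pi * 7 * t), rng.laplace(size=n)]
    )
    A = rng.normal(size=(3, 3))
    return ed.MixtureMatrix(A @ S, FS), S


def _matched_correlations(S, components):
    C = np.corrcoef(np.vstack([S, components]))[: S.shape[0], S.shape[0] :]
    ri, ci = linear_sum_assignment(-np.abs(C))
    return np.abs(C[ri, ci])


class TestCenter:
    @pytest.mark.parametrize(
        "row,expected_row,expected_mean",
        [
            ([1.0, 2.0, 3.0, 2.0], [-1.0, 0.0, 1.0, 0.0], 2.0),
            ([5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 0.0, 0.0], 5.0),
            ([-1.0, 0.0, 1.0, 0.0], [-1.0, 0.0, 1.0, 0.0], 0.0),
        ],
    )
    def test_rows_become_zero_mean(self, row, expected_row, expected_mean):
        X = ed.MixtureMatrix(np.array([row, row]), FS)
        Xc, means = ed.center(X)
        np.testing.assert_allclose(Xc.data[0], expected_row, atol=1e-12)
        assert means[0] == pytest.approx(expected_mean)
        assert abs(Xc.data.mean(axis=1)).max() < 1e-12


class TestWhiten:
    def test_diagonal_covariance_gives_diagonal_transform(self):
        rng = np.random.default_rng(0)
        n = 50_000
        X = ed.MixtureMatrix(
            np.vstack([2.0 * rng.standard_normal(n), 3.0 * rng.standard_normal(n)]), FS
        )
        Xc, _ = ed.center(X)
        _, model = ed.whiten(Xc)
        np.testing.assert_allclose(
            np.abs(model.transform), np.diag([0.5, 1 / 3]), atol=0.02
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_whitened_covariance_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = ed.MixtureMatrix(rng.normal(size=(6, 4000)) * rng.uniform(0.1, 5, (6, 1)), FS)
        Xc, _ = ed.center(X)
        Z, _ = ed.whiten(Xc)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        assert np.max(np.abs(cov - np.eye(Z.shape[0]))) < 1e-8

    def test_zero_input_raises_rank_error(self):
        X = ed.MixtureMatrix(np.zeros((3, 100)), FS)
        with pytest.raises(ed.RankError):
            ed.whiten(X)

    def test_duplicate_rows_warn_and_reduce_rank(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(2000)
        X = ed.MixtureMatrix(np.vstack([row, row, rng.standard_normal(2000)]), FS)
        Xc, _ = ed.center(X)
        with pytest.warns(ed.RankDeficiencyWarning):
            Z, model = ed.whiten(Xc)
        assert model.rank == 2
        assert Z.shape[0] == 2


class TestContrast:
    @pytest.mark.parametrize(
        "kind,u,g_expected,gp_expected",
        [
            ("g1", 0.0, 0.0, 1.0),
            ("g2", 0.0, 0.0, 1.0),
            ("g3", 2.0, 8.0, 12.0),
        ],
    )
    def test_values(self, kind, u, g_expected, gp_expected):
        g, gp = ed.contrast(np.array([u]), kind)
        assert g[0] == pytest.approx(g_expected)
        assert gp[0] == pytest.approx(gp_expected)

    @pytest.mark.parametrize("kind", ["g1", "g2", "g3"])
    def test_derivative_matches_central_difference(self, kind):
        u = np.linspace(-3, 3, 41)
        h = 1e-6
        g_plus, _ = ed.contrast(u + h, kind)
        g_minus, _ = ed.contrast(u - h, kind)
        _, gp = ed.contrast(u, kind)
        np.testing.assert_allclose((g_plus - g_minus) / (2 * h), gp, atol=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ed.ConfigError):
            ed.contrast(np.zeros(3), "g9")


class TestNegentropy:
    def test_gaussian_sample_is_near_zero(self):
        y = np.random.default_rng(0).standard_normal(100_000)
        assert ed.negentropy_approx(y, "g1") < 1e-3

    def test_uniform_exceeds_gaussian(self):
        rng = np.random.default_rng(1)
        g = ed.negentropy_approx(rng.standard_normal(100_000), "g2")
        u = ed.negentropy_approx(rng.uniform(-1, 1, 100_000), "g2")
        assert u > g

    @pytest.mark.parametrize("kind", ["g1", "g2", "g3"])
    def test_nonnegative(self, kind):
        y = np.random.default_rng(2).laplace(size=5000)
        assert ed.negentropy_approx(y, kind) >= 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ed.DataError):
            ed.negentropy_approx(np.ones(100))


class TestOneUnit:
    def test_fixed_point_converges_in_one_iteration(self):
        X, _ = _mix(seed=3)
        model = ed.fastica(X, 3, seed=0)
        Xc, _ = ed.center(X)
        Z, _ = ed.whiten(Xc)
        w, n_iter, ok = fastica_one_unit(Z, model.unmixing[0], max_iter=50)
        assert ok and n_iter == 1

    def test_tighter_tolerance_never_needs_fewer_iterations(self):
        X, _ = _mix(seed=4)
        Xc, _ = ed.center(X)
        Z, _ = ed.whiten(Xc)
        w0 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        _, it_loose, _ = fastica_one_unit(Z, w0, tol=1e-4, max_iter=500)
        _, it_tight, _ = fastica_one_unit(Z, w0, tol=1e-8, max_iter=500)
        assert it_tight >= it_loose

    def test_dominant_super_gaussian_direction_is_found(self):
        rng = np.random.default_rng(5)
        n = 8000
        S = np.vstack([rng.laplace(size=n), rng.standard_normal(n)])
        A = np.array([[1.0, 0.4], [0.3, 1.0]])
        X = ed.MixtureMatrix(A @ S, FS)
        Xc, _ = ed.center(X)
        Z, wm = ed.whiten(Xc)
        w, _, ok = fastica_one_unit(Z, np.array([0.6, 0.8]), max_iter=500)
        assert ok
        comp = w @ Z
        r = abs(np.corrcoef(comp, S[0])[0, 1])
        assert r > np.cos(np.deg2rad(2))


class TestFastICA:
    @pytest.mark.parametrize("kind", ["g1", "g2", "g3"])
    def test_recovers_known_sources(self, kind):
        X, S = _mix(seed=6)
        model = ed.fastica(X, 3, kind=kind, seed=1)
        assert np.all(_matched_correlations(S, model.components) >= 0.95)

    def test_mixing_estimate_reconstructs_centered_data(self):
        X, _ = _mix(seed=7)
        model = ed.fastica(X, 3, seed=2)
        Xc, _ = ed.center(X)
        rec = model.mixing_estimate @ model.components
        rel = np.linalg.norm(rec - Xc.data) / np.linalg.norm(Xc.data)
        assert rel < 1e-6

    def test_seeded_runs_are_byte_identical(self):
        X, _ = _mix(seed=8)
        m1 = ed.fastica(X, 3, seed=9)
        m2 = ed.fastica(X, 3, seed=9)
        assert np.array_equal(m1.components, m2.components)
        assert np.array_equal(m1.unmixing, m2.unmixing)
        assert np.array_equal(m1.mixing_estimate, m2.mixing_estimate)

    def test_unmixing_rows_unit_norm_and_orthogonal(self):
        X, _ = _mix(seed=10)
        model = ed.fastica(X, 3, seed=3)
        G = model.unmixing @ model.unmixing.T
        np.testing.assert_allclose(G, np.eye(3), atol=1e-8)

    def test_components_mutually_uncorrelated(self):
        X, _ = _mix(seed=11)
        model = ed.fastica(X, 3, seed=4)
        C = np.corrcoef(model.components)
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-6)

    def test_too_many_components_rejected(self):
        X, _ = _mix(seed=12)
        with pytest.raises(ed.ConfigError):
            ed.fastica(X, 4, seed=0)

    def test_agreement_with_reference_implementation(self):
        sklearn_decomp = pytest.importorskip("sklearn.decomposition")
        X, S = _mix(seed=13)
        model = ed.fastica(X, 3, seed=5)
        ref = sklearn_decomp.FastICA(
            n_components=3, fun="logcosh", algorithm="deflation", random_state=0,
            whiten="unit-variance", max_iter=1000,
        )
        ref_S = ref.fit_transform(X.data.T).T
        assert np.all(_matched_correlations(ref_S, model.components) >= 0.99)
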