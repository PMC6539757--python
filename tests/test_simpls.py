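"""SIMPLS partial least squares against independent oracles."""

import numpy as np
import pytest

import fentaqsar as fq
from fentaqsar.simpls import loo_q2_profile


def nipals_pls1(X, y, n_components):
    """Independent NIPALS PLS1 oracle (classic deflation form)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    E, f = X - x_mean, y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = f @ t / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.column_stack(W), np.column_stack(P), np.asarray(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return B, x_mean, y_mean


@pytest.fixture()
def random_problem():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(20, 10))
    beta = rng.normal(size=10)
    y = X @ beta + 0.1 * rng.normal(size=20)
    return X, y


class TestSimplsFit:
    def test_one_column_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 1))
        y = 2.5 * x.ravel() + 1.0 + 0.05 * rng.normal(size=15)
        m = fq.simpls_fit(x, y, 1)
        slope = np.polyfit(x.ravel(), y, 1)[0]
        assert m.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_equals_least_squares(self, random_problem):
        X, y = random_problem
        m = fq.simpls_fit(X, y, 10)
        Xc, yc = X - X.mean(0), y - y.mean()
        b = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        assert np.allclose(m.coef, b, atol=1e-8)

    def test_matches_nipals_oracle(self, random_problem):
        X, y = random_problem
        for a in (1, 2, 3):
            ours = fq.simpls_fit(X, y, a)
            B, xm, ym = nipals_pls1(X, y, a)
            assert np.allclose(ours.coef, B, atol=1e-8), f"{a} components"

    def test_matches_sklearn_cross_check(self, random_problem):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        ours = fq.simpls_fit(X, y, 3)
        assert np.allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_scores_are_orthogonal(self, random_problem):
        X, y = random_problem
        m = fq.simpls_fit(X, y, 5)
        T = (X - m.x_mean) @ m.weights
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-10

    def test_rss_never_increases_with_components(self, random_problem):
        X, y = random_problem
        rss = [
            np.sum((y - fq.simpls_fit(X, y, a).predict(X)) ** 2)
            for a in range(1, 8)
        ]
        assert all(rss[i + 1] <= rss[i] + 1e-10 for i in range(len(rss) - 1))

    def test_rank_deficiency_truncates_with_warning(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 2))
        X = np.column_stack([base, base @ [[1.0], [2.0]]])  # rank 2
        y = X @ [1.0, 1.0, 0.0] + 0.01 * rng.normal(size=10)
        with pytest.warns(UserWarning, match="truncating"):
            m = fq.simpls_fit(X, y, 3)
        assert m.n_components == 2

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError):
            fq.simpls_fit(np.eye(4), np.ones(4), 1)

    def test_predict_at_center_returns_mean(self, random_problem):
        X, y = random_problem
        m = fq.simpls_fit(X, y, 3)
        assert m.predict(m.x_mean)[0] == pytest.approx(m.y_mean)

    def test_json_round_trip(self, random_problem):
        X, y = random_problem
        m = fq.simpls_fit(X, y, 3)
        m2 = fq.PLSModel.from_json_dict(m.to_json_dict())
        assert np.allclose(m.predict(X), m2.predict(X))


class TestSelectComponents:
    def test_single_latent_direction_selects_one(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=30)
        p = rng.normal(size=8)
        X = np.outer(t, p) + 1e-9 * rng.normal(size=(30, 8))
        best, _ = fq.select_components(X, t, max_components=5)
        assert best == 1

    def test_max_components_one(self, random_problem):
        X, y = random_problem
        best, _ = fq.select_components(X, y, max_components=1)
        assert best == 1

    def test_pure_noise_warns_and_returns_smallest(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        with pytest.warns(UserWarning, match="q2"):
            best, q2s = fq.select_components(X, y, max_components=4)
        assert best == 1
        assert all(v <= 0 for v in q2s.values())

    def test_profile_matches_per_count_refits(self, random_problem):
        """Single-pass LOO profile equals naively refitting per count."""
        X, y = random_problem
        profile = loo_q2_profile(X, y, 4)
        for a, q2_fast in profile.items():

            def fit_predict(Xtr, ytr, Xte, a=a):
                return fq.simpls_fit(Xtr, ytr, a).predict(Xte)

            q2_naive, _ = fq.loo_q2(fit_predict, X, y)
            assert q2_fast == pytest.approx(q2_naive, abs=1e-10)
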