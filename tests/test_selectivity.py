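"""PLS target projection and selectivity ratio against independent oracles."""

import numpy as np
import pytest

from phytoactive import (
    SyntheticConfig,
    fit_pls,
    generate_fraction_profiles,
    log_transform,
    selectivity_ratio,
    sr_analysis,
    target_projection,
)
from phytoactive.selectivity import _center_scale


def nipals_pls1(X, y, n_components):
    """Textbook NIPALS PLS1 oracle: deflation on X only, closed-form weights.

    Independent of the fitted implementation; returns the regression vector
    in the coordinates of X.
    """
    X = X.copy().astype(float)
    y = y.astype(float).ravel()
    n, p = X.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    E = X.copy()
    for a in range(n_components):
        w = E.T @ y
        w = w / np.linalg.norm(w)
        t = E @ w
        p_a = E.T @ t / (t @ t)
        q_a = y @ t / (t @ t)
        E = E - np.outer(t, p_a)
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    b = W @ np.linalg.solve(P.T @ W, q)
    return b


def rand_problem(rng, n, p):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 0.1 * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_perfect_single_column_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        y = X[:, 2].copy()
        m = fit_pls(X, y, n_components=1, scale=False)
        resid = m.predict(X) - y
        # one component cannot be exact unless y is in the span of the first
        # weight direction; with more components the fit becomes exact
        m_full = fit_pls(X, y, n_components=5, scale=False)
        assert np.abs(m_full.predict(X) - y).max() < 1e-8
        assert np.abs(resid).max() < np.abs(y - y.mean()).max()

    def test_orthogonal_y_rejected(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # zero covariance with both columns
        with pytest.raises(ValueError, match="no covariance"):
            fit_pls(X, y, 1, scale=False)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(1)
        X, y = rand_problem(rng, 6, 10)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, y, 6)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_matches_textbook_nipals(self, n_components):
        rng = np.random.default_rng(42)
        X, y = rand_problem(rng, 10, 5)
        Xc, _, _ = _center_scale(X, scale=False)
        yc = y - y.mean()
        b_oracle = nipals_pls1(Xc, yc, n_components)
        m = fit_pls(X, y, n_components, scale=False)
        np.testing.assert_allclose(m.b, b_oracle, atol=1e-8)
        np.testing.assert_allclose(m.predict(X), Xc @ b_oracle + y.mean(), atol=1e-8)


class TestTargetProjection:
    def test_single_component_model_is_its_own_projection(self):
        rng = np.random.default_rng(7)
        X, y = rand_problem(rng, 12, 6)
        m = fit_pls(X, y, 1, scale=False)
        t_tp, p_tp = target_projection(m, X)
        t1 = m.scores[:, 0]
        # equal up to sign and scale: perfectly correlated
        r = np.abs(t_tp @ t1) / (np.linalg.norm(t_tp) * np.linalg.norm(t1))
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_residual_orthogonal_to_scores(self):
        rng = np.random.default_rng(8)
        X, y = rand_problem(rng, 12, 6)
        m = fit_pls(X, y, 3, scale=False)
        t_tp, p_tp = target_projection(m, X)
        Xs = m.preprocess(X)
        E = Xs - np.outer(t_tp, p_tp)
        np.testing.assert_allclose(E.T @ t_tp, 0.0, atol=1e-10)

    def test_loadings_match_per_column_least_squares(self):
        rng = np.random.default_rng(9)
        X, y = rand_problem(rng, 12, 6)
        m = fit_pls(X, y, 3, scale=False)
        t_tp, p_tp = target_projection(m, X)
        Xs = m.preprocess(X)
        # oracle: regress each column of Xs on t_tp
        for j in range(Xs.shape[1]):
            slope = np.linalg.lstsq(t_tp[:, None], Xs[:, j], rcond=None)[0][0]
            assert p_tp[j] == pytest.approx(slope, abs=1e-10)


class TestSelectivityRatio:
    def test_sr_one_iff_half_variance_explained(self):
        # construct a column whose projection on t explains exactly half its
        # variance: x = t/||t|| + u/||u|| with u orthogonal to t
        rng = np.random.default_rng(10)
        t = rng.normal(size=8)
        u = rng.normal(size=8)
        u -= u @ t / (t @ t) * t
        x = t / np.linalg.norm(t) + u / np.linalg.norm(u)
        X = x[:, None]
        p_tp = np.array([X[:, 0] @ t / (t @ t)])
        res = selectivity_ratio(X, t, p_tp)
        assert res.sr[0] == pytest.approx(1.0, abs=1e-10)
        assert res.explained_fraction[0] == pytest.approx(0.5, abs=1e-12)

    def test_orthogonal_feature_scores_zero(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=8)
        u = rng.normal(size=8)
        u -= u @ t / (t @ t) * t
        X = u[:, None]
        p_tp = np.array([0.0])
        res = selectivity_ratio(X, t, p_tp)
        assert res.sr[0] == 0.0

    def test_matches_bruteforce_decomposition(self):
        rng = np.random.default_rng(12)
        X, y = rand_problem(rng, 15, 8)
        m = fit_pls(X, y, 3)
        t_tp, p_tp = target_projection(m, X)
        res = selectivity_ratio(X, t_tp, p_tp, model=m)
        Xs = m.preprocess(X)
        for j in range(8):
            fit = t_tp * p_tp[j]
            v_expl = (fit**2).sum()
            v_resid = ((Xs[:, j] - fit) ** 2).sum()
            assert res.sr[j] == pytest.approx(v_expl / v_resid, abs=1e-10)

    def test_zero_residual_gives_infinite_sr_rank_one(self):
        t = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.column_stack([2.0 * t, t + np.array([0.1, -0.2, 0.3, 0.05])])
        p_tp = X.T @ t / (t @ t)
        res = selectivity_ratio(X, t, p_tp)
        assert np.isinf(res.sr[0])
        assert res.rank[0] == 1

    def test_invariant_to_positive_rescaling_of_scores(self):
        rng = np.random.default_rng(13)
        X, y = rand_problem(rng, 15, 8)
        m = fit_pls(X, y, 2)
        t_tp, p_tp = target_projection(m, X)
        res1 = selectivity_ratio(X, t_tp, p_tp, model=m)
        scale = 7.3
        res2 = selectivity_ratio(X, t_tp * scale, p_tp / scale, model=m)
        np.testing.assert_allclose(res1.sr, res2.sr, rtol=1e-10)

    def test_sr_is_monotone_in_explained_fraction(self):
        rng = np.random.default_rng(14)
        X, y = rand_problem(rng, 15, 8)
        m = fit_pls(X, y, 2)
        t_tp, p_tp = target_projection(m, X)
        res = selectivity_ratio(X, t_tp, p_tp, model=m)
        f = res.explained_fraction
        np.testing.assert_allclose(res.sr, f / (1 - f), rtol=1e-8)
        order_sr = np.argsort(-res.sr, kind="stable")
        order_f = np.argsort(-f, kind="stable")
        np.testing.assert_array_equal(order_sr, order_f)

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(15)
        X, y = rand_problem(rng, 15, 8)
        m = fit_pls(X, y, 2)
        t_tp, p_tp = target_projection(m, X)
        res = selectivity_ratio(X, t_tp, p_tp, model=m)
        assert sorted(res.rank) == list(range(1, 9))


class TestSrAnalysis:
    def test_noiseless_single_spike_ranks_first(self):
        cfg = SyntheticConfig(
            n_features=40,
            n_bioactive=1,
            noise_sd=0.0,
            viability_range=None,
            n_satellite_parents=0,
            effect_sizes=(10.0,),
            include_anchor_features=False,
            seed=2,
        )
        m, v, spikes = generate_fraction_profiles(cfg)
        res = sr_analysis(log_transform(m), v)
        df = res.to_frame()
        assert df.iloc[0]["feature_id"] == spikes[0].feature_id

    def test_deterministic(self, small_dataset):
        logged = log_transform(small_dataset.matrix)
        r1 = sr_analysis(logged, small_dataset.viability, n_components=3)
        r2 = sr_analysis(logged, small_dataset.viability, n_components=3)
        np.testing.assert_array_equal(r1.sr, r2.sr)
        np.testing.assert_array_equal(r1.rank, r2.rank)
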