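"""Graphical lasso path, EBIC selection and edge enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import panelnet as pn
from panelnet.ggm import GGMConfig, PathPoint, WeightedNetwork, glasso_path


def _random_correlation(p, n, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2 * p))
    Y = X[:, :p] + 0.4 * X[:, p:]
    return np.corrcoef(Y, rowvar=False), Y


class TestSampleCorrelation:
    def test_duplicate_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=200).astype(float)
        X = np.column_stack([x, x, rng.integers(0, 5, size=200)])
        R = pn.sample_correlation(X)
        assert R[0, 1] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, size=(10_000, 6)).astype(float)
        R = pn.sample_correlation(X)
        off = R[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.05

    def test_matches_textbook_pearson_formula(self):
        X = np.array([[1.0, 2.0, 0.0],
                      [3.0, 1.0, 2.0],
                      [4.0, 4.0, 1.0],
                      [0.0, 3.0, 3.0],
                      [2.0, 0.0, 4.0]])
        R = pn.sample_correlation(X)
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                expect = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
                assert R[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_item_named(self, tiny_schema):
        X = np.column_stack([np.full(50, 2.0), np.arange(50, dtype=float)])
        with pytest.raises(ValueError, match="'0'"):
            pn.sample_correlation(X)


class TestGlasso:
    def test_zero_penalty_equals_inverse_correlation(self):
        R, _ = _random_correlation(3, 500, 2)
        theta, converged, _ = pn.glasso(R, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(R), atol=1e-6)

    def test_saturation_penalty_empties_the_network(self):
        R, _ = _random_correlation(8, 400, 3)
        lam = np.max(np.abs(R - np.eye(8)))
        theta, converged, _ = pn.glasso(R, lam * 1.0001)
        off = theta[np.triu_indices(8, 1)]
        assert converged and np.abs(off).max() < 1e-8

    def test_matches_independent_sklearn_solver(self):
        """Cross-check against sklearn's graphical lasso on random problems."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        R, _ = _random_correlation(22, 300, 4)
        lam_max = np.max(np.abs(R - np.eye(22)))
        for lam in [0.5 * lam_max, 0.2 * lam_max, 0.05 * lam_max]:
            theta, _, _ = pn.glasso(R, lam, tol=1e-6)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                _, sk_theta = sk_glasso(R, alpha=float(lam), tol=1e-7, max_iter=1000)
            assert np.max(np.abs(theta - sk_theta)) < 5e-3

    def test_kkt_stationarity_along_path(self):
        R, _ = _random_correlation(10, 800, 5)
        path = glasso_path(R, 800, GGMConfig(n_lambda=8, lambda_min_ratio=0.05))
        off = ~np.eye(10, dtype=bool)
        for pt in path:
            W = np.linalg.inv(pt.precision)
            G = W - R
            nz = (np.abs(pt.precision) > 1e-8) & off
            z = (np.abs(pt.precision) <= 1e-8) & off
            if nz.any():
                assert np.abs(G[nz] - pt.lam * np.sign(pt.precision[nz])).max() < 1e-4
            if z.any():
                assert np.abs(G[z]).max() <= pt.lam + 1e-4

    def test_edge_count_trend_along_path(self):
        R, _ = _random_correlation(15, 500, 6)
        path = glasso_path(R, 500, GGMConfig(n_lambda=30))
        lams = [pt.lam for pt in path]
        largest = path[int(np.argmax(lams))]
        smallest = path[int(np.argmin(lams))]
        assert largest.n_edges <= smallest.n_edges

    def test_support_recovery_on_known_sparse_truth(self):
        """On Gaussian data from a sparse precision with uniform 0.2 partial
        correlations, some path point recovers >= 90% of the true edges with
        <= 10% false edges."""
        rng = np.random.default_rng(30)
        p = 15
        W = np.zeros((p, p))
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        for k in rng.choice(len(pairs), 20, replace=False):
            i, j = pairs[k]
            W[i, j] = W[j, i] = 0.2
        omega = np.eye(p) - W
        while np.linalg.eigvalsh(omega).min() < 0.05:
            omega += 0.1 * np.eye(p)
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        omega = omega * np.outer(d, d)
        X = rng.multivariate_normal(np.zeros(p), np.linalg.inv(omega), size=2000)
        path = glasso_path(pn.sample_correlation(X), 2000, GGMConfig())
        iu = np.triu_indices(p, 1)
        dd = np.sqrt(np.diag(omega))
        truth = np.abs((omega / np.outer(dd, dd))[iu]) > 1e-10
        found = False
        for pt in path:
            est = np.abs(pn.precision_to_partial(pt.precision)[iu]) > 0
            tpr = (est & truth).sum() / truth.sum()
            fpr = (est & ~truth).sum() / (~truth).sum()
            if tpr >= 0.9 and fpr <= 0.1:
                found = True
                break
        assert found

    def test_partials_at_zero_penalty_match_regression_oracle(self):
        """Partial correlations from inv(R) equal the correlation of
        residuals after regressing each pair on all remaining variables."""
        _, Y = _random_correlation(4, 3000, 7)
        R = np.corrcoef(Y, rowvar=False)
        theta, _, _ = pn.glasso(R, 0.0)
        W = pn.precision_to_partial(theta)
        for i, j in [(0, 1), (1, 3), (0, 2)]:
            others = [k for k in range(4) if k not in (i, j)]
            Z = np.column_stack([np.ones(len(Y)), Y[:, others]])
            ri = Y[:, i] - Z @ np.linalg.lstsq(Z, Y[:, i], rcond=None)[0]
            rj = Y[:, j] - Z @ np.linalg.lstsq(Z, Y[:, j], rcond=None)[0]
            oracle = np.corrcoef(ri, rj)[0, 1]
            assert W[i, j] == pytest.approx(oracle, abs=1e-6)


class TestEbicSelect:
    def test_gamma_zero_is_bic_and_denser(self):
        R, _ = _random_correlation(12, 300, 8)
        path = glasso_path(R, 300, GGMConfig(n_lambda=40))
        dense = pn.ebic_select(path, 300, gamma=0.0)
        sparse = pn.ebic_select(path, 300, gamma=0.5)
        assert dense.nonzero_edges >= sparse.nonzero_edges

    def test_independence_data_selects_empty_network(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(1000, 10))
        net = pn.fit_ggm(X)
        assert net.nonzero_edges == 0

    def test_study_like_edge_count_in_plausible_band(self, study_panel):
        data, _ = study_panel
        net = pn.fit_ggm(data, 0)
        assert 60 <= net.nonzero_edges <= 180

    def test_tie_break_prefers_larger_lambda(self):
        prec = np.eye(3)
        pts = [PathPoint(0.1, prec, -10.0, 0), PathPoint(0.5, prec, -10.0, 0)]
        net = pn.ebic_select(pts, 100, gamma=0.5)
        assert net.lambda_selected == 0.5


class TestEdgeList:
    def test_full_enumeration_has_231_pairs(self, study_panel):
        data, _ = study_panel
        net = pn.fit_ggm(data, 0)
        assert len(pn.edge_list(net)) == 231

    def test_empty_network_nonzero_only(self):
        net = WeightedNetwork(nodes=("a", "b", "c"), weights=np.zeros((3, 3)))
        assert pn.edge_list(net, nonzero_only=True) == []

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=2, max_value=8), st.integers(0, 2**31 - 1))
    def test_round_trip_reconstruction(self, p, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(-0.5, 0.5, size=(p, p))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        net = WeightedNetwork(nodes=tuple(f"n{i}" for i in range(p)), weights=W)
        rebuilt = np.zeros((p, p))
        idx = {name: i for i, name in enumerate(net.nodes)}
        for a, b, w in pn.edge_list(net):
            rebuilt[idx[a], idx[b]] = w
            rebuilt[idx[b], idx[a]] = w
        np.testing.assert_array_equal(rebuilt, W)
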