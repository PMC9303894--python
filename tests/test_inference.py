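"""Permutation comparison test, bootstrap CIs, difference tests, CS-coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import panelnet as pn
from panelnet.ggm import WeightedNetwork


def _sym_net(W):
    return WeightedNetwork(nodes=tuple(f"n{i}" for i in range(W.shape[0])), weights=W)


class TestGlobalStrength:
    def test_empty_and_single_edge(self):
        assert pn.global_strength(_sym_net(np.zeros((5, 5)))) == 0.0
        W = np.zeros((5, 5))
        W[1, 3] = W[3, 1] = -0.3
        assert pn.global_strength(_sym_net(W)) == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_upper_triangle(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(-0.4, 0.4, size=(7, 7))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        expect = sum(abs(W[i, j]) for i in range(7) for j in range(i + 1, 7))
        assert pn.global_strength(_sym_net(W)) == pytest.approx(expect, abs=1e-12)


class TestNctGlobal:
    def test_identical_groups_give_zero_statistic_and_p_one(self, fast_ggm_config):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 6))
        res = pn.nct_global(X, X.copy(), n_permutations=30, config=fast_ggm_config, seed=1)
        assert res.S_observed == 0.0
        assert res.p_value == 1.0

    def test_too_few_permutations_rejected(self):
        X = np.random.default_rng(1).normal(size=(50, 4))
        with pytest.raises(ValueError):
            pn.nct_global(X, X, n_permutations=10)

    def test_seed_determinism(self, fast_ggm_config, study_panel):
        data, _ = study_panel
        X = pn.wave_matrix(data, 0)[:200]
        a = pn.nct_global(X[:100], X[100:], n_permutations=30, config=fast_ggm_config, seed=5)
        b = pn.nct_global(X[:100], X[100:], n_permutations=30, config=fast_ggm_config, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.per_permutation_S, b.per_permutation_S)

    def test_p_value_follows_add_one_convention(self, fast_ggm_config, study_panel):
        data, _ = study_panel
        X1 = pn.wave_matrix(data, 0)[:150]
        X2 = pn.wave_matrix(data, 1)[:150]
        res = pn.nct_global(X1, X2, n_permutations=40, config=fast_ggm_config, seed=6)
        expect = (1 + np.sum(res.per_permutation_S >= res.S_observed)) / 41
        assert res.p_value == pytest.approx(expect)

    def test_power_against_clearly_different_connectivity(self, fast_ggm_config):
        """Groups from networks whose global strengths differ by >= 50% are
        separated by the test in most replicates."""
        strong = pn.build_true_network(seed=40, density=0.25,
                                       weight_range=(0.15, 0.35))
        weak = pn.build_true_network(seed=40, density=0.25,
                                     weight_range=(0.1, 0.35))
        # shrink the weak network's edges towards zero by diagonal inflation
        weak.omega1 = weak.omega1 + 1.5 * np.diag(np.diag(weak.omega1))
        iu = np.triu_indices(22, 1)
        gs_s = np.abs(strong.partial_correlations()[iu]).sum()
        gs_w = np.abs(weak.partial_correlations()[iu]).sum()
        assert gs_s >= 1.5 * gs_w
        rejections = 0
        n_rep = 25
        for rep in range(n_rep):
            da, _ = pn.simulate_panel(strong, 500, seed=500 + rep)
            db, _ = pn.simulate_panel(weak, 500, seed=800 + rep)
            res = pn.nct_global(
                pn.wave_matrix(da, 0), pn.wave_matrix(db, 0),
                n_permutations=200, config=fast_ggm_config, seed=rep,
            )
            rejections += res.p_value < 0.05
        assert rejections / n_rep >= 0.8


class TestBootstrapEdges:
    def test_null_data_cis_cover_zero(self, fast_ggm_config):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 5, size=(300, 10)).astype(float)
        res = pn.bootstrap_edges(X, n_boot=100, config=fast_ggm_config, seed=3)
        covers = (res.edge_ci[:, 0] <= 0) & (0 <= res.edge_ci[:, 1])
        assert covers.mean() >= 0.9

    def test_point_estimate_inside_own_ci(self, fast_ggm_config, study_panel):
        data, _ = study_panel
        X = pn.wave_matrix(data, 0)
        res = pn.bootstrap_edges(X, n_boot=100, config=fast_ggm_config, seed=4)
        inside = (res.edge_ci[:, 0] <= res.point_edges) & (
            res.point_edges <= res.edge_ci[:, 1]
        )
        assert inside.mean() >= 0.95

    def test_fixed_seed_reproduces_ci_bounds(self, fast_ggm_config, study_panel):
        data, _ = study_panel
        X = pn.wave_matrix(data, 0)[:250]
        a = pn.bootstrap_edges(X, n_boot=100, config=fast_ggm_config, seed=5)
        b = pn.bootstrap_edges(X, n_boot=100, config=fast_ggm_config, seed=5)
        np.testing.assert_array_equal(a.edge_ci, b.edge_ci)

    def test_minimum_replicates_enforced(self):
        X = np.random.default_rng(6).normal(size=(100, 4))
        with pytest.raises(ValueError):
            pn.bootstrap_edges(X, n_boot=50)


@pytest.fixture(scope="module")
def two_edge_spec():
    """6-node truth with one strong (0.4) and one weak (0.1) edge."""
    p = 6
    W = np.zeros((p, p))
    W[0, 1] = W[1, 0] = 0.4
    W[2, 3] = W[3, 2] = 0.1
    omega = np.eye(p) - W
    return pn.TrueNetworkSpec(
        schema=pn.ItemSchema(
            item_ids=tuple(f"x{i}" for i in range(p)),
            subscale_of={f"x{i}": "intrusion" for i in range(p)},
        ),
        omega1=omega,
        B=np.zeros((p, p)),
        sigma_e=np.linalg.inv(omega),
        thresholds=np.tile(np.array([-1.5, -0.5, 0.5, 1.5]), (p, 1)),
    )


class TestDifferenceTest:

    def test_significance_matrix_symmetric_with_false_diagonal(
        self, fast_ggm_config, study_panel
    ):
        data, _ = study_panel
        res = pn.bootstrap_edges(
            pn.wave_matrix(data, 0)[:300], n_boot=100, config=fast_ggm_config, seed=7
        )
        sig = pn.difference_test(res, kind="edge")
        assert np.array_equal(sig, sig.T)
        assert not sig.diagonal().any()

    def test_truly_different_edges_flagged(self, fast_ggm_config, two_edge_spec):
        """Edges whose true weights differ by ~0.3 separate in most replicates."""
        iu = np.triu_indices(6, 1)
        pairs = list(zip(*iu))
        e_strong = pairs.index((0, 1))
        e_weak = pairs.index((2, 3))
        flagged = 0
        n_rep = 30
        for rep in range(n_rep):
            data, _ = pn.simulate_panel(two_edge_spec, 2000, seed=900 + rep)
            res = pn.bootstrap_edges(
                pn.wave_matrix(data, 0), n_boot=100, config=fast_ggm_config, seed=rep
            )
            sig = pn.difference_test(res, kind="edge")
            flagged += sig[e_strong, e_weak]
        assert flagged / n_rep >= 0.9

    def test_centrality_kind_runs(self, fast_ggm_config, study_panel):
        data, _ = study_panel
        res = pn.bootstrap_edges(
            pn.wave_matrix(data, 0)[:300], n_boot=100, config=fast_ggm_config, seed=8
        )
        sig = pn.difference_test(res, kind="centrality")
        assert sig.shape == (22, 22)


class TestCaseDropCs:
    def test_pure_noise_is_unstable(self, fast_ggm_config):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 5, size=(150, 22)).astype(float)
        res = pn.case_drop_cs(X, "EI", n_boot=100, seed=10, config=fast_ggm_config)
        assert res.cs_coefficient <= 0.25

    def test_cs_bounded_by_grid_and_monotone_in_threshold(
        self, fast_ggm_config, study_panel
    ):
        data, _ = study_panel
        X = pn.wave_matrix(data, 0)
        res = pn.case_drop_cs(X, "EI", n_boot=100, seed=11, config=fast_ggm_config)
        assert res.cs_coefficient <= max(pn.inference.DEFAULT_DROP_GRID)

        def cs_at(threshold):
            cs = 0.0
            for q, cors in res.cs_curves.items():
                ok = np.isfinite(cors)
                if ok.any() and np.mean(cors[ok] >= threshold) >= 0.95:
                    cs = max(cs, q)
            return cs

        values = [cs_at(t) for t in (0.5, 0.7, 0.9)]
        assert values[0] >= values[1] >= values[2]
        assert cs_at(0.7) == res.cs_coefficient

    def test_small_subsample_grid_points_skipped_with_warning(self, fast_ggm_config):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 5, size=(30, 22)).astype(float) + rng.normal(
            0, 0.01, size=(30, 22)
        )
        X = np.round(np.clip(X, 0, 4))
        with pytest.warns(UserWarning, match="skipped"):
            res = pn.case_drop_cs(
                X, "EI", drop_grid=(0.5, 0.75), n_boot=100, seed=13,
                config=fast_ggm_config,
            )
        assert res.cs_curves == {}
        assert res.cs_coefficient == 0.0

    def test_clpn_metric_accepts_panel(self, fast_ggm_config):
        p = 6
        W = np.zeros((p, p))
        W[0, 1] = W[1, 0] = 0.3
        omega = np.eye(p) - W
        B = 0.4 * np.eye(p)
        B[0, 2] = 0.3
        sigma1 = np.linalg.inv(omega)
        spec = pn.TrueNetworkSpec(
            schema=pn.ItemSchema(
                item_ids=tuple(f"x{i}" for i in range(p)),
                subscale_of={f"x{i}": "intrusion" for i in range(p)},
            ),
            omega1=omega,
            B=B,
            sigma_e=sigma1 - B.T @ sigma1 @ B,
            thresholds=np.tile(np.array([-1.5, -0.5, 0.5, 1.5]), (p, 1)),
        )
        data, _ = pn.simulate_panel(spec, 200, seed=15)
        res = pn.case_drop_cs(
            data, "OEI", drop_grid=(0.1,), n_boot=100, seed=14,
            config=fast_ggm_config, folds=5, n_alphas=30,
        )
        assert res.metric == "OEI" and 0.1 in res.cs_curves
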