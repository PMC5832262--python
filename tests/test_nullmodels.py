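import numpy as np
import pytest
from scipy import stats

from proxnet.association import AssociationMatrix
from proxnet.brn import MODELS
from proxnet.netmetrics import build_network, degree, eigenvector_centrality, strength
from proxnet.nullmodels import (cross_deployment_correlation, metric_null,
                                permute_matrix, repeatability_null,
                                _permute_within_strata)
from proxnet.synthetic import simulate_observation_table

from conftest import random_symmetric_matrix


def spanning_ring_matrix(seed, n=12):
    """Heavy weights laid out as a ring covering every node, light elsewhere —
    an arrangement dyad shuffling almost surely destroys."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for a in range(n):
        b = (a + 1) % n
        w = 50.0 * (1 + 0.3 * rng.random())
        W[a, b] = W[b, a] = w
    iu, ju = np.triu_indices(n, k=1)
    for k in rng.choice(iu.size, 10, replace=False):
        if W[iu[k], ju[k]] == 0:
            w = rng.gamma(1.0, 1.0)
            W[iu[k], ju[k]] = W[ju[k], iu[k]] = w
    return AssociationMatrix(ids=[f"C{i}" for i in range(n)], weights=W,
                             symmetric=True)


class TestPermuteMatrix:
    def test_single_dyad_unchanged(self):
        m = AssociationMatrix(ids=["A", "B"], weights=np.array([[0, 3.0], [3.0, 0]]),
                              symmetric=True)
        assert np.array_equal(permute_matrix(m, seed=5).weights, m.weights)

    def test_weight_multiset_and_total_conserved(self, sym12_sparse):
        iu = np.triu_indices(12, k=1)
        out = permute_matrix(sym12_sparse, seed=3)
        assert np.array_equal(np.sort(out.weights[iu]),
                              np.sort(sym12_sparse.weights[iu]))
        assert out.weights.sum() == pytest.approx(sym12_sparse.weights.sum())
        assert np.array_equal(out.weights, out.weights.T)
        assert np.all(np.diag(out.weights) == 0)

    def test_uniform_over_slots(self):
        # 4 nodes -> 6 dyad slots; each weight should land in each slot 1/6
        W = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, k=1)
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        W[iu, ju] = vals
        W[ju, iu] = vals
        m = AssociationMatrix(ids=list("ABCD"), weights=W, symmetric=True)
        n_rep = 10_000
        hits = np.zeros(6)
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            out = permute_matrix(m, rng)
            hits += out.weights[iu, ju] == 1.0  # track weight 1.0 across slots
        freq = hits / n_rep
        se = np.sqrt((1 / 6) * (5 / 6) / n_rep)
        assert np.all(np.abs(freq - 1 / 6) < 3 * se + 1e-12)

    def test_node_mode_preserves_mean_metrics(self, sym12_sparse):
        out = permute_matrix(sym12_sparse, seed=8, mode="nodes")
        g0, g1 = build_network(sym12_sparse), build_network(out)
        for func in (eigenvector_centrality, strength, degree):
            assert np.mean(list(func(g0).values())) == pytest.approx(
                np.mean(list(func(g1).values())))


class TestMetricNull:
    def test_all_positive_weights_degree_null_degenerate(self):
        m = random_symmetric_matrix(seed=2)  # no zero dyads
        nd = metric_null(m, "degree", n_perm=100, seed=1)
        assert set(nd.permuted) == {11.0}
        assert nd.observed == 11.0
        assert not nd.nonrandom

    def test_equal_weight_matrix_strength_null_degenerate(self):
        W = np.full((6, 6), 4.0)
        np.fill_diagonal(W, 0.0)
        m = AssociationMatrix(ids=list("ABCDEF"), weights=W, symmetric=True)
        nd = metric_null(m, "strength", n_perm=100, seed=1)
        assert np.all(nd.permuted == nd.observed)

    def test_structured_arrangement_flagged_nonrandom(self):
        # heavy weights spanning all nodes maximize mean eigenvector
        # centrality; shuffles localize the mass and fall below the observed
        flagged = 0
        for seed in range(20):
            nd = metric_null(spanning_ring_matrix(seed), "eigenvector",
                             n_perm=200, seed=3000 + seed)
            flagged += nd.observed > nd.ci_high
        assert flagged >= 18  # >= 90% of seeds

    def test_band_stable_in_n_perm_for_discrete_null(self, sym12_sparse):
        nd1 = metric_null(sym12_sparse, "eigenvector", n_perm=1000, seed=5)
        nd2 = metric_null(sym12_sparse, "eigenvector", n_perm=10_000, seed=6)
        sd = nd2.permuted.std()
        assert abs(nd1.ci_low - nd2.ci_low) < 0.05 * sd + 1e-12
        assert abs(nd1.ci_high - nd2.ci_high) < 0.05 * sd + 1e-12

    def test_matches_explicit_permute_and_rebuild_route(self, sym12_sparse):
        nd = metric_null(sym12_sparse, "eigenvector", n_perm=25, seed=42)
        rng = np.random.default_rng(42)
        ref = []
        for _ in range(25):
            g = build_network(permute_matrix(sym12_sparse, rng))
            ref.append(np.mean(list(eigenvector_centrality(g).values())))
        assert np.allclose(nd.permuted, ref)


class TestRepeatabilityNull:
    def test_stratified_swap_conserves_rows_and_values(self):
        obs, _ = simulate_observation_table(8, sigma2_id=1.0, seed=3)
        rng = np.random.default_rng(1)
        out = _permute_within_strata(obs, rng, stratified=True)
        assert len(out) == len(obs)
        for key, grp in obs.groupby(["density", "replicate"]):
            swapped = out[(out["density"] == key[0]) & (out["replicate"] == key[1])]
            assert sorted(swapped["value"]) == sorted(grp["value"])

    def test_null_true_data_inside_band(self):
        obs, _ = simulate_observation_table(12, sigma2_id=0.0, sigma2_resid=1.0,
                                            seed=2)
        nd = repeatability_null(obs, MODELS["M2"], n_perm=60, seed=4)
        assert not nd.nonrandom

    def test_undefined_for_model_without_random_effects(self):
        obs, _ = simulate_observation_table(8, seed=5)
        with pytest.raises(ValueError, match="random effects"):
            repeatability_null(obs, MODELS["M1"], n_perm=5, seed=1)


class TestCrossDeploymentCorrelation:
    def test_identical_vectors(self):
        r, p = cross_deployment_correlation([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_reversed_vector(self):
        r, _ = cross_deployment_correlation([1.0, 2, 3, 4], [4.0, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_type_one_error_calibration(self):
        # independent collars: |r| significant at the 5% level ~5% of the time
        rng = np.random.default_rng(0)
        hits = sum(cross_deployment_correlation(rng.standard_normal(13),
                                                rng.standard_normal(13))[1] < 0.05
                   for _ in range(1000))
        assert 30 <= hits <= 75

    def test_mismatched_ids_rejected(self):
        import pandas as pd
        a = pd.Series([1.0, 2, 3], index=["A", "B", "C"])
        b = pd.Series([1.0, 2, 3], index=["A", "B", "X"])
        with pytest.raises(ValueError, match="collar ids"):
            cross_deployment_correlation(a, b)
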