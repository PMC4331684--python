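"""Regularized factorization: mask, Laplacian, objective, updates,
initialization, fit contract, and prediction readouts."""

import numpy as np
import pytest

from rnmfnet.data_model import LatentGraph
from rnmfnet.nmf_core import NmfFactors, nmf_objective, nmf_update
from rnmfnet.rnmf import (
    RnmfParams,
    RnmfState,
    build_weight_mask,
    graph_laplacian,
    init_V,
    interaction_similarity,
    predict_single_label,
    rank_labels,
    rnmf_fit,
    rnmf_objective,
    rnmf_update,
)

from conftest import random_instance, tiny_dataset


def brute_force_rnmf_objective(X, Y, state, params):
    """Scalar-loop recomputation of all three objective terms."""
    U, B, V, W, E = state.U, state.B, state.V, state.W, state.graph
    M, N = X.shape
    q = Y.shape[0]
    K = U.shape[1]
    recon = 0.0
    for i in range(M):
        for j in range(N):
            approx = sum(U[i, k] * V[j, k] for k in range(K))
            recon += (X[i, j] - approx) ** 2
    label = 0.0
    for c in range(q):
        for j in range(N):
            approx = sum(B[c, k] * V[j, k] for k in range(K))
            label += W[c, j] * (Y[c, j] - approx) ** 2
    smooth = 0.0
    for j in range(N):
        for l in range(N):
            d2 = sum((V[j, k] - V[l, k]) ** 2 for k in range(K))
            smooth += 0.5 * d2 * E[j, l]
    return recon + params.label_weight * label + params.graph_weight * smooth


class TestWeightMask:
    def test_mask_values(self, small_dataset):
        W = build_weight_mask(small_dataset)
        # node 'a': labeled, classes (1, 0)
        np.testing.assert_array_equal(W[:, 0], [0.01, 1.0])
        # node 'c': unlabeled
        np.testing.assert_array_equal(W[:, 2], [0.0, 0.0])
        # known absences are weighted harder than known memberships
        lab = small_dataset.labeled_mask
        Y = small_dataset.labels
        assert W[:, lab][Y[:, lab] == 0].min() > W[:, lab][Y[:, lab] == 1].max()


class TestLaplacian:
    def test_two_node_hand_example(self):
        g = LatentGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]), kind="integrated")
        L, D = graph_laplacian(g)
        np.testing.assert_array_equal(D, np.eye(2))
        np.testing.assert_array_equal(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_identical_rows_are_perfectly_smooth(self):
        g = LatentGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]), kind="integrated")
        L, _ = graph_laplacian(g)
        V = np.array([[0.3, 0.7], [0.3, 0.7]])
        assert np.trace(V.T @ L @ V) == pytest.approx(0.0)

    def test_trace_form_matches_double_sum(self):
        g = LatentGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]), kind="integrated")
        L, _ = graph_laplacian(g)
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.trace(V.T @ L @ V) == pytest.approx(2.0)

    def test_asymmetric_rejected(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        g = LatentGraph.__new__(LatentGraph)
        g.weights = w
        g.kind = "integrated"
        with pytest.raises(ValueError, match="symmetric"):
            graph_laplacian(g)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(size=(8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        L, _ = graph_laplacian(LatentGraph(weights=w, kind="integrated"))
        assert np.linalg.eigvalsh(L).min() > -1e-10


class TestObjective:
    def test_reduces_to_nmf_when_unregularized(self):
        rng = np.random.default_rng(1)
        X, Y, lab, state = random_instance(rng)
        params = RnmfParams(label_weight=0.0, graph_weight=0.0)
        assert rnmf_objective(X, Y, state, params) == pytest.approx(
            nmf_objective(X, NmfFactors(U=state.U, V=state.V))
        )

    def test_zero_mask_kills_label_term(self):
        rng = np.random.default_rng(2)
        X, Y, lab, state = random_instance(rng)
        state.W = np.zeros_like(state.W)
        p0 = RnmfParams(label_weight=50.0, graph_weight=0.0)
        state.B = np.random.default_rng(3).uniform(size=state.B.shape)
        ref = nmf_objective(X, NmfFactors(U=state.U, V=state.V))
        assert rnmf_objective(X, Y, state, p0) == pytest.approx(ref)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            X, Y, lab, state = random_instance(rng, n_max=10, m_max=5)
            params = RnmfParams(
                label_weight=float(rng.uniform(0, 20)),
                graph_weight=float(rng.uniform(0, 10)),
            )
            assert rnmf_objective(X, Y, state, params) == pytest.approx(
                brute_force_rnmf_objective(X, Y, state, params), abs=1e-9
            )


class TestUpdate:
    def test_unregularized_update_matches_plain_nmf(self):
        rng = np.random.default_rng(5)
        X, Y, lab, state = random_instance(rng)
        params = RnmfParams(label_weight=0.0, graph_weight=0.0)
        after = rnmf_update(X, Y, state, params)
        plain = nmf_update(X, NmfFactors(U=state.U, V=state.V))
        np.testing.assert_allclose(after.U, plain.U, atol=1e-12)
        np.testing.assert_allclose(after.V, plain.V, atol=1e-12)

    def test_monotone_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            X, Y, lab, state = random_instance(rng)
            params = RnmfParams(
                label_weight=float(rng.uniform(0, 20)),
                graph_weight=float(rng.uniform(0, 10)),
            )
            before = rnmf_objective(X, Y, state, params)
            after = rnmf_objective(X, Y, rnmf_update(X, Y, state, params), params)
            assert after <= before * (1 + 1e-9)

    def test_smoothing_contracts_rows_on_complete_graph(self):
        # with no labels and a complete graph, one V update from a random
        # start strictly reduces the spread of the rows
        rng = np.random.default_rng(7)
        N, M, K = 12, 6, 3
        X = rng.uniform(size=(M, N))
        Y = np.zeros((K, N))
        E = 1.0 - np.eye(N)
        D = np.diag(E.sum(axis=1))
        contracted = 0
        for trial in range(10):
            trial_rng = np.random.default_rng(100 + trial)
            state = RnmfState(
                U=trial_rng.uniform(size=(M, K)) + 0.1,
                B=trial_rng.uniform(size=(K, K)) + 0.1,
                V=trial_rng.uniform(size=(N, K)) + 0.1,
                W=np.zeros((K, N)),
                graph=E,
                L=D - E,
                D=D,
            )
            params = RnmfParams(label_weight=0.0, graph_weight=50.0)
            before = state.V.var(axis=0).sum()
            after = rnmf_update(X, Y, state, params).V.var(axis=0).sum()
            contracted += after < before
        assert contracted == 10


class TestInitV:
    def test_unlabeled_rows_are_class_priors(self, small_dataset):
        # labeled memberships: a->c1, b->c2, e->{c1,c2}: counts (2, 2)/4
        V = init_V(small_dataset, K=2)
        np.testing.assert_allclose(V[2], [0.5, 0.5])
        np.testing.assert_allclose(V[3], [0.5, 0.5])

    def test_labeled_rows_copy_memberships(self, small_dataset):
        V = init_V(small_dataset, K=2)
        np.testing.assert_array_equal(V[0], [1.0, 0.0])
        np.testing.assert_array_equal(V[4], [1.0, 1.0])

    def test_unlabeled_rows_normalized_for_single_label_data(self):
        ds = tiny_dataset()
        ds.labels[:, 4] = [1.0, 0.0]  # make every labeled node single-label
        V = init_V(ds, K=2)
        assert V[2].sum() == pytest.approx(1.0)

    def test_wrong_rank_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="K = q"):
            init_V(small_dataset, K=3)


class TestFit:
    def _latent(self, dataset):
        w = (dataset.adjacency > 0).astype(float)
        return LatentGraph(weights=w, kind="integrated")

    def test_labeled_rows_exactly_one_hot(self, small_dataset):
        state = rnmf_fit(
            small_dataset, self._latent(small_dataset), RnmfParams(seed=0)
        )
        lab = small_dataset.labeled_mask
        np.testing.assert_array_equal(
            state.V[lab], small_dataset.labels[:, lab].T
        )

    def test_trace_contract(self, small_dataset):
        params = RnmfParams(seed=1, max_iter=40, tol=0.0)
        state = rnmf_fit(small_dataset, self._latent(small_dataset), params)
        tr = np.array(state.objective_trace)
        assert len(tr) == 40
        assert (np.diff(tr) <= tr[:-1] * 1e-9 + 1e-15).all()

    def test_deterministic_given_seed(self, small_dataset):
        a = rnmf_fit(small_dataset, self._latent(small_dataset), RnmfParams(seed=5))
        b = rnmf_fit(small_dataset, self._latent(small_dataset), RnmfParams(seed=5))
        np.testing.assert_array_equal(a.V, b.V)
        np.testing.assert_array_equal(a.U, b.U)

    def test_rejects_unlabeled_dataset(self, small_dataset):
        ds = small_dataset
        ds.labels[:] = 0.0
        ds.labeled_mask[:] = False
        with pytest.raises(ValueError, match="no labeled nodes"):
            rnmf_fit(ds, self._latent(ds), RnmfParams())

    def test_rejects_mismatched_graph(self, small_dataset):
        latent = LatentGraph(weights=np.zeros((3, 3)), kind="integrated")
        with pytest.raises(ValueError, match="node set"):
            rnmf_fit(small_dataset, latent, RnmfParams())


class TestPrediction:
    def _state_with_V(self, V):
        N, K = V.shape
        E = np.zeros((N, N))
        return RnmfState(
            U=np.ones((2, K)),
            B=np.ones((K, K)),
            V=V,
            W=np.zeros((K, N)),
            graph=E,
            L=E,
            D=E,
        )

    def test_argmax_prediction(self):
        st = self._state_with_V(np.array([[0.1, 0.7, 0.2]]))
        assert predict_single_label(st)[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        st = self._state_with_V(np.array([[0.4, 0.4, 0.2]]))
        assert predict_single_label(st)[0] == 0

    def test_zero_row_falls_back_with_warning(self):
        st = self._state_with_V(np.array([[0.0, 0.0], [0.2, 0.1]]))
        with pytest.warns(UserWarning, match="all-zero"):
            pred = predict_single_label(st)
        assert pred[0] == 0

    def test_ranking_descends_scores(self):
        st = self._state_with_V(np.array([[0.1, 0.7, 0.2]]))
        np.testing.assert_array_equal(rank_labels(st)[0], [1, 2, 0])

    def test_ranking_ties_stable_by_class_index(self):
        st = self._state_with_V(np.array([[0.5, 0.5, 0.5]]))
        np.testing.assert_array_equal(rank_labels(st)[0], [0, 1, 2])

    def test_ranking_inverts_sorting_oracle(self):
        rng = np.random.default_rng(11)
        V = rng.uniform(size=(7, 5))
        ranking = rank_labels(self._state_with_V(V))
        for j in range(7):
            scores = [(-V[j, k], k) for k in range(5)]
            expected = [k for _, k in sorted(scores)]
            assert list(ranking[j]) == expected

    def test_interaction_similarity_extremes(self):
        V = np.array([[0.2, 0.4], [0.1, 0.2], [0.4, 0.0], [0.0, 0.3]])
        st = self._state_with_V(V)
        assert interaction_similarity(st, 0, 1) == pytest.approx(1.0)
        assert interaction_similarity(st, 2, 3) == pytest.approx(0.0)

    def test_interaction_similarity_matches_scalar_loop(self):
        rng = np.random.default_rng(12)
        V = rng.uniform(size=(4, 6))
        st = self._state_with_V(V)
        for a in range(4):
            for b in range(4):
                num = sum(V[a, k] * V[b, k] for k in range(6))
                den = np.sqrt(sum(v**2 for v in V[a])) * np.sqrt(
                    sum(v**2 for v in V[b])
                )
                assert interaction_similarity(st, a, b) == pytest.approx(
                    num / den, abs=1e-12
                )

    def test_zero_row_similarity_rejected(self):
        st = self._state_with_V(np.array([[0.0, 0.0], [0.2, 0.1]]))
        with pytest.raises(ValueError, match="all-zero"):
            interaction_similarity(st, 0, 1)
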