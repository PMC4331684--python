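"""Shared fixtures: small random problem instances and the planted
partition benchmark runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from rnmfnet.data_model import NetworkDataset, split_labels
from rnmfnet.graph_integration import integrate, learn_weights, restrict_to_labeled
from rnmfnet.latent_graphs import ErwrParams, erwr_latent_graph, ppi_latent_graph
from rnmfnet.nmf_core import nmf_fit
from rnmfnet.rnmf import (
    RnmfParams,
    RnmfState,
    build_weight_mask,
    graph_laplacian,
    predict_single_label,
    rnmf_fit,
)
from rnmfnet.synthetic_data import SyntheticConfig, generate


def random_instance(rng: np.random.Generator, n_max=30, m_max=10, q_max=4):
    """One random RNMF problem: data, labels, mask, graph, positive state."""
    N = int(rng.integers(5, n_max + 1))
    M = int(rng.integers(2, m_max + 1))
    q = int(rng.integers(2, q_max + 1))
    X = rng.uniform(size=(M, N))
    lab = rng.uniform(size=N) < 0.5
    if not lab.any():
        lab[int(rng.integers(0, N))] = True
    Y = (rng.uniform(size=(q, N)) < 0.3).astype(float)
    Y[:, ~lab] = 0.0
    for j in np.flatnonzero(lab):
        if Y[:, j].sum() == 0:
            Y[int(rng.integers(0, q)), j] = 1.0
    E = rng.uniform(size=(N, N))
    E = (E + E.T) / 2
    np.fill_diagonal(E, 0.0)
    W = np.zeros((q, N))
    W[:, lab] = np.where(Y[:, lab] == 1, 0.01, 1.0)
    D = np.diag(E.sum(axis=1))
    state = RnmfState(
        U=rng.uniform(size=(M, q)) + 0.1,
        B=rng.uniform(size=(q, q)) + 0.1,
        V=rng.uniform(size=(N, q)) + 0.1,
        W=W,
        graph=E,
        L=D - E,
        D=D,
    )
    return X, Y, lab, state


def tiny_dataset() -> NetworkDataset:
    """Deterministic 5-node, 2-class dataset used in I/O and shape tests."""
    node_ids = ["a", "b", "c", "d", "e"]
    adjacency = np.zeros((5, 5))
    for i, j, w in [(0, 1, 1.0), (1, 2, 2.5), (2, 3, 1.0), (0, 4, 0.75)]:
        adjacency[i, j] = adjacency[j, i] = w
    features = np.array(
        [
            [1.0, 0.0, 0.5, 0.0, 1.0],
            [0.0, 2.0, 0.0, 1.0, 0.0],
            [0.25, 0.0, 1.0, 1.0, 0.0],
        ]
    )
    labels = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 1.0],
            [0.0, 1.0, 0.0, 0.0, 1.0],
        ]
    )
    labeled_mask = np.array([True, True, False, False, True])
    return NetworkDataset(
        node_ids=node_ids,
        adjacency=adjacency,
        features=features,
        labels=labels,
        labeled_mask=labeled_mask,
        class_ids=["c1", "c2"],
    )


@pytest.fixture
def small_dataset() -> NetworkDataset:
    return tiny_dataset()


# ---------------------------------------------------------------------------
# The planted-partition benchmark: 10 repeated label splits with the
# integrated ppi+erwr latent graph, shared by the recovery, convergence
# and label-preservation tests.
# ---------------------------------------------------------------------------

FIXTURE_CONFIG = SyntheticConfig(
    n_nodes=300,
    n_classes=3,
    intra_class_edge_prob=0.05,
    inter_class_edge_prob=0.005,
    noise_rate=0.2,
    seed=1,
)
FIXTURE_LABEL_RATIO = 0.05
FIXTURE_SEEDS = tuple(range(10))


def _fit_one(dataset, split, seed, **param_overrides):
    g1 = ppi_latent_graph(split)
    g2 = erwr_latent_graph(split, ErwrParams())
    restricted, ybar = restrict_to_labeled([g1, g2], split)
    weights = learn_weights(restricted, ybar.T @ ybar, 0.01)
    latent = integrate([g1, g2], weights)
    params = RnmfParams(seed=seed, **param_overrides)
    return rnmf_fit(split, latent, params), latent


@pytest.fixture(scope="session")
def planted_runs():
    """Per-seed pipeline results on the planted-partition benchmark."""
    dataset = generate(FIXTURE_CONFIG)
    truth = np.argmax(dataset.labels, axis=0)
    runs = []
    for seed in FIXTURE_SEEDS:
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                split = split_labels(dataset, FIXTURE_LABEL_RATIO, seed)
                state, latent = _fit_one(dataset, split, seed)
                # full-length trace for the convergence-speed check
                state_full, _ = _fit_one(
                    dataset, split, seed, max_iter=60, tol=0.0
                )
                evaluated = ~split.labeled_mask
                pred = predict_single_label(state, split)
                rnmf_acc = float(np.mean(pred[evaluated] == truth[evaluated]))
                nmf = nmf_fit(dataset.features, K=3, seed=seed)
                nmf_acc = float(
                    np.mean(
                        np.argmax(nmf.V, axis=1)[evaluated] == truth[evaluated]
                    )
                )
                prior_class = int(
                    np.argmax(split.labels[:, split.labeled_mask].sum(axis=1))
                )
                prior_acc = float(np.mean(truth[evaluated] == prior_class))
        runs.append(
            {
                "seed": seed,
                "split": split,
                "state": state,
                "latent": latent,
                "trace_full": list(state_full.objective_trace),
                "rnmf_acc": rnmf_acc,
                "nmf_acc": nmf_acc,
                "prior_acc": prior_acc,
            }
        )
    return {"dataset": dataset, "truth": truth, "runs": runs}
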