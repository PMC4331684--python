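"""Construction of candidate latent graphs over the nodes of a network.

A latent graph is an N x N non-negative symmetric similarity matrix built
from one view of the data.  Three constructions are provided:

``ppi``
    The observed interaction network, binarized: two nodes are similar
    (weight 1) iff they interact.
``erwr``
    Even-step random walk with restart.  Walks on the squared adjacency
    matrix only ever land an even number of hops away, capturing the
    level-2 neighborhood: nodes sharing many interaction partners score
    high even when not directly connected.
``prediction_similarity``
    Cosine similarity between per-node class-probability vectors produced
    by a classifier trained on the labeled nodes' attribute features.

Each view can separate or link nodes the raw network cannot; they are
meant to be combined by :mod:`rnmfnet.graph_integration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from .data_model import LatentGraph, NetworkDataset

__all__ = [
    "ErwrParams",
    "ppi_latent_graph",
    "erwr_latent_graph",
    "prediction_similarity_graph",
    "cosine_similarity_matrix",
    "write_latent_graph",
    "read_latent_graph",
]


@dataclass(frozen=True)
class ErwrParams:
    """Even-step random walk with restart parameters.

    restart_prob : probability of returning to the start node at each
        step, strictly inside (0, 1); default 0.1.
    num_steps : number of walk steps T >= 1 accumulated; default 10, at
        which the geometric tail factor (1 - 0.1)^10 ~ 0.35 still retains
        meaningful mass while bounding cost.
    """

    restart_prob: float = 0.1
    num_steps: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob < 1:
            raise ValueError("restart_prob must lie strictly in (0, 1)")
        if self.num_steps < 1:
            raise ValueError("num_steps must be >= 1")


def ppi_latent_graph(dataset: NetworkDataset) -> LatentGraph:
    """Binarized interaction graph: weight 1 where any edge exists."""
    return LatentGraph(
        weights=(dataset.adjacency > 0).astype(float), kind="ppi"
    )


def erwr_latent_graph(
    dataset: NetworkDataset, params: ErwrParams = ErwrParams()
) -> LatentGraph:
    """Even-step random walk with restart over the interaction network.

    With E the adjacency matrix, the two-hop transition matrix is the
    column normalization P of E @ E.  The accumulated visiting
    probability after T steps with restart probability a is

        R = sum_{t=1..T} a (1 - a)^t P^t

    Columns of E @ E summing to zero (nodes with no two-hop neighbors)
    stay zero, with a warning.  Column normalization breaks symmetry, so
    the result is symmetrized as (R + R^T) / 2 — required for the graph
    Laplacian used downstream to be well defined.
    """
    E = dataset.adjacency
    if not np.any(E):
        raise ValueError("ERWR needs a network with at least one edge")
    P = E @ E
    colsums = P.sum(axis=0)
    dead = colsums <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} node(s) have no even-step neighbors; "
            "their columns carry no probability mass",
            stacklevel=2,
        )
    P = P / np.where(dead, 1.0, colsums)
    P[:, dead] = 0.0
    a = params.restart_prob
    R = np.zeros_like(P)
    Pt = np.eye(P.shape[0])
    for t in range(1, params.num_steps + 1):
        Pt = P @ Pt
        R += a * (1 - a) ** t * Pt
    return LatentGraph(weights=(R + R.T) / 2, kind="erwr")


def cosine_similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of the rows of ``vectors``.

    Zero rows get similarity 0 to everything.
    """
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = vectors / safe[:, None]
    sim = unit @ unit.T
    return (sim + sim.T) / 2


def prediction_similarity_graph(
    dataset: NetworkDataset, base_classifier=None
) -> LatentGraph:
    """Cosine similarity of classifier confidence vectors.

    A probabilistic classifier is trained on the labeled nodes' feature
    vectors and used to score class-membership probabilities for *all*
    nodes (the factorization downstream needs similarities between every
    pair).  Multi-label nodes contribute one training sample per class
    membership.  The default classifier is multinomial logistic
    regression; any estimator with ``fit`` / ``predict_proba`` works.

    The diagonal is zeroed so the graph carries no self-similarity.
    """
    if dataset.n_labeled == 0:
        raise ValueError("no labeled nodes to train the base classifier on")
    labeled = np.flatnonzero(dataset.labeled_mask)
    rows: list[int] = []
    targets: list[int] = []
    for j in labeled:
        for k in np.flatnonzero(dataset.labels[:, j]):
            rows.append(j)
            targets.append(int(k))
    present = sorted(set(targets))
    if len(present) < 2:
        raise ValueError(
            "labeled nodes cover a single class; confidence vectors would "
            "be degenerate"
        )
    if base_classifier is None:
        clf = LogisticRegression(max_iter=1000)
    else:
        clf = clone(base_classifier)
    X_train = dataset.features[:, rows].T
    clf.fit(X_train, np.asarray(targets))
    proba = clf.predict_proba(dataset.features.T)
    # embed into the full q-class space (absent classes get probability 0)
    confidences = np.zeros((dataset.n_nodes, dataset.n_classes))
    for col, k in enumerate(clf.classes_):
        confidences[:, int(k)] = proba[:, col]
    weights = cosine_similarity_matrix(confidences)
    np.fill_diagonal(weights, 0.0)
    weights = np.clip(weights, 0.0, 1.0)
    return LatentGraph(weights=weights, kind="prediction_similarity")


# ---------------------------------------------------------------------------
# Serialization: MatrixMarket sparse symmetric matrix + sidecar node ids
# ---------------------------------------------------------------------------

def write_latent_graph(
    graph: LatentGraph, path, node_ids: list[str]
) -> None:
    """Write ``<path>`` as MatrixMarket and ``<path stem>.nodes.txt``."""
    from pathlib import Path

    from scipy import io as spio
    from scipy import sparse

    path = Path(path)
    if len(node_ids) != graph.n_nodes:
        raise ValueError("node id list length must match the graph size")
    spio.mmwrite(
        path, sparse.coo_matrix(graph.weights), symmetry="symmetric",
        precision=17, comment=f"kind: {graph.kind}",
    )
    path.with_suffix(".nodes.txt").write_text("\n".join(node_ids) + "\n")


def read_latent_graph(path, kind: str) -> tuple[LatentGraph, list[str]]:
    """Load a graph written by :func:`write_latent_graph`."""
    from pathlib import Path

    from scipy import io as spio
    from scipy import sparse

    path = Path(path)
    mat = spio.mmread(path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    node_ids = path.with_suffix(".nodes.txt").read_text().split()
    return LatentGraph(weights=np.asarray(mat, dtype=float), kind=kind), node_ids
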