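"""Label- and graph-regularized non-negative matrix factorization.

The factorization couples three data sources through a shared coefficient
matrix V (N x K, one row z_j per node):

* the attribute matrix X (M x N), reconstructed as U V^T;
* the partial label matrix Y (q x N), reconstructed as B V^T, weighted by
  a confidence mask W so only labeled nodes constrain the fit;
* an integrated latent graph Ehat, whose Laplacian L = D - Ehat penalizes
  rough V via Tr(V^T L V) = (1/2) sum_jl ||z_j - z_l||^2 Ehat_jl.

The objective minimized by the multiplicative updates is

    O(U, B, V) = ||X - U V^T||_F^2
               + alpha * sum_ij W_ij (Y - B V^T)_ij^2
               + beta  * Tr(V^T L V)

The label misfit is the W-weighted squared Frobenius norm (each squared
residual scaled once by its weight); that is the form whose gradient the
multiplicative updates majorize, so every update pass is non-increasing.
With alpha = beta = 0 the updates coincide with plain NMF.

The mask W trusts observed memberships softly and observed absences
strongly: for a labeled node, W = 0.01 where Y = 1 (the reconstruction
need not reach exactly 1) and W = 1 where Y = 0 (spurious memberships are
penalized hard); unlabeled nodes get W = 0 and are constrained only by
features and the graph.

With K = q each coefficient column aligns with one class, so V rows act
directly as class scores: hard labels by row argmax, multi-label rankings
by sorting a row, and node-pair interaction strength as the cosine of two
rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import LatentGraph, NetworkDataset
from .nmf_core import EPS

__all__ = [
    "RnmfParams",
    "RnmfState",
    "build_weight_mask",
    "graph_laplacian",
    "rnmf_objective",
    "rnmf_update",
    "init_V",
    "rnmf_fit",
    "predict_single_label",
    "rank_labels",
    "interaction_similarity",
]


@dataclass(frozen=True)
class RnmfParams:
    """Hyperparameters of the regularized factorization.

    label_weight : alpha >= 0, weight of the masked label term
        (default 10).
    graph_weight : beta >= 0, weight of the Laplacian smoothness term
        (default 5).
    K : number of components; ``None`` means K = q, which the
        label-based initialization and class-aligned prediction require.
    max_iter, tol : stop when the relative objective change drops below
        ``tol`` or after ``max_iter`` passes.
    seed : seeds the uniform (0, 1) initialization of B (and of U and V
        when ``v_init='random'``).
    v_init : ``'labels'`` (one-hot labeled rows, class-prior unlabeled
        rows, projection warm start for U) or ``'random'`` (uniform
        U, V).
    reset_labeled : re-impose the one-hot labeled rows of V after every
        pass, preserving the supervision exactly.
    """

    label_weight: float = 10.0
    graph_weight: float = 5.0
    K: int | None = None
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    v_init: str = "labels"
    reset_labeled: bool = True

    def __post_init__(self) -> None:
        if self.label_weight < 0 or self.graph_weight < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.v_init not in ("labels", "random"):
            raise ValueError("v_init must be 'labels' or 'random'")


@dataclass
class RnmfState:
    """Factors and fixed side matrices of one factorization run."""

    U: np.ndarray  # M x K feature basis
    B: np.ndarray  # q x K label basis
    V: np.ndarray  # N x K shared coefficients
    W: np.ndarray  # q x N label confidence mask
    graph: np.ndarray  # N x N integrated latent graph Ehat
    L: np.ndarray  # N x N Laplacian D - Ehat
    D: np.ndarray  # N x N degree diagonal
    objective_trace: list[float] = field(default_factory=list)


TRUSTED_LABEL_WEIGHT = 0.01  # mask value where a known membership is 1
ABSENT_LABEL_WEIGHT = 1.0  # mask value where a known membership is 0


def build_weight_mask(dataset: NetworkDataset) -> np.ndarray:
    """q x N confidence mask over label entries.

    Labeled node columns get 0.01 at observed memberships and 1 at
    observed absences; unlabeled columns are all zero.  Absences are
    weighted harder than memberships so the reconstruction B V^T is pushed
    toward 0 where Y = 0 but only loosely toward 1 where Y = 1.
    """
    W = np.zeros_like(dataset.labels)
    lab = dataset.labeled_mask
    W[:, lab] = np.where(
        dataset.labels[:, lab] == 1, TRUSTED_LABEL_WEIGHT, ABSENT_LABEL_WEIGHT
    )
    return W


def graph_laplacian(latent: LatentGraph) -> tuple[np.ndarray, np.ndarray]:
    """Return (L, D) with D the diagonal of column sums and L = D - Ehat.

    Requires a symmetric weight matrix (tolerance 1e-10); L is then
    positive semi-definite and Tr(V^T L V) equals the pairwise smoothness
    penalty (1/2) sum_jl ||z_j - z_l||^2 Ehat_jl.
    """
    E = latent.weights
    if not np.allclose(E, E.T, atol=1e-10):
        raise ValueError("graph Laplacian needs a symmetric weight matrix")
    D = np.diag(E.sum(axis=1))
    return D - E, D


def rnmf_objective(
    X: np.ndarray, Y: np.ndarray, state: RnmfState, params: RnmfParams
) -> float:
    """Three-term objective: reconstruction + masked label misfit +
    Laplacian smoothness."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    U, B, V = state.U, state.B, state.V
    if X.shape != (U.shape[0], V.shape[0]) or Y.shape != (B.shape[0], V.shape[0]):
        raise ValueError("shape mismatch between data and factors")
    recon = X - U @ V.T
    label_resid = Y - B @ V.T
    smooth = float(np.trace(V.T @ state.L @ V))
    return (
        float(np.sum(recon * recon))
        + params.label_weight * float(np.sum(state.W * label_resid * label_resid))
        + params.graph_weight * smooth
    )


def _check_finite(mat: np.ndarray, name: str, iteration: int | None) -> None:
    if not np.all(np.isfinite(mat)):
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(
            f"non-finite values appeared in factor {name}{where}"
        )


def rnmf_update(
    X: np.ndarray,
    Y: np.ndarray,
    state: RnmfState,
    params: RnmfParams,
    *,
    iteration: int | None = None,
) -> RnmfState:
    """One multiplicative pass updating U, then B, then V.

        U <- U * (X V) / (U V^T V)
        B <- B * ([W.Y] V) / ([W.(B V^T)] V)
        V <- V * (X^T U + a [W.Y]^T B + b Ehat V)
               / (V U^T U + a [W.(B V^T)]^T B + b D V)

    (``.`` is the Hadamard product, a = label_weight, b = graph_weight.)
    Denominators are floored at a tiny epsilon; the pass never increases
    the objective (to numerical precision).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    a, b = params.label_weight, params.graph_weight
    W, Ehat, D = state.W, state.graph, state.D
    d = np.diag(D)

    U = state.U * (X @ state.V) / np.maximum(
        state.U @ (state.V.T @ state.V), EPS
    )
    _check_finite(U, "U", iteration)

    WY = W * Y
    B = state.B * (WY @ state.V) / np.maximum(
        (W * (state.B @ state.V.T)) @ state.V, EPS
    )
    _check_finite(B, "B", iteration)

    V = state.V
    numer = X.T @ U + a * (WY.T @ B) + b * (Ehat @ V)
    denom = V @ (U.T @ U) + a * ((W * (B @ V.T)).T @ B) + b * (d[:, None] * V)
    V = V * numer / np.maximum(denom, EPS)
    _check_finite(V, "V", iteration)

    return RnmfState(
        U=U, B=B, V=V, W=W, graph=Ehat, L=state.L, D=D,
        objective_trace=list(state.objective_trace),
    )


def init_V(dataset: NetworkDataset, K: int) -> np.ndarray:
    """Label-based initialization of the coefficient matrix.

    Labeled rows copy the node's binary label vector; unlabeled rows all
    equal the empirical class priors among labeled memberships
    (count of labeled nodes in class k over total membership count).
    Requires K = q, since columns are identified with classes.
    """
    q = dataset.n_classes
    if K != q:
        raise ValueError(
            f"label-based initialization requires K = q (got K={K}, q={q})"
        )
    V = np.zeros((dataset.n_nodes, K))
    lab = dataset.labeled_mask
    V[lab] = dataset.labels[:, lab].T
    counts = dataset.labels[:, lab].sum(axis=1)
    total = counts.sum()
    if total > 0:
        V[~lab] = counts / total
    return V


def labeled_row_values(dataset: NetworkDataset) -> np.ndarray:
    """One-hot rows (n' x q) the labeled rows of V are reset to."""
    return dataset.labels[:, dataset.labeled_mask].T.copy()


def rnmf_fit(
    dataset: NetworkDataset,
    latent: LatentGraph,
    params: RnmfParams = RnmfParams(),
) -> RnmfState:
    """Run the full alternating scheme on a dataset and a latent graph.

    V starts from the label-based initialization with U warm-started by
    projection (or both uniform random in ``'random'`` mode) and B starts
    uniform (0, 1); each pass updates U, B, V and then resets
    the labeled rows of V to their one-hot label vectors so the
    supervision survives the fit exactly.  Stops when the relative change
    of the objective (recorded after each pass) drops below ``tol``.
    Deterministic given ``params.seed``.
    """
    if latent.n_nodes != dataset.n_nodes:
        raise ValueError("latent graph must cover the dataset's node set")
    if dataset.n_labeled == 0:
        raise ValueError(
            "no labeled nodes: the label mask is all-zero and prediction "
            "is undefined"
        )
    q = dataset.n_classes
    K = params.K if params.K is not None else q
    if K < 1:
        raise ValueError("K must be a positive integer")
    M, N = dataset.features.shape
    rng = np.random.default_rng(params.seed)
    if params.v_init == "labels":
        V = init_V(dataset, K)
        # Projection warm start: U columns start at the V-weighted feature
        # sums, so each basis column is anchored to the class its
        # coefficient column represents.  A purely random U leaves the
        # column-to-class alignment to chance and the fit can settle in a
        # label-permuted local minimum that the few reset rows cannot
        # escape.
        U = dataset.features @ V + 1e-6
        U = U / U.max()
        B = rng.uniform(size=(q, K))
    else:
        # draw order (U, V, B) keeps U and V aligned with nmf_fit's stream
        U = rng.uniform(size=(M, K))
        V = rng.uniform(size=(N, K))
        B = rng.uniform(size=(q, K))
    L, D = graph_laplacian(latent)
    W = build_weight_mask(dataset)
    state = RnmfState(U=U, B=B, V=V, W=W, graph=latent.weights, L=L, D=D)
    lab = dataset.labeled_mask
    reset_rows = labeled_row_values(dataset) if params.reset_labeled else None
    X, Y = dataset.features, dataset.labels
    prev = rnmf_objective(X, Y, state, params)
    for it in range(params.max_iter):
        state = rnmf_update(X, Y, state, params, iteration=it)
        if reset_rows is not None:
            state.V[lab] = reset_rows
        obj = rnmf_objective(X, Y, state, params)
        state.objective_trace.append(obj)
        if prev > 0 and abs(prev - obj) / prev < params.tol:
            break
        prev = obj
    return state


def predict_single_label(
    state: RnmfState, dataset: NetworkDataset | None = None
) -> np.ndarray:
    """Hard class index per node: argmax over the V row, ties to the
    lowest class index.

    An all-zero row carries no signal; it falls back to the most frequent
    labeled class (index 0 if no dataset is supplied), with a warning.
    """
    import warnings

    V = state.V
    pred = np.argmax(V, axis=1)
    dead = ~V.any(axis=1)
    if dead.any():
        fallback = 0
        if dataset is not None and dataset.n_labeled > 0:
            fallback = int(
                np.argmax(dataset.labels[:, dataset.labeled_mask].sum(axis=1))
            )
        warnings.warn(
            f"{int(dead.sum())} node(s) have all-zero coefficient rows; "
            "assigned the most frequent labeled class",
            stacklevel=2,
        )
        pred[dead] = fallback
    return pred


def rank_labels(state: RnmfState) -> np.ndarray:
    """Per-node ranking of class indices, best first.

    Classes are sorted by descending V-row score; equal scores keep
    ascending class-index order, so the ranking is deterministic.
    """
    V = state.V
    # stable sort on negated scores preserves class-index order among ties
    return np.argsort(-V, axis=1, kind="stable")


def interaction_similarity(state: RnmfState, node_a: int, node_b: int) -> float:
    """Cosine similarity of two nodes' coefficient rows, in [0, 1].

    0 means the nodes' representations share no component (independent);
    1 means proportional rows (strongly interrelated).
    """
    va, vb = state.V[node_a], state.V[node_b]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError(
            "interaction similarity undefined for an all-zero coefficient row"
        )
    return float(va @ vb / (na * nb))
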