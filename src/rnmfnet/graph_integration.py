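"""Integration of several latent graphs into one by learned convex weights.

Given t candidate latent graphs, a weight vector w on the probability
simplex is fit so that the combination of the graphs *restricted to the
labeled nodes* matches the ideal label-derived similarity matrix
Ybar^T Ybar, whose (i, l) entry counts the classes labeled nodes i and l
share.  The fit is the ridge-smoothed least squares problem

    min_w  || sum_i w_i Ebar^(i)  -  Ybar^T Ybar ||_F^2  +  lambda ||w||^2
    s.t.   sum_i w_i = 1,  w_i >= 0

a t-dimensional convex quadratic program.  Because t is tiny (three graph
families), it is solved *exactly* by enumerating active sets: for every
support subset the equality-constrained KKT system is solved in closed
form and the best feasible candidate is returned.  A brute-force simplex
grid search is provided as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import LatentGraph, NetworkDataset

__all__ = [
    "CombinationWeights",
    "restrict_to_labeled",
    "learn_weights",
    "combination_objective",
    "grid_search_weights",
    "integrate",
    "write_weights",
]


@dataclass
class CombinationWeights:
    """Simplex weights over the candidate graphs.

    w : non-negative weights summing to 1, one per graph.
    smoothing : the ridge parameter lambda used in the fit.
    residual : optimal objective value attained by w.
    """

    w: np.ndarray
    smoothing: float = 0.01
    residual: float = float("nan")

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < -1e-12):
            raise ValueError("combination weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError("combination weights must sum to 1")
        self.w = np.clip(self.w, 0.0, None)
        self.w = self.w / self.w.sum()


def restrict_to_labeled(
    graphs: list[LatentGraph], dataset: NetworkDataset
) -> tuple[list[np.ndarray], np.ndarray]:
    """Restrict each graph and the label matrix to the labeled nodes.

    Returns the n' x n' submatrices (labeled rows/columns, in node order)
    and the q x n' label matrix Ybar with Ybar[j, i] = 1 iff the i-th
    labeled node belongs to class j.
    """
    idx = np.flatnonzero(dataset.labeled_mask)
    if idx.size < 2:
        raise ValueError(
            "need at least 2 labeled nodes to fit combination weights"
        )
    restricted = [g.weights[np.ix_(idx, idx)] for g in graphs]
    ybar = dataset.labels[:, idx]
    return restricted, ybar


def combination_objective(
    w: np.ndarray,
    restricted_graphs: list[np.ndarray],
    target: np.ndarray,
    smoothing: float,
) -> float:
    """Misfit ``||sum w_i Ebar_i - target||_F^2 + smoothing * ||w||^2``."""
    combo = sum(wi * g for wi, g in zip(w, restricted_graphs))
    return float(np.sum((combo - target) ** 2) + smoothing * np.sum(w**2))


def _quadratic_coefficients(
    restricted_graphs: list[np.ndarray], target: np.ndarray, smoothing: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Write the objective as w'Aw - 2 b'w + c."""
    t = len(restricted_graphs)
    flat = np.stack([g.ravel() for g in restricted_graphs])  # t x n'^2
    A = flat @ flat.T + smoothing * np.eye(t)
    b = flat @ target.ravel()
    c = float(np.sum(target**2))
    return A, b, c


def learn_weights(
    restricted_graphs: list[np.ndarray],
    target: np.ndarray,
    smoothing: float = 0.01,
) -> CombinationWeights:
    """Exact solution of the simplex-constrained ridge least squares.

    Enumerates all nonempty support subsets S; for each, the
    equality-constrained minimizer (weights sum to 1, zero off S) follows
    from the KKT linear system.  Candidates with negative entries are
    discarded; the feasible candidate with the lowest objective is
    optimal because the active inequality constraints of the true optimum
    correspond to one enumerated support.
    """
    t = len(restricted_graphs)
    if t < 1:
        raise ValueError("need at least one graph")
    shapes = {g.shape for g in restricted_graphs}
    if len(shapes) != 1 or restricted_graphs[0].shape != target.shape:
        raise ValueError("restricted graphs and target must share one shape")
    A, b, c = _quadratic_coefficients(restricted_graphs, target, smoothing)
    best_w, best_obj = None, np.inf
    for mask in range(1, 2**t):
        support = [i for i in range(t) if mask >> i & 1]
        s = len(support)
        As = A[np.ix_(support, support)]
        bs = b[support]
        # KKT: [2As, 1; 1', 0] [w; mu] = [2bs; 1]
        kkt = np.zeros((s + 1, s + 1))
        kkt[:s, :s] = 2 * As
        kkt[:s, s] = 1.0
        kkt[s, :s] = 1.0
        rhs = np.concatenate([2 * bs, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        ws = sol[:s]
        if np.any(ws < -1e-10):
            continue
        w = np.zeros(t)
        w[support] = np.clip(ws, 0.0, None)
        if abs(w.sum() - 1.0) > 1e-8:
            continue
        obj = float(w @ A @ w - 2 * b @ w + c)
        if obj < best_obj:
            best_w, best_obj = w, obj
    if best_w is None:
        raise RuntimeError(
            "no feasible simplex point satisfied the KKT system within "
            "tolerance 1e-8"
        )
    return CombinationWeights(
        w=best_w,
        smoothing=smoothing,
        residual=combination_objective(best_w, restricted_graphs, target, smoothing),
    )


def grid_search_weights(
    restricted_graphs: list[np.ndarray],
    target: np.ndarray,
    smoothing: float = 0.01,
    resolution: float = 0.001,
) -> CombinationWeights:
    """Brute-force search over a regular simplex grid (verification oracle).

    Only practical for t <= 3; enumerates all compositions of
    1/resolution into t parts, vectorized.
    """
    t = len(restricted_graphs)
    steps = int(round(1 / resolution))
    if t == 1:
        pts = np.array([[1.0]])
    elif t == 2:
        i = np.arange(steps + 1)
        pts = np.column_stack([i, steps - i]) / steps
    elif t == 3:
        i, j = np.meshgrid(np.arange(steps + 1), np.arange(steps + 1),
                           indexing="ij")
        keep = i + j <= steps
        i, j = i[keep], j[keep]
        pts = np.column_stack([i, j, steps - i - j]) / steps
    else:
        raise ValueError("grid search supports at most 3 graphs")
    A, b, c = _quadratic_coefficients(restricted_graphs, target, smoothing)
    objs = np.einsum("pi,ij,pj->p", pts, A, pts) - 2 * pts @ b + c
    best = int(np.argmin(objs))
    return CombinationWeights(
        w=pts[best],
        smoothing=smoothing,
        residual=combination_objective(pts[best], restricted_graphs, target, smoothing),
    )


def integrate(
    graphs: list[LatentGraph], weights: CombinationWeights
) -> LatentGraph:
    """Convex combination of full N x N graphs with the learned weights."""
    if len(graphs) != weights.w.size:
        raise ValueError(
            f"{weights.w.size} weights for {len(graphs)} graphs"
        )
    sizes = {g.n_nodes for g in graphs}
    if len(sizes) != 1:
        raise ValueError("all graphs must cover the same node set")
    combined = sum(wi * g.weights for wi, g in zip(weights.w, graphs))
    return LatentGraph(weights=combined, kind="integrated")


def write_weights(
    weights: CombinationWeights, kinds: list[str], path: str | Path
) -> None:
    """Serialize (graph kind, weight) rows as a small TSV."""
    lines = [f"{k}\t{w!r}" for k, w in zip(kinds, weights.w)]
    Path(path).write_text("\n".join(lines) + "\n")
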