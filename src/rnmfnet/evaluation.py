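"""Evaluation metrics and the repeated-split experiment runner.

Metrics are computed on the evaluated (typically unlabeled) nodes against
held-out ground truth:

* accuracy — fraction of evaluated nodes whose single predicted class is
  the true class;
* coverage — how far down the predicted class ranking one must go, on
  average, to collect all of a node's true labels, minus one (0 is
  perfect; at most q - 1);
* ranking loss — average fraction of (true, false) class pairs the score
  orders wrongly, ties counted as errors (0 is perfect, 1 worst).

Both ranking metrics depend only on the ordering of scores, so they are
invariant to strictly monotone transforms.  Rank ties are broken by
ascending class index, matching the ranking produced by the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import NetworkDataset, split_labels
from .graph_integration import integrate, learn_weights, restrict_to_labeled
from .latent_graphs import (
    ErwrParams,
    erwr_latent_graph,
    ppi_latent_graph,
    prediction_similarity_graph,
)
from .rnmf import RnmfParams, predict_single_label, rnmf_fit

__all__ = [
    "accuracy",
    "coverage",
    "ranking_loss",
    "PipelineConfig",
    "run_pipeline",
    "repeat_experiment",
]


def accuracy(
    predictions: np.ndarray, truth: np.ndarray, evaluated_mask: np.ndarray
) -> float:
    """Fraction of evaluated nodes classified correctly (single-label)."""
    evaluated_mask = np.asarray(evaluated_mask, dtype=bool)
    if not evaluated_mask.any():
        raise ValueError("empty evaluation set")
    p = np.asarray(predictions)[evaluated_mask]
    t = np.asarray(truth)[evaluated_mask]
    return float(np.mean(p == t))


def _ranks(scores: np.ndarray) -> np.ndarray:
    """Rank (1 = best) of each class for one node's score vector, with
    ties broken by ascending class index."""
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


def coverage(
    score_matrix: np.ndarray,
    truth: np.ndarray,
    evaluated_mask: np.ndarray,
) -> float:
    """Mean over evaluated nodes of (worst rank among true labels) - 1.

    ``score_matrix`` is N x q (larger is better); ``truth`` is q x N
    binary.  Every evaluated node must have at least one true label.
    """
    evaluated_mask = np.asarray(evaluated_mask, dtype=bool)
    scores = np.asarray(score_matrix, dtype=float)[evaluated_mask]
    y = np.asarray(truth, dtype=float).T[evaluated_mask]
    if not evaluated_mask.any():
        raise ValueError("empty evaluation set")
    if np.any(y.sum(axis=1) == 0):
        raise ValueError("evaluated node with no true label")
    depths = []
    for s, yi in zip(scores, y):
        ranks = _ranks(s)
        depths.append(ranks[yi > 0].max() - 1)
    return float(np.mean(depths))


def ranking_loss(
    score_matrix: np.ndarray,
    truth: np.ndarray,
    evaluated_mask: np.ndarray,
) -> float:
    """Mean fraction of (true, false) class pairs ordered wrongly.

    A pair counts as wrong when the true class's score is <= the false
    class's score (ties are errors).  Nodes whose label set is empty or
    full are excluded with a warning (the pair set is empty).
    """
    evaluated_mask = np.asarray(evaluated_mask, dtype=bool)
    scores = np.asarray(score_matrix, dtype=float)[evaluated_mask]
    y = np.asarray(truth, dtype=float).T[evaluated_mask] > 0
    fractions = []
    skipped = 0
    for s, yi in zip(scores, y):
        n_true, n_false = int(yi.sum()), int((~yi).sum())
        if n_true == 0 or n_false == 0:
            skipped += 1
            continue
        true_scores = s[yi]
        false_scores = s[~yi]
        bad = np.sum(true_scores[:, None] <= false_scores[None, :])
        fractions.append(bad / (n_true * n_false))
    if skipped:
        warnings.warn(
            f"{skipped} node(s) excluded from ranking loss (no true or no "
            "false labels)",
            stacklevel=2,
        )
    if not fractions:
        raise ValueError("no evaluable nodes for ranking loss")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One end-to-end configuration: which latent graphs to build, how to
    integrate them, and the factorization hyperparameters."""

    graphs: tuple[str, ...] = ("ppi", "erwr", "prediction_similarity")
    erwr: ErwrParams = field(default_factory=ErwrParams)
    smoothing: float = 0.01
    rnmf: RnmfParams = field(default_factory=RnmfParams)
    task: str = "single"  # 'single' or 'multi'

    def __post_init__(self) -> None:
        if self.task not in ("single", "multi"):
            raise ValueError("task must be 'single' or 'multi'")
        unknown = set(self.graphs) - {"ppi", "erwr", "prediction_similarity"}
        if unknown:
            raise ValueError(f"unknown latent graph kinds: {sorted(unknown)}")


def build_latent_graphs(dataset: NetworkDataset, config: PipelineConfig):
    """Construct the configured latent graphs for one split."""
    built = []
    for kind in config.graphs:
        if kind == "ppi":
            built.append(ppi_latent_graph(dataset))
        elif kind == "erwr":
            built.append(erwr_latent_graph(dataset, config.erwr))
        else:
            built.append(prediction_similarity_graph(dataset))
    return built


def run_pipeline(
    split: NetworkDataset,
    truth: NetworkDataset,
    config: PipelineConfig,
    seed: int,
) -> dict[str, float]:
    """Graphs -> integration -> factorization -> metrics on one split.

    ``split`` carries the revealed labels; ``truth`` the full ground
    truth.  Metrics are computed on the nodes unlabeled in the split.
    """
    graphs = build_latent_graphs(split, config)
    if len(graphs) > 1:
        restricted, ybar = restrict_to_labeled(graphs, split)
        weights = learn_weights(restricted, ybar.T @ ybar, config.smoothing)
        latent = integrate(graphs, weights)
    else:
        latent = graphs[0]
    params = RnmfParams(
        label_weight=config.rnmf.label_weight,
        graph_weight=config.rnmf.graph_weight,
        K=config.rnmf.K,
        max_iter=config.rnmf.max_iter,
        tol=config.rnmf.tol,
        seed=seed,
        v_init=config.rnmf.v_init,
        reset_labeled=config.rnmf.reset_labeled,
    )
    state = rnmf_fit(split, latent, params)
    evaluated = ~split.labeled_mask
    out: dict[str, float] = {"n_evaluated": float(evaluated.sum())}
    if config.task == "single":
        pred = predict_single_label(state, split)
        true_cls = np.argmax(truth.labels, axis=0)
        out["accuracy"] = accuracy(pred, true_cls, evaluated)
    else:
        out["coverage"] = coverage(state.V, truth.labels, evaluated)
        out["ranking_loss"] = ranking_loss(state.V, truth.labels, evaluated)
    return out


def derive_seed(global_seed: int, ratio_index: int, run_index: int) -> int:
    """Stable per-run seed below 2**31 derived from the experiment seed."""
    ss = np.random.SeedSequence([global_seed, ratio_index, run_index])
    return int(ss.generate_state(1)[0] % (2**31))


def repeat_experiment(
    dataset: NetworkDataset,
    config: PipelineConfig,
    label_ratios: list[float],
    n_runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- sample standard deviation of each metric per label ratio.

    For each ratio, runs the full pipeline ``n_runs`` times on fresh
    uniform label splits with seeds derived from ``seed``.  Returns a
    tidy frame with columns (label_ratio, metric, mean, sd, values).
    """
    if not dataset.labeled_mask.all():
        raise ValueError("repeat_experiment needs fully labeled ground truth")
    records = []
    for ri, ratio in enumerate(label_ratios):
        per_metric: dict[str, list[float]] = {}
        for run in range(n_runs):
            run_seed = derive_seed(seed, ri, run)
            split = split_labels(dataset, ratio, run_seed)
            result = run_pipeline(split, dataset, config, run_seed)
            for name, value in result.items():
                if name == "n_evaluated":
                    continue
                per_metric.setdefault(name, []).append(value)
        for name, values in per_metric.items():
            arr = np.asarray(values)
            records.append(
                {
                    "label_ratio": ratio,
                    "metric": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "values": list(map(float, arr)),
                }
            )
    return pd.DataFrame.from_records(records)
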