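"""Core domain types and file I/O for network classification datasets.

A dataset bundles an undirected weighted interaction network over N nodes,
an M x N non-negative attribute feature matrix (columns are nodes), and a
q x N binary label matrix over q classes.  Only a subset of nodes carries
labels; the rest are the prediction targets.

All matrix indices are fixed by the lexicographic order of node ids (and
class ids), so results are reproducible across runs and file round-trips.
File formats use ids, never indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "NetworkDataset",
    "LatentGraph",
    "read_network",
    "write_network",
    "split_labels",
]

#: Graph provenance tags accepted by :class:`LatentGraph`.
LATENT_GRAPH_KINDS = ("ppi", "erwr", "prediction_similarity", "integrated")


@dataclass
class NetworkDataset:
    """A partially labeled attributed network.

    Attributes
    ----------
    node_ids : list of str
        N opaque node identifiers, in lexicographic order; position in this
        list is the node's matrix index everywhere.
    adjacency : (N, N) ndarray
        Symmetric non-negative edge weight matrix with zero diagonal.
    features : (M, N) ndarray
        Non-negative attribute matrix; column j describes node j.
    labels : (q, N) ndarray
        Binary class membership; column j is all-zero iff node j is
        unlabeled.
    labeled_mask : (N,) bool ndarray
        True for the n' labeled nodes.
    class_ids : list of str
        q class identifiers, in lexicographic order.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    labeled_mask: np.ndarray
    class_ids: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        self.validate()

    # -- derived sizes -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        n = self.n_nodes
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} != ({n}, {n})"
            )
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency weights must be non-negative")
        if self.features.shape[1] != n:
            raise ValueError(
                f"features has {self.features.shape[1]} columns, expected {n}"
            )
        if np.any(self.features < 0):
            i, j = np.argwhere(self.features < 0)[0]
            raise ValueError(
                f"negative feature value at feature row {i}, node column {j} "
                f"(node id {self.node_ids[j]!r})"
            )
        q = self.n_classes
        if self.labels.shape != (q, n):
            raise ValueError(f"labels shape {self.labels.shape} != ({q}, {n})")
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("label entries must be 0 or 1")
        if self.labeled_mask.shape != (n,):
            raise ValueError("labeled_mask length must equal the node count")
        col_any = self.labels.sum(axis=0) > 0
        if np.any(col_any & ~self.labeled_mask):
            raise ValueError("unlabeled node has a nonzero label column")
        if np.any(self.labeled_mask & ~col_any):
            raise ValueError("labeled node has an all-zero label column")

    def copy(self) -> "NetworkDataset":
        return NetworkDataset(
            node_ids=list(self.node_ids),
            adjacency=self.adjacency.copy(),
            features=self.features.copy(),
            labels=self.labels.copy(),
            labeled_mask=self.labeled_mask.copy(),
            class_ids=list(self.class_ids),
        )


@dataclass
class LatentGraph:
    """One N x N non-negative symmetric similarity graph over the nodes.

    ``kind`` records provenance: the observed interaction graph (``ppi``),
    the even-step random-walk graph (``erwr``), the classifier-confidence
    cosine graph (``prediction_similarity``), or a convex combination of
    those (``integrated``).
    """

    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.kind not in LATENT_GRAPH_KINDS:
            raise ValueError(f"unknown latent graph kind {self.kind!r}")
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("latent graph weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("latent graph weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("latent graph weights must be non-negative")
        if self.kind == "ppi" and np.any(np.diag(w) != 0):
            raise ValueError("ppi latent graph must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_features(feature_path: Path) -> tuple[list[str], np.ndarray]:
    """Return (node_ids in file order, M x N matrix).

    Dense TSV: header row of node ids, one row per feature with a leading
    feature-id column.  MatrixMarket: ``<stem>.mtx`` with sidecar id files
    ``<stem>.rows.txt`` (feature ids) and ``<stem>.cols.txt`` (node ids).
    """
    feature_path = Path(feature_path)
    if feature_path.suffix == ".mtx":
        mat = spio.mmread(feature_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        cols_file = feature_path.with_suffix("").with_suffix(".cols.txt")
        node_ids = cols_file.read_text().split()
        if len(node_ids) != mat.shape[1]:
            raise ValueError(
                f"{cols_file} lists {len(node_ids)} node ids but the matrix "
                f"has {mat.shape[1]} columns"
            )
        return node_ids, np.asarray(mat, dtype=float)
    df = pd.read_csv(feature_path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def read_network(
    edge_path: str | Path,
    feature_path: str | Path,
    label_path: str | Path,
) -> NetworkDataset:
    """Assemble a :class:`NetworkDataset` from an edge list, a feature
    matrix, and a partial label assignment.

    The feature file defines the node universe; edge rows must reference
    known node ids.  Nodes absent from the label file are unlabeled.  The
    label file's class ids, sorted lexicographically, form the class
    vocabulary (an empty label file yields q = 0).

    Raises
    ------
    ValueError
        On negative feature values, self-loop edges, duplicate edges with
        conflicting weights, or unknown node ids in the edge/label files.
    """
    file_node_ids, feats = _read_features(Path(feature_path))
    if np.any(feats < 0):
        i, j = np.argwhere(feats < 0)[0]
        raise ValueError(
            f"negative feature value at row {i}, column {j} "
            f"(node id {file_node_ids[j]!r}) in {feature_path}"
        )
    node_ids = sorted(file_node_ids)
    index = {nid: k for k, nid in enumerate(node_ids)}
    # reorder columns into lexicographic node order
    feats = feats[:, [file_node_ids.index(nid) for nid in node_ids]]
    n = len(node_ids)

    adjacency = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    try:
        edges = pd.read_csv(
            edge_path, sep="\t", header=None, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        edges = pd.DataFrame(columns=[0, 1])
    if not edges.empty and edges.shape[1] not in (2, 3):
        raise ValueError("edge file must have 2 or 3 tab-separated columns")
    for row in edges.itertuples(index=False):
        src, dst = str(row[0]), str(row[1])
        weight = 1.0 if edges.shape[1] == 2 or pd.isna(row[2]) else float(row[2])
        if src == dst:
            raise ValueError(f"self-loop edge on node {src!r} rejected")
        for nid in (src, dst):
            if nid not in index:
                raise ValueError(f"edge references unknown node id {nid!r}")
        key = tuple(sorted((index[src], index[dst])))
        if key in seen and seen[key] != weight:
            raise ValueError(
                f"duplicate edge ({src}, {dst}) with conflicting weights "
                f"{seen[key]} and {weight}"
            )
        seen[key] = weight
        adjacency[key[0], key[1]] = adjacency[key[1], key[0]] = weight

    try:
        label_rows = pd.read_csv(label_path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        label_rows = pd.DataFrame()
    memberships: list[tuple[str, str]] = []
    if not label_rows.empty:
        if label_rows.shape[1] != 2:
            raise ValueError("label file must have 2 tab-separated columns")
        for row in label_rows.itertuples(index=False):
            nid, cid = str(row[0]), str(row[1])
            if nid not in index:
                raise ValueError(f"label references unknown node id {nid!r}")
            memberships.append((nid, cid))
    class_ids = sorted({cid for _, cid in memberships})
    class_index = {cid: k for k, cid in enumerate(class_ids)}
    labels = np.zeros((len(class_ids), n))
    labeled_mask = np.zeros(n, dtype=bool)
    for nid, cid in memberships:
        labels[class_index[cid], index[nid]] = 1.0
        labeled_mask[index[nid]] = True
    return NetworkDataset(
        node_ids=node_ids,
        adjacency=adjacency,
        features=feats,
        labels=labels,
        labeled_mask=labeled_mask,
        class_ids=class_ids,
    )


def write_network(dataset: NetworkDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``edges.tsv``, ``features.tsv`` and ``labels.tsv`` under
    ``out_dir``; returns the path of each file.

    Inverse of :func:`read_network` on any valid dataset (round-trip
    identity up to float formatting; weights are written with full
    precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out_dir / "edges.tsv",
        "features": out_dir / "features.tsv",
        "labels": out_dir / "labels.tsv",
    }
    with paths["edges"].open("w") as fh:
        for i, j in zip(*np.triu_indices(dataset.n_nodes, k=1)):
            w = dataset.adjacency[i, j]
            if w != 0:
                fh.write(
                    f"{dataset.node_ids[i]}\t{dataset.node_ids[j]}\t{float(w)!r}\n"
                )
    feat_df = pd.DataFrame(
        dataset.features,
        index=[f"f{i}" for i in range(dataset.n_features)],
        columns=dataset.node_ids,
    )
    feat_df.index.name = "feature_id"
    feat_df.to_csv(paths["features"], sep="\t", float_format="%.17g")
    with paths["labels"].open("w") as fh:
        for j in np.flatnonzero(dataset.labeled_mask):
            for k in np.flatnonzero(dataset.labels[:, j]):
                fh.write(f"{dataset.node_ids[j]}\t{dataset.class_ids[k]}\n")
    return paths


# ---------------------------------------------------------------------------
# Label splitting
# ---------------------------------------------------------------------------

def split_labels(
    dataset: NetworkDataset, label_ratio: float, seed: int
) -> NetworkDataset:
    """Hide labels on all but a uniform random ``round(label_ratio * N)``
    node subset of a fully labeled dataset.

    The returned copy shares nothing with the input; the caller keeps the
    original as ground truth for evaluation.  Adjacency and features are
    copied bit-exactly.  Deterministic given ``seed``.
    """
    if not 0 < label_ratio < 1:
        raise ValueError("label_ratio must lie strictly in (0, 1)")
    if not dataset.labeled_mask.all():
        raise ValueError("split_labels requires a fully labeled dataset")
    n = dataset.n_nodes
    n_keep = int(round(label_ratio * n))
    if n_keep < 1:
        raise ValueError(
            f"label_ratio {label_ratio} keeps zero of {n} nodes labeled"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    out = dataset.copy()
    mask = np.zeros(n, dtype=bool)
    mask[keep] = True
    out.labels[:, ~mask] = 0.0
    out.labeled_mask = mask
    represented = out.labels.sum(axis=1) > 0
    if not represented.all():
        missing = [c for c, r in zip(out.class_ids, represented) if not r]
        warnings.warn(
            f"classes {missing} have no labeled representative at "
            f"ratio {label_ratio}",
            stacklevel=2,
        )
    out.validate()
    return out
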