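"""Supervised clustering tree over per-instance Shapley attributions.

Instances are recursively partitioned in attribution space: at each node, the
node's attribution rows are reduced by PCA, the projections are clustered by
seeded k-means over a small set of candidate cluster counts, and the best
split is accepted only if its silhouette score clears a gate.  Leaves are
labeled high / average / low by their outcome prevalence relative to the
overall prevalence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .attribution import AttributionMatrix

__all__ = [
    "ClusterTreeParams",
    "ClusterNode",
    "silhouette_score",
    "node_pca",
    "split_node",
    "build_cluster_tree",
    "summarize_high_prevalence",
    "leaf_assignments",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterTreeParams:
    max_components: int = 3
    variance_target: float = 0.9
    candidate_k: tuple[int, ...] = (2, 3)
    min_silhouette: float = 0.4
    min_node_size: int = 50
    max_depth: int = 4
    high_factor: float = 2.0
    low_factor: float = 0.5
    seed: int = 0
    #: pairwise silhouette is O(n^2); nodes larger than this are scored on a
    #: seeded subsample
    silhouette_cap: int = 2000

    def __post_init__(self) -> None:
        if not -1.0 < self.min_silhouette < 1.0:
            raise ValueError("min_silhouette must be in (-1, 1)")
        if not self.low_factor < 1.0 < self.high_factor:
            raise ValueError("need low_factor < 1 < high_factor")


@dataclass
class ClusterNode:
    member_indices: np.ndarray
    depth: int
    prevalence: float
    node_id: str = "0"
    pca_basis: np.ndarray | None = None
    children: list["ClusterNode"] = field(default_factory=list)
    silhouette: float | None = None
    label: str | None = None  # high | average | low; leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "depth": self.depth,
            "n_members": int(len(self.member_indices)),
            "members": [int(i) for i in self.member_indices],
            "prevalence": self.prevalence,
            "silhouette": self.silhouette,
            "label": self.label,
            "children": [c.to_dict() for c in self.children],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean of (b - a) / max(a, b); a point in a singleton cluster scores 0."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = cdist(points, points)
    n = len(points)
    scores = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in unique}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (len(own) - 1)
        b = min(dist[i, members[c]].mean() for c in unique if c != labels[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def node_pca(
    attr_rows: np.ndarray, params: ClusterTreeParams
) -> tuple[np.ndarray, np.ndarray] | None:
    """Center the node's rows and project onto the smallest component count
    reaching the variance target (capped); None if the node has no variance."""
    rows = np.asarray(attr_rows, dtype=float)
    centered = rows - rows.mean(axis=0)
    # economy SVD; components are right singular vectors
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0.0 or not np.isfinite(total):
        return None
    frac = np.cumsum(var) / total
    n_comp = int(np.searchsorted(frac, params.variance_target) + 1)
    n_comp = min(n_comp, params.max_components, len(s))
    basis = vt[:n_comp]
    return basis, centered @ basis.T


def _cluster_labels(
    projections: np.ndarray, k: int, seed: int
) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(projections)


def split_node(
    projections: np.ndarray, params: ClusterTreeParams, seed: int
) -> tuple[np.ndarray, float] | None:
    """Best silhouette-gated partition of a node's projections, or None.

    Tries each candidate cluster count (seeded k-means, 10 restarts); a
    candidate producing any cluster smaller than 3 is disqualified.  The
    split is accepted only if the best silhouette clears the gate.
    """
    best: tuple[np.ndarray, float] | None = None
    n = len(projections)
    sil_idx = None
    if n > params.silhouette_cap:
        sil_rng = np.random.default_rng(seed)
        sil_idx = np.sort(sil_rng.choice(n, size=params.silhouette_cap, replace=False))
    for k in params.candidate_k:
        if n < k:
            continue
        labels = _cluster_labels(projections, k, seed)
        counts = np.bincount(labels, minlength=k)
        if counts.min() < 3:
            continue
        if sil_idx is not None:
            idx = sil_idx
            for c in np.setdiff1d(np.unique(labels), np.unique(labels[idx])):
                idx = np.union1d(idx, np.flatnonzero(labels == c)[:3])
            sil = silhouette_score(projections[idx], labels[idx])
        else:
            sil = silhouette_score(projections, labels)
        if best is None or sil > best[1]:
            best = (labels, sil)
    if best is None or best[1] < params.min_silhouette:
        return None if best is None else (None, best[1])  # type: ignore[return-value]
    return best


def build_cluster_tree(
    attr: AttributionMatrix,
    y: np.ndarray,
    params: ClusterTreeParams | None = None,
) -> ClusterNode:
    """Grow the tree from the root and label leaves by relative prevalence."""
    params = params or ClusterTreeParams()
    y = np.asarray(y).astype(int)
    rows = attr.contributions.to_numpy()
    if len(rows) != len(y):
        raise ValueError("attribution rows and outcome vector are misaligned")
    overall = float(y.mean())
    if overall in (0.0, 1.0):
        raise ValueError("overall prevalence is degenerate (0 or 1)")

    counter = {"n": 0}

    def grow(indices: np.ndarray, depth: int, node_id: str) -> ClusterNode:
        node = ClusterNode(
            member_indices=indices,
            depth=depth,
            prevalence=float(y[indices].mean()),
            node_id=node_id,
        )
        if depth >= params.max_depth or len(indices) < params.min_node_size:
            return node
        pca = node_pca(rows[indices], params)
        if pca is None:
            log.info("node %s has zero attribution variance; leaf", node_id)
            return node
        basis, projections = pca
        counter["n"] += 1
        result = split_node(projections, params, seed=params.seed + counter["n"])
        if result is None or result[0] is None:
            if result is not None:
                log.info(
                    "node %s best silhouette %.3f below gate %.2f; leaf",
                    node_id, result[1], params.min_silhouette,
                )
            return node
        labels, sil = result
        node.pca_basis = basis
        node.silhouette = float(sil)
        for c in np.unique(labels):
            child_idx = indices[labels == c]
            node.children.append(grow(child_idx, depth + 1, f"{node_id}.{c}"))
        return node

    root = grow(np.arange(len(rows)), 0, "0")
    for leaf in root.leaves():
        if leaf.prevalence >= params.high_factor * overall:
            leaf.label = "high"
        elif leaf.prevalence <= params.low_factor * overall:
            leaf.label = "low"
        else:
            leaf.label = "average"
    return root


def summarize_high_prevalence(
    root: ClusterNode, attr: AttributionMatrix, top_n: int = 10
) -> dict[str, list[dict]]:
    """Ranked driver features (mean signed contribution, with dispersion) for
    every high-prevalence leaf; empty when no leaf is labeled high."""
    out: dict[str, list[dict]] = {}
    contrib = attr.contributions
    for leaf in root.leaves():
        if leaf.label != "high":
            continue
        sub = contrib.iloc[leaf.member_indices]
        means = sub.mean(axis=0)
        order = means.abs().sort_values(ascending=False).index[:top_n]
        out[leaf.node_id] = [
            {
                "feature": f,
                "mean_contribution": float(means[f]),
                "sd": float(sub[f].std(ddof=0)),
                "q25": float(sub[f].quantile(0.25)),
                "q75": float(sub[f].quantile(0.75)),
            }
            for f in order
        ]
    return out


def leaf_assignments(root: ClusterNode) -> pd.DataFrame:
    """Flat (instance, leaf id, label) table covering every instance."""
    records = []
    for leaf in root.leaves():
        for i in leaf.member_indices:
            records.append((int(i), leaf.node_id, leaf.label))
    df = pd.DataFrame(records, columns=["instance", "leaf_id", "label"])
    return df.sort_values("instance").reset_index(drop=True)
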