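"""Per-instance Shapley attributions under one removal scheme.

Every flavor here explains the same cooperative game: the value of a feature
coalition S for instance x is the expected model output when features outside
S are replaced by values from an explicit background sample (marginal /
interventional removal).  Flavors:

- ``shap_exact``: exact enumeration over all 2^d coalitions (test oracle).
- ``shap_linear``: closed form for linear models on the link scale.
- ``shap_tree``: exact polynomial-time computation for additive tree
  ensembles, via per-leaf coalition-pattern tables.
- ``shap_marginal``: model-agnostic permutation sampling with per-row
  Monte-Carlo standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "AttributionMatrix",
    "Tree",
    "extract_trees",
    "tree_margin",
    "shap_exact",
    "shap_linear",
    "shap_tree",
    "shap_marginal",
    "summary_ranking",
]


@dataclass
class AttributionMatrix:
    contributions: pd.DataFrame      # instances x features
    base_value: float                # expected output over the background
    model_outputs: np.ndarray
    feature_values: pd.DataFrame     # aligned copy of the explained rows
    flavor: str                      # linear | tree | marginal | exact
    standard_errors: pd.DataFrame | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.contributions.columns)

    def additivity_gap(self) -> np.ndarray:
        """Per-row |base + sum(contributions) - model_output|."""
        total = self.base_value + self.contributions.to_numpy().sum(axis=1)
        return np.abs(total - self.model_outputs)

    def to_files(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        self.contributions.to_csv(csv_path, index=False)
        meta = {
            "base_value": self.base_value,
            "flavor": self.flavor,
            "n_instances": int(len(self.contributions)),
            "features": self.feature_names,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------


def shap_exact(
    predict_fn, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact Shapley values of the marginal-expectation game for one row.

    Enumerates all 2^d coalitions; rejects d > 15.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if d > 15:
        raise ValueError("shap_exact enumerates 2^d coalitions; d must be <= 15")
    m = background.shape[0]
    n_masks = 1 << d
    # hybrid rows for every (coalition, background row)
    hybrids = np.repeat(background, n_masks, axis=0).reshape(m, n_masks, d)
    for j in range(d):
        masks_with_j = (np.arange(n_masks) >> j) & 1 == 1
        hybrids[:, masks_with_j, j] = x[j]
    preds = np.asarray(predict_fn(hybrids.reshape(m * n_masks, d)), dtype=float)
    v = preds.reshape(m, n_masks).mean(axis=0)

    phi = np.zeros(d)
    weights = [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    popcount = np.array([bin(mask).count("1") for mask in range(n_masks)])
    for j in range(d):
        bit = 1 << j
        without = np.flatnonzero((np.arange(n_masks) & bit) == 0)
        w = np.array([weights[popcount[s]] for s in without])
        phi[j] = float(np.sum(w * (v[without | bit] - v[without])))
    return phi, float(v[0])


# ---------------------------------------------------------------------------
# Linear SHAP
# ---------------------------------------------------------------------------


def shap_linear(model, X, feature_means: np.ndarray) -> AttributionMatrix:
    """Closed-form attributions for a linear model on the link scale.

    ``model`` is a fitted :class:`LogisticRegression` or a ``(coef,
    intercept)`` pair.  Contribution of feature j for row i is
    ``beta_j * (x_ij - mean_j)``.
    """
    if isinstance(model, LogisticRegression):
        coef = model.coef_.ravel()
        intercept = float(model.intercept_.ravel()[0])
    else:
        coef, intercept = model
        coef = np.asarray(coef, dtype=float).ravel()
        intercept = float(intercept)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{j}" for j in range(coef.size)
    ]
    Xv = np.asarray(X, dtype=float)
    means = np.asarray(feature_means, dtype=float).ravel()
    contrib = coef[None, :] * (Xv - means[None, :])
    base = intercept + float(coef @ means)
    outputs = intercept + Xv @ coef
    return AttributionMatrix(
        contributions=pd.DataFrame(contrib, columns=names),
        base_value=base,
        model_outputs=outputs,
        feature_values=pd.DataFrame(Xv, columns=names),
        flavor="linear",
    )


# ---------------------------------------------------------------------------
# Tree SHAP (marginal-expectation game, exact)
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Binary decision tree; split rule is ``x[feature] <= threshold`` -> left."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    is_leaf: np.ndarray


def extract_trees(model) -> tuple[list[Tree], float]:
    """Pull the additive tree structure out of a fitted
    :class:`~sklearn.ensemble.HistGradientBoostingClassifier`.

    Returns the trees and the constant baseline margin; the raw decision
    function equals ``baseline + sum(tree outputs)``.
    """
    if not hasattr(model, "_predictors"):
        raise TypeError("model does not expose an additive tree structure")
    trees = []
    for group in model._predictors:
        for predictor in group:
            nodes = predictor.nodes
            trees.append(
                Tree(
                    feature=nodes["feature_idx"].astype(int),
                    threshold=nodes["num_threshold"].astype(float),
                    left=nodes["left"].astype(int),
                    right=nodes["right"].astype(int),
                    value=nodes["value"].astype(float),
                    is_leaf=nodes["is_leaf"].astype(bool),
                )
            )
    baseline = float(np.ravel(model._baseline_prediction)[0])
    return trees, baseline


def tree_margin(trees: list[Tree], baseline: float, X: np.ndarray) -> np.ndarray:
    """Raw margin by explicit tree descent (independent of sklearn predict)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.full(X.shape[0], baseline)
    for tree in trees:
        idx = np.zeros(X.shape[0], dtype=int)
        while not tree.is_leaf[idx].all():
            go_left = X[np.arange(X.shape[0]), tree.feature[idx]] <= tree.threshold[idx]
            nxt = np.where(go_left, tree.left[idx], tree.right[idx])
            idx = np.where(tree.is_leaf[idx], idx, nxt)
        out += tree.value[idx]
    return out


def _leaf_paths(tree: Tree) -> list[tuple[float, dict[int, tuple[float, float]]]]:
    """(leaf value, {feature: (lo, hi] interval}) for every leaf."""
    paths = []

    def descend(node: int, constraints: dict[int, tuple[float, float]]) -> None:
        if tree.is_leaf[node]:
            paths.append((float(tree.value[node]), dict(constraints)))
            return
        f, t = int(tree.feature[node]), float(tree.threshold[node])
        had = f in constraints
        lo, hi = constraints.get(f, (-np.inf, np.inf))
        if lo < min(hi, t):
            constraints[f] = (lo, min(hi, t))
            descend(int(tree.left[node]), constraints)
        if max(lo, t) < hi:
            constraints[f] = (max(lo, t), hi)
            descend(int(tree.right[node]), constraints)
        if had:
            constraints[f] = (lo, hi)
        else:
            del constraints[f]

    descend(0, {})
    return paths


def _pattern_tables(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Shapley weight tables for a leaf with p path features.

    For instance pattern a and background pattern b (bit j set = passes the
    path constraints on feature j), feature j's weight is
    ``+ (d-1)! c! / (d+c)!`` if j is in D = a & ~b, ``- d! (c-1)! / (d+c)!``
    if j is in C = b & ~a, else 0, where d = |D| and c = |C|.  Returns
    ``w[a, b, j]``and popcounts.
    """
    size = 1 << p
    full = size - 1
    pop = np.array([bin(v).count("1") for v in range(size)])
    w = np.zeros((size, size, p))
    for a in range(size):
        for b in range(size):
            if (a | b) != full:
                continue  # some path feature fails for both x and b: leaf unreachable
            D = a & ~b
            C = b & ~a
            d, c = int(pop[D]), int(pop[C])
            if d:
                wd = factorial(d - 1) * factorial(c) / factorial(d + c)
                for j in range(p):
                    if (D >> j) & 1:
                        w[a, b, j] = wd
            if c:
                wc = factorial(d) * factorial(c - 1) / factorial(d + c)
                for j in range(p):
                    if (C >> j) & 1:
                        w[a, b, j] = -wc
    return w, pop


_TABLE_CACHE: dict[int, np.ndarray] = {}


def _weights_for(p: int) -> np.ndarray:
    if p not in _TABLE_CACHE:
        _TABLE_CACHE[p] = _pattern_tables(p)[0]
    return _TABLE_CACHE[p]


def shap_tree(
    tree_model, X, background, column_names: list[str] | None = None
) -> AttributionMatrix:
    """Exact marginal-expectation Shapley values for an additive tree ensemble.

    Accepts a fitted ``HistGradientBoostingClassifier`` or a ``(trees,
    baseline)`` pair.  Attributions are on the margin (log-odds) scale.
    """
    if isinstance(tree_model, tuple):
        trees, baseline = tree_model
    else:
        trees, baseline = extract_trees(tree_model)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else column_names
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = Xv.shape
    m = B.shape[0]
    if names is None:
        names = [f"f{j}" for j in range(d)]

    phi = np.zeros((n, d))
    for tree in trees:
        for value, constraints in _leaf_paths(tree):
            feats = list(constraints)
            p = len(feats)
            if p == 0:  # constant tree: contributes only to the base value
                continue
            los = np.array([constraints[f][0] for f in feats])
            his = np.array([constraints[f][1] for f in feats])
            x_pass = (Xv[:, feats] > los) & (Xv[:, feats] <= his)
            b_pass = (B[:, feats] > los) & (B[:, feats] <= his)
            powers = 1 << np.arange(p)
            a_pat = x_pass @ powers
            b_pat = b_pass @ powers
            b_freq = np.bincount(b_pat, minlength=1 << p) / m
            w = _weights_for(p)                       # (2^p, 2^p, p)
            table = value * np.tensordot(w, b_freq, axes=([1], [0]))  # (2^p, p)
            phi[:, feats] += table[a_pat]
    # expected output over the background, computed by explicit descent
    base = float(tree_margin(trees, baseline, B).mean())
    outputs = tree_margin(trees, baseline, Xv)
    return AttributionMatrix(
        contributions=pd.DataFrame(phi, columns=names),
        base_value=base,
        model_outputs=outputs,
        feature_values=pd.DataFrame(Xv, columns=names),
        flavor="tree",
    )


# ---------------------------------------------------------------------------
# Marginal (model-agnostic) SHAP
# ---------------------------------------------------------------------------


def shap_marginal(
    predict_fn,
    X,
    background,
    n_samples: int = 128,
    seed: int = 0,
    column_names: list[str] | None = None,
) -> AttributionMatrix:
    """Permutation-sampling Shapley estimate of the marginal game.

    Each sample draws one feature ordering and one background row (shared
    across explained rows); contributions telescope so additivity holds
    exactly against the mean sampled background output.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else column_names
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    B = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = Xv.shape
    if names is None:
        names = [f"f{j}" for j in range(d)]
    rng = np.random.default_rng(seed)

    total = np.zeros((n, d))
    total_sq = np.zeros((n, d))
    base_acc = 0.0
    for _ in range(n_samples):
        order = rng.permutation(d)
        b = B[rng.integers(B.shape[0])]
        hybrid = np.tile(b, (n, 1))
        prev = np.asarray(predict_fn(hybrid), dtype=float)
        base_acc += float(prev[0])
        for f in order:
            hybrid[:, f] = Xv[:, f]
            cur = np.asarray(predict_fn(hybrid), dtype=float)
            delta = cur - prev
            total[:, f] += delta
            total_sq[:, f] += delta**2
            prev = cur
    phi = total / n_samples
    var = np.maximum(total_sq / n_samples - phi**2, 0.0)
    se = np.sqrt(var / n_samples)
    return AttributionMatrix(
        contributions=pd.DataFrame(phi, columns=names),
        base_value=base_acc / n_samples,
        model_outputs=np.asarray(predict_fn(Xv), dtype=float),
        feature_values=pd.DataFrame(Xv, columns=names),
        flavor="marginal",
        standard_errors=pd.DataFrame(se, columns=names),
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def summary_ranking(
    attr: AttributionMatrix, group_map: dict[str, str]
) -> dict[str, list[tuple[str, float]]]:
    """Per group, features ordered by mean |contribution| (desc, stable)."""
    missing = [f for f in attr.feature_names if f not in group_map]
    if missing:
        raise ValueError(f"features missing from group map: {missing}")
    mean_abs = attr.contributions.abs().mean(axis=0)
    out: dict[str, list[tuple[str, float]]] = {}
    for feat in attr.feature_names:
        out.setdefault(group_map[feat], []).append((feat, float(mean_abs[feat])))
    for group in out:
        out[group] = sorted(out[group], key=lambda t: -t[1])
    return out
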