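"""Global feature importance: AUC-based SAGE, coefficient ranking, and
feature-inclusion curves.

The SAGE estimator is a permutation-sampling Shapley estimator whose value
function is the AUC of the model's scores after marginalizing the features
outside the coalition with draws from a fixed background sample.  The value of
the empty coalition is fixed analytically at 0.5 (scores independent of the
labels), which makes the efficiency identity sum(values) = full_auc - 0.5 hold
exactly per sampled permutation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .ensemble import EnsembleHyperparams, auc, evaluate, fit_ensemble
from .preprocess import apply_preprocess, fit_preprocess

__all__ = [
    "SageRanking",
    "InclusionCurve",
    "sage_auc",
    "coef_importance",
    "inclusion_curve",
    "select_top_k",
    "aggregate_to_parents",
]

log = logging.getLogger(__name__)


@dataclass
class SageRanking:
    values: dict[str, float]
    standard_errors: dict[str, float]
    n_permutations: int
    baseline_auc: float       # v(empty set); fixed at 0.5 analytically
    full_auc: float           # v(all features) on the evaluation subsample

    def ordered(self) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda t: -t[1])

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.ordered()[:k]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "values": self.values,
                    "standard_errors": self.standard_errors,
                    "n_permutations": self.n_permutations,
                    "baseline_auc": self.baseline_auc,
                    "full_auc": self.full_auc,
                },
                indent=2,
            )
        )


def _stratified_subsample(y: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a label-stratified subsample of size <= cap."""
    n = len(y)
    if n <= cap:
        return np.arange(n)
    idx = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        take = max(2, int(round(cap * len(cls_idx) / n)))
        idx.append(rng.choice(cls_idx, size=min(take, len(cls_idx)), replace=False))
    return np.sort(np.concatenate(idx))


def sage_auc(
    predict_fn,
    X,
    y: np.ndarray,
    background,
    n_permutations: int = 64,
    seed: int = 0,
    eval_cap: int = 2000,
    marginal_mode: str = "draw",
) -> SageRanking:
    """Shapley values of the AUC value function by permutation sampling.

    For each sampled feature ordering, features enter one at a time; rows
    start as background draws and one column at a time is switched to the
    true values, re-scoring the fixed evaluation subsample after each switch.
    Per-feature values are mean marginal AUC gains across permutations, with
    standard errors from the across-permutation variance.

    ``marginal_mode`` controls how out-of-coalition features are removed:
    ``"draw"`` substitutes one background row per evaluation row per
    permutation (cheap, extra Monte-Carlo noise averaged over permutations);
    ``"mean"`` scores every evaluation row against the full background and
    averages, making the value function deterministic given the background
    (used by the exact-enumeration oracle in the tests).
    """
    if n_permutations < 2:
        raise ValueError("need n_permutations >= 2 to estimate standard errors")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    B = np.atleast_2d(np.asarray(background, dtype=float))
    if B.shape[0] == 0:
        raise ValueError("background sample is empty")
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, d = Xv.shape
    if names is None:
        names = [f"f{j}" for j in range(d)]
    rng = np.random.default_rng(seed)

    eval_idx = _stratified_subsample(y, eval_cap, rng)
    X_eval, y_eval = Xv[eval_idx], y[eval_idx]
    n_eval = len(eval_idx)
    full_auc = auc(np.asarray(predict_fn(X_eval), dtype=float), y_eval)

    if marginal_mode not in ("draw", "mean"):
        raise ValueError("marginal_mode must be 'draw' or 'mean'")
    m = B.shape[0]
    gains = np.zeros((n_permutations, d))
    for p in range(n_permutations):
        order = rng.permutation(d)
        if marginal_mode == "draw":
            hybrid = B[rng.integers(m, size=n_eval)].copy()
        else:
            # (row, background) pairs; scores average over the background axis
            hybrid = np.repeat(B[None, :, :], n_eval, axis=0).reshape(n_eval * m, d)
        prev_v = 0.5  # v(empty): scores carry no label information
        for step, f in enumerate(order):
            if marginal_mode == "draw":
                hybrid[:, f] = X_eval[:, f]
            else:
                hybrid[:, f] = np.repeat(X_eval[:, f], m)
            if step < d - 1:
                scores = np.asarray(predict_fn(hybrid), dtype=float)
                if marginal_mode == "mean":
                    scores = scores.reshape(n_eval, m).mean(axis=1)
                v = auc(scores, y_eval)
            else:  # all features restored: the value is the full AUC exactly
                v = full_auc
            gains[p, f] = v - prev_v
            prev_v = v

    values = gains.mean(axis=0)
    ses = gains.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return SageRanking(
        values={names[j]: float(values[j]) for j in range(d)},
        standard_errors={names[j]: float(ses[j]) for j in range(d)},
        n_permutations=n_permutations,
        baseline_auc=0.5,
        full_auc=full_auc,
    )


def aggregate_to_parents(
    values: dict[str, float], parent: dict[str, str]
) -> dict[str, float]:
    """Sum encoded-column values up to their parent cohort features."""
    out: dict[str, float] = {}
    for name, v in values.items():
        out[parent.get(name, name)] = out.get(parent.get(name, name), 0.0) + v
    return out


def coef_importance(
    logistic_model: LogisticRegression,
    feature_names: list[str],
    X=None,
) -> list[tuple[str, float]]:
    """Features ordered by |coefficient| descending; ties keep declared order."""
    coef = np.asarray(logistic_model.coef_).ravel()
    if len(feature_names) != coef.size:
        raise ValueError("feature_names length does not match the coefficient vector")
    if X is not None:
        Xv = np.asarray(X, dtype=float)
        means, sds = Xv.mean(axis=0), Xv.std(axis=0)
        nonconst = sds > 0
        if np.abs(means).max() > 0.5 or (
            nonconst.any() and np.abs(sds[nonconst] - 1).max() > 0.5
        ):
            log.warning(
                "coef_importance expects standardized features; "
                "column means/SDs look unstandardized"
            )
    order = sorted(range(coef.size), key=lambda j: (-abs(coef[j]), j))
    return [(feature_names[j], float(coef[j])) for j in order]


@dataclass
class InclusionCurve:
    ks: list[int]
    performance: list[float]
    ranking_used: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"ks": self.ks, "performance": self.performance, "ranking": self.ranking_used},
                indent=2,
            )
        )


def inclusion_curve(
    table: pd.DataFrame,
    y: np.ndarray,
    ranking: list[str],
    ks: list[int],
    cv_seed: int = 0,
    hyperparams: EnsembleHyperparams | None = None,
    missing_thresh: float = 0.6,
    corr_thresh: float = 0.8,
) -> InclusionCurve:
    """Held-out AUC of the ensemble refit on the top-k encoded features.

    A single fixed 80/20 split (seeded) is used for the whole curve; k = 0
    records the no-information baseline 0.5 without fitting.
    """
    if list(ks) != sorted(ks):
        raise ValueError("ks must be increasing")
    if max(ks) > len(ranking):
        raise ValueError("max k exceeds the ranked feature count")
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(cv_seed)
    perm = rng.permutation(len(table))
    n_train = int(round(0.8 * len(table)))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    plan = fit_preprocess(table.iloc[train_idx], missing_thresh, corr_thresh)
    X_train = apply_preprocess(plan, table.iloc[train_idx])
    X_test = apply_preprocess(plan, table.iloc[test_idx])
    available = [f for f in ranking if f in X_train.columns]

    perf: list[float] = []
    for k in ks:
        if k == 0:
            perf.append(0.5)
            continue
        cols = available[:k]
        ens = fit_ensemble(X_train[cols], y[train_idx], seed=cv_seed, hyperparams=hyperparams)
        report = evaluate(ens, X_test[cols], y[test_idx], n_boot=0)
        perf.append(float(report.auc))
    return InclusionCurve(ks=list(ks), performance=perf, ranking_used=list(ranking))


def select_top_k(curve: InclusionCurve, tolerance: float = 0.005) -> int:
    """Smallest k whose AUC is within ``tolerance`` of the curve maximum."""
    if not curve.ks:
        raise ValueError("empty inclusion curve")
    best = max(curve.performance)
    for k, perf in zip(curve.ks, curve.performance):
        if perf >= best - tolerance:
            return k
    return curve.ks[-1]
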