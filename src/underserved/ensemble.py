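"""Calibrated soft-voting classifier and imbalance-aware evaluation.

The ensemble averages a ridge-penalized logistic regression with an
isotonic-calibrated gradient-boosted tree model.  Evaluation uses Monte Carlo
cross-validation (repeated random train/test splits) with metrics robust to
heavy class imbalance (AUC, sensitivity, specificity, precision, lift, MCC),
classifying at the MCC-maximal threshold selected on training scores.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocess import PreprocessPlan, apply_preprocess, fit_preprocess

__all__ = [
    "EnsembleHyperparams",
    "CalibratedEnsemble",
    "MetricReport",
    "CVSummary",
    "auc",
    "mcc",
    "select_threshold",
    "fit_ensemble",
    "evaluate",
    "monte_carlo_cv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleHyperparams:
    ridge_c: float = 1.0           # inverse L2 strength for the logistic member
    n_rounds: int = 300
    max_depth: int = 4
    learning_rate: float = 0.05
    class_weighted: bool = True    # positive-class weight = n_neg / n_pos
    calibration_folds: int = 5
    vote_weights: tuple[float, float] = (0.5, 0.5)  # (tree, logistic)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation; 0 by convention when any marginal is 0."""
    tp, fp, fn, tn = (float(v) for v in (tp, fp, fn, tn))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def _confusion(scores: np.ndarray, y: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = np.asarray(scores) >= threshold
    y = np.asarray(y).astype(bool)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    return tp, fp, fn, tn


def select_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """MCC-maximal decision threshold over midpoints of distinct sorted scores
    plus endpoints; ties resolve to the smallest candidate."""
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    candidates = [float(distinct[0]) - 1.0]
    candidates.extend(0.5 * (distinct[:-1] + distinct[1:]))
    candidates.append(float(distinct[-1]) + 1.0)
    best_t, best_m = candidates[0], -np.inf
    for t in candidates:
        m = mcc(*_confusion(scores, y, t))
        if m > best_m + 1e-15:
            best_t, best_m = float(t), m
    return best_t


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class CalibratedEnsemble:
    logistic_model: LogisticRegression
    tree_model: HistGradientBoostingClassifier
    isotonic_x: np.ndarray          # step-function support (raw tree prob)
    isotonic_y: np.ndarray          # calibrated values, nondecreasing in [0,1]
    vote_weights: tuple[float, float]
    threshold: float
    feature_names: list[str] = field(default_factory=list)

    def calibrate(self, raw: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(raw, dtype=float), self.isotonic_x, self.isotonic_y)

    def member_probs(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tree_p = self.calibrate(self.tree_model.predict_proba(X)[:, 1])
        logit_p = self.logistic_model.predict_proba(X)[:, 1]
        return tree_p, logit_p

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        w_tree, w_logit = self.vote_weights
        tree_p, logit_p = self.member_probs(X)
        return w_tree * tree_p + w_logit * logit_p

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


def _sample_weights(y: np.ndarray, hp: EnsembleHyperparams) -> np.ndarray | None:
    if not hp.class_weighted:
        return None
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    w = np.ones(len(y))
    w[y == 1] = n_neg / max(n_pos, 1)
    return w


def _fit_tree(X, y, seed: int, hp: EnsembleHyperparams) -> HistGradientBoostingClassifier:
    model = HistGradientBoostingClassifier(
        max_iter=hp.n_rounds,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        early_stopping=False,
        random_state=seed,
    )
    model.fit(X, y, sample_weight=_sample_weights(y, hp))
    return model


def fit_ensemble(
    X,
    y: np.ndarray,
    seed: int = 0,
    hyperparams: EnsembleHyperparams | None = None,
) -> CalibratedEnsemble:
    """Fit both members, cross-fit the isotonic map, and pick the threshold.

    The isotonic map is fit on out-of-fold tree predictions (K-fold within
    the training data) so no row is calibrated against its own fit.
    """
    hp = hyperparams or EnsembleHyperparams()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    logistic = LogisticRegression(C=hp.ridge_c, max_iter=2000)
    logistic.fit(X, y)

    n_folds = min(hp.calibration_folds, int(y.sum()), int((1 - y).sum()))
    oof_raw = np.empty(len(y))
    if n_folds >= 2:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fit_idx, held_idx in kf.split(X, y):
            fold_model = _fit_tree(X[fit_idx], y[fit_idx], seed, hp)
            oof_raw[held_idx] = fold_model.predict_proba(X[held_idx])[:, 1]
    else:  # degenerate tiny data: calibrate in-sample
        oof_raw[:] = _fit_tree(X, y, seed, hp).predict_proba(X)[:, 1]
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(oof_raw, y)
    iso_x = np.asarray(iso.X_thresholds_, dtype=float)
    iso_y = np.asarray(iso.y_thresholds_, dtype=float)
    if iso_x.size == 1:
        iso_x = np.array([iso_x[0], iso_x[0] + 1e-12])
        iso_y = np.array([iso_y[0], iso_y[0]])

    tree = _fit_tree(X, y, seed, hp)
    ensemble = CalibratedEnsemble(
        logistic_model=logistic,
        tree_model=tree,
        isotonic_x=iso_x,
        isotonic_y=iso_y,
        vote_weights=hp.vote_weights,
        threshold=0.5,
        feature_names=feature_names,
    )
    ensemble.threshold = select_threshold(ensemble.predict_proba(X), y)
    return ensemble


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    auc: float | None
    sensitivity: float
    specificity: float
    precision: float
    lift: float
    mcc: float
    threshold: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _auc_bootstrap_ci(
    scores: np.ndarray, y: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        stats[b] = auc(scores[idx], y[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate(
    ensemble: CalibratedEnsemble,
    X,
    y: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricReport:
    """All metrics at the ensemble's threshold; AUC CI by stratified bootstrap."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    scores = ensemble.predict_proba(X)
    tp, fp, fn, tn = _confusion(scores, y, ensemble.threshold)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    prevalence = y.mean()
    lift = prec / prevalence if prevalence > 0 else 0.0
    single_class = len(np.unique(y)) < 2
    auc_val = ci_lo = ci_hi = None
    if not single_class:
        auc_val = auc(scores, y)
        if n_boot > 0:
            ci_lo, ci_hi = _auc_bootstrap_ci(scores, y, n_boot, seed)
    return MetricReport(
        auc=auc_val,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        lift=lift,
        mcc=mcc(tp, fp, fn, tn),
        threshold=ensemble.threshold,
        confusion=(tp, fp, fn, tn),
        ci_low=ci_lo,
        ci_high=ci_hi,
    )


@dataclass
class CVSummary:
    per_split: list[MetricReport]
    best_split: MetricReport
    mean_auc: float
    mean_auc_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "best_split": self.best_split.to_dict(),
            "splits": {
                "n_iterations": len(self.per_split),
                "mean_auc": self.mean_auc,
                "mean_auc_ci": list(self.mean_auc_ci),
            },
            "per_split": [r.to_dict() for r in self.per_split],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _split_indices(
    n: int, train_frac: float, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random split; reseeds (logged) until both classes appear in train."""
    attempt_seed = seed
    for _ in range(100):
        rng = np.random.default_rng(attempt_seed)
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if len(np.unique(y[train_idx])) == 2 and len(np.unique(y[test_idx])) == 2:
            return train_idx, test_idx
        log.warning("split seed %d missing a class; resampling", attempt_seed)
        attempt_seed += 1000
    raise ValueError("could not draw a split containing both classes")


def monte_carlo_cv(
    table: pd.DataFrame,
    y: np.ndarray,
    n_iterations: int = 30,
    train_frac: float = 0.8,
    base_seed: int = 0,
    hyperparams: EnsembleHyperparams | None = None,
    missing_thresh: float = 0.6,
    corr_thresh: float = 0.8,
    n_boot: int = 2000,
) -> CVSummary:
    """Repeated random train/test splits; preprocessing, calibration and the
    decision threshold are all fit inside each training split."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0,1)")
    y = np.asarray(y).astype(int)
    reports: list[MetricReport] = []
    for i in range(n_iterations):
        split_seed = base_seed + i
        train_idx, test_idx = _split_indices(len(table), train_frac, y, split_seed)
        train_tab, test_tab = table.iloc[train_idx], table.iloc[test_idx]
        plan = fit_preprocess(train_tab, missing_thresh, corr_thresh)
        X_train = apply_preprocess(plan, train_tab)
        X_test = apply_preprocess(plan, test_tab)
        ens = fit_ensemble(X_train, y[train_idx], seed=split_seed, hyperparams=hyperparams)
        reports.append(
            evaluate(ens, X_test, y[test_idx], n_boot=n_boot, seed=split_seed)
        )
    aucs = np.array([r.auc for r in reports], dtype=float)
    best = reports[int(np.argmax(aucs))]
    mean_auc = float(aucs.mean())
    half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0
    return CVSummary(
        per_split=reports,
        best_split=best,
        mean_auc=mean_auc,
        mean_auc_ci=(mean_auc - half, mean_auc + half),
    )
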