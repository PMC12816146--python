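"""Training-only preprocessing: missingness/collinearity filters, median
imputation, full one-hot encoding, and z-score standardization.

All statistics in a :class:`PreprocessPlan` come from the fitting table alone;
applying the plan to new data reuses those statistics (no leakage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessPlan",
    "fit_preprocess",
    "apply_preprocess",
    "pairwise_correlation_filter",
    "MISSING_LEVEL",
]

log = logging.getLogger(__name__)

#: Explicit category used when a categorical column has missing entries.
MISSING_LEVEL = "__missing__"


@dataclass
class PreprocessPlan:
    dropped_missingness: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    medians: dict[str, float] = field(default_factory=dict)
    category_levels: dict[str, list[str]] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: parent feature of every encoded column (one-hot children map to their
    #: categorical parent; continuous columns map to themselves)
    parent: dict[str, str] = field(default_factory=dict)

    @property
    def output_columns(self) -> list[str]:
        return list(self.standardization)

    @property
    def input_columns(self) -> list[str]:
        return list(self.medians) + list(self.category_levels)

    def to_json(self, path: str | Path) -> None:
        d = {
            "dropped_missingness": self.dropped_missingness,
            "dropped_collinear": [list(t) for t in self.dropped_collinear],
            "medians": self.medians,
            "category_levels": self.category_levels,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "parent": self.parent,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            dropped_missingness=d["dropped_missingness"],
            dropped_collinear=[tuple(t) for t in d["dropped_collinear"]],
            medians=d["medians"],
            category_levels=d["category_levels"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            parent=d["parent"],
        )


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def pairwise_correlation_filter(
    matrix: pd.DataFrame, corr_thresh: float
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy scan in column order; drop a column whose |Pearson r| with any
    already-kept column exceeds the threshold.

    Correlations use pairwise-complete observations; a zero-variance column
    correlates 0 with everything and is never dropped by this filter.
    """
    if matrix.shape[1] < 2:
        return list(matrix.columns), []
    corr = matrix.corr().fillna(0.0)
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in matrix.columns:
        partner = None
        for k in kept:
            r = float(corr.loc[k, col])
            if abs(r) > corr_thresh:
                partner = (k, col, r)
                break
        if partner is None:
            kept.append(col)
        else:
            dropped.append(partner)
    return kept, dropped


def fit_preprocess(
    train: pd.DataFrame, missing_thresh: float = 0.6, corr_thresh: float = 0.8
) -> PreprocessPlan:
    """Fit filters, medians, category levels and post-encoding z-score stats."""
    if train.empty:
        raise ValueError("training table is empty")
    if not (0.0 < missing_thresh <= 1.0 and 0.0 < corr_thresh <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    plan = PreprocessPlan()

    miss_frac = train.isna().mean()
    plan.dropped_missingness = [c for c in train.columns if miss_frac[c] > missing_thresh]
    cols = [c for c in train.columns if c not in plan.dropped_missingness]

    continuous = [c for c in cols if not _is_categorical(train[c])]
    categorical = [c for c in cols if _is_categorical(train[c])]

    if len(continuous) >= 2:
        kept, dropped = pairwise_correlation_filter(train[continuous], corr_thresh)
        plan.dropped_collinear = dropped
        continuous = kept

    if not continuous and not categorical:
        raise ValueError(
            "all columns dropped by filters "
            f"(missingness: {plan.dropped_missingness}, collinear: "
            f"{[d for _, d, _ in plan.dropped_collinear]})"
        )

    for c in continuous:
        med = train[c].median(skipna=True)
        plan.medians[c] = float(med) if np.isfinite(med) else 0.0
    for c in categorical:
        levels = sorted(train[c].dropna().astype(str).unique().tolist())
        if train[c].isna().any():
            levels.append(MISSING_LEVEL)
        plan.category_levels[c] = levels

    encoded = _encode(plan, train)
    for col in encoded.columns:
        mean = float(encoded[col].mean())
        sd = float(encoded[col].std(ddof=0))
        if sd == 0.0:
            log.warning("column %r has zero variance after encoding; scaled to zeros", col)
        plan.standardization[col] = (mean, sd)
    return plan


def _encode(plan: PreprocessPlan, table: pd.DataFrame) -> pd.DataFrame:
    """Impute + one-hot encode (no scaling); also fills ``plan.parent``."""
    out: dict[str, np.ndarray] = {}
    for c, med in plan.medians.items():
        if c not in table.columns:
            raise ValueError(f"expected column {c!r} absent from table")
        vals = table[c].to_numpy(dtype=float)
        out[c] = np.where(np.isnan(vals), med, vals)
        plan.parent[c] = c
    for c, levels in plan.category_levels.items():
        if c not in table.columns:
            raise ValueError(f"expected column {c!r} absent from table")
        raw = table[c]
        vals = raw.astype(str).where(~raw.isna(), MISSING_LEVEL).to_numpy()
        known = set(levels)
        if MISSING_LEVEL in known:
            vals = np.where(np.isin(vals, list(known)), vals, MISSING_LEVEL)
        else:
            unseen = ~np.isin(vals, list(known))
            if unseen.any():
                log.warning(
                    "%d unseen level(s) in %r map to all-zero indicators",
                    int(unseen.sum()), c,
                )
        for level in levels:  # keep every level: no reference drop
            name = f"{c}={level}"
            out[name] = (vals == level).astype(float)
            plan.parent[name] = c
    return pd.DataFrame(out)


def apply_preprocess(plan: PreprocessPlan, table: pd.DataFrame) -> pd.DataFrame:
    """Impute, encode and scale a table with a fitted plan.

    Scaling always uses the plan's (training) statistics; zero-variance
    columns become all-zero columns.
    """
    encoded = _encode(plan, table)
    for col, (mean, sd) in plan.standardization.items():
        if sd == 0.0:
            encoded[col] = 0.0
        else:
            encoded[col] = (encoded[col] - mean) / sd
    return encoded[plan.output_columns]
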