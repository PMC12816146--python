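"""Seeded synthetic dentist cohorts with planted, recoverable outcome effects.

The restricted survey data behind the original analysis cannot be shipped, so
this module generates cohorts whose marginal distributions match the published
sample description and whose outcome-generating mechanism plants known
nonlinear effects (piecewise debt response, post-change-point experience
decline, a race-by-debt interaction, and school-state effects).  The realized
generating parameters are stored on the cohort so downstream recovery tests
need no re-derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "REFERENCE_COUNTS",
    "reference_shares",
    "PiecewiseEffect",
    "EffectSpec",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "default_effect_spec",
    "calibrate_intercept",
    "linear_predictor",
    "generate_cohort",
    "inject_missingness",
    "load_cohort",
]

#: Published sample counts that anchor the generator defaults (totals, outcome
#: counts, and selected cross-tabulated cells).  Shares derived from these are
#: the worked-example reference values for the pipeline.
REFERENCE_COUNTS: dict[str, int] = {
    "total": 56_175,
    "fqhc": 2_591,
    "shortage": 679,
    "rural_shortage": 405,
    "male": 31_007,
    "female": 25_168,
    "white": 37_118,
    "fqhc_female": 1_479,
    "rural_shortage_general_practice": 383,
}


def reference_shares() -> dict[str, float]:
    """Percentages (one decimal) implied by :data:`REFERENCE_COUNTS`."""
    c = REFERENCE_COUNTS
    ratios = {
        "fqhc_pct": (c["fqhc"], c["total"]),
        "shortage_pct": (c["shortage"], c["total"]),
        "rural_shortage_pct": (c["rural_shortage"], c["total"]),
        "male_pct": (c["male"], c["total"]),
        "white_pct": (c["white"], c["total"]),
        "female_among_fqhc_pct": (c["fqhc_female"], c["fqhc"]),
        "general_among_rural_shortage_pct": (
            c["rural_shortage_general_practice"],
            c["rural_shortage"],
        ),
    }
    return {k: round(100.0 * num / den, 1) for k, (num, den) in ratios.items()}


# ---------------------------------------------------------------------------
# Effect specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseEffect:
    """Continuous piecewise-linear effect g(x) with g(0) = 0.

    ``slopes`` has one entry per segment, i.e. ``len(knots) + 1``; segment i
    spans ``[knots[i-1], knots[i])``.
    """

    knots: tuple[float, ...]
    slopes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.knots) + 1:
            raise ValueError("need len(slopes) == len(knots) + 1")
        if list(self.knots) != sorted(self.knots):
            raise ValueError("knots must be increasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        edges = np.concatenate([[0.0], self.knots])
        # cumulative value at each segment start
        seg_len = np.diff(np.concatenate([edges, [np.inf]]))[:-1]
        starts = np.concatenate([[0.0], np.cumsum(np.array(self.slopes[:-1]) * seg_len)])
        idx = np.searchsorted(self.knots, x, side="right")
        return starts[idx] + np.asarray(self.slopes)[idx] * (x - edges[idx])


@dataclass
class EffectSpec:
    """Per-outcome generating effects on the log-odds scale.

    ``linear_coefs`` terms are either ``"feature=Level"`` (categorical
    indicator, applied to the raw 0/1 indicator), a binary-flag column name
    (raw 0/1), or a continuous column name (applied to the marginally
    standardized value).  ``interactions`` entries are
    ``(indicator_term, "debt", coef)`` and scale the piecewise debt effect for
    rows where the indicator is 1.  ``intercepts`` are filled by calibration.
    """

    linear_coefs: dict[str, dict[str, float]] = field(default_factory=dict)
    debt_piecewise: dict[str, PiecewiseEffect] = field(default_factory=dict)
    experience_decline: dict[str, tuple[float, float]] = field(default_factory=dict)
    interactions: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    school_state_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["debt_piecewise"] = {
            k: {"knots": list(v.knots), "slopes": list(v.slopes)}
            for k, v in self.debt_piecewise.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        d = dict(d)
        d["debt_piecewise"] = {
            k: PiecewiseEffect(tuple(v["knots"]), tuple(v["slopes"]))
            for k, v in d.get("debt_piecewise", {}).items()
        }
        d["experience_decline"] = {
            k: tuple(v) for k, v in d.get("experience_decline", {}).items()
        }
        d["interactions"] = {
            k: [tuple(t) for t in v] for k, v in d.get("interactions", {}).items()
        }
        return cls(**d)

    def null(self) -> "EffectSpec":
        """Copy with every coefficient zeroed (for null-model experiments)."""
        return EffectSpec(
            linear_coefs={o: {t: 0.0 for t in c} for o, c in self.linear_coefs.items()},
            debt_piecewise={
                o: PiecewiseEffect(p.knots, tuple(0.0 for _ in p.slopes))
                for o, p in self.debt_piecewise.items()
            },
            experience_decline={
                o: (cp, 0.0) for o, (cp, _) in self.experience_decline.items()
            },
            interactions={o: [] for o in self.interactions},
            school_state_effects={
                o: {s: 0.0 for s in e} for o, e in self.school_state_effects.items()
            },
        )


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

#: Marginal distribution specs keyed by feature, in declared column order.
#: Kinds: normal (truncated), categorical, bernoulli, experience (derived from
#: age with fixed correlation), debt_mixture (zero-inflated truncated normal
#: with a high-debt tail component), scaled (deterministic multiple of another
#: column).
DEFAULT_MARGINALS: dict[str, dict] = {
    "sex": {"kind": "categorical", "probs": {"Male": 0.552, "Female": 0.448}},
    "age": {"kind": "normal", "mean": 41.2, "sd": 6.7, "lo": 25.0, "hi": 75.0},
    "experience": {
        "kind": "experience",
        "mean": 12.3,
        "sd": 5.6,
        "age_corr": 0.78,
        "lo": 0.0,
        "hi": 45.0,
    },
    "race": {
        "kind": "categorical",
        "probs": {
            "White": 0.661,
            "Asian": 0.189,
            "Black": 0.033,
            "Hispanic": 0.032,
            "Other": 0.085,
        },
    },
    "specialty": {
        "kind": "categorical",
        "probs": {
            "General Practice": 0.782,
            "Oral Surgery": 0.033,
            "Endodontics": 0.030,
            "Orthodontics": 0.057,
            "Pediatric": 0.061,
            "Periodontics": 0.020,
            "Other": 0.017,
        },
    },
    "debt": {
        "kind": "debt_mixture",
        "mean": 243_968.0,
        "sd": 180_254.0,
        "lo": 0.0,
        "hi": 1_200_000.0,
        "p_zero": 0.15,
        "p_tail": 0.06,
        "tail_lo": 600_000.0,
        "tail_hi": 1_200_000.0,
    },
    "debt_thousands": {"kind": "scaled", "source": "debt", "factor": 1e-3},
    "owner": {"kind": "bernoulli", "p": 0.55},
    "practice_rural": {"kind": "bernoulli", "p": 0.15},
    "school_state": {
        "kind": "categorical",
        "probs": {f"S{i:02d}": 1.0 / 12.0 for i in range(1, 13)},
    },
    "diversity_index": {"kind": "normal", "mean": 0.53, "sd": 0.15, "lo": 0.0, "hi": 1.0},
    "school_size": {"kind": "normal", "mean": 423.0, "sd": 228.0, "lo": 30.0, "hi": 1500.0},
    "pct_male_students": {"kind": "normal", "mean": 53.9, "sd": 7.2, "lo": 0.0, "hi": 100.0},
    "pct_us_citizens": {"kind": "normal", "mean": 92.6, "sd": 8.5, "lo": 0.0, "hi": 100.0},
    "pct_local_state": {"kind": "normal", "mean": 62.6, "sd": 33.4, "lo": 0.0, "hi": 100.0},
    "gpa_dat_ratio": {"kind": "normal", "mean": 0.17, "sd": 0.01, "lo": 0.10, "hi": 0.25},
    "applications": {"kind": "normal", "mean": 1146.0, "sd": 1151.0, "lo": 0.0, "hi": 6000.0},
    "phd_program": {"kind": "bernoulli", "p": 0.436},
    "survey_extra": {"kind": "normal", "mean": 0.0, "sd": 1.0, "lo": -5.0, "hi": 5.0},
}

#: Features drawn once per school and broadcast to its graduates.
SCHOOL_LEVEL_FEATURES: tuple[str, ...] = (
    "school_state",
    "diversity_index",
    "school_size",
    "pct_male_students",
    "pct_us_citizens",
    "pct_local_state",
    "gpa_dat_ratio",
    "applications",
    "phd_program",
)

#: 0/1 columns used raw (not standardized) in the generating linear predictor.
BINARY_FLAGS: tuple[str, ...] = ("owner", "practice_rural", "phd_program")

DEFAULT_PREVALENCES: dict[str, float] = {
    "fqhc": 0.046,
    "shortage": 0.012,
    "rural_shortage": 0.007,
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "debt": 0.10,
    "debt_thousands": 0.10,
    "pct_local_state": 0.10,
    "diversity_index": 0.05,
    "survey_extra": 0.70,
}


def default_effect_spec() -> EffectSpec:
    """Planted generating effects recoverable by the downstream pipeline."""
    return EffectSpec(
        linear_coefs={
            "fqhc": {
                "specialty=General Practice": 0.9,
                "sex=Female": 0.5,
                "race=Black": 0.7,
                "race=Asian": -0.5,
                "owner": -0.7,
                "practice_rural": 1.0,
            },
            "shortage": {
                "specialty=General Practice": 1.1,
                "sex=Male": 0.4,
                "race=Asian": -0.7,
                "owner": -0.5,
            },
            "rural_shortage": {
                "specialty=General Practice": 1.2,
                "sex=Male": 0.4,
                "race=Asian": -0.8,
                "owner": -0.4,
            },
        },
        debt_piecewise={
            # positive response in the moderate-debt band, negative at the
            # extreme high end
            "fqhc": PiecewiseEffect(
                knots=(100_000.0, 550_000.0, 800_000.0),
                slopes=(0.0, 1.3e-6, 0.0, -3.5e-6),
            ),
            # mild monotone positive response
            "shortage": PiecewiseEffect(knots=(100_000.0,), slopes=(0.0, 0.9e-6)),
            "rural_shortage": PiecewiseEffect(knots=(100_000.0,), slopes=(0.0, 1.0e-6)),
        },
        experience_decline={
            "fqhc": (12.0, -0.09),
            "shortage": (12.0, -0.07),
            "rural_shortage": (12.0, -0.07),
        },
        interactions={
            # White dentists respond more strongly to debt
            "fqhc": [("race=White", "debt", 0.6)],
            "shortage": [],
            "rural_shortage": [],
        },
        school_state_effects={
            # S01 is the high-risk planted subgroup marker across outcomes
            "fqhc": {"S01": 1.7, "S02": 0.8, "S03": 0.6},
            "shortage": {"S01": 1.0, "S04": 0.9},
            "rural_shortage": {"S01": 1.0, "S05": 1.0},
        },
    )


@dataclass
class CohortConfig:
    n_dentists: int = 20_000
    target_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    feature_marginals: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    effect_spec: EffectSpec = field(default_factory=default_effect_spec)
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    seed: int = 0
    n_schools: int = 60
    school_level: tuple[str, ...] = SCHOOL_LEVEL_FEATURES
    #: individual-level jitter on continuous school features (fraction of the
    #: marginal SD), standing in for year-to-year institutional variation;
    #: keeps school identity from being perfectly recoverable
    school_jitter: float = 0.2

    def validate(self) -> None:
        for name, p in self.target_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {name!r} must be in (0,1), got {p}")
        for name, spec in self.feature_marginals.items():
            if spec["kind"] == "categorical":
                total = sum(spec["probs"].values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"level probabilities for {name!r} sum to {total}, not 1"
                    )
        for name, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0,1]: {r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_spec"] = self.effect_spec.to_dict()
        d["school_level"] = list(self.school_level)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["effect_spec"] = EffectSpec.from_dict(d["effect_spec"])
        d["school_level"] = tuple(d.get("school_level", SCHOOL_LEVEL_FEATURES))
        return cls(**d)


def default_config(n: int = 20_000, seed: int = 0) -> CohortConfig:
    return CohortConfig(n_dentists=n, seed=seed)


@dataclass
class SyntheticCohort:
    features: pd.DataFrame
    outcomes: dict[str, np.ndarray]
    truth: EffectSpec
    seed: int

    @property
    def n(self) -> int:
        return len(self.features)

    def to_dir(self, path: str | Path, config: CohortConfig | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(path / "features.csv", index=False)
        pd.DataFrame(self.outcomes).to_csv(path / "outcomes.csv", index=False)
        meta = {"seed": self.seed, "truth": self.truth.to_dict()}
        if config is not None:
            meta["config"] = config.to_dict()
        (path / "truth.json").write_text(json.dumps(meta, indent=2))


def load_cohort(path: str | Path) -> SyntheticCohort:
    path = Path(path)
    features = pd.read_csv(path / "features.csv")
    outcomes_df = pd.read_csv(path / "outcomes.csv")
    meta = json.loads((path / "truth.json").read_text())
    return SyntheticCohort(
        features=features,
        outcomes={c: outcomes_df[c].to_numpy(dtype=int) for c in outcomes_df.columns},
        truth=EffectSpec.from_dict(meta["truth"]),
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def calibrate_intercept(
    linear_predictor: np.ndarray, target_prev: float, tol: float = 1e-8
) -> float:
    """Intercept b such that mean(logistic(b + lp)) hits ``target_prev``.

    Monotone bisection; the mean response is strictly increasing in b.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if lp.size == 0 or not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be nonempty and finite")
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target prevalence must be in (0,1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(expit(mid + lp)))
        if abs(p - target_prev) <= tol:
            return mid
        if p < target_prev:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _standardized(values: np.ndarray, marginal: dict) -> np.ndarray:
    sd = marginal.get("sd", 1.0) or 1.0
    return (values - marginal.get("mean", 0.0)) / sd


def linear_predictor(
    features: pd.DataFrame,
    outcome: str,
    effect: EffectSpec,
    marginals: dict[str, dict] | None = None,
) -> np.ndarray:
    """Generating log-odds (without intercept) for one outcome."""
    marginals = marginals if marginals is not None else DEFAULT_MARGINALS
    lp = np.zeros(len(features))
    for term, coef in effect.linear_coefs.get(outcome, {}).items():
        if "=" in term:
            col, level = term.split("=", 1)
            lp += coef * (features[col].to_numpy() == level)
        elif term in BINARY_FLAGS:
            lp += coef * features[term].to_numpy(dtype=float)
        else:
            lp += coef * _standardized(
                features[term].to_numpy(dtype=float), marginals.get(term, {})
            )
    debt_effect = None
    if outcome in effect.debt_piecewise:
        debt_effect = effect.debt_piecewise[outcome](features["debt"].to_numpy(float))
        lp += debt_effect
    if outcome in effect.experience_decline:
        cp, slope = effect.experience_decline[outcome]
        exp_years = features["experience"].to_numpy(dtype=float)
        lp += slope * np.maximum(exp_years - cp, 0.0)
    for term, modifier, coef in effect.interactions.get(outcome, []):
        if modifier != "debt":
            raise ValueError(f"unsupported interaction modifier {modifier!r}")
        if debt_effect is None:
            raise ValueError("debt interaction requires a debt_piecewise entry")
        col, level = term.split("=", 1)
        lp += coef * (features[col].to_numpy() == level) * debt_effect
    states = effect.school_state_effects.get(outcome, {})
    if states:
        state_col = features["school_state"].to_numpy()
        for state, coef in states.items():
            lp += coef * (state_col == state)
    return lp


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    # resample out-of-range draws; acceptance rate is high for all defaults
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_feature(
    rng: np.random.Generator, n: int, spec: dict, drawn: dict[str, np.ndarray]
) -> np.ndarray:
    kind = spec["kind"]
    if kind == "normal":
        return _truncated_normal(rng, n, spec["mean"], spec["sd"], spec["lo"], spec["hi"])
    if kind == "categorical":
        levels = list(spec["probs"])
        probs = np.array([spec["probs"][l] for l in levels])
        return rng.choice(np.array(levels, dtype=object), size=n, p=probs / probs.sum())
    if kind == "bernoulli":
        return (rng.random(n) < spec["p"]).astype(int)
    if kind == "experience":
        age_spec = DEFAULT_MARGINALS["age"]
        age = drawn["age"]
        slope = spec["age_corr"] * spec["sd"] / age_spec["sd"]
        noise_sd = spec["sd"] * np.sqrt(1.0 - spec["age_corr"] ** 2)
        exp_years = spec["mean"] + slope * (age - age_spec["mean"]) + rng.normal(
            0.0, noise_sd, size=n
        )
        return np.clip(exp_years, spec["lo"], spec["hi"])
    if kind == "debt_mixture":
        u = rng.random(n)
        out = _truncated_normal(rng, n, spec["mean"], spec["sd"], spec["lo"], spec["hi"])
        tail = u < spec["p_zero"] + spec["p_tail"]
        out[tail] = rng.uniform(spec["tail_lo"], spec["tail_hi"], size=int(tail.sum()))
        out[u < spec["p_zero"]] = 0.0
        return out
    if kind == "scaled":
        return drawn[spec["source"]] * spec["factor"]
    raise ValueError(f"unknown marginal kind {kind!r}")


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort, calibrate outcome intercepts, and plant missingness."""
    config.validate()
    n = config.n_dentists
    if n < 100:
        raise ValueError("n_dentists must be >= 100 for meaningful calibration")
    ss = np.random.SeedSequence(config.seed)
    feat_seed, school_seed, outcome_seed, miss_seed = ss.spawn(4)
    rng = np.random.default_rng(feat_seed)
    school_rng = np.random.default_rng(school_seed)

    # school-level features are drawn once per school and broadcast
    school_table: dict[str, np.ndarray] = {}
    for name in config.school_level:
        spec = config.feature_marginals[name]
        school_table[name] = _draw_feature(school_rng, config.n_schools, spec, school_table)
    school_of = rng.integers(0, config.n_schools, size=n)

    drawn: dict[str, np.ndarray] = {}
    for name, spec in config.feature_marginals.items():
        if name in config.school_level:
            vals = school_table[name][school_of]
            if spec["kind"] == "normal" and config.school_jitter > 0:
                vals = np.clip(
                    vals + rng.normal(0.0, config.school_jitter * spec["sd"], size=n),
                    spec["lo"],
                    spec["hi"],
                )
            drawn[name] = vals
        else:
            drawn[name] = _draw_feature(rng, n, spec, drawn)
    features = pd.DataFrame(drawn, columns=list(config.feature_marginals))

    truth = EffectSpec.from_dict(config.effect_spec.to_dict())
    outcome_rng = np.random.default_rng(outcome_seed)
    outcomes: dict[str, np.ndarray] = {}
    for outcome, prev in config.target_prevalence.items():
        lp = linear_predictor(features, outcome, truth, config.feature_marginals)
        intercept = calibrate_intercept(lp, prev)
        truth.intercepts[outcome] = intercept
        p = expit(intercept + lp)
        outcomes[outcome] = (outcome_rng.random(n) < p).astype(int)

    cohort = SyntheticCohort(features=features, outcomes=outcomes, truth=truth, seed=config.seed)
    if any(r > 0 for r in config.missingness_rates.values()):
        cohort = inject_missingness(
            cohort, config.missingness_rates, seed=int(miss_seed.generate_state(1)[0])
        )
    return cohort


def inject_missingness(
    cohort: SyntheticCohort, rates: dict[str, float], seed: int
) -> SyntheticCohort:
    """Mask feature entries independently at the given per-column rates."""
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col!r} outside [0,1]: {rate}")
    rng = np.random.default_rng(seed)
    features = cohort.features.copy()
    for col in features.columns:  # column order fixes the draw order
        rate = rates.get(col, 0.0)
        if rate <= 0.0:
            continue
        mask = rng.random(len(features)) < rate
        if features[col].dtype.kind in "iub":
            features[col] = features[col].astype(float)
        features.loc[mask, col] = np.nan
    return SyntheticCohort(
        features=features,
        outcomes={k: v.copy() for k, v in cohort.outcomes.items()},
        truth=cohort.truth,
        seed=cohort.seed,
    )
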