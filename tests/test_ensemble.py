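import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from underserved.ensemble import (
    EnsembleHyperparams,
    auc,
    evaluate,
    fit_ensemble,
    mcc,
    monte_carlo_cv,
    select_threshold,
)


def _brute_force_auc(scores, y):
    """Independent oracle: enumerate every positive x negative pair."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _brute_force_best_mcc(scores, y):
    """Independent oracle: scan thresholds at every score value and beyond."""
    candidates = np.concatenate([[scores.min() - 1], np.unique(scores), [scores.max() + 1]])
    best = -np.inf
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        best = max(best, mcc(tp, fp, fn, tn))
    return best


class TestMcc:
    def test_worked_example(self):
        assert mcc(2, 1, 1, 2) == pytest.approx(1.0 / 3.0)

    def test_perfect_classifier(self):
        assert mcc(10, 0, 0, 20) == 1.0

    def test_zero_marginal_convention(self):
        assert mcc(0, 0, 5, 10) == 0.0
        assert mcc(5, 10, 0, 0) == 0.0

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=50)] * 4)
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, counts):
        assert -1.0 <= mcc(*counts) <= 1.0


class TestAuc:
    def test_perfectly_separated(self):
        assert auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties(self):
        assert auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_matches_pair_counting_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        assert auc(scores, y) == pytest.approx(_brute_force_auc(scores, y))
        assert _brute_force_auc(scores, y) == 0.75

    def test_matches_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        assert auc(scores, y) == pytest.approx(_brute_force_auc(scores, y))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        base = auc(scores, y)
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7, lambda s: s**3):
            assert auc(f(scores), y) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSelectThreshold:
    def test_separated_scores_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert select_threshold(scores, y) == pytest.approx(0.5)

    def test_matches_exhaustive_grid_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            t = select_threshold(scores, y)
            achieved = mcc(
                *(int(v) for v in _confusion_counts(scores, y, t))
            )
            assert achieved == pytest.approx(_brute_force_best_mcc(scores, y), abs=1e-12)

    def test_all_identical_scores_returns_smallest_candidate(self):
        scores = np.full(5, 0.3)
        y = np.array([0, 1, 0, 1, 0])
        assert select_threshold(scores, y) == pytest.approx(0.3 - 1.0)


def _confusion_counts(scores, y, t):
    pred = scores >= t
    y = y.astype(bool)
    return (pred & y).sum(), (pred & ~y).sum(), (~pred & y).sum(), (~pred & ~y).sum()


def _separable_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-4, 0.5, (n // 2, 2)), rng.normal(4, 0.5, (n // 2, 2))])
    y = np.repeat([0, 1], n // 2)
    return pd.DataFrame(X, columns=["a", "b"]), y


class TestFitEnsemble:
    def test_separable_training_auc_is_one(self, light_hp):
        X, y = _separable_data()
        ens = fit_ensemble(X, y, seed=0, hyperparams=light_hp)
        assert auc(ens.predict_proba(X), y) == 1.0

    def test_vote_is_mean_of_member_probabilities(self, light_hp):
        X, y = _separable_data()
        ens = fit_ensemble(X, y, seed=0, hyperparams=light_hp)
        Xv = X.to_numpy()
        tree_p, logit_p = ens.member_probs(Xv)
        np.testing.assert_allclose(
            ens.predict_proba(Xv), 0.5 * tree_p + 0.5 * logit_p, atol=1e-12
        )

    def test_single_class_rejected(self, light_hp):
        X, _ = _separable_data()
        with pytest.raises(ValueError, match="single class"):
            fit_ensemble(X, np.zeros(len(X), dtype=int), seed=0, hyperparams=light_hp)

    def test_isotonic_map_monotone_on_dense_grid(self, light_hp, small_cohort):
        from underserved.preprocess import apply_preprocess, fit_preprocess

        y = small_cohort.outcomes["fqhc"]
        plan = fit_preprocess(small_cohort.features)
        X = apply_preprocess(plan, small_cohort.features)
        ens = fit_ensemble(X, y, seed=0, hyperparams=light_hp)
        grid = np.linspace(0, 1, 5001)
        mapped = ens.calibrate(grid)
        assert (np.diff(mapped) >= -1e-12).all()
        assert mapped.min() >= 0.0 and mapped.max() <= 1.0

    def test_permuted_labels_auc_near_half(self, light_hp):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(800, 5)), columns=list("abcde"))
        y_real = (X["a"] + rng.normal(size=800) > 0).astype(int).to_numpy()
        aucs = []
        for rep in range(10):
            y = rng.permutation(y_real)
            tr, te = np.arange(600), np.arange(600, 800)
            ens = fit_ensemble(X.iloc[tr], y[tr], seed=rep, hyperparams=light_hp)
            aucs.append(auc(ens.predict_proba(X.iloc[te]), y[te]))
        assert abs(np.mean(aucs) - 0.5) < 0.06


class _StubModel:
    """Duck-typed ensemble for metric arithmetic tests."""

    def __init__(self, threshold):
        self.threshold = threshold

    def predict_proba(self, X):
        return np.asarray(X, dtype=float)[:, 0]


class TestEvaluate:
    def test_lift_is_precision_over_prevalence(self):
        # 400 rows, prevalence 0.05; predictions catch 5 of 20 positives and
        # 20 negatives: precision 5/25 = 0.20, lift = 0.20/0.05 = 4.0
        scores = np.zeros(400)
        y = np.zeros(400, dtype=int)
        y[:20] = 1
        scores[:5] = 0.9          # TP
        scores[20:40] = 0.9       # FP
        scores[5:20] = 0.4
        report = evaluate(_StubModel(0.5), scores[:, None], y, n_boot=0)
        assert report.precision == pytest.approx(0.20)
        assert report.lift == pytest.approx(4.0)

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1] * 5)
        report = evaluate(_StubModel(0.5), y[:, None].astype(float), y, n_boot=100)
        assert report.sensitivity == report.specificity == report.precision == 1.0
        assert report.mcc == 1.0
        assert report.ci_low <= report.auc <= report.ci_high

    def test_predict_all_negative(self):
        y = np.array([0, 0, 1, 1] * 5)
        report = evaluate(_StubModel(2.0), y[:, None].astype(float), y, n_boot=0)
        assert report.sensitivity == 0.0
        assert report.specificity == 1.0
        assert report.precision == 0.0
        assert report.mcc == 0.0

    def test_single_class_reports_classification_but_no_auc(self):
        y = np.zeros(10, dtype=int)
        report = evaluate(_StubModel(0.5), np.zeros((10, 1)), y, n_boot=0)
        assert report.auc is None
        assert report.specificity == 1.0


class TestMonteCarloCV:
    def test_single_iteration_matches_evaluate(self, light_hp, small_cohort):
        y = small_cohort.outcomes["fqhc"]
        summary = monte_carlo_cv(
            small_cohort.features, y, n_iterations=1, base_seed=3,
            hyperparams=light_hp, n_boot=0,
        )
        assert summary.mean_auc == summary.per_split[0].auc
        assert summary.best_split.auc == summary.per_split[0].auc

    def test_best_split_at_least_mean(self, light_hp, small_cohort):
        y = small_cohort.outcomes["fqhc"]
        summary = monte_carlo_cv(
            small_cohort.features, y, n_iterations=3, base_seed=5,
            hyperparams=light_hp, n_boot=0,
        )
        assert summary.best_split.auc >= summary.mean_auc
        assert summary.best_split.auc == max(r.auc for r in summary.per_split)
        lo, hi = summary.mean_auc_ci
        assert lo <= summary.mean_auc <= hi

    def test_planted_cohort_auc_band(self, light_hp, small_cohort):
        # regression band for the reference generator at reduced scale
        y = small_cohort.outcomes["fqhc"]
        summary = monte_carlo_cv(
            small_cohort.features, y, n_iterations=3, base_seed=5,
            hyperparams=light_hp, n_boot=0,
        )
        assert 0.58 < summary.mean_auc < 0.95

    def test_rare_class_split_resampling(self, light_hp):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=60)})
        y = np.zeros(60, dtype=int)
        y[:4] = 1
        summary = monte_carlo_cv(
            table, y, n_iterations=2, base_seed=0, hyperparams=light_hp, n_boot=0
        )
        assert len(summary.per_split) == 2

    def test_rejects_bad_args(self, small_cohort):
        y = small_cohort.outcomes["fqhc"]
        with pytest.raises(ValueError):
            monte_carlo_cv(small_cohort.features, y, n_iterations=0)
        with pytest.raises(ValueError):
            monte_carlo_cv(small_cohort.features, y, train_frac=1.5)

    def test_report_serialization(self, tmp_path, light_hp, small_cohort):
        y = small_cohort.outcomes["fqhc"]
        summary = monte_carlo_cv(
            small_cohort.features, y, n_iterations=1, base_seed=3,
            hyperparams=light_hp, n_boot=50,
        )
        summary.to_json(tmp_path / "r.json")
        import json

        d = json.loads((tmp_path / "r.json").read_text())
        assert d["best_split"]["auc"] == summary.best_split.auc
        assert d["splits"]["n_iterations"] == 1
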