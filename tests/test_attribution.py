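import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression

from underserved.attribution import (
    Tree,
    extract_trees,
    shap_exact,
    shap_linear,
    shap_marginal,
    shap_tree,
    summary_ranking,
    tree_margin,
)


def _fit_small_tree_model(n_features=4, seed=0, max_iter=15, max_depth=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(400, n_features))
    logits = X[:, 0] + 0.8 * X[:, 1 % n_features] * X[:, 2 % n_features]
    y = (logits + 0.3 * rng.normal(size=400) > 0).astype(int)
    model = HistGradientBoostingClassifier(
        max_iter=max_iter, max_depth=max_depth, early_stopping=False, random_state=seed
    )
    model.fit(X, y)
    return model, X


class TestShapExact:
    def test_linear_closed_form(self):
        background = np.array([[-1.0, 5.0], [1.0, -5.0]])
        fn = lambda Z: 2.0 * Z[:, 0]
        phi, base = shap_exact(fn, np.array([3.0, 9.9]), background)
        assert phi[0] == pytest.approx(6.0)  # 2 * (3 - mean(0))
        assert phi[1] == pytest.approx(0.0)
        assert base == pytest.approx(0.0)

    def test_efficiency_axiom(self, rng):
        fn = lambda Z: np.sin(Z[:, 0]) + Z[:, 1] * Z[:, 2] + 0.5 * Z[:, 2]
        background = rng.normal(size=(8, 3))
        x = rng.normal(size=3)
        phi, base = shap_exact(fn, x, background)
        assert base + phi.sum() == pytest.approx(float(fn(x[None, :])[0]), abs=1e-12)

    def test_symmetry_axiom(self, rng):
        fn = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 0] + Z[:, 1]
        bg = rng.normal(size=(6, 2))
        bg[:, 1] = bg[:, 0]  # identical background marginals
        phi, _ = shap_exact(fn, np.array([2.0, 2.0]), bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_rejects_high_dimension(self):
        with pytest.raises(ValueError, match="<= 15"):
            shap_exact(lambda Z: Z[:, 0], np.zeros(16), np.zeros((2, 16)))


class TestShapLinear:
    def test_at_means_all_zero(self):
        means = np.array([1.0, -2.0])
        attr = shap_linear((np.array([3.0, 4.0]), 0.5), means[None, :], means)
        np.testing.assert_allclose(attr.contributions.to_numpy(), 0.0, atol=1e-12)
        assert attr.model_outputs[0] == pytest.approx(attr.base_value)

    def test_matches_exact_oracle(self, rng):
        coef, intercept = np.array([1.5, -2.0, 0.7]), 0.3
        background = rng.normal(size=(12, 3))
        x = rng.normal(size=3)
        fn = lambda Z: intercept + Z @ coef
        phi, base = shap_exact(fn, x, background)
        attr = shap_linear((coef, intercept), x[None, :], background.mean(axis=0))
        np.testing.assert_allclose(attr.contributions.to_numpy()[0], phi, atol=1e-9)
        assert attr.base_value == pytest.approx(base, abs=1e-9)

    def test_doubling_coefficient_doubles_contribution(self, rng):
        X = rng.normal(size=(5, 3))
        means = np.zeros(3)
        a = shap_linear((np.array([1.0, 2.0, 3.0]), 0.0), X, means)
        b = shap_linear((np.array([2.0, 2.0, 3.0]), 0.0), X, means)
        np.testing.assert_allclose(
            b.contributions.iloc[:, 0], 2 * a.contributions.iloc[:, 0]
        )
        np.testing.assert_allclose(b.contributions.iloc[:, 1], a.contributions.iloc[:, 1])

    def test_fitted_logistic_additivity_on_link_scale(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        model = LogisticRegression(max_iter=500).fit(X, y)
        attr = shap_linear(model, pd.DataFrame(X, columns=list("abc")), X.mean(axis=0))
        link = model.decision_function(X)
        np.testing.assert_allclose(
            attr.base_value + attr.contributions.sum(axis=1), link, atol=1e-9
        )


class TestShapTree:
    def test_stump_puts_all_mass_on_split_feature(self):
        # manual stump: split on feature 1 at 0; leaves -1 / +1
        stump = Tree(
            feature=np.array([1, 0, 0]),
            threshold=np.array([0.0, 0.0, 0.0]),
            left=np.array([1, 0, 0]),
            right=np.array([2, 0, 0]),
            value=np.array([0.0, -1.0, 1.0]),
            is_leaf=np.array([False, True, True]),
        )
        X = np.array([[5.0, 2.0, 7.0]])
        B = np.array([[0.0, -1.0, 0.0], [1.0, 1.0, 1.0]])
        attr = shap_tree(([stump], 0.0), X, B)
        contrib = attr.contributions.to_numpy()[0]
        assert contrib[0] == 0.0 and contrib[2] == 0.0
        assert attr.base_value + contrib[1] == pytest.approx(1.0)

    def test_matches_exact_oracle_depth2(self):
        model, X = _fit_small_tree_model()
        trees, base = extract_trees(model)
        fn = lambda Z: tree_margin(trees, base, Z)
        B = X[:16]
        attr = shap_tree(model, X[:8], B)
        for i in range(8):
            phi, b0 = shap_exact(fn, X[i], B)
            np.testing.assert_allclose(
                attr.contributions.iloc[i].to_numpy(), phi, atol=1e-6
            )
            assert attr.base_value == pytest.approx(b0, abs=1e-9)

    def test_additivity_reproduces_raw_outputs(self):
        model, X = _fit_small_tree_model(max_iter=30, max_depth=3)
        attr = shap_tree(model, X[:50], X[:32])
        np.testing.assert_allclose(
            attr.base_value + attr.contributions.sum(axis=1),
            model.decision_function(X[:50]),
            atol=1e-9,
        )

    def test_margin_descent_matches_sklearn(self):
        model, X = _fit_small_tree_model(max_iter=25, max_depth=3)
        trees, base = extract_trees(model)
        np.testing.assert_allclose(
            tree_margin(trees, base, X), model.decision_function(X), atol=1e-9
        )

    def test_unused_feature_gets_exactly_zero(self):
        model, X = _fit_small_tree_model(n_features=5)
        trees, _ = extract_trees(model)
        used = set()
        for t in trees:
            used |= set(t.feature[~t.is_leaf].tolist())
        unused = [j for j in range(5) if j not in used]
        if unused:
            attr = shap_tree(model, X[:20], X[:16])
            for j in unused:
                assert (attr.contributions.iloc[:, j] == 0.0).all()

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError):
            shap_tree(LogisticRegression(), np.zeros((1, 2)), np.zeros((2, 2)))


class TestShapMarginal:
    def test_matches_exact_oracle_within_three_ses(self):
        model, X = _fit_small_tree_model()
        trees, base = extract_trees(model)
        fn = lambda Z: tree_margin(trees, base, Z)
        B = X[:16]
        attr = shap_marginal(fn, X[:3], B, n_samples=600, seed=4)
        for i in range(3):
            phi, _ = shap_exact(fn, X[i], B)
            est = attr.contributions.iloc[i].to_numpy()
            se = np.maximum(attr.standard_errors.iloc[i].to_numpy(), 1e-9)
            assert (np.abs(est - phi) <= 3 * se + 1e-9).all()

    def test_exact_additivity_by_telescoping(self):
        model, X = _fit_small_tree_model()
        fn = lambda Z: model.predict_proba(Z)[:, 1]
        attr = shap_marginal(fn, X[:5], X[:10], n_samples=20, seed=0)
        assert attr.additivity_gap().max() < 1e-10

    def test_deterministic_given_seed(self):
        model, X = _fit_small_tree_model()
        fn = lambda Z: model.predict_proba(Z)[:, 1]
        a = shap_marginal(fn, X[:4], X[:8], n_samples=16, seed=9)
        b = shap_marginal(fn, X[:4], X[:8], n_samples=16, seed=9)
        pd.testing.assert_frame_equal(a.contributions, b.contributions)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError, match="n_samples"):
            shap_marginal(lambda Z: Z[:, 0], np.zeros((1, 2)), np.zeros((2, 2)), n_samples=5)

    def test_null_feature_within_three_ses_of_zero(self, rng):
        X = rng.normal(size=(6, 3))
        fn = lambda Z: Z[:, 0] ** 2  # ignores features 1 and 2
        attr = shap_marginal(fn, X, X, n_samples=200, seed=2)
        for j in (1, 2):
            est = attr.contributions.iloc[:, j].to_numpy()
            se = np.maximum(attr.standard_errors.iloc[:, j].to_numpy(), 1e-12)
            assert (np.abs(est) <= 3 * se + 1e-12).all()


class TestOracleEquivalenceSuite:
    """Every flavor against the enumeration oracle on random small models."""

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_flavor(self, seed):
        model, X = _fit_small_tree_model(n_features=4, seed=seed)
        trees, base = extract_trees(model)
        fn = lambda Z: tree_margin(trees, base, Z)
        B = X[seed : seed + 12]
        attr = shap_tree(model, X[:2], B)
        for i in range(2):
            phi, _ = shap_exact(fn, X[i], B)
            np.testing.assert_allclose(
                attr.contributions.iloc[i].to_numpy(), phi, atol=1e-6
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_flavor(self, seed):
        rng = np.random.default_rng(seed)
        coef = rng.normal(size=6)
        intercept = float(rng.normal())
        background = rng.normal(size=(10, 6))
        x = rng.normal(size=6)
        phi, base = shap_exact(lambda Z: intercept + Z @ coef, x, background)
        attr = shap_linear((coef, intercept), x[None, :], background.mean(axis=0))
        np.testing.assert_allclose(attr.contributions.to_numpy()[0], phi, atol=1e-9)


class TestSummaryRanking:
    def _attr(self, contrib, names):
        df = pd.DataFrame(contrib, columns=names)
        from underserved.attribution import AttributionMatrix

        return AttributionMatrix(
            contributions=df,
            base_value=0.0,
            model_outputs=df.sum(axis=1).to_numpy(),
            feature_values=df,
            flavor="exact",
        )

    def test_all_zero_keeps_original_order(self):
        attr = self._attr(np.zeros((4, 3)), ["a", "b", "c"])
        out = summary_ranking(attr, {"a": "g", "b": "g", "c": "g"})
        assert [f for f, _ in out["g"]] == ["a", "b", "c"]

    def test_dominant_feature_first_in_its_group(self, rng):
        contrib = rng.uniform(-0.1, 0.1, size=(20, 3))
        contrib[:, 1] = rng.choice([-5.0, 5.0], size=20)
        attr = self._attr(contrib, ["a", "b", "c"])
        out = summary_ranking(attr, {"a": "ind", "b": "ind", "c": "school"})
        assert out["ind"][0][0] == "b"

    def test_unmapped_feature_rejected(self):
        attr = self._attr(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="b"):
            summary_ranking(attr, {"a": "g"})
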