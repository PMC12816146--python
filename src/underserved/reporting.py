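"""Plot-ready report products and the end-to-end pipeline runner.

Reports are emitted as CSV/JSON data (dependence tables, heatmap layouts,
force decompositions) rather than rendered images, so every number is
testable.  ``run_pipeline`` chains simulate -> preprocess -> Monte Carlo CV ->
SAGE + inclusion curve -> top-k refit -> SHAP -> cluster tree -> reports, per
outcome, and writes a manifest with a content hash for every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .attribution import AttributionMatrix, shap_marginal, shap_tree, summary_ranking
from .cluster_tree import (
    ClusterTreeParams,
    build_cluster_tree,
    leaf_assignments,
    summarize_high_prevalence,
)
from .cohort import (
    SCHOOL_LEVEL_FEATURES,
    CohortConfig,
    generate_cohort,
)
from .ensemble import EnsembleHyperparams, evaluate, fit_ensemble, monte_carlo_cv
from .importance import (
    inclusion_curve,
    sage_auc,
    select_top_k,
)
from .preprocess import apply_preprocess, fit_preprocess

__all__ = [
    "PipelineConfig",
    "dependence_table",
    "heatmap_layout",
    "force_decomposition",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcomes: tuple[str, ...] = ("fqhc",)
    n_cv_iterations: int = 10
    train_frac: float = 0.8
    base_seed: int = 0
    sage_permutations: int = 64
    sage_background: int = 128
    sage_eval_cap: int = 2000
    shap_flavor: str = "marginal"
    shap_samples: int = 48
    shap_subsample: int = 500
    cluster: ClusterTreeParams = field(default_factory=ClusterTreeParams)
    hyperparams: EnsembleHyperparams = field(default_factory=EnsembleHyperparams)
    inclusion_tolerance: float = 0.005
    n_bootstrap: int = 2000
    out_dir: str = "pipeline_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["outcomes"] = list(self.outcomes)
        d["cluster"] = dataclasses.asdict(self.cluster)
        d["cluster"]["candidate_k"] = list(self.cluster.candidate_k)
        d["hyperparams"] = dataclasses.asdict(self.hyperparams)
        d["hyperparams"]["vote_weights"] = list(self.hyperparams.vote_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["cohort"] = CohortConfig.from_dict(d["cohort"])
        d["outcomes"] = tuple(d["outcomes"])
        cluster = dict(d["cluster"])
        cluster["candidate_k"] = tuple(cluster["candidate_k"])
        d["cluster"] = ClusterTreeParams(**cluster)
        hp = dict(d["hyperparams"])
        hp["vote_weights"] = tuple(hp["vote_weights"])
        d["hyperparams"] = EnsembleHyperparams(**hp)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Report products
# ---------------------------------------------------------------------------


def dependence_table(
    attr: AttributionMatrix, feature: str, interaction: str = "auto"
) -> pd.DataFrame:
    """One row per instance: feature value, its contribution, and the value of
    an interacting feature (auto = strongest |rank correlation| between the
    other features' values and this feature's contributions)."""
    if feature not in attr.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    contrib = attr.contributions[feature].to_numpy()
    if interaction == "auto":
        best, best_r = None, -1.0
        for other in attr.feature_names:
            if other == feature:
                continue
            vals = attr.feature_values[other].to_numpy()
            if np.std(vals) == 0 or np.std(contrib) == 0:
                continue
            r = abs(spearmanr(vals, contrib).statistic)
            if np.isfinite(r) and r > best_r:
                best, best_r = other, r
        interaction = best if best is not None else feature
    elif interaction not in attr.feature_names:
        raise ValueError(f"unknown interaction feature {interaction!r}")
    df = pd.DataFrame(
        {
            "feature_value": attr.feature_values[feature].to_numpy(),
            "contribution": contrib,
            "interaction_value": attr.feature_values[interaction].to_numpy(),
        }
    )
    df.attrs["feature"] = feature
    df.attrs["interaction_feature"] = interaction
    return df


def heatmap_layout(
    attr: AttributionMatrix, top_features: int
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Instances sorted by model output (desc), features by mean |contribution|
    (desc); returns (instance order, feature order, aligned slice)."""
    if top_features > len(attr.feature_names):
        raise ValueError("top_features exceeds feature count")
    instance_order = np.argsort(-attr.model_outputs, kind="stable")
    mean_abs = attr.contributions.abs().mean(axis=0)
    feature_order = list(mean_abs.sort_values(ascending=False, kind="stable").index[:top_features])
    block = attr.contributions.iloc[instance_order][feature_order].to_numpy()
    return instance_order, feature_order, block


def force_decomposition(attr: AttributionMatrix, instance: int) -> dict:
    """Signed contributions sorted by |value| for one instance."""
    n = len(attr.contributions)
    if not 0 <= instance < n:
        raise ValueError(f"instance index {instance} out of range [0, {n})")
    row = attr.contributions.iloc[instance]
    order = row.abs().sort_values(ascending=False).index
    return {
        "instance": int(instance),
        "base_value": attr.base_value,
        "model_output": float(attr.model_outputs[instance]),
        "contributions": [(f, float(row[f])) for f in order],
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_map(parent: dict[str, str]) -> dict[str, str]:
    school = set(SCHOOL_LEVEL_FEATURES)
    return {
        col: ("school" if par in school else "individual")
        for col, par in parent.items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every configured outcome; returns the bundle."""
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = config.base_seed
    log.info("pipeline start: %s", json.dumps(config.to_dict())[:500])

    stage = "simulate"
    bundle: dict = {"config": config.to_dict(), "outcomes": {}}
    written: list[Path] = []
    try:
        cohort_cfg = replace(config.cohort, seed=base)
        cohort = generate_cohort(cohort_cfg)
        cohort_dir = out_dir / "cohort"
        cohort.to_dir(cohort_dir, config=cohort_cfg)
        written += sorted(cohort_dir.iterdir())
        config.to_json(out_dir / "pipeline_config.json")
        written.append(out_dir / "pipeline_config.json")
        bundle["cohort"] = cohort

        for outcome in config.outcomes:
            res: dict = {}
            odir = out_dir / outcome
            odir.mkdir(exist_ok=True)
            y = cohort.outcomes[outcome]
            features = cohort.features

            stage = f"{outcome}:cross_validation"
            log.info("stage %s", stage)
            cv = monte_carlo_cv(
                features,
                y,
                n_iterations=config.n_cv_iterations,
                train_frac=config.train_frac,
                base_seed=base + 100,
                hyperparams=config.hyperparams,
                n_boot=config.n_bootstrap,
            )
            cv.to_json(odir / "cv_report.json")
            res["cv"] = cv

            stage = f"{outcome}:final_fit"
            log.info("stage %s", stage)
            rng = np.random.default_rng(base + 200)
            perm = rng.permutation(len(features))
            n_train = int(round(config.train_frac * len(features)))
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            plan = fit_preprocess(features.iloc[train_idx])
            X_train = apply_preprocess(plan, features.iloc[train_idx])
            X_test = apply_preprocess(plan, features.iloc[test_idx])
            ens = fit_ensemble(
                X_train, y[train_idx], seed=base + 200, hyperparams=config.hyperparams
            )
            final_eval = evaluate(
                ens, X_test, y[test_idx], n_boot=config.n_bootstrap, seed=base + 200
            )
            _write_json(odir / "final_eval.json", final_eval.to_dict())
            plan.to_json(odir / "preprocess_plan.json")
            res.update(plan=plan, ensemble=ens, final_eval=final_eval,
                       train_idx=train_idx, test_idx=test_idx)

            stage = f"{outcome}:sage"
            log.info("stage %s", stage)
            bg_rng = np.random.default_rng(base + 300)
            bg_idx = bg_rng.choice(
                len(X_train), size=min(config.sage_background, len(X_train)), replace=False
            )
            background = X_train.to_numpy()[bg_idx]
            sage = sage_auc(
                ens.predict_proba,
                X_test,
                y[test_idx],
                background,
                n_permutations=config.sage_permutations,
                seed=base + 300,
                eval_cap=config.sage_eval_cap,
            )
            sage.to_json(odir / "sage.json")
            res["sage"] = sage

            stage = f"{outcome}:inclusion_curve"
            log.info("stage %s", stage)
            ranking = [name for name, _ in sage.ordered()]
            d = len(ranking)
            ks = sorted({0, 1, 2, 3, 4, 5, 6, 8, 10, 14, 20, 28, d} & set(range(d + 1)))
            curve = inclusion_curve(
                features, y, ranking, ks, cv_seed=base + 200,
                hyperparams=config.hyperparams,
            )
            curve.to_json(odir / "inclusion_curve.json")
            k_sel = select_top_k(curve, config.inclusion_tolerance)
            res.update(curve=curve, k_selected=k_sel)

            stage = f"{outcome}:topk_refit"
            log.info("stage %s (k=%d)", stage, k_sel)
            top_cols = [f for f in ranking[:k_sel] if f in X_train.columns]
            ens_k = fit_ensemble(
                X_train[top_cols], y[train_idx], seed=base + 200,
                hyperparams=config.hyperparams,
            )
            topk_eval = evaluate(
                ens_k, X_test[top_cols], y[test_idx],
                n_boot=config.n_bootstrap, seed=base + 200,
            )
            _write_json(
                odir / "topk.json",
                {"k": k_sel, "features": top_cols, "eval": topk_eval.to_dict()},
            )
            res["topk_eval"] = topk_eval

            stage = f"{outcome}:shap"
            log.info("stage %s", stage)
            X_all = apply_preprocess(plan, features)
            attr_tree = shap_tree(ens.tree_model, X_all, background)
            attr_tree.to_files(odir / "shap_tree.csv", odir / "shap_tree.json")
            sub_rng = np.random.default_rng(base + 400)
            sub_idx = np.sort(
                sub_rng.choice(
                    len(X_all), size=min(config.shap_subsample, len(X_all)), replace=False
                )
            )
            attr_marginal = shap_marginal(
                ens.predict_proba,
                X_all.iloc[sub_idx],
                background,
                n_samples=config.shap_samples,
                seed=base + 400,
            )
            attr_marginal.to_files(odir / "shap_marginal.csv", odir / "shap_marginal.json")
            res.update(attr_tree=attr_tree, attr_marginal=attr_marginal, X_all=X_all)

            stage = f"{outcome}:cluster_tree"
            log.info("stage %s", stage)
            cluster_params = replace(config.cluster, seed=base + 500)
            root = build_cluster_tree(attr_tree, y, cluster_params)
            root.to_json(odir / "cluster_tree.json")
            leaf_assignments(root).to_csv(odir / "leaf_assignments.csv", index=False)
            _write_json(
                odir / "high_prevalence_drivers.json",
                summarize_high_prevalence(root, attr_tree),
            )
            res["cluster_root"] = root

            stage = f"{outcome}:reports"
            log.info("stage %s", stage)
            for feat in ("debt", "experience"):
                if feat in attr_tree.feature_names:
                    dep = dependence_table(attr_tree, feat)
                    dep.to_csv(odir / f"dependence_{feat}.csv", index=False)
                    res[f"dependence_{feat}"] = dep
            inst_order, feat_order, block = heatmap_layout(
                attr_tree, min(15, len(attr_tree.feature_names))
            )
            _write_json(
                odir / "heatmap.json",
                {
                    "instance_order": [int(i) for i in inst_order],
                    "feature_order": feat_order,
                    "values": block.tolist(),
                },
            )
            top_instance = int(np.argmax(attr_tree.model_outputs))
            force = force_decomposition(attr_tree, top_instance)
            _write_json(odir / "force_top_instance.json", force)
            res["force_top"] = force
            res["summary_ranking"] = summary_ranking(attr_tree, _group_map(plan.parent))
            _write_json(
                odir / "summary_ranking.json",
                {g: [[f, v] for f, v in items] for g, items in res["summary_ranking"].items()},
            )
            written += sorted(odir.iterdir())
            bundle["outcomes"][outcome] = res
    except Exception:
        log.error("pipeline failed at stage %s (base_seed=%d)", stage, base)
        raise

    manifest = {
        "base_seed": base,
        "elapsed_seconds": round(time.time() - t_start, 3),
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in written if p.is_file()
        },
    }
    _write_json(out_dir / "manifest.json", manifest)
    bundle["manifest"] = manifest
    log.info("pipeline done in %.1fs", manifest["elapsed_seconds"])
    return bundle
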