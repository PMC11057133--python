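"""Stage-stratified module comparisons and the grade classifier.

A stage chain (e.g. normal -> low-grade -> high-grade, or normal -> benign ->
malignant) builds co-expression modules independently per stage and scores
each stage's modules for novelty against the previous stage, tracking how
co-expression rewiring accumulates with progression.  A random-forest
classifier on per-sample module activity scores quantifies how well module
expression separates grades, with mean-decrease-in-Gini variable importance
identifying the discriminating modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from . import network as net
from .network import ExpressionMatrix, ModuleSet
from .novelty import NoveltyResult, score_modules
from .scoring import ModuleScoreMatrix


@dataclass
class StageLink:
    reference_stage: str
    target_stage: str
    results: list[NoveltyResult]


@dataclass
class StageChain:
    stages: list[str]
    module_sets: dict[str, ModuleSet]
    links: list[StageLink]


def build_stage_chain(
    expr: ExpressionMatrix,
    stages: Sequence[str],
    beta: float = 6.0,
    min_size: int = 30,
    min_samples: int = 4,
    **detect_kwargs,
) -> StageChain:
    """Per-stage module detection plus per-link novelty scoring.

    *stages* orders the values of the manifest's ``stage`` column from least
    to most advanced.  Modules are built independently for each stage from
    that stage's samples; each consecutive pair of stages forms a link whose
    target modules are novelty-scored (with tertiles computed within the
    link) against the previous stage's modules.
    """
    if len(stages) < 2:
        raise ValueError("a stage chain needs at least two stages")
    if expr.sample_meta is None or "stage" not in expr.sample_meta.columns:
        raise ValueError("sample manifest must carry a 'stage' column")
    module_sets: dict[str, ModuleSet] = {}
    for stage in stages:
        samples = expr.samples_where(stage=stage)
        if len(samples) < min_samples:
            raise ValueError(
                f"stage {stage!r} has {len(samples)} samples; need >= {min_samples}"
            )
        sub = net.drop_bad_genes(expr.subset_samples(samples))
        adj = net.adjacency(sub, beta=beta)
        module_sets[stage] = net.detect_modules(
            net.tom(adj), min_size=min_size, provenance=stage, **detect_kwargs
        )
    links = [
        StageLink(ref, tgt, score_modules(module_sets[tgt], module_sets[ref]))
        for ref, tgt in zip(stages[:-1], stages[1:])
    ]
    return StageChain(list(stages), module_sets, links)


@dataclass
class ClassifierReport:
    aucs: np.ndarray  # one per iteration
    gini: pd.Series  # mean decrease in Gini per module, R randomForest scale
    important: pd.Series  # gini > threshold
    threshold: float
    seed: int

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))


def _mean_decrease_gini(forest: RandomForestClassifier, n_features: int) -> np.ndarray:
    """Unnormalized impurity decrease per feature, averaged over trees.

    Sums ``n_node_samples * impurity - sum(children)`` over the nodes using
    each feature, i.e. the same raw scale R's randomForest reports as
    MeanDecreaseGini (sklearn's feature_importances_ rescales to sum 1 and
    would not be comparable across forests).
    """
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            decrease = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            total[t.feature[node]] += decrease
    return total / len(forest.estimators_)


def rf_grade_classifier(
    scores: ModuleScoreMatrix | pd.DataFrame,
    labels: Mapping[str, object] | pd.Series,
    n_iter: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    n_trees: int = 500,
    importance_threshold: float = 5.0,
) -> ClassifierReport:
    """Repeated random-forest classification of samples from module scores.

    Each iteration draws a stratified *train_frac* split, fits a forest on
    the training samples' module scores, and records the held-out ROC AUC;
    Gini importances are averaged over iterations.  All randomness derives
    from *seed*, so identical inputs give byte-identical reports.
    """
    mat = scores.scores if isinstance(scores, ModuleScoreMatrix) else scores
    y = pd.Series(labels).reindex(mat.columns)
    if y.isna().any():
        raise ValueError("labels missing for some scored samples")
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    X = mat.T.to_numpy(dtype=float)
    y_bin = (y == classes[1]).to_numpy()
    if len(y_bin) < 10:
        raise ValueError("need at least 10 samples")

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(2 * n_iter) % (2**31 - 1)
    aucs = np.empty(n_iter)
    gini_sum = np.zeros(X.shape[1])
    for i in range(n_iter):
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=train_frac, random_state=int(iter_seeds[2 * i])
        )
        (train_idx, test_idx), = splitter.split(X, y_bin)
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(iter_seeds[2 * i + 1]), n_jobs=1
        )
        rf.fit(X[train_idx], y_bin[train_idx])
        prob = rf.predict_proba(X[test_idx])[:, list(rf.classes_).index(True)]
        aucs[i] = roc_auc_score(y_bin[test_idx], prob)
        gini_sum += _mean_decrease_gini(rf, X.shape[1])

    gini = pd.Series(gini_sum / n_iter, index=mat.index)
    return ClassifierReport(
        aucs=aucs,
        gini=gini,
        important=gini > importance_threshold,
        threshold=importance_threshold,
        seed=seed,
    )


def importance_age_summary(
    report: ClassifierReport,
    age_categories: Mapping[str, str],
    mc_fraction: Mapping[str, float] | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Tabulate grade-discriminating modules by gene-age category.

    A module counts as important when its mean decrease in Gini exceeds the
    threshold (the report's own by default).  When per-module MC gene
    fractions are supplied, the balanced 40-60% MC band is reported as well.
    """
    thr = report.threshold if threshold is None else threshold
    important = report.gini[report.gini > thr]
    rows = []
    for module, g in important.items():
        cat = age_categories.get(module)
        if cat is None:
            raise ValueError(f"age category unknown for module {module!r}")
        row = {"module": module, "gini": float(g), "category": cat}
        if mc_fraction is not None:
            frac = mc_fraction[module]
            row["mc_fraction"] = float(frac)
            row["balanced_40_60"] = bool(0.40 <= frac <= 0.60)
        rows.append(row)
    return pd.DataFrame(rows)
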