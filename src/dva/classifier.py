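"""Feature-matrix assembly, the 500-tree vote-fraction forest, and CV.

The feature matrix concatenates, in fixed order, the 8 conservation
features, the 17 allele-frequency features, and the k graph-embedding
dimensions (8 + 17 + k columns).  A random forest of 500 classification
trees is fitted on it; the pathogenicity score of a variant is the *vote
fraction* — the fraction of trees whose hard prediction is
disease-related — so a single-tree forest scores in {0, 1} and ties at
0.5 classify as disease-related.  Model quality is estimated by tenfold
cross-validation (stratified by label by default), reporting both the
mean of the per-fold metrics and the AUROC of the pooled out-of-fold
scores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from . import evaluation
from .exceptions import (ContractError, FingerprintError, ParameterError,
                         StratificationError)
from .ppi_embedding import EmbeddingMatrix, variant_embedding
from .variant_io import VariantSet

MODEL_FORMAT_VERSION = 1
POSITIVE_LABEL = 1  # disease-related


def embedding_block(vs: VariantSet, emb: EmbeddingMatrix,
                    gene_map: dict[str, str]) -> pd.DataFrame:
    """Per-variant embedding rows (zero vectors for unmapped genes)."""
    rows = np.vstack([variant_embedding(r, emb, gene_map) for r in vs.records]) \
        if len(vs) else np.zeros((0, emb.k))
    return pd.DataFrame(rows, columns=[f"emb_{j + 1}" for j in range(emb.k)])


def build_feature_matrix(vs: VariantSet, conservation: pd.DataFrame,
                         af: pd.DataFrame,
                         embeddings: pd.DataFrame) -> pd.DataFrame:
    """Concatenate the three row-aligned feature blocks.

    Column order is conservation schema, then AF schema, then embedding
    dimensions; the row index is the variant key.
    """
    n = len(vs)
    for name, block in (("conservation", conservation), ("af", af),
                        ("embedding", embeddings)):
        if len(block) != n:
            raise ContractError(
                f"{name} block has {len(block)} rows for {n} variants")
    idx = pd.MultiIndex.from_tuples(vs.keys(), names=("chrom", "pos", "ref", "alt")) \
        if n else pd.MultiIndex.from_arrays([[], [], [], []],
                                            names=("chrom", "pos", "ref", "alt"))
    blocks = [b.reset_index(drop=True) for b in (conservation, af, embeddings)]
    fm = pd.concat(blocks, axis=1)
    fm.index = idx
    return fm


def labels_array(vs: VariantSet) -> np.ndarray:
    """Binary label vector: 1 = disease-related, 0 = neutral."""
    out = []
    for r in vs.records:
        if r.label == "disease_related":
            out.append(1)
        elif r.label == "neutral":
            out.append(0)
        else:
            raise ContractError(f"record {r.key} has non-binary label {r.label!r}")
    return np.array(out, dtype=int)


@dataclass
class ForestModel:
    """Fitted vote-fraction ensemble with its feature schema and seed."""

    forest: RandomForestClassifier
    feature_schema: tuple
    n_trees: int
    seed: int
    fingerprint: str = ""

    def __post_init__(self):
        if not self.fingerprint:
            payload = json.dumps({"schema": list(self.feature_schema),
                                  "n_trees": self.n_trees, "seed": self.seed,
                                  "version": MODEL_FORMAT_VERSION},
                                 sort_keys=True)
            self.fingerprint = hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_forest(fm: pd.DataFrame, labels, n_trees: int = 500,
                 seed: int = 0, **tree_kwargs) -> ForestModel:
    """Fit the classification forest on an imputed feature matrix."""
    if n_trees < 1:
        raise ParameterError(f"n_trees must be >= 1, got {n_trees}")
    y = np.asarray(labels, dtype=int)
    if len(y) != len(fm):
        raise ContractError(f"{len(fm)} rows but {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise ContractError("training labels are single-class")
    X = fm.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ContractError("feature matrix contains missing values; impute first")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1, **tree_kwargs)
    forest.fit(X, y)
    return ForestModel(forest=forest, feature_schema=tuple(fm.columns),
                       n_trees=n_trees, seed=seed)


def score(model: ForestModel, fm: pd.DataFrame) -> np.ndarray:
    """Vote-fraction score: share of trees predicting disease-related."""
    if tuple(fm.columns) != model.feature_schema:
        raise ContractError("feature matrix columns do not match model schema")
    X = fm.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ContractError("feature matrix contains missing values")
    votes = np.zeros(len(fm))
    for tree in model.forest.estimators_:
        votes += (tree.predict(X) == POSITIVE_LABEL)
    return votes / len(model.forest.estimators_)


def classify(scores, threshold: float = 0.5) -> np.ndarray:
    """Hard labels at the vote threshold; a tie votes disease-related."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


@dataclass
class CVPlan:
    """Fold assignment for k-fold cross-validation."""

    n_folds: int
    assignments: np.ndarray  # record index -> fold id
    seed: int

    def __post_init__(self):
        sizes = np.bincount(self.assignments, minlength=self.n_folds)
        if sizes.max() - sizes.min() > 1:
            raise ContractError("fold sizes differ by more than 1")


def make_cv_plan(labels, n_folds: int = 10, seed: int = 0,
                 stratified: bool = True) -> CVPlan:
    """Random near-equal partition into folds, stratified by label by default."""
    y = np.asarray(labels, dtype=int)
    if n_folds < 2 or n_folds > len(y):
        raise ParameterError(f"n_folds must be in [2, n_records], got {n_folds}")
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assignments[test_idx] = fold
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    fold_reports: list
    averaged: evaluation.MetricsReport
    oof_scores: np.ndarray
    pooled_auroc: float
    plan: CVPlan = field(repr=False, default=None)


def cross_validate(fm: pd.DataFrame, labels, plan: CVPlan | None = None,
                   n_trees: int = 500, seed: int = 0, n_folds: int = 10,
                   stratified: bool = True) -> CVResult:
    """Tenfold (by default) cross-validation of the vote-fraction forest.

    For each fold: train on the other folds, score the held-out records,
    evaluate with the standard metrics.  The final report averages the
    per-fold metrics arithmetically; the out-of-fold scores of all records
    are pooled for a single pooled-AUROC estimate as well.
    """
    y = np.asarray(labels, dtype=int)
    if plan is None:
        plan = make_cv_plan(y, n_folds=n_folds, seed=seed, stratified=stratified)
    if len(plan.assignments) != len(fm):
        raise ContractError("CV plan does not cover the feature matrix rows")

    for fold in range(plan.n_folds):
        if len(np.unique(y[plan.assignments != fold])) < 2:
            raise StratificationError(
                f"training split of fold {fold} is single-class")

    oof = np.full(len(fm), np.nan)
    fold_reports = []
    for fold in range(plan.n_folds):
        test_mask = plan.assignments == fold
        y_train = y[~test_mask]
        model = train_forest(fm.loc[~test_mask], y_train, n_trees=n_trees,
                             seed=seed)
        s = score(model, fm.loc[test_mask])
        oof[test_mask] = s
        fold_reports.append(evaluation.evaluate(y[test_mask], s))

    averaged = evaluation.MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        f1=float(np.mean([r.f1 for r in fold_reports])),
        auroc=float(np.mean([r.auroc for r in fold_reports])),
    )
    pooled_auroc = evaluation.roc_auc(y, oof)
    return CVResult(fold_reports=fold_reports, averaged=averaged,
                    oof_scores=oof, pooled_auroc=pooled_auroc, plan=plan)


@dataclass
class ImportanceRanking:
    ranking: list          # (feature name, importance), descending
    category_counts: dict  # {'conservation': c, 'af': a, 'embedding': e} in top_n
    top_n: int


def feature_importance(model: ForestModel, top_n: int = 20) -> ImportanceRanking:
    """Mean-decrease-in-impurity importance ranking with category roll-up.

    Features are attributed to their block by name: ``emb_*`` columns are
    embedding features, ``af_*`` columns allele-frequency features, the
    rest conservation features.
    """
    imps = model.forest.feature_importances_
    n_feat = len(model.feature_schema)
    if top_n > n_feat:
        import warnings
        warnings.warn(f"top_n={top_n} exceeds feature count {n_feat}; clipped",
                      stacklevel=2)
        top_n = n_feat
    order = np.argsort(imps)[::-1]
    ranking = [(model.feature_schema[i], float(imps[i])) for i in order]
    counts = {"conservation": 0, "af": 0, "embedding": 0}
    for name, _ in ranking[:top_n]:
        if name.startswith("emb_"):
            counts["embedding"] += 1
        elif name.startswith("af_"):
            counts["af"] += 1
        else:
            counts["conservation"] += 1
    return ImportanceRanking(ranking=ranking, category_counts=counts, top_n=top_n)


def permutation_feature_importance(model: ForestModel, fm: pd.DataFrame,
                                   labels, seed: int = 0,
                                   top_n: int = 20) -> ImportanceRanking:
    """Permutation-based alternative to the impurity ranking."""
    from sklearn.inspection import permutation_importance

    res = permutation_importance(model.forest, fm.to_numpy(dtype=float),
                                 np.asarray(labels, dtype=int),
                                 random_state=seed, n_repeats=5, n_jobs=1)
    order = np.argsort(res.importances_mean)[::-1]
    top_n = min(top_n, len(model.feature_schema))
    ranking = [(model.feature_schema[i], float(res.importances_mean[i]))
               for i in order]
    counts = {"conservation": 0, "af": 0, "embedding": 0}
    for name, _ in ranking[:top_n]:
        if name.startswith("emb_"):
            counts["embedding"] += 1
        elif name.startswith("af_"):
            counts["af"] += 1
        else:
            counts["conservation"] += 1
    return ImportanceRanking(ranking=ranking, category_counts=counts, top_n=top_n)


def save_model(model: ForestModel, path) -> None:
    """Persist a fitted model with its schema, seed and fingerprint."""
    import joblib

    joblib.dump({"version": MODEL_FORMAT_VERSION,
                 "schema": list(model.feature_schema),
                 "n_trees": model.n_trees, "seed": model.seed,
                 "fingerprint": model.fingerprint,
                 "forest": model.forest}, path)


def load_model(path, expect_fingerprint: str | None = None) -> ForestModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("version") != MODEL_FORMAT_VERSION:
        raise FingerprintError(f"unsupported model format version {blob.get('version')}")
    model = ForestModel(forest=blob["forest"],
                        feature_schema=tuple(blob["schema"]),
                        n_trees=blob["n_trees"], seed=blob["seed"],
                        fingerprint=blob["fingerprint"])
    if expect_fingerprint is not None and model.fingerprint != expect_fingerprint:
        raise FingerprintError(
            f"model fingerprint {model.fingerprint} != expected {expect_fingerprint}")
    return model
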