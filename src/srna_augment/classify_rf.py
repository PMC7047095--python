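"""Two-stage random-forest classifier with Gini-based feature selection.

Stage 1 fits a 100-tree forest on all features and ranks them by mean
decrease in Gini impurity; the top 1000 enter a 500-tree stage-2 forest.
Both stages train on class-balanced data: every class is downsampled
without replacement to the smallest class size.  mtry = floor(sqrt(p)).
The forest learner itself is scikit-learn's; the selection, balancing
and determinism contracts live here.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["TwoStageForestModel", "two_stage_fit", "rf_predict",
           "save_model", "load_model"]

N_TREES_STAGE1 = 100
N_TREES_STAGE2 = 500
TOP_K = 1000


@dataclass
class TwoStageForestModel:
    stage1_importances: np.ndarray
    selected_indices: np.ndarray        # importance-rank order
    selected_feature_ids: list[str]
    stage2: RandomForestClassifier
    classes_: np.ndarray
    seed: int
    n_trees_stage1: int = N_TREES_STAGE1
    n_trees_stage2: int = N_TREES_STAGE2
    mtry_stage1: int = 0
    mtry_stage2: int = 0
    # row indices used after downsampling, kept for auditability
    stage1_sample_idx: np.ndarray = field(default=None)
    stage2_sample_idx: np.ndarray = field(default=None)
    feature_ids: list[str] = field(default_factory=list)


def _downsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices balancing every class to the smallest class size."""
    values, counts = np.unique(y, return_counts=True)
    m = counts.min()
    picked = []
    for v in values:
        idx = np.where(y == v)[0]
        picked.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(picked))


def two_stage_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_ids: list[str] | None = None,
    top_k: int = TOP_K,
    n_trees_stage1: int = N_TREES_STAGE1,
    n_trees_stage2: int = N_TREES_STAGE2,
) -> TwoStageForestModel:
    """Fit the two-stage forest; deterministic given ``seed``.

    Downsampling is drawn independently for each stage from the same
    seeded stream.  Ties in stage-1 importance break by feature order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        bad = values[counts.argmin()]
        raise ValueError(
            f"class {bad!r} has a single sample; run filter_small_classes first"
        )
    p = X.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    rng = np.random.default_rng(seed)

    idx1 = _downsample(y, rng)
    mtry = max(1, int(np.floor(np.sqrt(p))))
    stage1 = RandomForestClassifier(
        n_estimators=n_trees_stage1,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )
    stage1.fit(X[idx1], y[idx1])
    importances = stage1.feature_importances_

    k = min(top_k, p)
    order = np.argsort(-importances, kind="stable")  # stable => ties by feature order
    selected = order[:k]

    idx2 = _downsample(y, rng)
    mtry2 = max(1, int(np.floor(np.sqrt(k))))
    stage2 = RandomForestClassifier(
        n_estimators=n_trees_stage2,
        max_features=mtry2,
        random_state=seed + 1,
        n_jobs=1,
    )
    stage2.fit(X[np.ix_(idx2, selected)], y[idx2])

    return TwoStageForestModel(
        stage1_importances=importances,
        selected_indices=selected,
        selected_feature_ids=[feature_ids[i] for i in selected],
        stage2=stage2,
        classes_=stage2.classes_,
        seed=seed,
        n_trees_stage1=n_trees_stage1,
        n_trees_stage2=n_trees_stage2,
        mtry_stage1=mtry,
        mtry_stage2=mtry2,
        stage1_sample_idx=idx1,
        stage2_sample_idx=idx2,
        feature_ids=list(feature_ids),
    )


def rf_predict(
    model: TwoStageForestModel,
    X: np.ndarray,
    feature_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over stage-2 trees.

    ``X`` must carry the full stage-1 feature space (columns are mapped
    through ``selected_indices``) unless ``feature_ids`` names its
    columns, in which case selected features are located by id.  Returns
    (labels, vote fractions); vote-fraction rows sum to 1 and ties break
    to the lowest class index.
    """
    X = np.asarray(X, dtype=np.float64)
    if feature_ids is not None:
        pos = {f: i for i, f in enumerate(feature_ids)}
        missing = [f for f in model.selected_feature_ids if f not in pos]
        if missing:
            raise ValueError(f"missing selected feature(s): {missing[:5]}")
        cols = np.array([pos[f] for f in model.selected_feature_ids])
    else:
        if X.shape[1] <= model.selected_indices.max():
            raise ValueError(
                "X narrower than the stage-1 feature space; pass feature_ids"
            )
        cols = model.selected_indices
    Xs = X[:, cols]
    n_classes = len(model.classes_)
    votes = np.zeros((X.shape[0], n_classes))
    class_pos = {c: i for i, c in enumerate(model.classes_)}
    for tree in model.stage2.estimators_:
        pred = model.stage2.classes_[
            np.argmax(tree.predict_proba(Xs), axis=1)
        ]
        for r, c in enumerate(pred):
            votes[r, class_pos[c]] += 1
    fractions = votes / votes.sum(axis=1, keepdims=True)
    labels = model.classes_[np.argmax(fractions, axis=1)]
    return labels, fractions


def save_model(model: TwoStageForestModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> TwoStageForestModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
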