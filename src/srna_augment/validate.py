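"""Validation schemes and metrics.

Two split generators — stratified five-fold cross-validation and
one-dataset-out (each held-out dataset must leave every one of its
target classes represented in training) — plus confusion-matrix based
evaluation with per-class precision and unweighted aggregation across
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan",
    "EvalReport",
    "stratified_kfold_split",
    "one_dataset_out_splits",
    "evaluate",
    "aggregate_accuracy",
    "write_reports",
]


@dataclass
class SplitPlan:
    name: str
    train_ids: list
    test_ids: list
    fold: int | None = None
    heldout_dataset: str | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"split {self.name}: train/test overlap {sorted(overlap)[:5]}")


@dataclass
class EvalReport:
    accuracy: float
    precision: dict          # class -> fraction, or None if never predicted
    confusion: np.ndarray    # true x predicted
    classes: list
    n_test: int
    name: str = ""


def stratified_kfold_split(
    sample_ids,
    y,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> list[SplitPlan]:
    """Deterministic k-fold plans over sample ids.

    With stratification, per-class test counts across folds differ by at
    most one.  Every sample lands in exactly one test fold.
    """
    sample_ids = list(sample_ids)
    y = np.asarray(y)
    if len(sample_ids) != len(y):
        raise ValueError("sample_ids and y must align")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    if stratified:
        for cls in np.unique(y):
            idx = np.where(y == cls)[0]
            if len(idx) < k:
                raise ValueError(
                    f"class {cls!r} has {len(idx)} < k={k} samples; "
                    "apply filter_small_classes first"
                )
            idx = rng.permutation(idx)
            for f in range(k):
                fold_of[idx[f::k]] = f
    else:
        idx = rng.permutation(len(y))
        for f in range(k):
            fold_of[idx[f::k]] = f
    plans = []
    for f in range(k):
        test = [sample_ids[i] for i in np.where(fold_of == f)[0]]
        train = [sample_ids[i] for i in np.where(fold_of != f)[0]]
        plans.append(SplitPlan(name=f"fold{f}", train_ids=train, test_ids=test, fold=f))
    return plans


def one_dataset_out_splits(md: pd.DataFrame, target: str) -> list[SplitPlan]:
    """One plan per eligible dataset.

    A dataset is eligible iff every target class it contains also occurs
    in at least one other dataset, so holding it out never removes a
    class from training.
    """
    if md["dataset_id"].nunique() < 2:
        raise ValueError("need at least 2 datasets for one-dataset-out")
    plans = []
    for ds in sorted(md["dataset_id"].unique()):
        inside = md[md["dataset_id"] == ds]
        outside = md[md["dataset_id"] != ds]
        if not set(inside[target]).issubset(set(outside[target])):
            continue
        plans.append(
            SplitPlan(
                name=f"out_{ds}",
                train_ids=outside["sample_id"].tolist(),
                test_ids=inside["sample_id"].tolist(),
                heldout_dataset=ds,
            )
        )
    if not plans:
        raise ValueError("no eligible dataset: every dataset is the sole carrier of some class")
    return plans


def evaluate(y_pred, y_true, classes, name: str = "") -> EvalReport:
    """Confusion matrix, accuracy and per-class precision.

    Precision of a class never predicted is reported as None rather
    than 0.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError("prediction/truth length mismatch")
    classes = list(classes)
    pos = {c: i for i, c in enumerate(classes)}
    for v in np.unique(np.concatenate([y_true, y_pred])):
        if v not in pos:
            raise ValueError(f"label {v!r} outside the declared class set")
    K = len(classes)
    confusion = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[pos[t], pos[p]] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    precision = {}
    for c in classes:
        col = confusion[:, pos[c]]
        predicted = col.sum()
        precision[c] = float(confusion[pos[c], pos[c]] / predicted) if predicted else None
    return EvalReport(
        accuracy=accuracy,
        precision=precision,
        confusion=confusion,
        classes=classes,
        n_test=int(confusion.sum()),
        name=name,
    )


def aggregate_accuracy(reports: list[EvalReport], weighted: bool = False) -> float:
    """Mean accuracy across splits; unweighted by default (per-split mean)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    if weighted:
        total = sum(r.n_test for r in reports)
        return float(sum(r.accuracy * r.n_test for r in reports) / total)
    return float(np.mean([r.accuracy for r in reports]))


def write_reports(reports: list[EvalReport], outdir: str | Path) -> Path:
    """One summary TSV (per split + aggregate row) and a confusion TSV each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in reports:
        row = {"split": r.name, "n_test": r.n_test, "accuracy": r.accuracy}
        for c in r.classes:
            row[f"precision_{c}"] = r.precision[c]
        rows.append(row)
        pd.DataFrame(r.confusion, index=r.classes, columns=r.classes).to_csv(
            outdir / f"confusion_{r.name}.tsv", sep="\t"
        )
    rows.append(
        {
            "split": "aggregate_mean",
            "n_test": sum(r.n_test for r in reports),
            "accuracy": aggregate_accuracy(reports),
        }
    )
    summary = outdir / "evaluation.tsv"
    pd.DataFrame(rows).to_csv(summary, sep="\t", index=False)
    return summary
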