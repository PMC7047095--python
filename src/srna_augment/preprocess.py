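"""Count-matrix I/O, normalization, filtering, tissue grouping, age binning.

The fixed preprocessing order is: RPM normalization, removal of features
with more than ``max_zero_frac`` zeros, then per-feature min-max scaling
to [0, 1].  Tissue labels can be merged to ontology groups via a packaged
mapping table, and continuous ages are discretized into the 2/3/4
interval schemes (first interval closed at both ends, the rest left-open
right-closed).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScalerParams",
    "ParseError",
    "AGE_BINNINGS",
    "read_counts",
    "write_counts",
    "read_metadata",
    "rpm_normalize",
    "filter_zero_features",
    "minmax_fit",
    "minmax_transform",
    "load_ontology_map",
    "group_tissues",
    "bin_ages",
    "filter_small_classes",
    "select_feature_kind",
]

#: Age-interval edges for the 2/3/4-bin schemes (years).
AGE_BINNINGS: dict[int, list[float]] = {
    2: [0, 65, 110],
    3: [0, 45, 70, 110],
    4: [0, 30, 60, 80, 110],
}

VALID_KINDS = ("srna", "contaminant")


class ParseError(ValueError):
    """Malformed input table."""


@dataclass
class ExpressionMatrix:
    """Expression values, features x samples, each feature tagged by kind."""

    values: np.ndarray
    feature_ids: list[str]
    feature_kind: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_kind = np.asarray(self.feature_kind, dtype=object)
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValueError("feature_ids length does not match values")
        if len(self.feature_kind) != n_feat:
            raise ValueError("feature_kind length does not match values")
        if len(self.sample_ids) != n_samp:
            raise ValueError("sample_ids length does not match values")
        dup = _duplicates(self.feature_ids)
        if dup:
            raise ParseError(f"duplicate feature_id(s): {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ParseError(f"duplicate sample_id(s): {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("matrix contains non-finite values")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative value at feature {self.feature_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        unknown = set(self.feature_kind) - set(VALID_KINDS)
        if unknown:
            raise ParseError(f"unknown feature_kind value(s): {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[indices, :],
            feature_ids=[self.feature_ids[i] for i in indices],
            feature_kind=self.feature_kind[indices],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, indices],
            feature_ids=list(self.feature_ids),
            feature_kind=self.feature_kind.copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def to_sample_matrix(self) -> np.ndarray:
        """Samples x features array, the orientation classifiers expect."""
        return self.values.T.copy()


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a TSV count matrix.

    First column holds feature ids; an optional ``feature_kind`` second
    column tags each feature (defaults to ``srna``); remaining header
    fields are sample ids.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = _duplicates(header[1:])
    if dup:
        raise ParseError(f"{path}: duplicate sample_id(s): {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 columns")
    feature_ids = df.iloc[:, 0].tolist()
    if "feature_kind" in df.columns:
        kind = df["feature_kind"].astype(str).to_numpy()
        data = df.drop(columns=[df.columns[0], "feature_kind"])
    else:
        kind = np.array(["srna"] * len(feature_ids), dtype=object)
        data = df.drop(columns=[df.columns[0]])
    sample_ids = [str(c) for c in data.columns]
    try:
        values = data.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: non-numeric cell ({e})") from None
    return ExpressionMatrix(
        values=values,
        feature_ids=feature_ids,
        feature_kind=kind,
        sample_ids=sample_ids,
    )


def write_counts(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, columns=m.sample_ids)
    df.insert(0, "feature_id", m.feature_ids)
    df.insert(1, "feature_kind", m.feature_kind)
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, dataset_id, tissue, sex, age)."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    if "sample_id" not in md.columns:
        raise ParseError(f"{path}: missing sample_id column")
    dup = _duplicates(md["sample_id"].tolist())
    if dup:
        raise ParseError(f"duplicate sample_id(s): {sorted(dup)}")
    if "age" in md.columns:
        ages = md["age"].dropna()
        bad = ages[(ages < 0) | (ages > 120)]
        if len(bad):
            raise ParseError(f"age out of [0, 120] for sample(s) {bad.index.tolist()}")
    return md


def rpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample column to sum to one million (reads per million)."""
    colsums = m.values.sum(axis=0)
    zero = np.where(colsums == 0)[0]
    if len(zero):
        raise ValueError(
            f"cannot RPM-normalize all-zero sample(s): "
            f"{[m.sample_ids[i] for i in zero]}"
        )
    return replace(m, values=m.values * (1e6 / colsums)[None, :])


def filter_zero_features(
    m: ExpressionMatrix, max_zero_frac: float = 0.30
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop features whose fraction of exact zeros exceeds the threshold.

    The comparison is strict: a feature with exactly ``max_zero_frac``
    zeros is retained.  Feature order is preserved.
    """
    zero_frac = (m.values == 0).mean(axis=1)
    keep = np.where(zero_frac <= max_zero_frac)[0]
    if len(keep) == 0:
        logger.warning("zero filter removed every feature")
    retained = [m.feature_ids[i] for i in keep]
    return m.subset_features(keep), retained


@dataclass
class ScalerParams:
    """Per-feature min/max observed on the fitting set."""

    feature_ids: list[str]
    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_ < self.min_):
            raise ValueError("ScalerParams: max < min for some feature")


def minmax_fit(m: ExpressionMatrix) -> ScalerParams:
    if m.n_samples == 0:
        raise ValueError("cannot fit MinMax scaler on an empty matrix")
    return ScalerParams(
        feature_ids=list(m.feature_ids),
        min_=m.values.min(axis=1),
        max_=m.values.max(axis=1),
    )


def minmax_transform(m: ExpressionMatrix, p: ScalerParams) -> ExpressionMatrix:
    """Map each feature affinely so the fitted range becomes [0, 1].

    Constant features map to 0; values outside the fitted range are
    clipped into [0, 1].
    """
    if list(m.feature_ids) != list(p.feature_ids):
        raise ValueError("scaler params were fitted on a different feature set")
    span = p.max_ - p.min_
    safe = np.where(span > 0, span, 1.0)
    scaled = (m.values - p.min_[:, None]) / safe[:, None]
    scaled[span == 0, :] = 0.0
    return replace(m, values=np.clip(scaled, 0.0, 1.0))


def load_ontology_map(path: str | Path | None = None) -> dict[str, str]:
    """Tissue -> tissue-group mapping; defaults to the packaged table."""
    if path is None:
        source = resources.files("srna_augment.data") / "tissue_groups.tsv"
        with resources.as_file(source) as f:
            df = pd.read_csv(f, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["tissue", "group"]:
        raise ParseError("ontology map must have columns: tissue, group")
    dup = _duplicates(df["tissue"].tolist())
    if dup:
        raise ParseError(f"tissue mapped more than once: {sorted(dup)}")
    return dict(zip(df["tissue"], df["group"]))


def group_tissues(md: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Replace tissue labels by their ontology group.

    Labels absent from the map pass through unchanged with a warning.
    """
    md = md.copy()
    unmapped: set = set()
    lower_map = {k.lower(): v for k, v in mapping.items()}
    md["tissue"] = md["tissue"].map(lambda x: _map_with(lower_map, x, unmapped))
    for label in sorted(unmapped):
        logger.warning("tissue label not in ontology map, kept as-is: %r", label)
    return md


def _map_with(mapping, label, unmapped):
    if pd.isna(label):
        return label
    key = str(label).strip().lower()
    if key in mapping:
        return mapping[key]
    unmapped.add(label)
    return label


def bin_ages(ages, boundaries: list[float], sample_ids=None) -> np.ndarray:
    """Discretize ages into interval indices.

    The first interval is closed at both ends, later intervals are
    left-open right-closed, e.g. edges [0, 65, 110] put 65 in bin 0 and
    66 in bin 1.
    """
    edges = list(boundaries)
    if sorted(set(edges)) != edges:
        raise ValueError("age boundaries must be strictly increasing")
    ages = np.asarray(ages, dtype=float)
    labels = np.empty(len(ages), dtype=int)
    for i, a in enumerate(ages):
        if np.isnan(a) or a < edges[0] or a > edges[-1]:
            sid = sample_ids[i] if sample_ids is not None else f"index {i}"
            raise ValueError(
                f"age {a} for sample {sid} outside [{edges[0]}, {edges[-1]}]"
            )
        # bisect_left over inner edges gives left-open right-closed bins
        labels[i] = bisect_left(edges[1:], a) if a > edges[0] else 0
    return labels


def filter_small_classes(
    X: np.ndarray, y: np.ndarray, min_samples: int, extra: np.ndarray | None = None
):
    """Drop all samples of classes with fewer than ``min_samples`` members.

    ``X`` is samples x features.  ``extra`` (e.g. sample ids or dataset
    ids, aligned with ``y``) is filtered identically when given.  Raises
    if fewer than two classes survive.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    y = np.asarray(y)
    values, counts = np.unique(y, return_counts=True)
    keep_classes = set(values[counts >= min_samples])
    if len(keep_classes) < 2:
        raise ValueError(
            f"fewer than 2 classes with >= {min_samples} samples remain"
        )
    mask = np.array([label in keep_classes for label in y])
    if extra is not None:
        return X[mask], y[mask], np.asarray(extra)[mask]
    return X[mask], y[mask]


def select_feature_kind(m: ExpressionMatrix, kind: str) -> ExpressionMatrix:
    """Restrict to the sRNA block, the contaminant block, or keep both."""
    if kind == "both":
        return m
    if kind not in VALID_KINDS:
        raise ValueError(f"feature_set must be one of srna, contaminant, both; got {kind}")
    idx = np.where(m.feature_kind == kind)[0]
    return m.subset_features(idx)
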