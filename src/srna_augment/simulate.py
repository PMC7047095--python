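"""Synthetic sRNA cohort generator.

Produces count matrices with the statistical structure the downstream
analysis assumes: negative-binomial counts, class-specific marker
features, per-dataset multiplicative batch shifts, weak sex/age signal
planted in both the sRNA and contaminant feature blocks, zero inflation
and variable library sizes.  Everything is driven by a single seeded
generator so a config reproduces bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from srna_augment.preprocess import ExpressionMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimConfigError",
    "generate_cohort",
    "write_cohort",
]


class SimConfigError(ValueError):
    """Raised when a simulation config violates an invariant; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid SimConfig.{field_name}: {message}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    ``marker_log2fc`` is the log2 fold change applied to a class's
    planted marker features in samples of that class.  ``age_slope`` is
    a log2-scale change per year, applied relative to the midpoint of
    ``age_range``.  ``dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2 / dispersion).
    """

    n_classes: int = 3
    datasets_per_class: int = 3
    samples_per_dataset: int = 30
    n_srna: int = 2000
    n_contaminant: int = 200
    markers_per_class: int = 20
    marker_log2fc: float = 3.0
    dispersion: float = 5.0
    batch_sd: float = 0.1
    zero_inflation: float = 0.1
    sex_effect_features: int = 20
    sex_log2fc: float = 1.0
    age_range: tuple[float, float] = (20.0, 90.0)
    age_effect_features: int = 20
    age_slope: float = 0.02
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_classes",
            "datasets_per_class",
            "samples_per_dataset",
            "n_srna",
        ):
            if getattr(self, name) < 1:
                raise SimConfigError(name, "must be >= 1")
        for name in (
            "n_contaminant",
            "markers_per_class",
            "sex_effect_features",
            "age_effect_features",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(name, "must be >= 0")
        if self.markers_per_class * self.n_classes > self.n_srna:
            raise SimConfigError(
                "markers_per_class",
                "markers_per_class * n_classes must not exceed n_srna",
            )
        if self.dispersion <= 0:
            raise SimConfigError("dispersion", "must be > 0")
        if self.batch_sd < 0:
            raise SimConfigError("batch_sd", "must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise SimConfigError("zero_inflation", "must be in [0, 1]")
        lo, hi = self.age_range
        if not (0 <= lo <= hi):
            raise SimConfigError("age_range", "must satisfy 0 <= lo <= hi")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            raise SimConfigError(
                "library_size_range", "must satisfy 0 < lo <= hi"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery checks."""

    marker_ids_by_class: dict[str, list[str]]
    sex_feature_ids: list[str]
    age_feature_ids: list[str]
    dataset_batch_shifts: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def all_marker_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.marker_ids_by_class.values():
            out.update(ids)
        return out


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial in mean/size parameterization; mean may be 0."""
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a synthetic cohort.

    Returns the count matrix (features x samples), a per-sample metadata
    frame (sample_id, dataset_id, tissue, sex, age) and the planted
    ground truth.  Identical configs (including seed) yield bit-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_feat = config.n_srna + config.n_contaminant
    feature_ids = [f"srna_{i:05d}" for i in range(config.n_srna)] + [
        f"contam_{i:05d}" for i in range(config.n_contaminant)
    ]
    feature_kind = np.array(
        ["srna"] * config.n_srna + ["contaminant"] * config.n_contaminant
    )

    # Baseline per-feature mean abundances (relative), heavy-tailed as in
    # real sRNA-seq.
    base_mu = rng.lognormal(mean=2.0, sigma=1.2, size=n_feat)

    classes = [f"tissue_{c}" for c in range(config.n_classes)]

    # Planted markers: disjoint sets drawn from the sRNA block.
    marker_pool = rng.permutation(config.n_srna)
    marker_idx_by_class: dict[str, np.ndarray] = {}
    used = 0
    for cls in classes:
        idx = np.sort(marker_pool[used : used + config.markers_per_class])
        marker_idx_by_class[cls] = idx
        used += config.markers_per_class

    # Sex/age effect features live in BOTH blocks (when a contaminant
    # block exists), disjoint from markers.
    marker_set = set(int(i) for i in marker_pool[:used])
    free_srna = np.array(
        [i for i in range(config.n_srna) if i not in marker_set], dtype=int
    )
    contam_idx = np.arange(config.n_srna, n_feat)

    def _pick_effect(n: int) -> np.ndarray:
        if n == 0:
            return np.array([], dtype=int)
        n_s = n // 2 if config.n_contaminant > 0 else n
        n_c = n - n_s if config.n_contaminant > 0 else 0
        picked_s = rng.choice(free_srna, size=min(n_s, len(free_srna)), replace=False)
        picked_c = (
            rng.choice(contam_idx, size=min(n_c, len(contam_idx)), replace=False)
            if n_c
            else np.array([], dtype=int)
        )
        return np.sort(np.concatenate([picked_s, picked_c]))

    sex_idx = _pick_effect(config.sex_effect_features)
    age_idx = _pick_effect(config.age_effect_features)

    # Planted signal goes on reliably detected features, otherwise the
    # zero filter silences it before any classifier sees it.
    floor = np.median(base_mu)
    for idx in (*marker_idx_by_class.values(), sex_idx, age_idx):
        if len(idx):
            base_mu[idx] = np.maximum(base_mu[idx], floor)

    # Samples and metadata.
    sample_ids: list[str] = []
    dataset_ids: list[str] = []
    tissues: list[str] = []
    batch_shifts: dict[str, float] = {}
    n_samples = (
        config.n_classes * config.datasets_per_class * config.samples_per_dataset
    )
    sample_no = 0
    for ci, cls in enumerate(classes):
        for d in range(config.datasets_per_class):
            ds_id = f"{cls}_ds{d}"
            shift = float(rng.normal(0.0, config.batch_sd)) if config.batch_sd > 0 else 0.0
            batch_shifts[ds_id] = shift
            for _ in range(config.samples_per_dataset):
                sample_ids.append(f"sample_{sample_no:05d}")
                dataset_ids.append(ds_id)
                tissues.append(cls)
                sample_no += 1

    sexes = np.where(rng.random(n_samples) < 0.5, "female", "male")
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n_samples)
    age_mid = (lo + hi) / 2.0
    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.uniform(lib_lo, lib_hi, size=n_samples)
    lib_scale = lib_sizes / np.mean([lib_lo, lib_hi])

    # Expected mean matrix (features x samples).
    mu = np.tile(base_mu[:, None], (1, n_samples))
    for ci, cls in enumerate(classes):
        cols = np.array([t == cls for t in tissues])
        idx = marker_idx_by_class[cls]
        if len(idx):
            mu[np.ix_(idx, np.where(cols)[0])] *= 2.0 ** config.marker_log2fc
    if len(sex_idx):
        male_cols = np.where(sexes == "male")[0]
        mu[np.ix_(sex_idx, male_cols)] *= 2.0 ** config.sex_log2fc
    if len(age_idx) and config.age_slope != 0.0:
        age_factor = 2.0 ** (config.age_slope * (ages - age_mid))
        mu[age_idx, :] *= age_factor[None, :]
    shifts = np.array([batch_shifts[d] for d in dataset_ids])
    mu *= np.exp(shifts)[None, :]
    mu *= lib_scale[None, :]

    counts = _nb_sample(rng, mu, config.dispersion).astype(np.float64)
    if config.zero_inflation > 0:
        drop = rng.random(counts.shape) < config.zero_inflation
        counts[drop] = 0.0

    matrix = ExpressionMatrix(
        values=counts,
        feature_ids=feature_ids,
        feature_kind=feature_kind,
        sample_ids=sample_ids,
    )
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dataset_id": dataset_ids,
            "tissue": tissues,
            "sex": sexes,
            "age": np.round(ages, 2),
        }
    )
    truth = GroundTruth(
        marker_ids_by_class={
            cls: [feature_ids[i] for i in idx]
            for cls, idx in marker_idx_by_class.items()
        },
        sex_feature_ids=[feature_ids[i] for i in sex_idx],
        age_feature_ids=[feature_ids[i] for i in age_idx],
        dataset_batch_shifts=batch_shifts,
        config=asdict(config),
    )
    return matrix, metadata, truth


def write_cohort(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, metadata.tsv and truth.json into ``outdir``."""
    from srna_augment import preprocess

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    preprocess.write_counts(matrix, paths["counts"])
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
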