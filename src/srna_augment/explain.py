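"""DeepLIFT attribution and ablation-based class-stability analysis.

Contribution scores are computed with the Rescale rule against a zero
reference: multipliers start at the pre-softmax outputs (where the
summation-to-delta property is exact), propagate through linear layers
by transposed weights and through ReLUs by the ratio of activation
difference to pre-activation difference.  On top of the per-sample
score tensor the module computes class-average difference scores (D1),
top-N marker lists, per-rival score differences (D2) and the
order-then-zero ablation procedure that counts how many features must
be silenced before a prediction flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from srna_augment.classify_dl import DenseNetModel

__all__ = [
    "AttributionTensor",
    "AblationResult",
    "StabilityReport",
    "deeplift_attribute",
    "class_average_scores",
    "top_n_features",
    "topn_expression_summary",
    "pairwise_differences",
    "ablate_until_flip",
    "stability_similarity_matrices",
    "per_sample_score_table",
    "write_d1_table",
    "write_top_n",
    "write_stability_report",
]

#: below this |delta pre-activation| the ReLU multiplier falls back to the
#: derivative at the reference
RESCALE_EPS = 1e-7


@dataclass
class AttributionTensor:
    """Scores C[i, j, k]: sample i x input feature j x output class k."""

    scores: np.ndarray
    reference: np.ndarray
    ref_output: np.ndarray       # pre-softmax outputs at the reference
    classes: np.ndarray
    feature_ids: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[2]


def deeplift_attribute(
    model: DenseNetModel, X: np.ndarray, reference: np.ndarray | None = None
) -> AttributionTensor:
    """Rescale-rule attribution of pre-softmax outputs to inputs.

    Satisfies summation-to-delta: sum_j C[i,j,k] equals
    logit_k(x_i) - logit_k(reference) (up to the epsilon branch on
    near-zero pre-activation differences).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if reference is None:
        reference = np.zeros(model.n_inputs)
    reference = np.asarray(reference, dtype=np.float64).reshape(-1)
    if reference.shape[0] != model.n_inputs:
        raise ValueError("reference width does not match model inputs")

    _, internals, _ = model.forward(X, return_internals=True)
    _, ref_internals, _ = model.forward(reference[None, :], return_internals=True)

    n = X.shape[0]
    K = model.n_classes
    last = model.n_layers - 1
    # multipliers at the pre-softmax output: identity per sample
    mult = np.broadcast_to(np.eye(K), (n, K, K)).copy()
    for l in range(last, -1, -1):
        if l < last:
            # ReLU nonlinearity between pre-activation and activation
            pre, act = internals[l]
            ref_pre, ref_act = ref_internals[l]
            d_pre = pre - ref_pre
            d_act = act - ref_act
            ratio = np.where(
                np.abs(d_pre) > RESCALE_EPS,
                d_act / np.where(np.abs(d_pre) > RESCALE_EPS, d_pre, 1.0),
                (ref_pre > 0).astype(float),
            )
            mult = mult * ratio[:, :, None]
        # linear layer: multipliers flow through transposed weights
        mult = np.einsum("du,nuk->ndk", model.weights[l], mult)
    scores = mult * (X - reference[None, :])[:, :, None]
    return AttributionTensor(
        scores=scores,
        reference=reference,
        ref_output=ref_internals[-1][0][0],
        classes=model.classes_,
    )


def class_average_scores(tensor: AttributionTensor, y) -> np.ndarray:
    """D1[j, k]: class-k mean of (own-class score minus mean rival score).

    Columns of classes with no samples are NaN.
    """
    y = np.asarray(y)
    if len(y) != tensor.n_samples:
        raise ValueError("labels do not align with attribution samples")
    K = tensor.n_classes
    if K < 2:
        raise ValueError("need at least 2 classes")
    C = tensor.scores
    D1 = np.full((tensor.n_features, K), np.nan)
    for ki, cls in enumerate(tensor.classes):
        rows = np.where(y == cls)[0]
        if len(rows) == 0:
            continue
        own = C[rows, :, ki]
        others = (C[rows].sum(axis=2) - own) / (K - 1)
        D1[:, ki] = (own - others).mean(axis=0)
    return D1


def top_n_features(
    D1: np.ndarray,
    classes,
    feature_ids: list[str],
    n: int = 300,
) -> dict:
    """Per class, the top-n features by D1 descending; ties by feature order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = {}
    for ki, cls in enumerate(classes):
        col = D1[:, ki]
        if np.all(np.isnan(col)):
            out[cls] = None
            continue
        order = np.argsort(-col, kind="stable")[: min(n, len(col))]
        out[cls] = [feature_ids[i] for i in order]
    return out


def topn_expression_summary(
    top_lists: dict,
    X: np.ndarray,
    y,
    feature_ids: list[str],
) -> pd.DataFrame:
    """Mean scaled expression (rows = classes, columns = union of top features)."""
    y = np.asarray(y)
    pos = {f: i for i, f in enumerate(feature_ids)}
    feats: list[str] = []
    for lst in top_lists.values():
        if lst:
            feats.extend(f for f in lst if f not in feats)
    missing = [f for f in feats if f not in pos]
    if missing:
        raise ValueError(f"feature(s) not in X: {missing[:5]}")
    rows = {}
    for cls in top_lists:
        mask = y == cls
        if not mask.any():
            continue
        rows[cls] = [float(X[mask, pos[f]].mean()) for f in feats]
    return pd.DataFrame.from_dict(rows, orient="index", columns=feats)


def pairwise_differences(
    tensor: AttributionTensor, i: int, k, k_prime
) -> tuple[np.ndarray, np.ndarray]:
    """D2[j] = C[i,j,k] - C[i,j,k'] and the descending-D2 feature order.

    Features arguing most strongly for k over k' come first; ties break
    by feature order.
    """
    if k == k_prime:
        raise ValueError("k_prime must differ from k")
    classes = list(tensor.classes)
    ki, kpi = classes.index(k), classes.index(k_prime)
    d2 = tensor.scores[i, :, ki] - tensor.scores[i, :, kpi]
    order = np.argsort(-d2, kind="stable")
    return order, d2


@dataclass
class AblationResult:
    steps: int
    censored: bool
    cap: int


def ablate_until_flip(
    model: DenseNetModel,
    x: np.ndarray,
    ordering: np.ndarray,
    k_source,
    k_target=None,
    mode: str = "stability",
    reference: np.ndarray | None = None,
    chunk: int = 64,
) -> AblationResult:
    """Zero features one at a time in the given order until the class flips.

    Zeroing sets a feature to the reference value (0 by default); after
    each zeroing a fresh forward pass decides whether the prediction has
    left ``k_source`` (stability mode) or reached ``k_target``
    (similarity mode).  Returns the number of features zeroed; censored
    when the ordering is exhausted without a flip.
    """
    if mode not in ("stability", "similarity"):
        raise ValueError("mode must be 'stability' or 'similarity'")
    if mode == "similarity" and k_target is None:
        raise ValueError("similarity mode needs k_target")
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if reference is None:
        reference = np.zeros_like(x)
    from srna_augment.classify_dl import predict

    if predict(model, x[None, :])[0] != k_source:
        raise ValueError(f"model does not predict {k_source!r} for this sample")
    ordering = np.asarray(ordering, dtype=int)
    cap = len(ordering)
    # evaluate ablation path in chunks: row s has ordering[:s+1] zeroed,
    # equivalent to a fresh forward pass after each single zeroing
    current = x.copy()
    done = 0
    while done < cap:
        stop = min(done + chunk, cap)
        block = np.repeat(current[None, :], stop - done, axis=0)
        for r, feat in enumerate(ordering[done:stop]):
            block[r:, feat] = reference[feat]
        preds = predict(model, block)
        for r in range(stop - done):
            flipped = (
                preds[r] == k_target if mode == "similarity" else preds[r] != k_source
            )
            if flipped:
                return AblationResult(steps=done + r + 1, censored=False, cap=cap)
        current = block[-1]
        done = stop
    return AblationResult(steps=cap, censored=True, cap=cap)


@dataclass
class StabilityReport:
    """Average flip-step counts per class.

    ``similarity[k, k']`` is the mean number of ablation steps to turn a
    correctly-predicted class-k sample into k'; ``stability[k]`` the
    mean per-sample minimum over rivals of steps to leave k.  Censored
    runs are excluded from the means and counted.
    """

    classes: list
    similarity: np.ndarray
    stability: np.ndarray
    n_samples: dict
    censored_similarity: np.ndarray
    censored_stability: dict
    sample_logs: list = field(default_factory=list)


def stability_similarity_matrices(
    model: DenseNetModel,
    X: np.ndarray,
    y,
    tensor: AttributionTensor,
    max_samples_per_class: int | None = None,
    seed: int = 0,
) -> StabilityReport:
    """Run the ablation-until-flip procedure for every class pair.

    Only correctly-predicted samples enter; the ablation order for the
    (k, k') analysis is the descending-D2 order restricted to features
    with strictly positive D2 (zeroing features that argue against k is
    not motivated by the procedure).  For each sample both stopping
    rules are read off the same ablation path.
    """
    from srna_augment.classify_dl import predict

    y = np.asarray(y)
    classes = list(tensor.classes)
    K = len(classes)
    preds = predict(model, X)
    rng = np.random.default_rng(seed)

    sim_sums = np.zeros((K, K))
    sim_counts = np.zeros((K, K), dtype=int)
    cens_sim = np.zeros((K, K), dtype=int)
    stab_vals: dict = {c: [] for c in classes}
    cens_stab = {c: 0 for c in classes}
    logs = []

    for ki, k in enumerate(classes):
        rows = np.where((y == k) & (preds == k))[0]
        if max_samples_per_class is not None and len(rows) > max_samples_per_class:
            rows = np.sort(rng.choice(rows, size=max_samples_per_class, replace=False))
        for i in rows:
            per_rival_stab = []
            for kpi, kp in enumerate(classes):
                if kp == k:
                    continue
                order, d2 = pairwise_differences(tensor, i, k, kp)
                order = order[d2[order] > 0]
                sim = ablate_until_flip(
                    model, X[i], order, k, k_target=kp, mode="similarity",
                    reference=tensor.reference,
                )
                stab = ablate_until_flip(
                    model, X[i], order, k, mode="stability",
                    reference=tensor.reference,
                )
                if not sim.censored:
                    sim_sums[ki, kpi] += sim.steps
                    sim_counts[ki, kpi] += 1
                else:
                    cens_sim[ki, kpi] += 1
                if not stab.censored:
                    per_rival_stab.append(stab.steps)
                logs.append(
                    {
                        "sample": int(i),
                        "class": k,
                        "rival": kp,
                        "similarity_steps": sim.steps,
                        "similarity_censored": sim.censored,
                        "stability_steps": stab.steps,
                        "stability_censored": stab.censored,
                        "cap": sim.cap,
                    }
                )
            if per_rival_stab:
                stab_vals[k].append(min(per_rival_stab))
            else:
                cens_stab[k] += 1

    similarity = np.full((K, K), np.nan)
    nz = sim_counts > 0
    similarity[nz] = sim_sums[nz] / sim_counts[nz]
    stability = np.array(
        [np.mean(stab_vals[c]) if stab_vals[c] else np.nan for c in classes]
    )
    n_samples = {
        c: int(((y == c) & (preds == c)).sum()) for c in classes
    }
    return StabilityReport(
        classes=classes,
        similarity=similarity,
        stability=stability,
        n_samples=n_samples,
        censored_similarity=cens_sim,
        censored_stability=cens_stab,
        sample_logs=logs,
    )


def per_sample_score_table(tensor: AttributionTensor, i: int) -> pd.DataFrame:
    """C[i, ., .] as a feature x class table."""
    if not 0 <= i < tensor.n_samples:
        raise IndexError(f"sample index {i} out of range")
    index = tensor.feature_ids or [f"f{j}" for j in range(tensor.n_features)]
    return pd.DataFrame(
        tensor.scores[i], index=index, columns=[str(c) for c in tensor.classes]
    )


def write_d1_table(
    D1: np.ndarray, classes, feature_ids: list[str], path: str | Path
) -> None:
    df = pd.DataFrame(D1, index=feature_ids, columns=[str(c) for c in classes])
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.12g")


def write_top_n(top_lists: dict, D1: np.ndarray, classes, feature_ids, path) -> None:
    pos = {f: i for i, f in enumerate(feature_ids)}
    cls_pos = {c: i for i, c in enumerate(classes)}
    rows = []
    for cls, lst in top_lists.items():
        if lst is None:
            continue
        for rank, f in enumerate(lst, start=1):
            rows.append(
                {
                    "class": cls,
                    "rank": rank,
                    "feature_id": f,
                    "d1": D1[pos[f], cls_pos[cls]],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_stability_report(report: StabilityReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cls = [str(c) for c in report.classes]
    pd.DataFrame(report.similarity, index=cls, columns=cls).to_csv(
        outdir / "similarity_matrix.tsv", sep="\t", index_label="class"
    )
    pd.DataFrame(
        {
            "class": cls,
            "stability_steps": report.stability,
            "n_correct_samples": [report.n_samples[c] for c in report.classes],
            "censored": [report.censored_stability[c] for c in report.classes],
        }
    ).to_csv(outdir / "stability.tsv", sep="\t", index=False)
    pd.DataFrame(report.sample_logs).to_csv(
        outdir / "ablation_log.tsv", sep="\t", index=False
    )
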