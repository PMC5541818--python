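"""Cross-stream score fusion, ROC/AUC evaluation, and paired testing.

In multi-RSVP the same image is presented on up to three streams, so each
image collects up to three interest scores; fusion averages them into one
score per image — the multitrial step that raises detection accuracy.
Evaluation is threshold-free (AUC via the Mann-Whitney rank statistic with
mid-ranks for ties) under stratified, image-grouped k-fold cross-validation,
with paired Wilcoxon signed-rank tests for comparing paradigms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .hdca import hdca_features, hdca_fit_features, hdca_score_features
from .preprocess import EpochSet
from .swlda import build_feature_vectors, swlda_fit, swlda_score

__all__ = [
    "fuse_scores",
    "classify_by_threshold",
    "default_threshold",
    "roc_auc",
    "RocResult",
    "kfold_cv",
    "score_epochs_cv",
    "image_fold_assignment",
    "paradigm_aucs_from_scores",
    "evaluate_paradigms",
    "paired_wilcoxon",
]


class EvaluationError(ValueError):
    pass


def fuse_scores(
    per_stream_scores: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Average per-stream interest scores of the same image.

    ``per_stream_scores`` needs columns ``image_id``, ``stream``, ``score``
    and ``label``.  Returns a table indexed by image_id with one column per
    stream, the fused mean over the streams that scored the image, and the
    label.  With ``strict=True`` images not scored on every stream present in
    the input are dropped (e.g. images the gaze model skipped on one stream);
    by default the mean runs over the available streams.
    """
    required = {"image_id", "stream", "score", "label"}
    missing = required - set(per_stream_scores.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = per_stream_scores
    if df["image_id"].isna().any():
        raise EvaluationError("scores with unknown image_id")

    wide = df.pivot_table(
        index="image_id", columns="stream", values="score", aggfunc="mean"
    )
    labels = df.groupby("image_id")["label"].first()
    if wide.isna().all(axis=1).any():
        raise EvaluationError("image with no scores on any stream")
    if strict:
        keep = wide.notna().all(axis=1)
        wide, labels = wide[keep], labels[keep]
    out = wide.copy()
    out["fused_score"] = wide.mean(axis=1, skipna=True)
    out["label"] = labels
    return out


def default_threshold(score_table: pd.DataFrame) -> float:
    """Midpoint between the class medians of the fused training scores."""
    fused, label = score_table["fused_score"], score_table["label"].astype(bool)
    if label.all() or (~label).all():
        raise EvaluationError("both classes needed to place a threshold")
    return 0.5 * (fused[label].median() + fused[~label].median())


def classify_by_threshold(score_table: pd.DataFrame, threshold: float) -> pd.Series:
    """Per-image boolean decision: fused_score > threshold."""
    if not np.isfinite(threshold) and not np.isinf(threshold):
        raise ValueError("threshold must be finite or ±inf")
    return score_table["fused_score"] > threshold


class RocResult:
    """AUC with its ROC curve and optional per-fold values."""

    def __init__(self, auc: float, curve: np.ndarray, fold_aucs=None):
        self.auc = float(auc)
        self.curve = curve  # (points, 2): FPR, TPR
        self.fold_aucs = None if fold_aucs is None else np.asarray(fold_aucs)

    def __repr__(self):
        return f"RocResult(auc={self.auc:.4f}, n_points={len(self.curve)})"


def roc_auc(scores, labels) -> RocResult:
    """Threshold-free detection performance.

    AUC is the Mann-Whitney rank statistic (mid-ranks on ties), identical to
    the trapezoidal area under the threshold-swept ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise EvaluationError("both classes must be present to compute AUC")
    auc = roc_auc_score(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(auc, np.column_stack([fpr, tpr]))


class _MethodDriver:
    """Builds a method's design once; fits/scores on row subsets per fold."""

    def __init__(self, method: str, epochs: EpochSet, **kw):
        self.method = method
        if method == "hdca":
            self.window_s = kw.pop("window_s", 0.025)
            self.fs_hz = epochs.fs_hz
            self.design = hdca_features(epochs, self.window_s)
            self.kw = kw
        elif method == "swlda":
            channels = kw.pop("channels_used", None)
            points = kw.pop("points_per_channel", 60)
            self.design = build_feature_vectors(epochs, points, channels)
            self.kw = kw
        else:
            raise ValueError(f"unknown method {method!r}")
        self.labels = np.asarray(epochs.labels, dtype=bool)

    def fit_score(self, train_idx, test_idx) -> np.ndarray:
        if self.method == "hdca":
            model = hdca_fit_features(
                self.design[train_idx], self.labels[train_idx],
                self.window_s, self.fs_hz, **self.kw,
            )
            return hdca_score_features(model, self.design[test_idx])
        model = swlda_fit(
            self.design[train_idx], self.labels[train_idx], **self.kw
        )
        return swlda_score(model, self.design[test_idx])


def image_fold_assignment(image_ids, labels, k, seed) -> dict:
    """Label-stratified fold per unique image_id (grouping across streams).

    Assigning folds at the image level keeps all stream presentations of one
    image together and lets the same partition be reused when evaluating
    stream subsets (single vs dual vs triple) for paired comparisons.
    """
    image_ids = np.asarray(image_ids)
    labels = np.asarray(labels, dtype=int)
    uniq, first = np.unique(image_ids, return_index=True)
    img_labels = labels[first]
    counts = np.bincount(img_labels, minlength=2)
    if k > counts.min():
        raise EvaluationError(
            f"cannot stratify {k} folds: smallest class has {counts.min()} images"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    for f, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(uniq)), img_labels)
    ):
        for i in test_idx:
            fold_of[uniq[i]] = f
    return fold_of


def _grouped_folds(labels, image_ids, k, seed, grouped=True):
    labels_int = np.asarray(labels, dtype=int)
    n = len(labels_int)
    if grouped:
        fold_of = image_fold_assignment(image_ids, labels_int, k, seed)
        epoch_folds = np.array([fold_of[i] for i in np.asarray(image_ids)])
        return [
            (np.flatnonzero(epoch_folds != f), np.flatnonzero(epoch_folds == f))
            for f in range(k)
        ]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    try:
        return list(splitter.split(np.zeros(n), labels_int))
    except ValueError as exc:
        raise EvaluationError(f"cannot build stratified folds: {exc}")


def score_epochs_cv(
    epochs: EpochSet,
    method: str = "hdca",
    k: int = 10,
    seed: int = 0,
    grouped: bool = True,
    per_stream: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Out-of-fold interest score for every epoch.

    Folds are stratified by label and grouped by image_id, so all stream
    presentations of one image are scored by a model that never saw that
    image.  With ``per_stream`` (default) a separate classifier is fitted
    per stream within each training fold — each stream carries one
    repetition of the target with its own characteristic amplitude and
    latency, so stream-specific models stay latency-homogeneous; with
    ``per_stream=False`` one model per fold is trained on the pooled epochs
    of all streams.  Returns a frame with image_id, stream, label, score,
    fold.
    """
    folds = _grouped_folds(epochs.labels, epochs.image_ids, k, seed, grouped)
    driver = _MethodDriver(method, epochs, **fit_kwargs)
    n = epochs.n_epochs
    score = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    stream_arr = np.asarray(epochs.stream_ids, dtype=object)
    stream_masks = (
        [stream_arr == s for s in dict.fromkeys(stream_arr)]
        if per_stream
        else [np.ones(n, dtype=bool)]
    )
    for f, (tr, te) in enumerate(folds):
        in_tr, in_te = np.zeros(n, bool), np.zeros(n, bool)
        in_tr[tr] = True
        in_te[te] = True
        for mask in stream_masks:
            tr_s = np.flatnonzero(in_tr & mask)
            te_s = np.flatnonzero(in_te & mask)
            if len(te_s):
                score[te_s] = driver.fit_score(tr_s, te_s)
        fold_of[te] = f
    return pd.DataFrame(
        {
            "image_id": epochs.image_ids,
            "stream": epochs.stream_ids,
            "label": epochs.labels,
            "score": score,
            "fold": fold_of,
        }
    )


def kfold_cv(
    epochs: EpochSet,
    method: str = "hdca",
    k: int = 10,
    seed: int = 0,
    grouped: bool = True,
    fuse: bool = True,
    **fit_kwargs,
) -> tuple[np.ndarray, float]:
    """Stratified grouped k-fold cross-validated AUC.

    Per fold: fit on the training epochs, score the held-out epochs, fuse
    per image across streams (when ``fuse``), and compute the fold AUC.
    Returns ``(fold_aucs, mean_auc)``; deterministic given ``seed``.
    """
    scored = score_epochs_cv(epochs, method, k, seed, grouped, **fit_kwargs)
    fold_aucs = []
    for f in sorted(scored["fold"].unique()):
        part = scored[scored["fold"] == f]
        if fuse:
            table = fuse_scores(part)
            fold_aucs.append(roc_auc(table["fused_score"], table["label"]).auc)
        else:
            fold_aucs.append(roc_auc(part["score"], part["label"]).auc)
    fold_aucs = np.array(fold_aucs)
    return fold_aucs, float(fold_aucs.mean())


def paradigm_aucs_from_scores(
    scored: pd.DataFrame,
    subsets: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, dict]:
    """Per-fold fused AUC for nested stream subsets from out-of-fold scores."""
    streams_present = list(dict.fromkeys(scored["stream"]))
    if subsets is None:
        names = ("single", "dual", "triple")
        subsets = {
            names[i]: tuple(streams_present[: i + 1])
            for i in range(len(streams_present))
        }
    results: dict[str, dict] = {}
    for name, streams in subsets.items():
        fold_aucs = []
        for f in sorted(scored["fold"].unique()):
            part = scored[(scored["fold"] == f) & scored["stream"].isin(streams)]
            table = fuse_scores(part)
            fold_aucs.append(roc_auc(table["fused_score"], table["label"]).auc)
        fold_aucs = np.array(fold_aucs)
        results[name] = {
            "streams": list(streams),
            "fold_aucs": fold_aucs,
            "mean_auc": float(fold_aucs.mean()),
        }
    return results


def evaluate_paradigms(
    epochs: EpochSet,
    method: str = "hdca",
    k: int = 10,
    seed: int = 0,
    subsets: dict[str, tuple[str, ...]] | None = None,
    per_stream: bool = True,
    **fit_kwargs,
) -> dict[str, dict]:
    """Cross-validated AUC for nested stream subsets on one recording.

    Interest scores are computed once per epoch (out-of-fold, per-stream
    classifiers by default; see `score_epochs_cv`), then fused over each
    requested subset — e.g. single (left), dual (left+right) and triple
    (all streams) — so subset AUCs are paired per fold and differ only in
    which streams enter the fusion, mirroring how multi-RSVP performance is
    compared against the standard single-stream paradigm.
    """
    scored = score_epochs_cv(
        epochs, method, k, seed, per_stream=per_stream, **fit_kwargs
    )
    return paradigm_aucs_from_scores(scored, subsets)


def paired_wilcoxon(auc_a, auc_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired AUCs.

    Uses the exact null distribution for n <= 25 after dropping zero
    differences.  Returns ``(p_value, statistic)``.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    diff = a - b
    nz = diff[diff != 0]
    if len(nz) == 0:
        raise EvaluationError("all paired differences are zero")
    if len(a) < 5:
        raise ValueError("need n >= 5 pairs")
    method = "exact" if len(nz) <= 25 else "auto"
    res = stats.wilcoxon(nz, zero_method="wilcox", method=method)
    return float(res.pvalue), float(res.statistic)
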