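"""Hierarchical discriminant component analysis (HDCA) for single-trial P300.

The epoch is split into K contiguous time windows of T seconds (N = T·Fs
samples each).  Stage one learns, per window k, a spatial weight vector
w_k over the electrodes by Fisher's linear discriminant on the window-mean
features, producing one score per window,

    y_k = (1/N) Σ_n Σ_i  w_ki · x_i[(k-1)N + n] ,

i.e. the spatially filtered, time-averaged activity in window k.  Stage two
learns temporal weights v_k by logistic regression on the window scores and
emits a single interest score per epoch, y_IS = Σ_k v_k y_k.  Defaults are
T = 25 ms on 1000 ms epochs at 600 Hz, hence K = 40 and N = 15.

The within-class covariance of the FLD is Ledoit-Wolf shrinkage-regularised:
with only N samples averaged per window and ~16 channels, the pooled sample
covariance can be ill-conditioned.  Window scores are z-scored with training
statistics before the logistic stage; v_k lives in that standardised space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.linear_model import LogisticRegression

from .preprocess import EpochSet

__all__ = [
    "HdcaModel",
    "hdca_fit",
    "hdca_window_scores",
    "hdca_score",
    "hdca_features",
    "hdca_fit_features",
    "hdca_score_features",
]

#: fixed inverse ridge strength for the logistic temporal stage; mild and
#: deterministic, guards against separable training sets
_LOGREG_C = 1.0


class HdcaFitError(ValueError):
    pass


@dataclass
class HdcaModel:
    """Fitted HDCA parameters."""

    window_s: float
    samples_per_window: int  # N
    n_windows: int  # K
    fs_hz: float
    spatial_weights: np.ndarray  # K x channels, rows w_k
    temporal_weights: np.ndarray  # length K, v_k
    score_means: np.ndarray | None = None  # train-set window-score means
    score_stds: np.ndarray | None = None  # train-set window-score stds
    intercept: float = 0.0
    fitted: bool = True

    @property
    def n_channels(self) -> int:
        return self.spatial_weights.shape[1]

    # -- JSON (de)serialisation -------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return None if a is None else {
                "shape": list(a.shape), "data": np.asarray(a).ravel().tolist()
            }

        return json.dumps(
            {
                "model": "hdca",
                "window_s": self.window_s,
                "samples_per_window": self.samples_per_window,
                "n_windows": self.n_windows,
                "fs_hz": self.fs_hz,
                "spatial_weights": arr(self.spatial_weights),
                "temporal_weights": arr(self.temporal_weights),
                "score_means": arr(self.score_means),
                "score_stds": arr(self.score_stds),
                "intercept": self.intercept,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HdcaModel":
        d = json.loads(text)
        if d.get("model") != "hdca":
            raise ValueError("not an HDCA model file")

        def arr(v):
            return None if v is None else np.array(v["data"]).reshape(v["shape"])

        return cls(
            window_s=d["window_s"],
            samples_per_window=d["samples_per_window"],
            n_windows=d["n_windows"],
            fs_hz=d["fs_hz"],
            spatial_weights=arr(d["spatial_weights"]),
            temporal_weights=arr(d["temporal_weights"]),
            score_means=arr(d["score_means"]),
            score_stds=arr(d["score_stds"]),
            intercept=d["intercept"],
        )


def _window_layout(n_samples: int, window_s: float, fs_hz: float) -> tuple[int, int]:
    """Return (K, N); raises when the window itself is not sample-aligned,
    warns and drops a trailing partial window otherwise."""
    n_exact = window_s * fs_hz
    n = int(round(n_exact))
    if n < 1 or abs(n_exact - n) > 1e-6:
        raise HdcaFitError(
            f"window of {window_s * 1000:g} ms is {n_exact:g} samples at "
            f"{fs_hz:g} Hz; need a whole number of samples per window"
        )
    k = n_samples // n
    if k < 1:
        raise HdcaFitError(
            f"epoch of {n_samples} samples is shorter than one window (N={n})"
        )
    if k * n != n_samples:
        warnings.warn(
            f"epoch length {n_samples} not divisible by window N={n}; "
            f"dropping the trailing {n_samples - k * n} samples (K={k})",
            stacklevel=3,
        )
    return k, n


def _window_means(data: np.ndarray, k: int, n: int) -> np.ndarray:
    """(epochs, channels, samples) -> (epochs, K, channels) window means."""
    e, c, _ = data.shape
    return (
        data[:, :, : k * n]
        .reshape(e, c, k, n)
        .mean(axis=3, dtype=np.float64)
        .transpose(0, 2, 1)
    )


def hdca_features(epochs: EpochSet, window_s: float = 0.025) -> np.ndarray:
    """Stage-zero design: per-window per-channel time averages (E, K, C).

    Computing this once and slicing rows is equivalent to fitting/scoring on
    epoch subsets, and is what the cross-validation drivers do.
    """
    k, n = _window_layout(epochs.n_samples, window_s, epochs.fs_hz)
    return _window_means(epochs.data, k, n)


def hdca_fit_features(
    feats: np.ndarray,
    labels,
    window_s: float,
    fs_hz: float,
    shrinkage: str = "ledoit-wolf",
) -> HdcaModel:
    """Fit HDCA from a precomputed window-mean design (see `hdca_features`)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all() or len(labels) < 4:
        raise HdcaFitError(
            "need at least two epochs of each class to fit the discriminant"
        )
    k, c = feats.shape[1], feats.shape[2]
    n = int(round(window_s * fs_hz))

    spatial = np.empty((k, c))
    tgt, non = feats[labels], feats[~labels]
    for w in range(k):
        mu_t, mu_n = tgt[:, w].mean(axis=0), non[:, w].mean(axis=0)
        centred = np.vstack([tgt[:, w] - mu_t, non[:, w] - mu_n])
        if shrinkage == "ledoit-wolf":
            cov, _ = ledoit_wolf(centred, assume_centered=True)
            wk = np.linalg.solve(cov, mu_t - mu_n)
        elif shrinkage == "none":
            cov = centred.T @ centred / len(centred)
            wk = np.linalg.pinv(cov) @ (mu_t - mu_n)
        else:
            raise ValueError(f"unknown shrinkage {shrinkage!r}")
        if not np.all(np.isfinite(wk)):
            raise HdcaFitError(f"non-finite spatial weights in window {w}")
        # orientation: target window-scores above nontarget (holds for the
        # FLD solution; enforced for robustness under degenerate covariances)
        if (mu_t - mu_n) @ wk < 0:
            wk = -wk
        spatial[w] = wk

    scores = np.einsum("ekc,kc->ek", feats, spatial)  # y_k per epoch
    means = scores.mean(axis=0)
    stds = scores.std(axis=0)
    stds[stds == 0] = 1.0
    z = (scores - means) / stds

    clf = LogisticRegression(C=_LOGREG_C, solver="lbfgs", max_iter=1000)
    clf.fit(z, labels.astype(int))

    return HdcaModel(
        window_s=window_s,
        samples_per_window=n,
        n_windows=k,
        fs_hz=fs_hz,
        spatial_weights=spatial,
        temporal_weights=clf.coef_[0].copy(),
        score_means=means,
        score_stds=stds,
        intercept=float(clf.intercept_[0]),
    )


def hdca_fit(
    epochs: EpochSet,
    window_s: float = 0.025,
    shrinkage: str = "ledoit-wolf",
) -> HdcaModel:
    """Fit spatial FLD filters per window and logistic temporal weights.

    ``shrinkage='ledoit-wolf'`` (default) regularises the pooled within-class
    covariance automatically; ``'none'`` uses the raw pooled covariance with a
    pseudo-inverse.  Deterministic given its inputs.
    """
    feats = hdca_features(epochs, window_s)
    return hdca_fit_features(
        feats, epochs.labels, window_s, epochs.fs_hz, shrinkage
    )


def hdca_score_features(model: HdcaModel, feats: np.ndarray) -> np.ndarray:
    """Interest scores from a precomputed window-mean design."""
    y = np.einsum("ekc,kc->ek", feats, model.spatial_weights)
    if model.score_means is not None:
        y = (y - model.score_means) / model.score_stds
    return y @ model.temporal_weights


def hdca_window_scores(model: HdcaModel, epochs: EpochSet) -> np.ndarray:
    """Per-epoch window scores y_k (epochs x K), the stage-one output."""
    if not model.fitted:
        raise HdcaFitError("model is not fitted")
    if epochs.n_channels != model.n_channels:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels, model expects "
            f"{model.n_channels}"
        )
    k, n = model.n_windows, model.samples_per_window
    if epochs.n_samples < k * n:
        raise ValueError(
            f"epochs have {epochs.n_samples} samples, model needs >= {k * n}"
        )
    feats = _window_means(epochs.data, k, n)
    return np.einsum("ekc,kc->ek", feats, model.spatial_weights)


def hdca_score(model: HdcaModel, epochs: EpochSet) -> np.ndarray:
    """Final interest score per epoch: y_IS = Σ_k v_k y_k.

    Window scores are standardised with the training statistics when the
    model carries them (the space in which v_k was learned); the intercept is
    omitted as it shifts every score equally.
    """
    y = hdca_window_scores(model, epochs)
    if model.score_means is not None:
        y = (y - model.score_means) / model.score_stds
    return y @ model.temporal_weights
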