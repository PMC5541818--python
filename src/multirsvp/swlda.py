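"""Stepwise linear discriminant analysis (SWLDA) for P300 detection.

Each epoch is reduced to a fixed-length feature vector: every channel is
decimated to ``points_per_channel`` values (non-overlapping block means by
default) and the channels are concatenated — with 14 channels and 60 points
per channel this is the classic 840-point P300 feature vector.  Class labels
are then regressed on a stepwise-selected subset of features by ordinary
least squares: forward entry adds the most significant candidate while its
partial-F p-value is below ``p_enter``; after every entry a backward sweep
removes any retained feature whose p-value has risen above ``p_remove``;
the process stops when the selection no longer changes or ``max_features``
is reached.  The conventional thresholds p_enter = 0.10, p_remove = 0.15 and
a 60-feature cap follow long-standing P300-speller practice; the source
experiments state no values.

Ties in p-values break toward the lowest feature index, making fits
bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet

__all__ = ["SwldaModel", "build_feature_vectors", "swlda_fit", "swlda_score",
           "default_channel_subset"]

_VAR_EPS = 1e-12


class SwldaFitError(ValueError):
    pass


@dataclass
class SwldaModel:
    """Stepwise-selected linear discriminant."""

    selected_features: list[int]
    weights: np.ndarray  # coefficient per selected feature
    intercept: float
    p_enter: float
    p_remove: float
    max_features: int
    n_features_total: int
    fitted: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "swlda",
                "selected_features": list(map(int, self.selected_features)),
                "weights": np.asarray(self.weights).tolist(),
                "intercept": self.intercept,
                "p_enter": self.p_enter,
                "p_remove": self.p_remove,
                "max_features": self.max_features,
                "n_features_total": self.n_features_total,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SwldaModel":
        d = json.loads(text)
        if d.get("model") != "swlda":
            raise ValueError("not an SWLDA model file")
        return cls(
            selected_features=d["selected_features"],
            weights=np.array(d["weights"], dtype=float),
            intercept=d["intercept"],
            p_enter=d["p_enter"],
            p_remove=d["p_remove"],
            max_features=d["max_features"],
            n_features_total=d["n_features_total"],
        )


def default_channel_subset(channel_labels: tuple[str, ...]) -> list[int]:
    """Default 14-of-16 channel subset: drop the frontopolar pair.

    Fp1/Fp2 sit closest to the eyes and carry the most ocular contamination,
    making them the natural pair to exclude when 14 of 16 recorded channels
    feed the feature vector; the subset is configurable throughout.
    """
    drop = {"Fp1", "Fp2"}
    keep = [i for i, c in enumerate(channel_labels) if c not in drop]
    if len(keep) == len(channel_labels):  # montage without frontopolar leads
        return list(range(len(channel_labels)))
    return keep


def build_feature_vectors(
    epochs: EpochSet,
    points_per_channel: int = 60,
    channels_used: list[int] | None = None,
    method: str = "block_mean",
) -> np.ndarray:
    """Decimate each channel and concatenate into one vector per epoch.

    ``block_mean`` (default) averages non-overlapping sample blocks;
    ``subsample`` keeps every (samples/points)-th sample instead.
    """
    if channels_used is None:
        if epochs.channel_labels:
            channels_used = default_channel_subset(epochs.channel_labels)
        else:
            channels_used = list(range(epochs.n_channels))
    data = epochs.data[:, channels_used, :]
    e, c, s = data.shape
    if s % points_per_channel != 0:
        raise ValueError(
            f"epoch length {s} not divisible by points_per_channel="
            f"{points_per_channel}"
        )
    block = s // points_per_channel
    if method == "block_mean":
        dec = data.reshape(e, c, points_per_channel, block).mean(
            axis=3, dtype=np.float64
        )
    elif method == "subsample":
        dec = data[:, :, ::block].astype(np.float64)
    else:
        raise ValueError(f"unknown decimation method {method!r}")
    return dec.reshape(e, c * points_per_channel)


def _ols_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS of y on [1, x]; returns (two-sided p per column of x, intercept,
    coefficients)."""
    n, k = x.shape
    design = np.column_stack([np.ones(n), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - (k + 1)
    if dof <= 0:
        return np.zeros(k), float(coef[0]), coef[1:]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv)[1:], _VAR_EPS * 1e-6))
    t = coef[1:] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return p, float(coef[0]), coef[1:]


def swlda_fit(
    features: np.ndarray,
    labels: np.ndarray,
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    max_features: int = 60,
) -> SwldaModel:
    """Forward-entry / backward-removal stepwise least-squares discriminant.

    Entry significance uses the partial F statistic of each candidate given
    the current selection; removal uses the coefficient t-tests of the
    current OLS fit.  Zero-variance columns are skipped with a warning.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("features must be (epochs, n_features) matching labels")
    if not np.all(np.isfinite(x)):
        raise SwldaFitError("features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise SwldaFitError("both classes must be present")
    n, m = x.shape

    col_var = x.var(axis=0)
    usable = col_var > _VAR_EPS
    if not usable.any():
        raise SwldaFitError("all feature columns have zero variance")
    if not usable.all():
        warnings.warn(
            f"skipping {int((~usable).sum())} zero-variance feature columns",
            stacklevel=2,
        )

    selected: list[int] = []
    yc = y - y.mean()
    # orthonormal basis of the current design (intercept first)
    q = np.ones((n, 1)) / np.sqrt(n)
    resid_y = y - q @ (q.T @ y)
    resid_x = x - q @ (q.T @ x)

    for _ in range(4 * max_features + 4):
        changed = False

        # ---- forward entry ------------------------------------------------
        if len(selected) < max_features:
            rss = resid_y @ resid_y
            denom_dof = n - len(selected) - 2  # after adding the candidate
            if denom_dof > 0 and rss > _VAR_EPS:
                xr2 = np.einsum("ij,ij->j", resid_x, resid_x)
                xy = resid_x.T @ resid_y
                cand = usable & (xr2 > _VAR_EPS * np.maximum(col_var, 1.0))
                cand[selected] = False
                if cand.any():
                    red = np.zeros(m)
                    red[cand] = xy[cand] ** 2 / xr2[cand]
                    rss_new = np.maximum(rss - red, 0.0)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        f_stat = np.where(
                            cand, red / np.maximum(rss_new / denom_dof, _VAR_EPS), 0.0
                        )
                    pvals = np.where(cand, stats.f.sf(f_stat, 1, denom_dof), np.inf)
                    j = int(np.argmin(pvals))  # argmin takes the lowest index on ties
                    if pvals[j] < p_enter:
                        selected.append(j)
                        # extend the orthonormal basis with the new column
                        v = resid_x[:, j].copy()
                        v /= np.linalg.norm(v)
                        q = np.column_stack([q, v])
                        resid_y = resid_y - v * (v @ resid_y)
                        resid_x = resid_x - np.outer(v, v @ resid_x)
                        changed = True

        # ---- backward removal --------------------------------------------
        while len(selected) > 1:
            p_sel, _, _ = _ols_pvalues(x[:, selected], y)
            worst = int(np.argmax(p_sel))
            if p_sel[worst] <= p_remove:
                break
            del selected[worst]
            changed = True
            # rebuild the residual basis from scratch (selection shrank)
            q = np.ones((n, 1)) / np.sqrt(n)
            for jj in selected:
                v = x[:, jj] - q @ (q.T @ x[:, jj])
                v /= np.linalg.norm(v)
                q = np.column_stack([q, v])
            resid_y = y - q @ (q.T @ y)
            resid_x = x - q @ (q.T @ x)

        if not changed:
            break

    if selected:
        _, intercept, coefs = _ols_pvalues(x[:, selected], y)
    else:
        intercept, coefs = float(y.mean()), np.empty(0)
    return SwldaModel(
        selected_features=selected,
        weights=np.asarray(coefs, dtype=float),
        intercept=intercept,
        p_enter=p_enter,
        p_remove=p_remove,
        max_features=max_features,
        n_features_total=m,
    )


def swlda_score(model: SwldaModel, features: np.ndarray) -> np.ndarray:
    """Linear interest score per epoch from the selected features."""
    if not model.fitted:
        raise SwldaFitError("model is not fitted")
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.n_features_total:
        raise ValueError(
            f"features have {x.shape[-1]} columns, model expects "
            f"{model.n_features_total}"
        )
    if not model.selected_features:
        return np.full(x.shape[0], model.intercept)
    return x[:, model.selected_features] @ model.weights + model.intercept
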