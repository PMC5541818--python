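import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from multirsvp.fusion import (
    EvaluationError,
    classify_by_threshold,
    default_threshold,
    fuse_scores,
    image_fold_assignment,
    kfold_cv,
    paired_wilcoxon,
    roc_auc,
    score_epochs_cv,
)


def pairwise_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mu = w_all.mean()
    p = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    return p


def score_frame(scores_by_stream, labels):
    rows = []
    for stream, scores in scores_by_stream.items():
        for i, sc in enumerate(scores):
            rows.append(
                {"image_id": i, "stream": stream, "score": sc,
                 "label": bool(labels[i])}
            )
    return pd.DataFrame(rows)


class TestFuseScores:
    def test_two_stream_mean(self):
        df = score_frame({"left": [0.4], "right": [0.8]}, [1])
        out = fuse_scores(df)
        assert out.loc[0, "fused_score"] == pytest.approx(0.6)

    def test_idempotent_on_identical_scores(self):
        df = score_frame(
            {"left": [0.3, 0.9], "right": [0.3, 0.9], "bottom": [0.3, 0.9]},
            [0, 1],
        )
        out = fuse_scores(df)
        np.testing.assert_allclose(out["fused_score"], [0.3, 0.9])

    def test_missing_stream_uses_available(self):
        df = score_frame({"left": [0.2, 0.4], "right": [0.6, 0.8]}, [0, 1])
        df = df.drop(df[(df.image_id == 1) & (df.stream == "right")].index)
        out = fuse_scores(df)
        assert out.loc[0, "fused_score"] == pytest.approx(0.4)
        assert out.loc[1, "fused_score"] == pytest.approx(0.4)
        strict = fuse_scores(df, strict=True)
        assert list(strict.index) == [0]

    def test_fusion_reduces_score_noise(self):
        # truth + independent unit noise per stream: the fused AUC should
        # beat each single stream in nearly every replicate
        wins = 0
        n = 2000
        for seed in range(100):
            rng = np.random.default_rng(seed)
            labels = np.zeros(n, bool)
            labels[:200] = True
            truth = np.where(labels, 1.5, 0.0)
            singles, scores = [], {}
            for s in ("left", "right", "bottom"):
                scores[s] = truth + rng.standard_normal(n)
                singles.append(pairwise_auc_fast(scores[s], labels))
            fused = np.mean([scores[s] for s in scores], axis=0)
            if pairwise_auc_fast(fused, labels) >= max(singles):
                wins += 1
        assert wins >= 95

    def test_unknown_image_raises(self):
        df = score_frame({"left": [0.1]}, [0])
        df.loc[0, "image_id"] = np.nan
        with pytest.raises(EvaluationError):
            fuse_scores(df)


def pairwise_auc_fast(scores, labels):
    from sklearn.metrics import roc_auc_score

    return roc_auc_score(labels, scores)


class TestThreshold:
    def test_extreme_thresholds(self):
        df = score_frame({"left": [0.1, 0.9]}, [0, 1])
        table = fuse_scores(df)
        assert classify_by_threshold(table, -np.inf).all()
        assert not classify_by_threshold(table, np.inf).any()

    def test_threshold_sweep_reproduces_roc(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.random(50) > 0.6
        res = roc_auc(scores, labels)
        df = score_frame({"left": scores}, labels)
        table = fuse_scores(df)
        n_pos, n_neg = labels.sum(), (~labels).sum()
        points = {(0.0, 0.0), (1.0, 1.0)}
        for thr in scores:
            dec = classify_by_threshold(table, thr).to_numpy()
            lab = table["label"].to_numpy().astype(bool)
            tpr = (dec & lab).sum() / n_pos
            fpr = (dec & ~lab).sum() / n_neg
            points.add((round(fpr, 12), round(tpr, 12)))
        curve = {(round(f, 12), round(t, 12)) for f, t in res.curve}
        assert curve <= points

    def test_default_threshold_between_class_medians(self):
        df = score_frame({"left": [0.0, 0.2, 1.0, 1.4]}, [0, 0, 1, 1])
        table = fuse_scores(df)
        assert default_threshold(table) == pytest.approx((0.1 + 1.2) / 2)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert res.auc == 1.0

    def test_worked_example(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_null_scores_near_half(self, rng):
        scores = rng.standard_normal(5000)
        labels = rng.random(5000) > 0.9
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.05

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, size=40).astype(float)  # many ties
            labels = rng.random(40) > 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pairwise_auc(scores, labels)
            )

    def test_curve_monotone_from_origin_to_corner(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.random(200) > 0.7
        curve = roc_auc(scores, labels).curve
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            roc_auc([1.0, 2.0], [1, 1])


class TestKfold:
    def make_multi_stream_epochs(self, rng, n_images=40, streams=("left", "right")):
        labels_img = np.zeros(n_images, bool)
        labels_img[: n_images // 5] = True
        data, labels, ids, strs = [], [], [], []
        for s in streams:
            for i in range(n_images):
                x = rng.standard_normal((2, 40))
                if labels_img[i]:
                    x[0] += 1.5
                data.append(x)
                labels.append(labels_img[i])
                ids.append(i)
                strs.append(s)
        ep = make_epochs(np.array(data), 600.0, labels=labels, streams=strs)
        ep.image_ids = np.array(ids)
        return ep

    def test_groups_respected(self, rng):
        ep = self.make_multi_stream_epochs(rng, n_images=20)
        scored = score_epochs_cv(ep, "hdca", k=2, seed=0,
                                 window_s=10 / 600.0)
        per_image_folds = scored.groupby("image_id")["fold"].nunique()
        assert (per_image_folds == 1).all()

    def test_same_seed_same_folds(self, rng):
        ep = self.make_multi_stream_epochs(rng)
        a = image_fold_assignment(ep.image_ids, ep.labels, 4, seed=9)
        b = image_fold_assignment(ep.image_ids, ep.labels, 4, seed=9)
        assert a == b

    def test_infeasible_stratification_raises(self, rng):
        ep = self.make_multi_stream_epochs(rng, n_images=10)
        with pytest.raises(EvaluationError):
            image_fold_assignment(ep.image_ids, ep.labels, 8, seed=0)

    def test_cv_detects_planted_signal(self, rng):
        ep = self.make_multi_stream_epochs(rng, n_images=60)
        fold_aucs, mean_auc = kfold_cv(ep, "hdca", k=4, seed=1,
                                       window_s=10 / 600.0)
        assert len(fold_aucs) == 4
        assert mean_auc > 0.8


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        a = np.arange(8.0)
        with pytest.raises(EvaluationError):
            paired_wilcoxon(a, a)

    def test_all_positive_n8_exact_p(self):
        a = np.arange(8.0) + 1.0
        p, w = paired_wilcoxon(a, a - 1.0)
        assert p == pytest.approx(0.0078125)
        assert p == pytest.approx(exact_wilcoxon_p(np.ones(8)))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.standard_normal(9)
            p, _ = paired_wilcoxon(d + 0.3, np.zeros(9) + 0.0)
            assert p == pytest.approx(exact_wilcoxon_p(d + 0.3), abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(10)
        b = a + rng.standard_normal(10) * 0.5
        p_ab, _ = paired_wilcoxon(a, b)
        p_ba, _ = paired_wilcoxon(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [0.0, 1.0])
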