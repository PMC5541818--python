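import numpy as np
import pytest
from scipy import stats

from conftest import make_epochs
from multirsvp.fusion import roc_auc
from multirsvp.swlda import (
    SwldaFitError,
    SwldaModel,
    build_feature_vectors,
    default_channel_subset,
    swlda_fit,
    swlda_score,
)
from multirsvp.synth import CHANNELS_16


def naive_stepwise(x, y, p_enter=0.10, p_remove=0.15, max_features=60):
    """Reference stepwise selection by brute-force OLS refits.

    At each forward step every candidate is evaluated by refitting the full
    OLS with intercept and reading the candidate's t-test p-value (equivalent
    to the partial F test); backward removal re-checks every retained
    feature the same way.  Entirely independent of the fast implementation.
    """
    def pvals(cols):
        design = np.column_stack([np.ones(len(y)), x[:, cols]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = len(y) - design.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.pinv(design.T @ design)
        t = coef[1:] / np.sqrt(np.diag(cov)[1:])
        return 2 * stats.t.sf(np.abs(t), dof)

    selected = []
    while True:
        changed = False
        if len(selected) < max_features:
            best_p, best_j = np.inf, None
            for j in range(x.shape[1]):
                if j in selected or x[:, j].var() < 1e-12:
                    continue
                p = pvals(selected + [j])[-1]
                if p < best_p - 1e-15:
                    best_p, best_j = p, j
            if best_j is not None and best_p < p_enter:
                selected.append(best_j)
                changed = True
        while len(selected) > 1:
            p = pvals(selected)
            worst = int(np.argmax(p))
            if p[worst] <= p_remove:
                break
            del selected[worst]
            changed = True
        if not changed:
            return selected


class TestFeatureVectors:
    def test_840_point_vector(self, rng):
        data = rng.standard_normal((5, 16, 600)).astype(np.float32)
        ep = make_epochs(data, 600.0, channel_labels=CHANNELS_16)
        feats = build_feature_vectors(ep)  # default: 14 channels x 60 points
        assert feats.shape == (5, 840)

    def test_default_subset_drops_frontopolar(self):
        keep = default_channel_subset(CHANNELS_16)
        assert len(keep) == 14
        kept_names = [CHANNELS_16[i] for i in keep]
        assert "Fp1" not in kept_names and "Fp2" not in kept_names

    def test_constant_epoch_constant_features(self):
        ep = make_epochs(np.full((2, 3, 60), 2.5), 600.0)
        feats = build_feature_vectors(ep, points_per_channel=10)
        np.testing.assert_allclose(feats, 2.5)

    def test_hand_block_means(self):
        ep = make_epochs(np.array([[[1.0, 2.0, 3.0, 4.0]]]), 600.0)
        feats = build_feature_vectors(ep, points_per_channel=2)
        np.testing.assert_allclose(feats, [[1.5, 3.5]])

    def test_subsample_mode(self):
        ep = make_epochs(np.array([[[1.0, 2.0, 3.0, 4.0]]]), 600.0)
        feats = build_feature_vectors(ep, points_per_channel=2, method="subsample")
        np.testing.assert_allclose(feats, [[1.0, 3.0]])

    def test_non_divisible_raises(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 50)), 600.0)
        with pytest.raises(ValueError, match="divisible"):
            build_feature_vectors(ep, points_per_channel=7)


class TestStepwiseFit:
    def test_perfect_predictor_selected_first(self, rng):
        n = 60
        labels = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 100))
        x[:, 37] = labels
        model = swlda_fit(x, labels)
        assert model.selected_features[0] == 37

    def test_matches_naive_oracle_on_small_instances(self, rng):
        for trial in range(20):
            n, m = 30, 6
            x = rng.standard_normal((n, m))
            beta = np.zeros(m)
            beta[: trial % 3 + 1] = 1.0
            y = (x @ beta + rng.standard_normal(n) > 0).astype(float)
            if y.min() == y.max():
                continue
            model = swlda_fit(x, y, max_features=4)
            ref = naive_stepwise(x, y, max_features=4)
            assert model.selected_features == ref

    def test_null_false_entry_rate(self, rng):
        # with labels independent of all features, selection is rare and
        # driven by the nominal entry threshold; the chance that at least
        # one of m independent candidates clears p_enter is ~1-(1-p)^m
        n, m, runs = 50, 15, 200
        counts, any_sel = [], 0
        for _ in range(runs):
            x = rng.standard_normal((n, m))
            y = (rng.random(n) > 0.5).astype(float)
            if y.min() == y.max():
                continue
            model = swlda_fit(x, y)
            counts.append(len(model.selected_features))
            any_sel += bool(model.selected_features)
        frac = any_sel / len(counts)
        expected = 1 - (1 - 0.10) ** m  # ≈ 0.79 under independence
        assert abs(frac - expected) < 0.15
        assert np.mean(counts) < 4.0

    def test_max_features_respected(self, rng):
        n = 200
        y = (np.arange(n) % 2).astype(float)
        x = y[:, None] * 2.0 + rng.standard_normal((n, 30))
        model = swlda_fit(x, y, max_features=5)
        assert len(model.selected_features) <= 5

    def test_retained_features_significant(self, rng):
        n = 150
        y = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 20))
        x[:, 3] += y
        x[:, 8] += 0.5 * y
        model = swlda_fit(x, y)
        design = np.column_stack([np.ones(n), x[:, model.selected_features]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = n - design.shape[1]
        cov = (resid @ resid / dof) * np.linalg.pinv(design.T @ design)
        t = coef[1:] / np.sqrt(np.diag(cov)[1:])
        p = 2 * stats.t.sf(np.abs(t), dof)
        assert (p <= 0.15 + 1e-12).all()

    def test_deterministic_bit_for_bit(self, rng):
        n = 80
        y = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 40))
        x[:, 5] += y
        a = swlda_fit(x.copy(), y.copy())
        b = swlda_fit(x.copy(), y.copy())
        assert a.selected_features == b.selected_features
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_single_class_raises(self, rng):
        with pytest.raises(SwldaFitError):
            swlda_fit(rng.standard_normal((10, 3)), np.zeros(10))

    def test_zero_variance_columns_skipped(self, rng):
        n = 60
        y = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 5))
        x[:, 2] = 3.0  # constant column
        x[:, 0] += 2 * y
        with pytest.warns(UserWarning, match="zero-variance"):
            model = swlda_fit(x, y)
        assert 2 not in model.selected_features

    def test_all_zero_variance_raises(self):
        with pytest.raises(SwldaFitError):
            swlda_fit(np.ones((10, 3)), (np.arange(10) % 2).astype(float))


class TestScoring:
    def test_empty_selection_constant_score(self):
        model = SwldaModel(
            selected_features=[], weights=np.empty(0), intercept=0.4,
            p_enter=0.1, p_remove=0.15, max_features=60, n_features_total=8,
        )
        np.testing.assert_allclose(
            swlda_score(model, np.zeros((5, 8))), 0.4
        )

    def test_single_feature_identity(self, rng):
        model = SwldaModel(
            selected_features=[2], weights=np.array([1.0]), intercept=0.0,
            p_enter=0.1, p_remove=0.15, max_features=60, n_features_total=4,
        )
        x = rng.standard_normal((10, 4))
        np.testing.assert_allclose(swlda_score(model, x), x[:, 2])

    def test_auc_invariant_to_affine_weight_transform(self, rng):
        n = 100
        y = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 10))
        x[:, 1] += y
        model = swlda_fit(x, y)
        base = roc_auc(swlda_score(model, x), y.astype(bool)).auc
        scaled = SwldaModel(
            selected_features=model.selected_features,
            weights=3.0 * model.weights,
            intercept=3.0 * model.intercept - 7.0,
            p_enter=model.p_enter, p_remove=model.p_remove,
            max_features=model.max_features,
            n_features_total=model.n_features_total,
        )
        assert roc_auc(swlda_score(scaled, x), y.astype(bool)).auc == base

    def test_length_mismatch_raises(self, rng):
        model = SwldaModel(
            selected_features=[0], weights=np.array([1.0]), intercept=0.0,
            p_enter=0.1, p_remove=0.15, max_features=60, n_features_total=4,
        )
        with pytest.raises(ValueError):
            swlda_score(model, rng.standard_normal((5, 3)))

    def test_json_round_trip(self, rng):
        n = 80
        y = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((n, 12))
        x[:, 4] += y
        model = swlda_fit(x, y)
        back = SwldaModel.from_json(model.to_json())
        np.testing.assert_allclose(swlda_score(back, x), swlda_score(model, x))
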