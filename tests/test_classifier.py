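"""Feature engineering, autoencoder, random forest, and CV machinery."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from chromascan import (
    DMap,
    cross_validate,
    extract_features,
    fit_autoencoder,
    optimal_cutpoint,
    preprocess_nucleus,
    train_rf,
)
from chromascan.synthetic import disk_phantom
from helpers import make_feature_cohort as _feature_cohort


def _dmap(values):
    values = np.asarray(values, float)
    return DMap(values=values, mask=np.isfinite(values),
                out_of_range_flags=np.zeros_like(values, bool))


class TestPreprocess:
    def test_output_range_spans_unit_interval(self):
        mask = disk_phantom((30, 30), [(15, 15)], radius=10)
        rng = np.random.default_rng(0)
        values = np.where(mask > 0, rng.uniform(2.2, 2.8, (30, 30)), np.nan)
        img = preprocess_nucleus(_dmap(values), mask, 1, out_side=32)
        assert img.shape == (32, 32)
        assert img.min() == pytest.approx(0.0)
        assert img.max() == pytest.approx(1.0, abs=1e-9)

    def test_constant_nucleus_maps_to_half(self):
        mask = disk_phantom((20, 20), [(10, 10)], radius=6)
        values = np.where(mask > 0, 2.5, np.nan)
        img = preprocess_nucleus(_dmap(values), mask, 1, out_side=16)
        in_body = img > 0
        assert np.allclose(img[in_body], 0.5)

    def test_deterministic(self):
        mask = disk_phantom((20, 20), [(10, 10)], radius=6)
        rng = np.random.default_rng(1)
        values = np.where(mask > 0, rng.uniform(2.3, 2.7, (20, 20)), np.nan)
        a = preprocess_nucleus(_dmap(values), mask, 1, out_side=24)
        b = preprocess_nucleus(_dmap(values), mask, 1, out_side=24)
        assert np.array_equal(a, b)

    def test_empty_label_rejected(self):
        mask = np.zeros((5, 5), int)
        with pytest.raises(ValueError):
            preprocess_nucleus(_dmap(np.full((5, 5), 2.5)), mask, 3)


class TestTextureBank:
    def test_constant_image_zero_variance_features(self):
        fm = extract_features([np.full((16, 16), 0.5)])
        named = dict(zip(fm.feature_names, fm.values[0]))
        assert named["sd"] == 0.0
        assert named["gradient_energy"] == 0.0
        assert all(named[f"glcm_contrast_d{d}"] == 0.0 for d in (1, 2, 3, 4, 5))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (24, 24))
        fm = extract_features([img, np.rot90(img)])
        assert np.allclose(fm.values[0], fm.values[1], atol=1e-10)

    def test_identical_images_identical_rows(self):
        img = np.random.default_rng(3).uniform(0, 1, (16, 16))
        fm = extract_features([img, img.copy()])
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError):
            extract_features([np.zeros((8, 8)), np.zeros((9, 9))])

    def test_unavailable_plugin_raises(self):
        with pytest.raises((ImportError, NotImplementedError)):
            extract_features([np.zeros((8, 8))], extractor="pretrained_cnn")


class TestAutoencoder:
    def test_linear_subspace_reconstructs(self):
        """Data on an 8-dimensional linear subspace of 40 features."""
        rng = np.random.default_rng(4)
        latent = rng.normal(size=(200, 8))
        mixing = rng.normal(size=(8, 40))
        x = latent @ mixing
        enc, latents = fit_autoencoder(x, latent_dim=8, epochs=500, seed=0)
        assert enc.reconstruction_mse < 1e-3
        assert latents.values.shape == (200, 8)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 12))
        _, a = fit_autoencoder(x, latent_dim=4, seed=3)
        _, b = fit_autoencoder(x, latent_dim=4, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_no_reduction_rejected(self):
        x = np.random.default_rng(6).normal(size=(30, 10))
        with pytest.raises(ValueError):
            fit_autoencoder(x, latent_dim=10)


class TestTrainRf:
    def test_separable_data_perfect_training_auc(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(-3, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
        y = np.array([0] * 20 + [1] * 20)
        model, params = train_rf(x, y, grid={"n_estimators": [50]}, seed=0)
        scores = model.predict_proba(x)[:, 1]
        assert roc_auc_score(y, scores) == 1.0
        assert params["n_estimators"] == 50

    def test_grid_selection_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 4))
        y = (x[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        grid = {"n_estimators": [20, 50], "max_depth": [None, 3]}
        _, a = train_rf(x, y, grid=grid, seed=1)
        _, b = train_rf(x, y, grid=grid, seed=1)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_rf(np.zeros((10, 2)), np.zeros(10), seed=0)


class TestOptimalCutpoint:
    def test_two_point_separation(self):
        t, sens, spec = optimal_cutpoint(np.array([0.1, 0.9]), np.array([0, 1]))
        assert sens == 1.0 and spec == 1.0
        assert 0.1 < t <= 0.9

    def test_all_equal_scores_majority_rule(self):
        scores = np.full(10, 0.5)
        labels = np.array([1] * 7 + [0] * 3)
        t, sens, spec = optimal_cutpoint(scores, labels)
        accuracy = (sens * 7 + spec * 3) / 10
        assert accuracy == pytest.approx(0.7)  # majority-class prevalence

    def test_matches_brute_force_scan(self):
        """Exhaustive oracle over every threshold on random 50-point sets."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            scores = rng.uniform(0, 1, 50).round(2)  # force ties
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            t, sens, spec = optimal_cutpoint(scores, labels)
            n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
            achieved = sens * n_pos + spec * n_neg
            best = max(
                ((scores >= c) == labels).sum()
                for c in np.concatenate([scores - 1e-9, scores + 1e-9])
            )
            assert achieved == best

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.array([0.3, 0.4]), np.array([1, 1]))


class TestAucOracle:
    def test_auc_equals_mann_whitney(self):
        """ROC AUC == U / (n1 n2) on random score sets (small-n oracle)."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            n1, n0 = rng.integers(5, 30, 2)
            pos = rng.normal(0.5, 1, n1)
            neg = rng.normal(0.0, 1, n0)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * n0 + [1] * n1)
            auc = roc_auc_score(labels, scores)
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestCrossValidate:
    FAST = {"n_estimators": [60], "max_depth": [None], "max_features": ["sqrt"]}

    def test_fold_count_is_k_times_repeats(self):
        features, labels = _feature_cohort(8, effect=1.0, seed=1)
        report = cross_validate(features, labels, k=4, repeats=5, seed=0,
                                latent_dim=4, epochs=100, grid=self.FAST)
        assert len(report.folds) == 20
        assert set(report.folds["repeat"]) == set(range(5))

    def test_separable_cohort_perfect_auc(self):
        features, labels = _feature_cohort(8, effect=30.0, seed=2)
        report = cross_validate(features, labels, k=4, repeats=2, seed=0,
                                latent_dim=4, epochs=100, grid=self.FAST)
        assert report.summary["auc"]["mean"] == pytest.approx(1.0)

    def test_permutation_null_auc_near_half(self):
        """Labels carry no signal: the permutation-null mean AUC sits at
        0.5 +/- 0.1 (averaged over independent label randomizations — a
        single 100-patient cohort has ~0.06 null SE on its own)."""
        aucs = []
        for cohort_seed in range(4):
            features, labels = _feature_cohort(
                50, effect=0.0, nuclei_per_patient=3, seed=cohort_seed
            )
            report = cross_validate(features, labels, k=4, repeats=5, seed=0,
                                    latent_dim=4, epochs=100, grid=self.FAST)
            aucs.append(report.summary["auc"]["mean"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_too_few_patients_per_class_rejected(self):
        features, labels = _feature_cohort(3, effect=1.0, seed=4)
        with pytest.raises(ValueError):
            cross_validate(features, labels, k=4, repeats=1, seed=0,
                           latent_dim=4, grid=self.FAST)

    def test_latent_aggregation_path(self):
        """Pooling latents per patient before the forest also separates a
        strongly separated cohort perfectly."""
        features, labels = _feature_cohort(8, effect=30.0, seed=5)
        report = cross_validate(features, labels, k=4, repeats=1, seed=0,
                                latent_dim=4, epochs=100, grid=self.FAST,
                                aggregate="latent")
        assert report.summary["auc"]["mean"] == pytest.approx(1.0)

    def test_passthrough_columns(self):
        """Passthrough features bypass the autoencoder; unknown names fail."""
        features, labels = _feature_cohort(8, effect=30.0, seed=6)
        report = cross_validate(features, labels, k=4, repeats=1, seed=0,
                                latent_dim=4, epochs=100, grid=self.FAST,
                                passthrough=["f0"])
        assert report.summary["auc"]["mean"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cross_validate(features, labels, k=4, repeats=1, seed=0,
                           latent_dim=4, grid=self.FAST, passthrough=["nope"])
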