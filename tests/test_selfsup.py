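"""CDAE pretext stage, PCA baseline, SVM selection, Bayesian search."""

import numpy as np
import pytest

from taskmo import (
    CDAEConfig,
    DetectionDataset,
    build_cdae,
    cdae_bayesian_search,
    corrupt_inputs,
    fit_pca,
    svm_grid_search,
    train_cdae,
)
from taskmo.selfsup import fit_ssl_observer


@pytest.fixture(scope="module")
def toy_images():
    """Rank-1 ensemble on [0,1]: scaled copies of one smooth pattern."""
    rng = np.random.default_rng(0)
    base = np.outer(np.hanning(8), np.hanning(8))
    coef = rng.uniform(0.2, 0.9, size=64)
    return np.clip(coef[:, None, None] * base[None], 0, 1).astype(np.float32)


class TestCorruption:
    def test_rate_zero_is_identity(self, rng):
        x = rng.random((4, 8, 8))
        np.testing.assert_array_equal(corrupt_inputs(x, 0.0, 0), x)

    def test_rate_one_zeroes_everything(self, rng):
        x = rng.random((4, 8, 8)) + 0.5
        assert np.all(corrupt_inputs(x, 1.0, 0) == 0)

    def test_original_untouched(self, rng):
        x = rng.random((2, 8, 8)) + 0.5
        before = x.copy()
        corrupt_inputs(x, 0.5, 0)
        np.testing.assert_array_equal(x, before)

    def test_zeroed_fraction_binomial_bound(self, rng):
        x = rng.random((1, 64, 64)) + 0.5  # strictly positive
        out = corrupt_inputs(x, 0.2, seed=1)
        frac = np.mean(out == 0)
        assert abs(frac - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / 4096)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            corrupt_inputs(rng.random((1, 4, 4)), 1.5, 0)


class TestCDAEModel:
    def test_encoder_output_shape(self, toy_images):
        model = build_cdae(CDAEConfig(latent_units=7), image_shape=(8, 8))
        model.trained = True  # direct encoder shape check
        feats = model.encode(toy_images)
        assert feats.shape == (64, 7)

    def test_decoder_output_in_unit_interval_and_same_size(self, toy_images):
        model = build_cdae(CDAEConfig(depth=2, filters=4, latent_units=4),
                           image_shape=(8, 8))
        out = model.forward(toy_images[:5, :, :, None])
        assert out.shape == (5, 8, 8, 1)
        assert np.all(out > 0) and np.all(out < 1)

    def test_config_bounds_enforced(self):
        for bad in (dict(depth=0), dict(depth=9), dict(filters=3),
                    dict(latent_units=1), dict(latent_units=33),
                    dict(corruption_rate=1.5), dict(weight_decay=-1e-3)):
            with pytest.raises(ValueError):
                CDAEConfig(**bad)

    def test_untrained_encode_rejected(self, toy_images):
        model = build_cdae(image_shape=(8, 8))
        with pytest.raises(RuntimeError, match="untrained"):
            model.encode(toy_images)


class TestCDAETraining:
    def test_validation_loss_decreases_on_toy(self, toy_images):
        model = build_cdae(CDAEConfig(latent_units=2, filters=4,
                                      corruption_rate=0.05), image_shape=(8, 8))
        train_cdae(model, toy_images[:48], toy_images[48:], max_epochs=30,
                   patience=30, seed=0)
        h = model.history["val_loss"]
        assert h.iloc[-1] < h.iloc[0]

    def test_inputs_outside_unit_interval_rejected(self, toy_images):
        model = build_cdae(image_shape=(8, 8))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_cdae(model, toy_images + 2.0, toy_images, max_epochs=1, seed=0)

    def test_labels_never_consumed(self):
        import inspect

        sig = inspect.signature(train_cdae)
        assert "labels" not in sig.parameters

    def test_encoding_deterministic_and_corruption_free(self, toy_images):
        model = build_cdae(CDAEConfig(latent_units=3, filters=4,
                                      corruption_rate=0.5), image_shape=(8, 8))
        train_cdae(model, toy_images[:48], toy_images[48:], max_epochs=3,
                   patience=3, seed=0)
        f1 = model.encode(toy_images[:4])
        f2 = model.encode(toy_images[:4])
        np.testing.assert_array_equal(f1, f2)
        # identical images map to identical rows
        dup = np.repeat(toy_images[:1], 3, axis=0)
        feats = model.encode(dup)
        assert np.all(feats == feats[0])

    def test_weight_decay_shrinks_weight_norm(self, toy_images):
        norms = []
        for lam in (0.0, 1e-3, 1e-1):
            model = build_cdae(
                CDAEConfig(latent_units=2, filters=4, weight_decay=lam,
                           corruption_rate=0.05),
                image_shape=(8, 8), seed=1,
            )
            train_cdae(model, toy_images[:48], toy_images[48:], max_epochs=20,
                       patience=20, seed=1)
            norms.append(model.weight_sq_norm())
        assert norms[0] >= norms[1] >= norms[2]


class TestPCA:
    def test_line_data_single_component(self, rng):
        direction = rng.standard_normal(64)
        coef = rng.standard_normal(200)
        X = (0.5 + np.outer(coef, direction * 0.01)).reshape(200, 8, 8)
        pca = fit_pca(X, 3)
        assert pca.explained_variance_ratio[0] > 0.999

    def test_components_orthonormal(self, rng):
        X = rng.random((50, 8, 8))
        pca = fit_pca(X, 5)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.random((5, 8, 8)), 10)


class TestSVMGridSearch:
    def test_single_point_grid_selected(self, rng):
        X = rng.standard_normal((60, 3))
        y = (X[:, 0] > 0).astype(int)
        _, cfg, table = svm_grid_search(X, y, C_grid=[2.0], sigma_grid=[0.7],
                                        seed=0)
        assert (cfg.C, cfg.sigma) == (2.0, 0.7)
        assert len(table) == 1

    def test_uninformative_features_tie_break_small_c_sigma(self, rng):
        X = np.zeros((80, 2))
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        _, cfg, table = svm_grid_search(X, y, C_grid=[1.0, 10.0],
                                        sigma_grid=[0.5, 5.0], seed=0)
        assert np.allclose(table["cv_auc_mean"], 0.5)
        assert (cfg.C, cfg.sigma) == (1.0, 0.5)

    def test_wide_margin_separable_features_perfect_cv(self, rng):
        X = np.concatenate([
            rng.standard_normal((50, 2)) * 0.1 - 3,
            rng.standard_normal((50, 2)) * 0.1 + 3,
        ])
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        _, cfg, table = svm_grid_search(X, y, C_grid=[1.0, 10.0],
                                        sigma_grid=[1.0, 3.0], seed=0)
        best = table.loc[(table["C"] == cfg.C) & (table["sigma"] == cfg.sigma)]
        assert best["cv_auc_mean"].iloc[0] == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            svm_grid_search(rng.random((10, 2)), np.zeros(10), seed=0)

    def test_grouped_folds_keep_pairs_together(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        groups = np.tile(np.arange(20), 2)
        from taskmo.selfsup import _grouped_folds

        folds = _grouped_folds(groups, 5, seed=0)
        for tr, te in folds:
            assert not set(groups[tr]) & set(groups[te])


class TestBayesianSearch:
    def test_one_point_space(self, toy_images):
        best, log = cdae_bayesian_search(
            toy_images, trials=1, depth_bounds=(1, 1), filters_choices=(4,),
            latent_bounds=(2, 2), seed=0, max_epochs=2, patience=2,
        )
        assert (best.depth, best.filters, best.latent_units) == (1, 4, 2)
        assert len(log) == 1

    def test_proposals_within_bounds_and_deterministic(self, toy_images):
        kwargs = dict(
            trials=4, depth_bounds=(1, 2), filters_choices=(4, 8),
            latent_bounds=(2, 4), seed=3, max_epochs=1, patience=1, n_initial=2,
        )
        best1, log1 = cdae_bayesian_search(toy_images, **kwargs)
        best2, log2 = cdae_bayesian_search(toy_images, **kwargs)
        assert log1[["depth", "filters", "latent_units"]].equals(
            log2[["depth", "filters", "latent_units"]]
        )
        assert best1 == best2
        assert log1["depth"].between(1, 2).all()
        assert log1["latent_units"].between(2, 4).all()
        assert set(log1["filters"]) <= {4, 8}
        # best config is the one with minimal logged objective
        row = log1.loc[log1["val_recon_loss"].idxmin()]
        assert (best1.depth, best1.filters, best1.latent_units) == (
            row["depth"], row["filters"], row["latent_units"]
        )


class TestSSLObserver:
    def test_scores_deterministic_and_permutation_equivariant(self, small_dataset):
        from taskmo import train_val_test_split

        tr, va, te = train_val_test_split(small_dataset, (120, 60, 60), seed=0)
        obs = fit_ssl_observer(
            tr, va, config=CDAEConfig(latent_units=4, filters=4,
                                      corruption_rate=0.05),
            C_grid=(1.0,), sigma_grid=(1.0,), max_epochs=2, patience=2, seed=0,
        )
        s1 = obs.score(te.images)
        s2 = obs.score(te.images)
        np.testing.assert_array_equal(s1, s2)
        perm = np.random.default_rng(0).permutation(len(te.images))
        np.testing.assert_allclose(obs.score(te.images[perm]), s1[perm])

    def test_pca_extractor_route(self, small_dataset):
        from taskmo import train_val_test_split

        tr, va, te = train_val_test_split(small_dataset, (120, 60, 60), seed=0)
        obs = fit_ssl_observer(
            tr, va, config=CDAEConfig(latent_units=4), extractor="pca",
            C_grid=(1.0,), sigma_grid=(1.0,), seed=0,
        )
        assert obs.score(te.images).shape == (60,)
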