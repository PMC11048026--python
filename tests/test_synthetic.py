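"""Synthetic task generation: signal profiles, backgrounds, dataset assembly."""

import numpy as np
import pytest
from scipy.stats import chisquare

from taskmo import (
    BackgroundSpec,
    PixelGrid,
    SignalSpecSKE,
    SignalSpecSKS,
    analytic_background_covariance,
    background_spectrum,
    build_detection_dataset,
    load_dataset,
    sample_backgrounds,
    save_dataset,
    ske_profile,
    sks_profile,
)


class TestSKEProfile:
    def test_center_value_is_amplitude(self):
        # reference GGO-mimicking amplitude of -870 HU
        grid = PixelGrid(64, 64, 0.7)
        spec = SignalSpecSKE(amplitude=-870.0, radius=4.0, exponent=4.0,
                             center=(31.5, 31.5))
        prof = ske_profile(grid, spec)
        # center falls between pixels; evaluate with an on-pixel center too
        spec_on = SignalSpecSKE(amplitude=-870.0, radius=4.0, exponent=4.0,
                                center=(32.0, 32.0))
        prof_on = ske_profile(grid, spec_on)
        assert prof_on[32, 32] == pytest.approx(-870.0)
        assert prof.min() >= -870.0

    def test_zero_outside_support(self):
        grid = PixelGrid(64, 64, 0.7)
        spec = SignalSpecSKE(amplitude=-870.0, radius=4.0, center=(32.0, 32.0))
        prof = ske_profile(grid, spec)
        r_pix = 4.0 / 0.7
        rows, cols = grid.coords()
        outside = (rows - 32.0) ** 2 + (cols - 32.0) ** 2 > r_pix**2
        assert np.max(np.abs(prof[outside])) == 0.0

    def test_closed_form_at_half_radius(self):
        # A*(1 - 0.25)^4 at distance R/2
        grid = PixelGrid(33, 33, 1.0)
        spec = SignalSpecSKE(amplitude=-870.0, radius=8.0, exponent=4.0,
                             center=(16.0, 16.0))
        prof = ske_profile(grid, spec)
        assert prof[16, 20] == pytest.approx(-870.0 * 0.75**4)
        assert prof[16, 20] == pytest.approx(-275.2734375)

    def test_unresolvable_radius_raises(self):
        grid = PixelGrid(64, 64, 0.7)
        with pytest.raises(ValueError, match="unresolvable"):
            ske_profile(grid, SignalSpecSKE(radius=0.5))

    def test_energy_monotone_in_amplitude(self):
        grid = PixelGrid(32, 32, 0.7)
        energies = [
            np.sum(ske_profile(grid, SignalSpecSKE(amplitude=a, radius=3.0)) ** 2)
            for a in (-20.0, -60.0, -120.0)
        ]
        assert energies[0] < energies[1] < energies[2]


class TestSKSProfile:
    def test_amplitude_at_center(self):
        grid = PixelGrid(33, 33, 1.0)
        spec = SignalSpecSKS(amplitude=-50.0, sigma_x=5.0, sigma_y=1.5,
                             center=(16.0, 16.0))
        prof = sks_profile(grid, spec, 0.0)
        assert prof[16, 16] == pytest.approx(-50.0)

    def test_one_sigma_offset(self):
        # at offset (sigma_x, 0) along the major axis the value is A/e
        grid = PixelGrid(33, 33, 1.0)
        spec = SignalSpecSKS(amplitude=-50.0, sigma_x=5.0, sigma_y=1.5,
                             center=(16.0, 16.0))
        prof = sks_profile(grid, spec, 0.0)
        assert prof[16, 21] == pytest.approx(-50.0 * np.exp(-1.0))

    def test_rotation_symmetry(self):
        # value at (a, b) under 90 deg equals value at (b, -a) under 0 deg
        grid = PixelGrid(33, 33, 1.0)
        spec = SignalSpecSKS(amplitude=-50.0, sigma_x=5.0, sigma_y=1.5,
                             center=(16.0, 16.0), angle_set=(0.0, 90.0))
        p0 = sks_profile(grid, spec, 0.0)
        p90 = sks_profile(grid, spec, 90.0)
        # (row, col) offsets: rotating the signal by 90 deg maps the value at
        # column offset +d onto row offset +d
        assert p90[16 + 4, 16] == pytest.approx(p0[16, 16 + 4], rel=1e-10)
        assert p90[16, 16 + 2] == pytest.approx(p0[16 + 2, 16], rel=1e-10)

    def test_angle_outside_set_rejected(self):
        grid = PixelGrid(33, 33, 1.0)
        spec = SignalSpecSKS()
        with pytest.raises(ValueError, match="angle"):
            sks_profile(grid, spec, 30.0)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            SignalSpecSKS(sigma_x=-1.0)


class TestBackgrounds:
    def test_white_sample_sd(self, tiny_grid):
        spec = BackgroundSpec(kind="white", mean_level=0.0, noise_sd=5.0)
        stack = sample_backgrounds(tiny_grid, spec, 10000, seed=0)
        assert stack.std() == pytest.approx(5.0, rel=0.02)

    def test_seeded_determinism(self, tiny_grid, corr_bg):
        a = sample_backgrounds(tiny_grid, corr_bg, 10, seed=7)
        b = sample_backgrounds(tiny_grid, corr_bg, 10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_periodogram_matches_target_spectrum(self, tiny_grid):
        spec = BackgroundSpec(kind="correlated-gaussian", mean_level=0.0,
                              noise_sd=3.0)
        stack = sample_backgrounds(tiny_grid, spec, 6000, seed=1)
        target = background_spectrum(tiny_grid, spec)
        per = (np.abs(np.fft.fft2(stack, axes=(1, 2))) ** 2).mean(0) / tiny_grid.n_pixels
        ratio = per / target
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown background kind"):
            BackgroundSpec(kind="pink")

    def test_stationary_mean_and_variance(self, tiny_grid, corr_bg):
        stack = sample_backgrounds(tiny_grid, corr_bg, 20000, seed=3)
        pixel_means = stack.mean(axis=0)
        pixel_sds = stack.std(axis=0)
        se = corr_bg.noise_sd / np.sqrt(20000)
        assert np.all(np.abs(pixel_means - corr_bg.mean_level) < 4 * se)
        assert np.all(np.abs(pixel_sds - corr_bg.noise_sd) < 0.05 * corr_bg.noise_sd)

    def test_lumpy_backgrounds_generate(self, tiny_grid):
        spec = BackgroundSpec(kind="lumpy", lump_count_mean=5.0)
        stack = sample_backgrounds(tiny_grid, spec, 4, seed=0)
        assert stack.shape == (4, 8, 8)
        assert np.all(np.isfinite(stack))


class TestAnalyticCovariance:
    def test_white_covariance_is_scaled_identity(self, tiny_grid):
        spec = BackgroundSpec(kind="white", noise_sd=2.0)
        K = analytic_background_covariance(tiny_grid, spec)
        np.testing.assert_allclose(K, 4.0 * np.eye(64))

    def test_block_toeplitz_structure(self, tiny_grid, corr_bg):
        # stationarity on the torus: entries depend only on the pixel lag
        K = analytic_background_covariance(tiny_grid, corr_bg)
        n = tiny_grid.n_rows
        np.testing.assert_allclose(K, K.T)
        # same-lag entries are equal: compare a few translated pairs
        for (i1, j1), (i2, j2) in [((0, 1), (5, 6)), ((0, 9), (3, 12)),
                                   ((2, 10), (42, 50))]:
            assert K[i1, j1] == pytest.approx(K[i2, j2], rel=1e-10)

    def test_monte_carlo_agreement(self, tiny_grid):
        spec = BackgroundSpec(kind="correlated-gaussian", mean_level=0.0,
                              noise_sd=3.0)
        K = analytic_background_covariance(tiny_grid, spec)
        n = 50_000
        stack = sample_backgrounds(tiny_grid, spec, n, seed=5)
        X = stack.reshape(n, -1)
        K_emp = np.cov(X, rowvar=False)
        # SE of a covariance entry ~ sqrt((K_ii K_jj + K_ij^2) / n)
        se = np.sqrt((np.outer(np.diag(K), np.diag(K)) + K**2) / n)
        assert np.all(np.abs(K_emp - K) < 3.5 * se)

    def test_lumpy_has_no_closed_form(self, tiny_grid):
        with pytest.raises(ValueError, match="lumpy"):
            analytic_background_covariance(tiny_grid, BackgroundSpec(kind="lumpy"))


class TestDetectionDataset:
    def test_paired_construction_counts(self, small_dataset):
        labels = np.asarray(small_dataset.labels)
        assert (labels == 0).sum() == 300
        assert (labels == 1).sum() == 300

    def test_additive_insertion_exact(self, small_grid, corr_bg, ske_spec):
        ds = build_detection_dataset(small_grid, corr_bg, ske_spec,
                                     n_pairs=5, seed=3)
        lo, hi = ds.provenance["hu_window"]
        prof = ske_profile(small_grid, ske_spec)
        for i in range(5):
            absent_hu = ds.images[i].astype(np.float64) * (hi - lo) + lo
            present_hu = ds.images[5 + i].astype(np.float64) * (hi - lo) + lo
            # exact away from the clipping boundary
            interior = (absent_hu > lo + 1) & (present_hu > lo + 1)
            np.testing.assert_allclose(
                (present_hu - absent_hu)[interior], prof[interior], atol=1e-3
            )

    def test_images_unit_interval(self, small_dataset):
        assert small_dataset.images.min() >= 0.0
        assert small_dataset.images.max() <= 1.0

    def test_sks_angles_recorded_and_uniform(self, small_grid, corr_bg, sks_spec):
        ds = build_detection_dataset(small_grid, corr_bg, sks_spec,
                                     n_pairs=4000, paradigm="SKS", seed=9)
        drawn = ds.angles[np.asarray(ds.labels) == 1]
        assert len(drawn) == 4000
        counts = [np.sum(drawn == a) for a in sks_spec.angle_set]
        bound = 3 * np.sqrt(4000 * 0.25 * 0.75)
        assert all(abs(c - 1000) <= bound for c in counts)
        assert chisquare(counts).pvalue > 0.01

    def test_signal_beyond_grid_rejected(self, corr_bg):
        grid = PixelGrid(8, 8, 0.7)
        with pytest.raises(ValueError, match="beyond the grid"):
            build_detection_dataset(grid, corr_bg, SignalSpecSKE(radius=4.0),
                                    n_pairs=2, seed=0)

    def test_pair_ids_mark_siblings(self, small_dataset):
        pids = small_dataset.pair_ids
        labels = np.asarray(small_dataset.labels)
        assert pids is not None
        for pid in (0, 17, 299):
            members = labels[pids == pid]
            assert sorted(members) == [0, 1]

    def test_roundtrip_identity(self, small_dataset, tmp_path):
        path = tmp_path / "ds.h5"
        save_dataset(small_dataset, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.images, small_dataset.images)
        np.testing.assert_array_equal(back.labels, small_dataset.labels)
        np.testing.assert_array_equal(back.pair_ids, small_dataset.pair_ids)
        assert back.provenance == small_dataset.provenance
        assert back.grid == small_dataset.grid

    def test_roundtrip_seed_regenerates(self, small_dataset, tmp_path,
                                        small_grid, corr_bg, ske_spec):
        path = tmp_path / "ds.h5"
        save_dataset(small_dataset, path)
        back = load_dataset(path)
        regen = build_detection_dataset(
            small_grid, corr_bg, ske_spec,
            n_pairs=back.provenance["n_pairs"], seed=back.provenance["seed"],
        )
        np.testing.assert_array_equal(regen.images, back.images)

    def test_unpaired_mode_independent_backgrounds(self, small_grid, corr_bg,
                                                   ske_spec):
        ds = build_detection_dataset(small_grid, corr_bg, ske_spec,
                                     n_pairs=50, seed=3, paired=False)
        assert ds.pair_ids is None
        assert ds.provenance["paired"] is False
        # absent and same-index present images do not share a background
        diff = ds.images[50].astype(float) - ds.images[0].astype(float)
        prof = ske_profile(small_grid, ske_spec) / 1500.0
        assert np.abs(diff - prof).max() > 10 * np.abs(prof).max() / 100

    def test_tiff_export_roundtrip(self, small_dataset, tmp_path):
        import tifffile

        from taskmo.synthetic import export_tiff

        path = tmp_path / "stack.tif"
        export_tiff(small_dataset, path)
        back = tifffile.imread(path)
        np.testing.assert_array_equal(back, small_dataset.images)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "nope.h5")

    def test_corrupt_file_raises(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="corrupt|invalid"):
            load_dataset(path)
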