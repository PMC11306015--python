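"""Synthetic trial generator: markers, spectra, point clouds, weather, yields."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box
from sklearn.metrics import adjusted_rand_score

from phenoyield.errors import ConfigurationError, DomainError
from phenoyield.genetics import kmeans_cluster, pca_markers
from phenoyield.simulate import (
    SpectrumStageParams,
    SyntheticConfig,
    accumulate_weather,
    daily_gdd,
    generate_canopy_point_cloud,
    generate_dataset,
    generate_marker_matrix,
    generate_plot_spectrum,
    generate_weather,
    generate_yields,
)
from phenoyield.spectral import vegetation_index


class TestMarkerMatrix:
    def test_no_divergence_means_no_recoverable_structure(self):
        aris = []
        for seed in range(20):
            m, labels = generate_marker_matrix(120, 400, 2, divergence=0.0, seed=seed)
            scores = pca_markers(m, 6).scores
            aris.append(adjusted_rand_score(labels, kmeans_cluster(scores, 2, seed)))
        assert abs(np.mean(aris)) < 0.1

    def test_full_scale_shape_and_cluster_separation(self):
        m, labels = generate_marker_matrix(401, 2000, 2, divergence=0.8, seed=0)
        assert m.shape == (401, 2000)
        assert set(np.unique(m)) <= {0, 1, 2}
        scores = pca_markers(m, 6).scores
        assert adjusted_rand_score(labels, kmeans_cluster(scores, 2, 0)) > 0.9

    def test_strong_divergence_recovered_over_seeds(self):
        for seed in range(5):
            m, labels = generate_marker_matrix(200, 800, 2, divergence=0.8, seed=seed)
            scores = pca_markers(m, 6).scores
            assert adjusted_rand_score(labels, kmeans_cluster(scores, 2, seed)) > 0.9

    def test_frequency_gap_monotone_in_divergence(self):
        gaps = []
        for div in (0.1, 0.4, 0.8):
            per_seed = []
            for seed in range(20):
                m, labels = generate_marker_matrix(200, 300, 2, div, seed=seed)
                f0 = m[labels == 0].mean(axis=0) / 2
                f1 = m[labels == 1].mean(axis=0) / 2
                per_seed.append(np.abs(f0 - f1).mean())
            gaps.append(np.mean(per_seed))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_invalid_divergence_rejected(self):
        with pytest.raises(DomainError):
            generate_marker_matrix(10, 10, 2, divergence=1.5, seed=0)


class TestPlotSpectrum:
    def test_peak_green_canopy_has_high_ndre(self):
        s = generate_plot_spectrum(
            SpectrumStageParams(chlorophyll=1.0, nir_plateau=0.5, red_reflectance=0.05),
            n_pixels=20, pixel_noise_sd=0.0, seed=0,
        )
        assert vegetation_index(s, "NDRE") > 0.5

    def test_zero_noise_pixels_identical(self):
        s = generate_plot_spectrum(
            SpectrumStageParams(0.7, 0.4, 0.06), n_pixels=10, pixel_noise_sd=0.0, seed=1
        )
        assert np.all(s.pixels == s.pixels[0])

    def test_senescence_raises_psri(self):
        green = generate_plot_spectrum(
            SpectrumStageParams(1.0, 0.5, 0.05), 10, 0.0, seed=2
        )
        senescent = generate_plot_spectrum(
            SpectrumStageParams(0.05, 0.35, 0.15), 10, 0.0, seed=2
        )
        assert vegetation_index(senescent, "PSRI") > vegetation_index(green, "PSRI")

    def test_wavelengths_increasing_and_reflectance_bounded(self):
        s = generate_plot_spectrum(
            SpectrumStageParams(0.9, 0.75, 0.05), 50, pixel_noise_sd=0.2, seed=3
        )
        assert np.all(np.diff(s.wavelengths) > 0)
        assert s.pixels.min() >= 0.0 and s.pixels.max() <= 1.0

    def test_out_of_range_reflectance_warns(self):
        with pytest.warns(UserWarning):
            generate_plot_spectrum(
                SpectrumStageParams(0.9, 0.75, 0.05), 50, pixel_noise_sd=0.3, seed=3
            )


class TestPointCloud:
    PLOT = box(0, 0, 3.775, 1.5)

    def test_degenerate_canopy_exact(self):
        from phenoyield.lidar import extract_lidar_features

        c = generate_canopy_point_cloud(2.0, 0.0, 1.0, 200, self.PLOT, seed=0)
        vec = extract_lidar_features(c).as_dict()
        assert vec["height_p75"] == 2.0
        assert vec["height_p90"] == 2.0
        assert vec["height_qmean"] == pytest.approx(2.0)

    def test_bare_ground(self):
        from phenoyield.lidar import extract_lidar_features

        c = generate_canopy_point_cloud(2.0, 0.2, 0.0, 200, self.PLOT, seed=1)
        vec = extract_lidar_features(c).as_dict()
        assert vec["voxel_volume"] == 0.0
        assert vec["cover_p20"] == 0.0

    def test_p90_within_truncated_normal_band(self):
        from phenoyield.lidar import height_percentile

        # 4.575 m x 1.5 m plot at 500 pts/m^2, canopy N(2.5, 0.2) truncated at 0
        plot = box(0, 0, 4.575, 1.5)
        for seed in range(20):
            c = generate_canopy_point_cloud(2.5, 0.2, 0.9, 500, plot, seed=seed)
            assert 2.5 <= height_percentile(c, 90) <= 3.1

    def test_ground_fraction_within_binomial_interval(self):
        cover = 0.7
        c = generate_canopy_point_cloud(2.0, 0.3, cover, 400, self.PLOT, seed=5)
        n = c.n_points
        p = 1 - cover
        se = np.sqrt(p * (1 - p) / n)
        assert abs(c.ground_flag.mean() - p) < 2.58 * se

    def test_points_inside_polygon(self):
        c = generate_canopy_point_cloud(1.5, 0.2, 0.8, 300, self.PLOT, seed=6)
        assert c.x.min() >= 0 and c.x.max() <= 3.775
        assert c.y.min() >= 0 and c.y.max() <= 1.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            generate_canopy_point_cloud(2.0, 0.2, 0.9, 0.0, self.PLOT, seed=0)
        from shapely.geometry import Polygon

        with pytest.raises(DomainError):
            generate_canopy_point_cloud(2.0, 0.2, 0.9, 100, Polygon(), seed=0)


class TestWeather:
    def test_tmax_never_below_tmin(self):
        for seed in range(5):
            w = generate_weather(140, seed=seed)
            assert (w["tmax_f"] >= w["tmin_f"]).all()

    def test_cumulative_gdd_nondecreasing(self):
        w = generate_weather(120, seed=0)
        assert (np.diff(np.cumsum(w["gdd"])) >= 0).all()

    def test_maize_gdd_rule_on_reference_day(self):
        # 86 F / 50 F day: (86+50)/2 - 50 = 18 GDD, 120-day total 2160
        gdd = daily_gdd(np.full(120, 50.0), np.full(120, 86.0))
        assert gdd[0] == 18.0 and gdd.sum() == 2160.0

    def test_gdd_caps_and_floors(self):
        assert daily_gdd([40.0], [100.0])[0] == 18.0  # both clamped
        assert daily_gdd([30.0], [45.0])[0] == 0.0    # cold day floors at 0


class TestAccumulateWeather:
    def test_planting_day_carries_first_day_only(self):
        w = generate_weather(60, seed=1)
        vec = accumulate_weather(w, [0])
        assert vec[0, 0] == w["gdd"].iloc[0]
        assert vec[0, 1] == w["precip_mm"].iloc[0]

    def test_identical_dates_identical_vectors(self):
        w = generate_weather(60, seed=2)
        vec = accumulate_weather(w, [30, 30])
        np.testing.assert_array_equal(vec[0], vec[1])

    def test_matches_prefix_sum_oracle(self):
        w = generate_weather(90, seed=3)
        days = [5, 17, 44, 89]
        vec = accumulate_weather(w, days)
        for k, d in enumerate(days):
            assert vec[k, 0] == pytest.approx(w["gdd"].iloc[: d + 1].sum())
            assert vec[k, 1] == pytest.approx(w["precip_mm"].iloc[: d + 1].sum())
            assert vec[k, 2] == pytest.approx(w["radiation_mj"].iloc[: d + 1].sum())

    def test_out_of_range_date_rejected(self):
        with pytest.raises(DomainError):
            accumulate_weather(generate_weather(30, 0), [45])


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(SyntheticConfig(n_plots=40, seed=0))


class TestYields:
    def test_noise_free_yields_exact_function_of_planted_features(self):
        cfg = SyntheticConfig(n_plots=50, seed=1, noise_sd=0.0)
        ds = generate_dataset(cfg)
        gt = ds.ground_truth
        recon = np.full(50, cfg.yield_mean) + gt.cluster_effects[
            ds.plot_table["cluster"].to_numpy()
        ]
        parts = np.zeros(50)
        for m, prof in gt.importance_profile.items():
            v = ds.tensors[m].values
            z = (v - v.mean(0)) / np.where(v.std(0) == 0, 1, v.std(0))
            parts += np.einsum("ptf,tf->p", z, gt.coefficients[m])
        recon += cfg.signal_sd * parts / parts.std()
        np.testing.assert_allclose(ds.plot_table["observed_yield"], recon, atol=1e-8)
        np.testing.assert_array_equal(
            ds.plot_table["observed_yield"], ds.plot_table["true_yield"]
        )

    def test_noise_free_generation_reproducible_bitwise(self):
        cfg = SyntheticConfig(n_plots=20, seed=3, noise_sd=0.0)
        a = generate_dataset(cfg).plot_table["true_yield"].to_numpy()
        b = generate_dataset(cfg).plot_table["true_yield"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_observed_equals_true_plus_noise_of_requested_scale(self, small_dataset):
        tab = small_dataset.plot_table
        resid = tab["observed_yield"] - tab["true_yield"]
        assert resid.abs().max() < 6 * small_dataset.config.noise_sd
        assert resid.abs().sum() > 0

    def test_wrong_profile_length_rejected(self, small_dataset):
        with pytest.raises(DomainError):
            generate_yields(
                small_dataset.tensors,
                small_dataset.plot_table["cluster"].to_numpy(),
                {"lidar": np.ones(3) / 3},
                noise_sd=1.0,
                seed=0,
            )

    def test_every_plot_has_all_dates(self, small_dataset):
        for t in small_dataset.tensors.values():
            assert t.values.shape[:2] == (40, 7)
            assert np.isfinite(t.values).all()

    def test_check_fraction_and_clusters(self, small_dataset):
        tab = small_dataset.plot_table
        assert tab["is_check"].sum() == round(0.05 * 40)
        assert set(tab["cluster"]) <= {0, 1}


class TestConfigValidation:
    def test_counts_validated(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_plots=0)

    def test_divergence_validated(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(cluster_divergence=1.2)

    def test_importance_profile_validated(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(importance_profile={"lidar": np.ones(7)})  # sums to 7

    def test_default_profiles_are_deltas_at_planted_dates(self):
        cfg = SyntheticConfig()
        assert cfg.importance_profile["lidar"][2] == 1.0
        assert cfg.importance_profile["hyperspectral"][4] == 1.0


def test_acquisition_dates_track_gdd_targets():
    ds = generate_dataset(SyntheticConfig(n_plots=10, seed=4))
    gdd = ds.tensors["lidar"].dates.astype(float)
    from phenoyield.simulate import DATE_GDD_TARGETS

    assert np.all(np.diff(gdd) > 0)
    np.testing.assert_allclose(gdd, DATE_GDD_TARGETS, rtol=0.05)


def test_write_dataset_round_trip(tmp_path):
    from phenoyield.simulate import write_dataset

    ds = generate_dataset(SyntheticConfig(n_plots=8, seed=5))
    write_dataset(ds, tmp_path)
    table = pd.read_csv(tmp_path / "plot_table.csv")
    assert len(table) == 8
    feats = pd.read_csv(tmp_path / "features_lidar.csv")
    assert len(feats) == 8 * 7
    assert (tmp_path / "ground_truth.json").exists()
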