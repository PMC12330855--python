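import numpy as np
import pytest

from vasculomap.relaxometry import delta_r2star, fit_r2star
from vasculomap.synthetic import (LABELS, ParcelTableSpec, PhantomSpec,
                                  SyntheticBundleSpec, depth_model_curve,
                                  make_bundles, make_cortical_phantom,
                                  make_parcel_table, make_stepwise_dataset)
from vasculomap.tracts import clean_bundle


class TestPhantomSpec:
    def test_b0_normalized(self):
        spec = PhantomSpec(b0_direction=(0, 0, 2.0))
        assert np.allclose(spec.b0_direction, (0, 0, 1))

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(voxel_size_mm=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(b0_direction=(0, 0, 0))
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(tissue_r2star_pre={"gm": -5.0, "swm": 25.0,
                                           "deep_wm": 20.0})


class TestMakeCorticalPhantom:
    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            make_cortical_phantom(PhantomSpec(grid_shape=(16, 16, 64)))

    def test_no_vessels_post_equals_pre(self):
        ph = make_cortical_phantom(PhantomSpec(
            seed=2, vessel_density_gm=0.0, vessel_density_swm=0.0,
            noise_sd=0.0))
        for pre, post in zip(ph.pre_echoes.echoes, ph.post_echoes.echoes):
            assert np.array_equal(pre, post)
        assert not ph.vessel_mask.any()
        assert np.allclose(ph.true_delta_r2star, 0.0)

    def test_flat_sheet_tangential_vessels_orthogonal_to_b0(self):
        # flat sheet, b0 along z: every tangential vessel has cos2 = 0
        ph = make_cortical_phantom(PhantomSpec(
            seed=3, fold_amplitude_mm=0.0, vessel_density_gm=0.0,
            vessel_density_swm=0.9, b0_direction=(0, 0, 1)))
        m = ph.vessel_mask
        assert m.any()
        cos2 = (ph.vessel_orientations[m] @ np.array([0, 0, 1.0])) ** 2
        assert np.allclose(cos2, 0.0, atol=1e-20)

    def test_vessels_inside_tissue(self, default_phantom):
        ph = default_phantom
        assert not (ph.vessel_mask & (ph.tissue_labels == LABELS["background"])).any()

    def test_true_delta_nonnegative(self, default_phantom):
        assert default_phantom.true_delta_r2star.min() >= 0.0

    def test_orientations_defined_on_vessel_mask(self, default_phantom):
        ph = default_phantom
        norms = np.linalg.norm(ph.vessel_orientations[ph.vessel_mask], axis=1)
        assert np.allclose(norms, 1.0)

    def test_orientation_ground_truth(self, default_phantom):
        ph = default_phantom
        m = ph.vessel_mask
        dots = np.abs((ph.vessel_orientations[m]
                       * ph.vessel_local_normals[m]).sum(axis=1))
        cls = ph.vessel_class[m]
        assert (cls > 0).all()
        assert (dots[cls == 1] > 0.99).all()  # radial gray-matter vessels
        assert (dots[cls == 2] < 0.01).all()  # tangential SWM vessels

    def test_noise_free_relaxometry_round_trip(self, default_phantom):
        ph = default_phantom
        mask = ph.tissue_labels > 0
        d = delta_r2star(fit_r2star(ph.post_echoes, mask=mask),
                         fit_r2star(ph.pre_echoes, mask=mask))
        assert np.nanmax(np.abs(d.delta[mask] - ph.true_delta_r2star[mask])) < 1e-8

    def test_seed_reproducibility(self):
        a = make_cortical_phantom(PhantomSpec(seed=11))
        b = make_cortical_phantom(PhantomSpec(seed=11))
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert np.array_equal(a.post_echoes.echoes[0], b.post_echoes.echoes[0])


class TestMakeBundles:
    def test_zero_noise_metrics_on_curve(self):
        spec = SyntheticBundleSpec(
            n_bundles=2, streamlines_per_bundle=8,
            node_noise_sd={"delta_r2star": 0.0, "odi": 0.0, "ndi": 0.0},
            seed=0)
        bs = make_bundles(spec)
        d = bs.meta["relative_distance"]
        for b in bs:
            for metric, params in spec.depth_models.items():
                expected = depth_model_curve(d, params)
                assert np.allclose(b.node_metrics[metric],
                                   expected[None, :], atol=1e-12)

    def test_paper_display_value_at_zero_distance(self):
        # ΔR2* model (11.64, 0.05, 19.13) evaluates to 30.77 at d = 0
        assert depth_model_curve(0.0, (11.64, 0.05, 19.13)) == pytest.approx(30.77)

    def test_planted_outliers_cleaned_exactly(self):
        spec = SyntheticBundleSpec(n_bundles=3, streamlines_per_bundle=20,
                                   outlier_fraction=0.1,
                                   outlier_displacement_sd=5.0, seed=9)
        bs = make_bundles(spec)
        for b in bs:
            planted = set(bs.meta["outlier_indices"][b.name].tolist())
            cleaned = clean_bundle(b)
            kept = {i for i, s in enumerate(b.streamlines)
                    if any(s is k for k in cleaned.streamlines)}
            removed = set(range(len(b.streamlines))) - kept
            assert removed == planted

    def test_metric_means_converge_to_curve(self):
        # law of large numbers: mean within 3 standard errors per node
        spec = SyntheticBundleSpec(n_bundles=1, streamlines_per_bundle=2000,
                                   node_noise_sd={"delta_r2star": 0.5},
                                   depth_models={"delta_r2star": (11.64, 0.05, 19.13)},
                                   seed=21)
        bs = make_bundles(spec)
        b = bs.bundles[0]
        d = bs.meta["relative_distance"]
        curve = depth_model_curve(d, (11.64, 0.05, 19.13))
        se = 0.5 / np.sqrt(2000)
        assert np.all(np.abs(b.node_metrics["delta_r2star"].mean(axis=0) - curve)
                      < 3 * se + 1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticBundleSpec(nodes_per_streamline=1)
        with pytest.raises(ValueError):
            SyntheticBundleSpec(node_noise_sd={"ndi": -0.1})
        with pytest.raises(ValueError):
            SyntheticBundleSpec(outlier_fraction=1.5)


class TestMakeParcelTable:
    def test_default_n_areas_103(self):
        df = make_parcel_table(ParcelTableSpec())
        assert len(df) == 103

    def test_identity_target_small_sample_correlations(self):
        df = make_parcel_table(ParcelTableSpec(n_areas=100_000, seed=0))
        cols = [c for c in df.columns if c != "area"]
        corr = df[cols].corr().to_numpy()
        off = corr[~np.eye(len(cols), dtype=bool)]
        assert np.all(np.abs(off) < 0.01)

    def test_target_correlation_recovered_fisher_z(self):
        # 1000 replicates of n=103: mean r within the Fisher-z SE of 0.5
        target = np.eye(4)
        target[0, 2] = target[2, 0] = 0.5  # ΔR2* vs receptor
        rs = []
        for seed in range(1000):
            df = make_parcel_table(ParcelTableSpec(
                target_correlations=target, seed=seed))
            rs.append(np.corrcoef(df["delta_r2star"], df["receptor"])[0, 1])
        se_fisher = 1.0 / np.sqrt(103 - 3)
        r_band = np.tanh(np.arctanh(0.5) + np.array([-se_fisher, se_fisher]))
        assert r_band[0] < np.mean(rs) < r_band[1]

    def test_non_psd_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[1, 2] = bad[2, 1] = 0.9
        bad[0, 2] = bad[2, 0] = -0.9
        with pytest.raises(ValueError, match="positive semidefinite"):
            make_parcel_table(ParcelTableSpec(target_correlations=bad))

    def test_asymmetric_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            make_parcel_table(ParcelTableSpec(target_correlations=bad))

    def test_means_and_sds_applied(self):
        df = make_parcel_table(ParcelTableSpec(n_areas=50_000, seed=1))
        spec = ParcelTableSpec()
        for m in spec.metrics:
            assert df[m].mean() == pytest.approx(spec.means[m],
                                                 abs=0.02 * spec.sds[m])
            assert df[m].std() == pytest.approx(spec.sds[m], rel=0.02)


class TestMakeStepwiseDataset:
    def test_columns_and_size(self):
        df = make_stepwise_dataset(n_bundles=4, nodes_per_bundle=10, seed=0)
        assert len(df) == 40
        assert {"bundle", "node", "relative_distance", "ndi", "odi",
                "delta_r2star"} <= set(df.columns)

    def test_noise_free_response_deterministic(self):
        df = make_stepwise_dataset(noise_sd=0.0, predictor_noise_sd=0.0, seed=0)
        d = df["relative_distance"].to_numpy()
        expected = (20.0 - 20.0 * df["ndi"] + 25.0 * df["odi"]
                    + 10.0 * np.exp(-0.05 * d))
        assert np.allclose(df["delta_r2star"], expected)
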