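import numpy as np
import pytest

from marshcover.geometry import GsdModel, default_design
from marshcover.raster import BARREN, NONSHRUB, SHRUB
from marshcover.synthetic import (
    SHADOW_FACTOR,
    SceneSpec,
    generate_truth_map,
    render_rgb,
    resample_nearest,
    shadow_mask,
    simulate_study,
)


class TestTruthMap:
    def test_degenerate_all_barren(self):
        spec = SceneSpec(seed=0, gsd_m=0.5, target_props=(1.0, 0.0, 0.0))
        truth = generate_truth_map(spec, (50.0, 50.0))
        assert np.all(truth.data == BARREN)

    def test_realized_proportions_track_targets(self):
        # 1000 x 1000 px scene at default marsh composition
        spec = SceneSpec(seed=1, gsd_m=0.1, target_props=(0.755, 0.035, 0.210))
        truth = generate_truth_map(spec, (100.0, 100.0))
        assert truth.data.shape == (1000, 1000)
        props = truth.class_proportions()
        np.testing.assert_allclose(props, (0.755, 0.035, 0.210), atol=0.02)

    def test_deterministic_given_seed(self):
        spec = SceneSpec(seed=7, gsd_m=0.25)
        a = generate_truth_map(spec, (60.0, 40.0))
        b = generate_truth_map(spec, (60.0, 40.0))
        assert np.array_equal(a.data, b.data)

    def test_proportion_fidelity_across_seeds(self):
        # generator contract: within +/-0.02 per class on large scenes
        for seed in range(20):
            spec = SceneSpec(seed=seed, gsd_m=0.1)
            props = generate_truth_map(spec, (100.0, 100.0)).class_proportions()
            np.testing.assert_allclose(props, spec.target_props, atol=0.02)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="zero pixels"):
            generate_truth_map(SceneSpec(seed=0, gsd_m=0.5), (0.0, 50.0))

    def test_correlation_length_must_resolve(self):
        with pytest.raises(ValueError, match="corr_length"):
            generate_truth_map(SceneSpec(seed=0, gsd_m=4.0, spatial_corr_length_m=6.0), (100.0, 100.0))

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SceneSpec(seed=0, target_props=(0.5, 0.2, 0.2))


class TestRenderRGB:
    def test_noiseless_disjoint_means_render_exactly(self):
        spec = SceneSpec(seed=0, gsd_m=0.5, confusability=0.0, noise_sd=0.0,
                         shadow_fraction=0.0, dark_soil_fraction=0.0)
        truth = generate_truth_map(spec, (50.0, 50.0))
        rgb = render_rgb(truth, spec)
        for c, mean in spec.class_means.items():
            m = truth.data == c
            if m.any():
                assert np.all(rgb.data[m] == np.rint(mean).astype(np.uint8))

    def test_full_confusability_merges_nonshrub_into_dark_soil(self):
        spec = SceneSpec(seed=0, confusability=1.0)
        means = spec.effective_means()
        np.testing.assert_array_equal(means[NONSHRUB], spec.dark_soil_mean)

    def test_shadow_mask_covers_stated_fraction_of_adjacent_zone(self):
        spec = SceneSpec(seed=7, gsd_m=0.2, shadow_fraction=0.1)
        truth = generate_truth_map(spec, (250.0, 250.0))
        rng = np.random.default_rng(7)
        mask = shadow_mask(truth, spec, rng)
        shrub = truth.data == SHRUB
        adjacent = np.zeros_like(shrub)
        adjacent[:-1, :] = shrub[1:, :]
        adjacent &= ~shrub
        frac = mask.sum() / adjacent.sum()
        assert frac == pytest.approx(0.1, rel=0.1)

    def test_shadow_darkens_pixels(self):
        spec = SceneSpec(seed=3, gsd_m=0.25, shadow_fraction=0.3, noise_sd=0.0)
        truth = generate_truth_map(spec, (50.0, 50.0))
        rgb = render_rgb(truth, spec)
        rng = np.random.default_rng(spec.seed)
        # consume the same rng draws as render_rgb does before shadows
        for c in (BARREN, NONSHRUB, SHRUB):
            n = int((truth.data == c).sum())
            if n:
                rng.standard_normal((n, 3))
                if c == BARREN:
                    rng.random(n)
        mask = shadow_mask(truth, spec, rng)
        means = spec.effective_means()
        shadowed_barren = mask & (truth.data == BARREN)
        if shadowed_barren.any():
            expect = np.clip(np.rint(np.asarray(means[BARREN]) * SHADOW_FACTOR), 0, 255)
            got = rgb.data[shadowed_barren]
            # non-dark-soil shadowed barren pixels match the darkened mean
            assert np.any(np.all(got == expect.astype(np.uint8), axis=1))


class TestMonotoneDifficulty:
    def test_mean_accuracy_non_increasing_in_confusability(self):
        """More non-shrub <-> dark-soil spectral overlap can only make the
        downstream classification worse on average (10 seeds, fixed
        classifier settings)."""
        from marshcover.classify import fit_clusters, reclassify_clusters

        mean_oa = []
        for c in (0.0, 0.5, 1.0):
            oas = []
            for seed in range(10):
                spec = SceneSpec(seed=seed, gsd_m=0.25, confusability=c, shadow_fraction=0.0,
                                 spatial_corr_length_m=3.0, noise_sd=8.0)
                truth = generate_truth_map(spec, (60.0, 60.0))
                rgb = render_rgb(truth, spec)
                model = fit_clusters(rgb, K=10, seed=seed)
                mapped = reclassify_clusters(model, rgb, reference=truth)
                oas.append(np.mean(mapped.data == truth.data))
            mean_oa.append(np.mean(oas))
        assert mean_oa[0] >= mean_oa[1] >= mean_oa[2]


class TestStudySimulation:
    def test_paper_calibrated_gsds(self):
        from marshcover.geometry import gsd_at_altitude
        model = GsdModel.calibrate(100.0, 3.2)
        got = [gsd_at_altitude(model, a)[1] for a in (75, 100, 120)]
        assert got == [2.4, 3.2, 3.8]

    def test_identity_resample(self, tiny_truth):
        out = resample_nearest(tiny_truth, tiny_truth.gsd_m)
        assert np.array_equal(out.data, tiny_truth.data)

    def test_coarser_gsd_quarters_pixel_count(self, tiny_truth):
        out = resample_nearest(tiny_truth, 2 * tiny_truth.gsd_m)
        ratio = tiny_truth.data.size / out.data.size
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_same_truth_across_altitudes(self, tiny_design):
        spec = SceneSpec(seed=5, gsd_m=0.5, spatial_corr_length_m=4.0)
        scenes = simulate_study(spec, tiny_design, [75.0, 100.0], GsdModel(k=1.0 / 150.0))
        a = scenes[75.0].truth  # 0.5 m — native resolution
        b = resample_nearest(a, scenes[100.0].truth.gsd_m)
        assert np.array_equal(b.data, scenes[100.0].truth.data)

    def test_negative_altitude_rejected(self, tiny_design):
        with pytest.raises(ValueError):
            simulate_study(SceneSpec(seed=0, gsd_m=0.5), tiny_design, [-10.0])

    def test_scene_determinism(self, tiny_design):
        spec = SceneSpec(seed=9, gsd_m=0.5, spatial_corr_length_m=4.0)
        s1 = simulate_study(spec, tiny_design, [100.0], GsdModel(k=0.005))
        s2 = simulate_study(spec, tiny_design, [100.0], GsdModel(k=0.005))
        assert np.array_equal(s1[100.0].rgb.data, s2[100.0].rgb.data)
        assert np.array_equal(s1[100.0].truth.data, s2[100.0].truth.data)
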