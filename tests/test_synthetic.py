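import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from invquant import synthetic as syn


class TestRushGenerator:
    def test_logistic_midpoint_identity(self):
        # noiseless trace sampled exactly at x_half must sit at (y0+ymax)/2
        cfg = syn.SynthConfig(seed=0, noise_sd=0.0, frame_interval=2.0,
                              n_samples=40)
        tr = syn.gen_rush_trace(0.05, 0.6, 20.0, 6.0, -0.01, cfg)
        i = np.flatnonzero(tr.times == 20.0)[0]
        assert tr.values[i] == pytest.approx((0.05 + 0.6) / 2, abs=1e-12)

    def test_deterministic_under_seed(self):
        cfg = syn.SynthConfig(seed=9, noise_sd=0.05, frame_interval=2.0,
                              n_samples=40)
        a = syn.gen_rush_trace(0.05, 0.6, 20.0, 6.0, -0.01, cfg)
        b = syn.gen_rush_trace(0.05, 0.6, 20.0, 6.0, -0.01, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_residual_sd_matches_noise(self):
        # oracle: direct residuals against the stored noiseless model
        resid = []
        for seed in range(1000):
            cfg = syn.SynthConfig(seed=seed, noise_sd=0.01,
                                  frame_interval=2.0, n_samples=40)
            tr = syn.gen_rush_trace(0.05, 0.6, 20.0, 6.0, -0.01, cfg)
            resid.append(tr.values - tr.meta["ground_truth"]["noiseless"])
        sd = np.std(np.concatenate(resid))
        assert abs(sd - 0.01) / 0.01 < 0.05

    @pytest.mark.parametrize("bad", [
        dict(x_half=-1.0), dict(x_half=0.0), dict(n=0.0), dict(n=-2.0),
    ])
    def test_invalid_parameters(self, bad):
        cfg = syn.SynthConfig(seed=0)
        kwargs = dict(y0=0.05, ymax=0.6, x_half=20.0, n=6.0,
                      decay_slope=-0.01)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            syn.gen_rush_trace(cfg=cfg, **kwargs)

    def test_decline_after_peak(self):
        cfg = syn.SynthConfig(seed=0, noise_sd=0.0, frame_interval=2.0,
                              n_samples=60)
        tr = syn.gen_rush_trace(0.05, 0.6, 20.0, 6.0, -0.01, cfg)
        tail = tr.values[tr.times > tr.meta["ground_truth"]["t_peak"]]
        assert np.all(np.diff(tail) < 0)


class TestExponentialGenerator:
    def test_value_at_tau(self, cfg):
        tr = syn.gen_exponential_trace(0.5, 2.0, [10.0], [1.0], None, cfg)
        i = np.flatnonzero(tr.times == 10.0)[0]
        assert tr.values[i] == pytest.approx(0.5 + 2.0 * (1 - np.exp(-1)),
                                             abs=1e-12)

    def test_no_bleach_reference_constant(self, cfg):
        tr = syn.gen_exponential_trace(0.5, 2.0, [10.0], [1.0], None, cfg)
        np.testing.assert_allclose(tr.reference, 1.0)

    def test_two_tau_closed_form(self, cfg):
        # oracle: direct evaluation of the two-component sum
        tr = syn.gen_exponential_trace(0.0, 1.0, [2.0, 40.0], [0.2, 0.8],
                                       None, cfg)
        t = tr.times
        expected = 0.2 * (1 - np.exp(-t / 2.0)) + 0.8 * (1 - np.exp(-t / 40.0))
        assert np.max(np.abs(tr.values - expected)) < 1e-12

    def test_mismatched_lengths(self, cfg):
        with pytest.raises(ValueError, match="equal length"):
            syn.gen_exponential_trace(0.0, 1.0, [2.0, 40.0], [1.0], None, cfg)

    def test_fractions_must_sum_to_one(self, cfg):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.gen_exponential_trace(0.0, 1.0, [2.0, 40.0], [0.5, 0.4],
                                      None, cfg)

    def test_bleach_envelope_applied(self, cfg):
        tr = syn.gen_exponential_trace(0.5, 2.0, [10.0], [1.0], 100.0, cfg)
        envelope = np.exp(-tr.times / 100.0)
        np.testing.assert_allclose(tr.reference, envelope, rtol=1e-12)
        clean = tr.meta["ground_truth"]["noiseless"]
        np.testing.assert_allclose(tr.values, clean * envelope, rtol=1e-12)


class TestEmSceneGenerator:
    def test_no_vesicles(self):
        scene = syn.gen_em_scene(0, 30.0, 9.4, None, 1.0, 1.0,
                                 syn.SynthConfig(seed=0))
        assert scene.vesicle_contours == []
        assert len(scene.mito_contours) == 1

    def test_diameter_distribution(self):
        # oracle: sample statistics of the stored ground truth
        scene = syn.gen_em_scene(500, 30.0, 9.4, None, 0.0, 1.0,
                                 syn.SynthConfig(seed=11))
        d = np.array(scene.ground_truth["diameters_nm"])
        assert len(d) == 500
        se = 9.4 / np.sqrt(500)
        assert abs(d.mean() - 30.0) < 3 * se

    def test_capture_contract(self):
        scene = syn.gen_em_scene(25, 30.0, 5.0, None, 1.0, 1.0,
                                 syn.SynthConfig(seed=3))
        mito = scene.mito_contours[0][:, :2] * scene.scale
        ring = LineString(np.vstack([mito, mito[:1]]))
        for contour in scene.vesicle_contours:
            poly = Polygon(contour[:, :2] * scene.scale)
            assert poly.exterior.distance(ring) <= 15.0 + 1e-6

    def test_far_vesicles_kept_away(self):
        scene = syn.gen_em_scene(25, 30.0, 5.0, None, 0.0, 1.0,
                                 syn.SynthConfig(seed=3))
        mito = scene.mito_contours[0][:, :2] * scene.scale
        ring = LineString(np.vstack([mito, mito[:1]]))
        for contour in scene.vesicle_contours:
            poly = Polygon(contour[:, :2] * scene.scale)
            assert poly.exterior.distance(ring) >= 100.0 - 1e-6

    def test_vesicle_polygons_have_enough_vertices(self, small_scene):
        for contour in small_scene.vesicle_contours:
            assert len(contour) >= 16

    def test_deterministic(self):
        a = syn.gen_em_scene(10, 30.0, 5.0, None, 0.5, 1.0,
                             syn.SynthConfig(seed=5))
        b = syn.gen_em_scene(10, 30.0, 5.0, None, 0.5, 1.0,
                             syn.SynthConfig(seed=5))
        for ca, cb in zip(a.vesicle_contours, b.vesicle_contours):
            np.testing.assert_array_equal(ca, cb)


class TestLocalizationGenerator:
    def test_argmax_at_center_without_noise(self):
        img = syn.gen_localization_image(1, 20.0, 16.0, (2.0, 2.0), 500.0,
                                         syn.SynthConfig(seed=0),
                                         poisson_noise=False)
        (cx, cy), = img.meta["ground_truth"]["centers_px"]
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert abs(ix - cx) <= 0.5 + 1e-9
        assert abs(iy - cy) <= 0.5 + 1e-9

    def test_density_placement_arithmetic(self):
        # 26.8 spots per 10 um^2 over a 100 um^2 field
        assert syn.spots_for_density(26.8, (10.0, 10.0)) == 268

    def test_total_counts_within_poisson_error(self):
        n_spots, counts = 50, 400.0
        img = syn.gen_localization_image(n_spots, 20.0, 16.0, (10.0, 10.0),
                                         counts, syn.SynthConfig(seed=2))
        total = img.pixels.sum()
        expected = n_spots * counts
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_separation_contract(self):
        img = syn.gen_localization_image(80, 20.0, 16.0, (10.0, 10.0), 400.0,
                                         syn.SynthConfig(seed=4))
        centers = np.array(img.meta["ground_truth"]["centers_nm"])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        assert d.min() >= 6 * 20.0

    def test_field_too_small(self):
        with pytest.raises(RuntimeError, match="too small"):
            syn.gen_localization_image(500, 30.0, 16.0, (2.0, 2.0), 400.0,
                                       syn.SynthConfig(seed=0))


class TestFlickerGenerator:
    def test_uniform_zero_noise_flat(self):
        stack, _ = syn.gen_flicker_stack("uniform", 30, 50, 3.0,
                                         syn.SynthConfig(seed=0),
                                         shot_noise=False)
        assert np.ptp(stack) == 0.0

    def test_same_seed_identical(self):
        a, _ = syn.gen_flicker_stack("vesicles", 10, 50, 3.0,
                                     syn.SynthConfig(seed=6))
        b, _ = syn.gen_flicker_stack("vesicles", 10, 50, 3.0,
                                     syn.SynthConfig(seed=6))
        np.testing.assert_array_equal(a, b)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            syn.gen_flicker_stack("sparkle", 10, 50, 3.0,
                                  syn.SynthConfig(seed=0))

    def test_matched_mean_intensity(self):
        u, _ = syn.gen_flicker_stack("uniform", 30, 50, 3.0,
                                     syn.SynthConfig(seed=1))
        v, _ = syn.gen_flicker_stack("vesicles", 30, 50, 3.0,
                                     syn.SynthConfig(seed=1))
        assert abs(u.mean() - v.mean()) / u.mean() < 0.05


class TestScreenGenerator:
    def test_deterministic(self):
        spec = {"GFP": 1.0, "A": 1.8}
        a = syn.gen_screen_table(spec, 10, 2, 0.2, syn.SynthConfig(seed=8))
        b = syn.gen_screen_table(spec, 10, 2, 0.2, syn.SynthConfig(seed=8))
        assert a.equals(b)

    def test_fold_change_recovery(self):
        table = syn.gen_screen_table({"GFP": 1.0, "A": 2.5}, 200, 3, 0.2,
                                     syn.SynthConfig(seed=9))
        ratios = table.loc[table.construct == "A", "F_post"] / \
            table.loc[table.construct == "A", "F_pre"]
        # lognormal(0, 0.2) has mean exp(0.02); allow for that small bias
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 2.5 * np.exp(0.02)) < 3 * se

    def test_null_fold_centered_on_zero(self):
        table = syn.gen_screen_table({"GFP": 1.0, "A": 1.0}, 300, 3, 0.2,
                                     syn.SynthConfig(seed=10))
        ra = table.loc[table.construct == "A", "F_post"] / \
            table.loc[table.construct == "A", "F_pre"]
        rg = table.loc[table.construct == "GFP", "F_post"] / \
            table.loc[table.construct == "GFP", "F_pre"]
        diff = ra.mean() - rg.mean()
        se = np.sqrt(ra.var() / len(ra) + rg.var() / len(rg))
        assert abs(diff) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            syn.gen_screen_table({"GFP": 1.0, "A": -1.0}, 10, 2, 0.2,
                                 syn.SynthConfig(seed=0))
        with pytest.raises(ValueError):
            syn.gen_screen_table({"GFP": 1.0}, 2, 1, 0.2,
                                 syn.SynthConfig(seed=0))


class TestConfigValidation:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            syn.SynthConfig(seed=0, noise_sd=-0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            syn.SynthConfig(seed=0, n_samples=1)
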