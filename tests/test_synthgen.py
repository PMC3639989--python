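"""Generator-side checks: activity field, nucleus layout, rendering,
cohorts, determinism and IO."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit

from introndot import (
    SynthConfig,
    make_activity_field,
    make_cohort,
    render_intensity_channel,
    render_midsagittal,
    render_surface,
    sample_nuclei,
)
from introndot.synthgen import load_surface_stack, save_embryo

from conftest import noise_free, small_config


class TestActivityField:
    def test_plateau_saturation_and_midpoint(self):
        cfg = SynthConfig()
        cfg.activity_profile.stripe_amp = 0.0
        q = make_activity_field(cfg)
        # far anterior of the boundary the logistic saturates at q_plat
        assert q(0.05) == pytest.approx(cfg.activity_profile.q_plat, abs=1e-6)
        # expected dots/nucleus on the plateau: allele_count * q_plat
        assert 2 * q(0.05) == pytest.approx(1.0, abs=1e-5)
        assert q(cfg.activity_profile.x_b) == pytest.approx(
            cfg.activity_profile.q_plat / 2.0, abs=1e-12
        )

    def test_stripe_adds_gaussian_on_top_of_logistic(self):
        cfg = SynthConfig()
        p = cfg.activity_profile
        p.stripe_amp, p.stripe_center = 0.3, 0.62
        q = make_activity_field(cfg)
        base = p.q_plat * expit((p.x_b - 0.62) / p.w)
        assert q(0.62) - base == pytest.approx(0.3, abs=1e-9)

    def test_overflow_warns_and_clips(self):
        cfg = SynthConfig()
        cfg.activity_profile.q_plat = 0.9
        cfg.activity_profile.stripe_amp = 0.9
        cfg.activity_profile.stripe_center = 0.3
        with pytest.warns(UserWarning, match="clipping"):
            q = make_activity_field(cfg)
        assert np.all(q(np.linspace(0, 1, 501)) <= 1.0)

    @pytest.mark.parametrize(
        "field,value", [("q_plat", 1.5), ("x_b", 0.0), ("w", -1.0)]
    )
    def test_invalid_profile_rejected(self, field, value):
        cfg = SynthConfig()
        setattr(cfg.activity_profile, field, value)
        with pytest.raises(ValueError):
            make_activity_field(cfg)


class TestNucleusLayout:
    def test_surface_counts_match_capture_ranges(self):
        # one imaged surface holds about half of the periphery total
        cfg = SynthConfig()
        n14 = sample_nuclei(cfg, "14A", 1).n_nuclei
        n13 = sample_nuclei(cfg, "13", 1).n_nuclei
        assert 1530 <= n14 <= 2463
        assert 787 <= n13 <= 1296

    def test_silent_genome_yields_no_dots(self):
        cfg = small_config()
        cfg.activity_profile.q_plat = 0.0
        cfg.activity_profile.stripe_amp = 0.0
        cfg.false_dot_rate = 0.0
        gt = sample_nuclei(cfg, "14A", 0)
        assert (gt.nuclei.true_dot_count == 0).all()
        assert (gt.nuclei.true_false_dots == 0).all()

    def test_overpacked_density_rejected(self):
        cfg = small_config()
        cfg.nucleus_density = {k: 2.0 for k in cfg.nucleus_density}
        with pytest.raises(ValueError, match="packing"):
            sample_nuclei(cfg, "14A", 0)

    def test_positions_inside_embryo_and_fractional(self):
        gt = sample_nuclei(small_config(), "13", 3)
        assert gt.nuclei.x_over_L.between(0, 1, inclusive="left").all()
        cx, cy = gt.center_px
        a, b = gt.semi_axes_px
        r = ((gt.nuclei.cx - cx) / a) ** 2 + ((gt.nuclei.cy - cy) / b) ** 2
        assert (r <= 1.0).all()

    def test_dot_counts_follow_binomial_on_plateau(self):
        # chi-square against Binomial(2, q_plat) over >=2000 plateau nuclei
        cfg = SynthConfig()
        cfg.activity_profile.x_b = 0.95  # whole surface on the plateau
        cfg.activity_profile.stripe_amp = 0.0
        import pandas as pd

        nuclei = pd.concat(
            [sample_nuclei(cfg, "14A", s).nuclei for s in (12, 13)]
        )
        sub = nuclei[nuclei.x_over_L < 0.85]
        assert len(sub) >= 2000
        obs = np.bincount(sub.true_dot_count, minlength=3)
        q = cfg.activity_profile.q_plat
        exp = len(sub) * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert sps.chi2.sf(chi2, df=2) > 0.01

    def test_empirical_mean_matches_binomial_mean(self):
        cfg = SynthConfig()
        cfg.activity_profile.stripe_amp = 0.0
        gt = sample_nuclei(cfg, "14A", 2)
        plat = gt.nuclei[gt.nuclei.x_over_L < 0.40]
        q = cfg.activity_profile.q_plat
        se = np.sqrt(2 * q * (1 - q) / len(plat))
        assert plat.true_dot_count.mean() == pytest.approx(2 * q, abs=3 * se)


class TestSurfaceRender:
    def test_noise_free_blank_is_flat_background(self):
        cfg = noise_free(small_config())
        cfg.activity_profile.q_plat = 0.0
        cfg.activity_profile.stripe_amp = 0.0
        cfg.false_dot_rate = 0.0
        gt = sample_nuclei(cfg, "14A", 0)
        imgset = render_surface(gt, cfg, 0)
        assert np.allclose(imgset.signal, cfg.noise.background_mean)

    def test_single_dot_has_at_least_three_pixels_at_half_peak(self):
        cfg = noise_free(small_config())
        cfg.false_dot_rate = 0.0
        gt = sample_nuclei(cfg, "14A", 1)
        imgset = render_surface(gt, cfg, 1)
        proj = imgset.signal.max(axis=0) - cfg.noise.background_mean
        for row in gt.dots.head(20).itertuples():
            x, y = int(round(row.x)), int(round(row.y))
            patch = proj[y - 4 : y + 5, x - 4 : x + 5]
            assert (patch > patch.max() / 2).sum() >= 3

    def test_dots_rendered_inside_their_nucleus(self):
        cfg = small_config()
        gt = sample_nuclei(cfg, "14A", 2)
        render_surface(gt, cfg, 2)
        nuc = gt.nuclei.set_index("label")
        d = gt.dots
        dx = d.x.to_numpy() - nuc.loc[d.nucleus_label, "cx"].to_numpy()
        dy = d.y.to_numpy() - nuc.loc[d.nucleus_label, "cy"].to_numpy()
        assert (np.hypot(dx, dy) <= nuc.loc[d.nucleus_label, "radius_px"].to_numpy() + 1e-9).all()

    def test_intensities_nonnegative(self, small_embryo):
        _, _, imgset = small_embryo
        assert imgset.surface.min() >= 0

    def test_seed_determinism_bit_for_bit(self):
        outs = []
        for _ in range(2):
            cfg = small_config()
            rng = np.random.default_rng(99)
            gt = sample_nuclei(cfg, "14A", rng)
            outs.append(render_surface(gt, cfg, rng).surface.tobytes())
        assert outs[0] == outs[1]


class TestMidsagittal:
    def test_height_model_intercept_and_doubling(self):
        cfg = small_config()
        _, tr0 = render_midsagittal(cfg, 0.0, 0)
        _, tr15 = render_midsagittal(cfg, 15.0, 0)
        assert tr0.true_height == pytest.approx(cfg.height_model.h0)
        assert tr15.true_height == pytest.approx(2 * cfg.height_model.h0)

    @pytest.mark.parametrize("t", [-1.0, 25.0])
    def test_time_out_of_range_rejected(self, t):
        with pytest.raises(ValueError, match="time_min"):
            render_midsagittal(SynthConfig(), t, 0)


class TestIntensityChannels:
    def test_flat_gradient_in_long_decay_limit(self):
        cfg = noise_free(small_config())
        cfg.gradient.lam = 1e6
        img = render_intensity_channel(cfg, "bcd", noise=False)
        g = cfg.gradient
        inside = img > 0
        assert np.allclose(img[inside], g.b_max + g.offset, rtol=1e-5)

    def test_exponential_decay_identity(self):
        # intensity(lam) / intensity(0) = 1/e when offset = 0
        cfg = noise_free(small_config())
        cfg.gradient.offset = 0.0
        img = render_intensity_channel(cfg, "bcd", noise=False)
        cx, cy = cfg.center_px
        a, _ = cfg.semi_axes_px
        x0 = int(round(cx - a + 1))
        x1 = int(round(cx - a + cfg.gradient.lam * 2 * a))
        x_at = lambda px: (px - (cx - a)) / (2 * a)
        expected = np.exp(-(x_at(x1) - x_at(x0)) / cfg.gradient.lam)
        assert img[int(cy), x1] / img[int(cy), x0] == pytest.approx(expected, rel=1e-4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            render_intensity_channel(SynthConfig(), "protein")


class TestCohorts:
    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_cohort({}, 4, 0)

    def test_zero_embryos_gives_empty_cohort(self):
        assert make_cohort({"t1": {"q_plat": 0.2}}, 0, 0) == []

    def test_bad_class_label_rejected(self):
        with pytest.raises(ValueError):
            make_cohort({"x3": {}}, 1, 0)

    def test_cohort_determinism(self):
        base = small_config()
        a = make_cohort({"t1": {"q_plat": 0.3}}, 2, 7, base_cfg=base)
        b = make_cohort({"t1": {"q_plat": 0.3}}, 2, 7, base_cfg=base)
        ia, _ = a[1].render()
        ib, _ = b[1].render()
        assert ia.surface.tobytes() == ib.surface.tobytes()

    def test_times_jittered_within_class_window(self):
        sims = make_cohort({"t3": {"q_plat": 0.5}}, 16, 3, base_cfg=small_config())
        times = np.array([s.time_min for s in sims])
        assert np.all(np.abs(times - 2.5) <= 0.35 + 1e-9)


class TestDiskIO:
    def test_tiff_roundtrip(self, tmp_path, small_embryo):
        cfg, gt, imgset = small_embryo
        save_embryo(imgset, gt, tmp_path)
        back = load_surface_stack(tmp_path / "surface.tif")
        assert back.shape == imgset.surface.shape
        assert np.array_equal(back, imgset.surface)
        assert (tmp_path / "nuclei_truth.csv").exists()
        assert (tmp_path / "truth.json").exists()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = small_config()
        cfg.activity_profile.q_plat = 0.4321
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SynthConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
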