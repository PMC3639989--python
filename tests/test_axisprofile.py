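"""AP-axis profiles: binning, boundary, plateau, peak and maximum."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from introndot import (
    AxisProfile,
    bin_intensity,
    bin_rho,
    bmax,
    find_boundary,
    peak_stat,
    plateau_stat,
)
from introndot.axisprofile import ProfileError
from introndot.segmentation import AxisFrame

from conftest import noise_free, small_config


def make_profile(values, kind="rho"):
    v = np.asarray(values, dtype=float)
    return AxisProfile(
        values=v, n_per_bin=(~np.isnan(v)).astype(int) * 10, kind=kind
    )


def logistic_profile(x_mid, width, n_bins=50):
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return make_profile(expit((x_mid - centers) / width))


class TestBinRho:
    def test_empty_table_gives_all_missing(self):
        prof = bin_rho(pd.DataFrame(columns=["x_over_L", "dot_count"]))
        assert np.isnan(prof.values).all()
        assert prof.n_per_bin.sum() == 0

    def test_single_position_fills_single_bin(self):
        table = pd.DataFrame(
            {"x_over_L": np.full(100, 0.255), "dot_count": np.full(100, 2)}
        )
        prof = bin_rho(table)
        assert prof.values[12] == 2.0  # bin [0.24, 0.26)
        assert prof.n_per_bin[12] == 100
        others = np.delete(prof.values, 12)
        assert np.isnan(others).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "x_over_L": rng.uniform(0, 1, 500),
                "dot_count": rng.integers(0, 3, 500),
            }
        )
        prof = bin_rho(table)
        oracle = table.groupby(np.floor(table.x_over_L * 50).astype(int))[
            "dot_count"
        ].mean()
        for b in range(50):
            if b in oracle.index:
                assert prof.values[b] == pytest.approx(oracle[b])
            else:
                assert np.isnan(prof.values[b])

    def test_conservation_of_nucleus_count(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"x_over_L": rng.uniform(0, 1, 321), "dot_count": np.zeros(321)}
        )
        assert bin_rho(table).n_per_bin.sum() == 321


def analytic_axis(cfg):
    """AxisFrame matching the generator's continuous x/L mapping."""
    cx, cy = cfg.center_px
    a, b = cfg.semi_axes_px
    return AxisFrame(
        anterior_pole_px=(cx - a, cy),
        posterior_pole_px=(cx + a, cy),
        L_px=2 * a,
        unit=(1.0, 0.0),
        mask=None,
    )


class TestBinIntensity:
    def test_uniform_image_and_background_policies(self, small_cfg):
        from introndot import ellipse_mask

        cfg = small_cfg
        mask = ellipse_mask(cfg)
        img = np.full(cfg.image_shape, 7.0)
        axis = analytic_axis(cfg)
        prof = bin_intensity(img, axis, background="none", mask=mask)
        good = ~np.isnan(prof.values)
        assert np.allclose(prof.values[good], 7.0)
        prof0 = bin_intensity(img, axis, background=("constant", 7.0), mask=mask)
        assert np.allclose(prof0.values[~np.isnan(prof0.values)], 0.0)
        profm = bin_intensity(img, axis, background="min-bin", mask=mask)
        assert np.allclose(profm.values[~np.isnan(profm.values)], 0.0)

    def test_noise_free_exponential_matches_pixel_quadrature(self):
        # per-bin means equal an independent evaluation of the analytic
        # field over the same pixels, to 1e-6 relative
        from introndot import ellipse_mask, render_intensity_channel

        cfg = noise_free(small_config())
        cfg.gradient.offset = 0.0
        img = render_intensity_channel(cfg, "bcd", noise=False)
        mask = ellipse_mask(cfg)
        axis = analytic_axis(cfg)
        prof = bin_intensity(img, axis, mask=mask)

        cx, _ = cfg.center_px
        a, _ = cfg.semi_axes_px
        ys, xs = np.nonzero(mask)
        xl = np.clip((xs - (cx - a)) / (2 * a), 0, 1)
        f = cfg.gradient.b_max * np.exp(-xl / cfg.gradient.lam)
        idx = np.floor(np.clip(xl, 0, np.nextafter(1, 0)) * 50).astype(int)
        oracle = np.bincount(idx, weights=f, minlength=50) / np.bincount(
            idx, minlength=50
        )
        good = ~np.isnan(prof.values)
        rel = np.abs(prof.values[good] - oracle[good]) / oracle[good]
        assert rel.max() < 1e-6

    def test_bmax_on_noise_free_exponential(self):
        from introndot import ellipse_mask, render_intensity_channel
        from introndot.synthgen import binned_exponential_mean

        cfg = noise_free(small_config())
        cfg.gradient.offset = 0.0
        img = render_intensity_channel(cfg, "bcd", noise=False)
        prof = bin_intensity(
            img, analytic_axis(cfg), mask=ellipse_mask(cfg)
        )
        g = cfg.gradient
        # oracle: independent pixel-quadrature bin means of the analytic field
        cx, _ = cfg.center_px
        a, _ = cfg.semi_axes_px
        ys, xs = np.nonzero(ellipse_mask(cfg))
        xl = np.clip((xs - (cx - a)) / (2 * a), 0, 1)
        f = g.b_max * np.exp(-xl / g.lam)
        idx = np.floor(np.clip(xl, 0, np.nextafter(1, 0)) * 50).astype(int)
        with np.errstate(invalid="ignore"):
            oracle = np.bincount(idx, weights=f, minlength=50) / np.bincount(
                idx, minlength=50
            )
        assert bmax(prof) == pytest.approx(np.nanmax(oracle), rel=1e-6)
        # and the continuous bin average agrees to within the pixel grid
        first = int(np.flatnonzero(~np.isnan(prof.values))[0])
        assert bmax(prof) == pytest.approx(
            binned_exponential_mean(g.b_max, g.lam, 0.0, first), rel=0.02
        )


class TestFindBoundary:
    def test_step_profile_crosses_at_midpoint(self):
        vals = np.where((np.arange(50) + 0.5) / 50 < 0.5, 1.0, 0.0)
        b = find_boundary(make_profile(vals))
        assert b.x_hb == pytest.approx(0.5, abs=0.01)
        assert b.half_level == 0.5

    def test_flat_profile_has_no_boundary(self):
        with pytest.raises(ProfileError, match="no boundary"):
            find_boundary(make_profile(np.ones(50)))

    @settings(max_examples=40, deadline=None)
    @given(
        x_mid=st.floats(0.30, 0.55),
        width=st.floats(0.012, 0.06),
    )
    def test_matches_dense_grid_oracle_on_logistic(self, x_mid, width):
        prof = logistic_profile(x_mid, width)
        b = find_boundary(prof)
        # oracle: 10^4-point grid crossing of the same binned profile,
        # linearly interpolated between bin centres
        centers = prof.bin_centers
        grid = np.linspace(centers[0], centers[-1], 10_000)
        dense = np.interp(grid, centers, prof.values)
        win = (grid >= 0.05) & (grid <= 0.60)
        half = dense[win].max() / 2.0
        below = np.flatnonzero((dense < half) & (grid > x_mid - 0.2) & win)
        oracle = grid[below[0]]
        assert abs(b.x_hb - oracle) <= 0.005

    def test_shift_equivariance_one_bin(self):
        vals = expit((0.47 - (np.arange(50) + 0.5) / 50) / 0.02)
        b0 = find_boundary(make_profile(vals))
        shifted = np.roll(vals, 1)
        shifted[0] = vals[0]
        b1 = find_boundary(make_profile(shifted))
        assert b1.x_hb - b0.x_hb == pytest.approx(0.02, abs=1e-9)


class TestPlateauStat:
    def test_flat_profile_gives_constant(self):
        prof = make_profile(np.full(50, 0.8))
        b = find_boundary(logistic_profile(0.47, 0.02))
        assert plateau_stat(prof, b).value == pytest.approx(0.8)

    def test_window_placement_and_anterior_tie_break(self):
        # x_hb = 0.50: centres 0.39 and 0.41 are equidistant from 0.40;
        # the tie goes anterior, so the window is bins 15..19 (0-based)
        prof = make_profile(np.linspace(1, 50, 50))
        from introndot.axisprofile import BoundaryEstimate

        b = BoundaryEstimate(x_hb=0.50, half_level=0.5, max_level=1.0, crossing_bins=(24, 25))
        p = plateau_stat(prof, b)
        assert p.window_bins == (15, 16, 17, 18, 19)

    def test_window_never_reaches_the_boundary(self):
        prof = make_profile(np.ones(50))
        from introndot.axisprofile import BoundaryEstimate

        for x_hb in np.linspace(0.25, 0.6, 12):
            b = BoundaryEstimate(x_hb=float(x_hb), half_level=0.5, max_level=1.0, crossing_bins=(0, 1))
            p = plateau_stat(prof, b)
            assert max(p.window_bins) < x_hb * 50

    def test_missing_window_bin_rejected(self):
        vals = np.ones(50)
        vals[17] = np.nan
        prof = make_profile(vals)
        from introndot.axisprofile import BoundaryEstimate

        b = BoundaryEstimate(x_hb=0.50, half_level=0.5, max_level=1.0, crossing_bins=(24, 25))
        with pytest.raises(ProfileError, match="missing"):
            plateau_stat(prof, b)

    def test_window_too_anterior_rejected(self):
        prof = make_profile(np.ones(50))
        from introndot.axisprofile import BoundaryEstimate

        b = BoundaryEstimate(x_hb=0.05, half_level=0.5, max_level=1.0, crossing_bins=(1, 2))
        with pytest.raises(ProfileError, match="outside"):
            plateau_stat(prof, b)


class TestPeakStat:
    def test_single_bin_spike_averages_with_zero_neighbours(self):
        vals = np.zeros(50)
        vals[28] = 3.0
        p = peak_stat(make_profile(vals), (0.40, 0.75))
        assert p.value == pytest.approx(1.0)
        assert p.peak_bin == 28

    def test_flat_stripe_gives_stripe_value(self):
        p = peak_stat(make_profile(np.full(50, 0.7)), (0.40, 0.75))
        assert p.value == pytest.approx(0.7)

    def test_gaussian_stripe_matches_exhaustive_oracle(self):
        centers = (np.arange(50) + 0.5) / 50
        vals = 0.6 * np.exp(-((centers - 0.52) ** 2) / (2 * 0.05**2))
        prof = make_profile(vals)
        p = peak_stat(prof, (0.40, 0.75))
        # oracle: scan every admissible centre bin
        best, best_bin = -np.inf, None
        for b in range(50):
            if 0.40 <= centers[b] <= 0.75 and vals[b] > best:
                best, best_bin = vals[b], b
        assert p.peak_bin == best_bin
        assert p.value == pytest.approx(vals[best_bin - 1 : best_bin + 2].mean())

    def test_anterior_tie_break(self):
        vals = np.zeros(50)
        vals[25] = vals[30] = 2.0
        assert peak_stat(make_profile(vals), (0.40, 0.75)).peak_bin == 25

    def test_peak_with_missing_flank_rejected(self):
        vals = np.full(50, np.nan)
        vals[25] = 1.0
        vals[26] = 0.5
        vals[27] = 0.4
        with pytest.raises(ProfileError):
            peak_stat(make_profile(vals), (0.40, 0.60))


class TestBmax:
    def test_monotone_profile_takes_first_bin(self):
        vals = np.linspace(5, 1, 50)
        assert bmax(make_profile(vals, kind="intensity")) == 5.0

    def test_all_missing_rejected(self):
        with pytest.raises(ProfileError):
            bmax(make_profile(np.full(50, np.nan)))
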