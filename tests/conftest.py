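"""Shared fixtures: small fast embryos for unit tests, one full-size
rendered embryo for pipeline-level checks."""

from __future__ import annotations

import numpy as np
import pytest

from introndot import (
    SynthConfig,
    attach_axis,
    calibrate_threshold,
    fit_axis,
    render_surface,
    sample_nuclei,
    segment_nuclei,
)


def small_config(**overrides) -> SynthConfig:
    """A short embryo (L=360 px, ~250 cycle-14A nuclei) for fast tests."""
    cfg = SynthConfig(embryo_length_px=360, **overrides)
    return cfg


def noise_free(cfg: SynthConfig) -> SynthConfig:
    cfg.noise.background_sd = 0.0
    cfg.noise.photon_scale = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_embryo():
    """One small rendered embryo (with noise) plus its ground truth."""
    cfg = small_config()
    rng = np.random.default_rng(5)
    gt = sample_nuclei(cfg, "14A", rng)
    imgset = render_surface(gt, cfg, rng)
    return cfg, gt, imgset


@pytest.fixture(scope="session")
def small_embryo_clean():
    """Noise-free small embryo for exact recovery checks."""
    cfg = noise_free(small_config())
    rng = np.random.default_rng(6)
    gt = sample_nuclei(cfg, "14A", rng)
    imgset = render_surface(gt, cfg, rng)
    return cfg, gt, imgset


@pytest.fixture(scope="session")
def small_segmented(small_embryo):
    """Segmentation products of the small noisy embryo."""
    cfg, gt, imgset = small_embryo
    table, mask = segment_nuclei(imgset.envelope)
    axis = fit_axis(mask > 0)
    table = attach_axis(table, axis)
    return cfg, gt, imgset, table, mask, axis


@pytest.fixture(scope="session")
def full_embryo():
    """One default-size cycle-14A embryo (~1900 nuclei), rendered and
    segmented; used by count-range and calibration-recovery tests."""
    cfg = SynthConfig()
    rng = np.random.default_rng(48)
    gt = sample_nuclei(cfg, "14A", rng)
    imgset = render_surface(gt, cfg, rng)
    table, mask = segment_nuclei(imgset.envelope)
    axis = fit_axis(mask > 0)
    table = attach_axis(table, axis)
    calib = calibrate_threshold(imgset.signal, mask, table, (0.05, 0.53))
    return cfg, gt, imgset, table, mask, axis, calib
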