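"""Synthetic blastoderm embryo images with per-nucleus ground truth.

The generator emulates the data the analysis pipeline consumes:

* a "surface" z-stack of a flattened embryo with a nuclear-envelope
  channel (rings) and a nascent-transcript channel (diffraction-limited
  puncta, 0..allele_count per nucleus, drawn from a binomial model with a
  position-dependent activity probability q(x));
* a midsagittal section showing the ring of peripheral nuclei whose
  apical-basal height grows linearly with interphase time;
* smooth intensity channels for an exponential anterior morphogen
  gradient and a plateau-shaped cytoplasmic mRNA pattern.

Every random draw goes through a single :class:`numpy.random.Generator`,
so identical config + seed reproduce identical images bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    CYCLES,
    MIDSAGITTAL_PERIPHERY_COUNT,
    ActivityProfile,
    SynthConfig,
)

# half-max half-width of a Gaussian, in sigmas
_HM = np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generator-side truth for one embryo surface."""

    nuclei: pd.DataFrame  # label, cx, cy, x_over_L, radius_px, true_dot_count, true_false_dots
    cycle: str
    profile_params: ActivityProfile
    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    seed: int
    true_height: float | None = None
    true_time_min: float | None = None
    dots: pd.DataFrame | None = None  # filled by render_surface

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


@dataclass
class MidsagTruth:
    heights_um: np.ndarray
    mean_height: float
    true_height: float
    time_min: float


@dataclass
class EmbryoImageSet:
    """Raw rasters for one embryo: surface stack plus optional midsagittal."""

    surface: np.ndarray  # (n_z, H, W, 2): channel 0 envelope, 1 signal
    pixel_size: float
    midsagittal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def envelope(self) -> np.ndarray:
        return self.surface[..., 0]

    @property
    def signal(self) -> np.ndarray:
        return self.surface[..., 1]


# ---------------------------------------------------------------------------
# activity field
# ---------------------------------------------------------------------------

def make_activity_field(cfg: SynthConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Return q(x): fractional AP position -> allele-activity probability.

    The expected dot count per nucleus at position x is
    ``allele_count * q(x) + false_dot_rate``.
    """
    cfg.validate()
    p = cfg.activity_profile

    def q(x):
        x = np.asarray(x, dtype=float)
        main = p.q_plat * expit((p.x_b - x) / p.w)
        stripe = p.stripe_amp * np.exp(
            -((x - p.stripe_center) ** 2) / (2.0 * p.stripe_sigma**2)
        )
        return np.clip(main + stripe, 0.0, 1.0)

    grid = np.linspace(0.0, 1.0, 2001)
    raw = p.q_plat * expit((p.x_b - grid) / p.w) + p.stripe_amp * np.exp(
        -((grid - p.stripe_center) ** 2) / (2.0 * p.stripe_sigma**2)
    )
    if raw.max() > 1.0 + 1e-12:
        warnings.warn(
            "activity profile exceeds probability 1 (max %.3f); clipping"
            % raw.max(),
            stacklevel=2,
        )
    return q


# ---------------------------------------------------------------------------
# nucleus layout and allele states
# ---------------------------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_nuclei(cfg: SynthConfig, cycle: str, rng) -> GroundTruth:
    """Lay out nuclei on a jittered hexagonal lattice inside the embryo
    ellipse and draw per-nucleus allele states.

    True dot counts are Binomial(allele_count, q(x)); spurious (dim)
    puncta are Poisson(false_dot_rate).
    """
    cfg.validate()
    if cycle not in CYCLES:
        raise ValueError(f"cycle must be one of {CYCLES}, got {cycle!r}")
    rng = _as_rng(rng)
    seed_note = int(rng.integers(0, 2**31 - 1))  # advances state; recorded only

    density = cfg.nucleus_density[cycle] * cfg.pixel_size**2  # per px^2
    spacing = float(np.sqrt(2.0 / (np.sqrt(3.0) * density)))  # px
    if spacing < 4.0:
        raise ValueError(
            f"nucleus density {cfg.nucleus_density[cycle]} /um^2 packs nuclei "
            f"closer than 4 px at {cfg.pixel_size} um/px; beyond packing limit"
        )
    radius = 0.36 * spacing

    cx, cy = cfg.center_px
    a, b = cfg.semi_axes_px
    # hexagonal lattice covering the bounding box
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = np.arange(-int(b / dy) - 1, int(b / dy) + 2)
    xs, ys = [], []
    for r in rows:
        y = cy + r * dy
        off = (r % 2) * spacing / 2.0
        cols = np.arange(-int(a / spacing) - 1, int(a / spacing) + 2)
        x = cx + off + cols * spacing
        xs.append(x)
        ys.append(np.full_like(x, y))
    xs = np.concatenate(xs)
    ys = np.concatenate(ys)

    # positional jitter, clipped so neighbouring nuclei cannot overlap
    jit = 0.06 * spacing
    xs = xs + np.clip(rng.normal(0.0, jit, xs.size), -2 * jit, 2 * jit)
    ys = ys + np.clip(rng.normal(0.0, jit, ys.size), -2 * jit, 2 * jit)

    inside = ((xs - cx) / (a - radius)) ** 2 + ((ys - cy) / (b - radius)) ** 2 <= 1.0
    xs, ys = xs[inside], ys[inside]
    order = np.lexsort((xs, ys))
    xs, ys = xs[order], ys[order]

    x_over_l = np.clip((xs - (cx - a)) / (2.0 * a), 0.0, np.nextafter(1.0, 0.0))
    q = make_activity_field(cfg)(x_over_l)
    dot_count = rng.binomial(cfg.allele_count, q)
    false_dots = rng.poisson(cfg.false_dot_rate, xs.size)

    nuclei = pd.DataFrame(
        {
            "label": np.arange(1, xs.size + 1),
            "cx": xs,
            "cy": ys,
            "x_over_L": x_over_l,
            "radius_px": np.full(xs.size, radius),
            "true_dot_count": dot_count,
            "true_false_dots": false_dots,
        }
    )
    return GroundTruth(
        nuclei=nuclei,
        cycle=cycle,
        profile_params=cfg.activity_profile,
        center_px=(cx, cy),
        semi_axes_px=(a, b),
        seed=seed_note,
    )


def ellipse_mask(cfg: SynthConfig) -> np.ndarray:
    """Boolean mask of the embryo ellipse for a config's image geometry."""
    cx, cy = cfg.center_px
    a, b = cfg.semi_axes_px
    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def embryo_mask(gt: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the embryo ellipse on an image of ``shape``."""
    cx, cy = gt.center_px
    a, b = gt.semi_axes_px
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _stamp(img: np.ndarray, x: float, y: float, patch_r: int, fn) -> None:
    """Add fn(dx, dy) to img on a square patch centred at (x, y)."""
    h, w = img.shape
    x0, x1 = int(np.floor(x)) - patch_r, int(np.floor(x)) + patch_r + 1
    y0, y1 = int(np.floor(y)) - patch_r, int(np.floor(y)) + patch_r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    img[y0c:y1c, x0c:x1c] += fn(xx - x, yy - y)


def _ring(dx, dy, r0, sigma, amp):
    r = np.hypot(dx, dy)
    return amp * np.exp(-((r - r0) ** 2) / (2.0 * sigma**2))


def _punctum(dx, dy, sigma, amp):
    return amp * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))


def _apply_noise(stack: np.ndarray, cfg: SynthConfig, rng) -> np.ndarray:
    """Additive background plus Poisson-like signal-dependent noise.

    The shot-noise term uses the Gaussian approximation with variance
    intensity/photon_scale, adequate at the background levels rendered
    here (>= ~5 expected counts per pixel)."""
    base = np.asarray(stack, dtype=np.float32) + np.float32(cfg.noise.background_mean)
    var = np.float32(cfg.noise.background_sd) ** 2
    if cfg.noise.photon_scale > 0:
        sd = np.sqrt(base / np.float32(cfg.noise.photon_scale) + var)
    else:
        sd = np.full_like(base, np.sqrt(var))
    if cfg.noise.background_sd > 0 or cfg.noise.photon_scale > 0:
        base = base + rng.standard_normal(base.shape, dtype=np.float32) * sd
    return np.clip(base, 0.0, None, out=base)


def render_surface(gt: GroundTruth, cfg: SynthConfig, rng) -> EmbryoImageSet:
    """Render the two-channel surface z-stack for a sampled embryo.

    Envelope channel: one ring stroke per nucleus, identical across z.
    Signal channel: one Gaussian punctum per active allele, placed inside
    its nucleus at a random z and split over at most two adjacent
    z-sections.  Spurious puncta are rendered at a quarter of the true
    amplitude so that the self-calibrating intensity threshold rejects
    them.  Records punctum placements in ``gt.dots``.
    """
    rng = _as_rng(rng)
    h, w = cfg.image_shape
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    ring_sigma_px = cfg.ring_sigma / cfg.pixel_size

    envelope = np.zeros((h, w), dtype=np.float64)
    ring_r = int(np.ceil(gt.nuclei["radius_px"].iloc[0] + 4 * ring_sigma_px)) if len(gt.nuclei) else 0
    for row in gt.nuclei.itertuples():
        _stamp(
            envelope,
            row.cx,
            row.cy,
            ring_r,
            lambda dx, dy, r0=row.radius_px: _ring(dx, dy, r0, ring_sigma_px, cfg.ring_amp),
        )

    signal = np.zeros((cfg.n_z, h, w), dtype=np.float64)
    patch_r = int(np.ceil(4 * sigma_px))
    records = []

    def place_dot(row, dx, dy, amp, kind):
        x, y = row.cx + dx, row.cy + dy
        z = int(rng.integers(0, cfg.n_z))
        frac = float(rng.uniform(0.6, 1.0))
        _stamp(signal[z], x, y, patch_r, lambda a_, b_: _punctum(a_, b_, sigma_px, amp * frac))
        if frac < 1.0 and z + 1 < cfg.n_z:
            _stamp(
                signal[z + 1], x, y, patch_r,
                lambda a_, b_: _punctum(a_, b_, sigma_px, amp * (1.0 - frac)),
            )
        records.append((row.label, x, y, z, amp, frac, kind))

    for row in gt.nuclei.itertuples():
        r0 = row.radius_px
        k = int(row.true_dot_count)
        if k == 1:
            theta = rng.uniform(0, 2 * np.pi)
            u = rng.uniform(0.0, 0.6) * r0
            amp = cfg.dot_amp * rng.lognormal(0.0, cfg.amp_jitter_sigma)
            place_dot(row, u * np.cos(theta), u * np.sin(theta), amp, "true")
        elif k >= 2:
            # alleles sit on distinct chromosomes: keep puncta well apart
            # (near-opposite placement keeps pairs resolved on projection)
            theta = rng.uniform(0, 2 * np.pi)
            for j in range(k):
                ang = theta + j * 2 * np.pi / k
                u = rng.uniform(0.7, 0.85) * r0
                amp = cfg.dot_amp * rng.lognormal(0.0, cfg.amp_jitter_sigma)
                place_dot(row, u * np.cos(ang), u * np.sin(ang), amp, "true")
        for _ in range(int(row.true_false_dots)):
            theta = rng.uniform(0, 2 * np.pi)
            u = rng.uniform(0.0, 0.8) * r0
            amp = (
                cfg.dot_amp
                * cfg.false_dot_amp_frac
                * rng.lognormal(0.0, cfg.amp_jitter_sigma)
            )
            place_dot(row, u * np.cos(theta), u * np.sin(theta), amp, "false")

    gt.dots = pd.DataFrame(
        records, columns=["nucleus_label", "x", "y", "z", "amp", "frac", "kind"]
    )

    surface = np.empty((cfg.n_z, h, w, 2), dtype=np.float32)
    surface[..., 0] = _apply_noise(
        np.broadcast_to(envelope, (cfg.n_z, h, w)), cfg, rng
    )
    surface[..., 1] = _apply_noise(signal, cfg, rng)
    return EmbryoImageSet(
        surface=surface,
        pixel_size=cfg.pixel_size,
        meta={"seed": gt.seed, "config": cfg.digest(), "cycle": gt.cycle},
    )


# ---------------------------------------------------------------------------
# midsagittal section
# ---------------------------------------------------------------------------

def _ellipse_perimeter_points(a: float, b: float, n: int) -> np.ndarray:
    """n angles spaced ~equally by arc length on an ellipse (a, b)."""
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    ds = np.hypot(-a * np.sin(t), b * np.cos(t))
    s = np.concatenate(([0.0], np.cumsum(ds)))
    s /= s[-1]
    targets = np.arange(n) / n
    return np.interp(targets, s[:-1], t)


def render_midsagittal(
    cfg: SynthConfig,
    time_min: float,
    rng,
    cycle: str = "14A",
    heights_um: np.ndarray | None = None,
) -> tuple[np.ndarray, MidsagTruth]:
    """Render a midsagittal (midplane) envelope image at ``time_min``
    minutes into the cycle-14A interphase.

    Nuclei are drawn as elongated envelope rings around the embryo
    outline, apical edge at the outline, long axis along the local
    normal.  The rendered ring is shrunk by the half-max half-width of
    the membrane stroke so that the outer-edge-to-outer-edge distance
    (the operational definition of nuclear height) equals the model
    height h(t) = h0 + k*t.
    """
    cfg.validate()
    if not 0.0 <= time_min <= 20.0:
        raise ValueError(
            f"time_min must be within [0, 20] min of interphase onset, got {time_min}"
        )
    rng = _as_rng(rng)
    h_img, w_img = cfg.image_shape
    cx, cy = cfg.center_px
    a, b = cfg.semi_axes_px
    px = cfg.pixel_size
    hm = cfg.height_model

    # peripheral counts are calibrated for the default L=1000 px embryo;
    # scale with length so nucleus spacing stays constant
    n_nuc = int(round(
        MIDSAGITTAL_PERIPHERY_COUNT[cycle] * cfg.embryo_length_px / 1000.0
    ))
    true_h = hm.height_at(time_min)
    if heights_um is None:
        heights_um = true_h + rng.normal(0.0, hm.height_sd, n_nuc)
        heights_um = np.clip(heights_um, 0.5, None)
    else:
        heights_um = np.asarray(heights_um, dtype=float)
        n_nuc = heights_um.size

    angles = _ellipse_perimeter_points(a, b, n_nuc)
    sigma_m = cfg.midsag_ring_sigma / px  # membrane stroke width, px
    edge_corr = _HM * sigma_m  # half-max offset of the stroke

    img = np.zeros((h_img, w_img), dtype=np.float64)
    arc = 2 * np.pi * np.sqrt((a**2 + b**2) / 2.0) / n_nuc  # mean spacing, px
    half_w = 0.5 * 0.62 * arc  # tangential semi-axis

    for ang, h_um in zip(angles, heights_um):
        bx, by = cx + a * np.cos(ang), cy + b * np.sin(ang)
        # outward normal of the ellipse at this point
        nx, ny = np.cos(ang) / a, np.sin(ang) / b
        norm = np.hypot(nx, ny)
        nx, ny = nx / norm, ny / norm
        h_px = h_um / px
        au = h_px / 2.0 - edge_corr  # semi-axis along the normal
        av = half_w - edge_corr
        ccx = bx - nx * h_px / 2.0
        ccy = by - ny * h_px / 2.0
        patch = int(np.ceil(max(au, av) + 4 * sigma_m))

        def ring(dx, dy, au=au, av=av, nx=nx, ny=ny):
            u = dx * nx + dy * ny
            v = -dx * ny + dy * nx
            m = np.sqrt((u / au) ** 2 + (v / av) ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                r_dir = np.where(
                    m > 0, np.hypot(u, v) / np.maximum(m, 1e-9), au
                )
            d = (m - 1.0) * r_dir
            return cfg.ring_amp * np.exp(-(d**2) / (2.0 * sigma_m**2))

        _stamp(img, ccx, ccy, patch, ring)

    out = _apply_noise(img[None], cfg, rng)[0]
    truth = MidsagTruth(
        heights_um=heights_um,
        mean_height=float(np.mean(heights_um)),
        true_height=float(true_h),
        time_min=float(time_min),
    )
    return out, truth


# ---------------------------------------------------------------------------
# smooth intensity channels
# ---------------------------------------------------------------------------

def render_intensity_channel(
    cfg: SynthConfig, kind: str, rng=None, noise: bool = True
) -> np.ndarray:
    """Render a smooth intensity raster over the embryo ellipse.

    kind="bcd":  b_max * exp(-x / lam) + offset
    kind="mrna": plateau_level * logistic((x_b - x) / w) + offset
    Pixels outside the embryo are left at the noise floor.
    """
    cfg.validate()
    if kind not in ("bcd", "mrna"):
        raise ValueError(f"kind must be 'bcd' or 'mrna', got {kind!r}")
    h, w = cfg.image_shape
    cx, cy = cfg.center_px
    a, b = cfg.semi_axes_px
    yy, xx = np.mgrid[0:h, 0:w]
    x_over_l = np.clip((xx - (cx - a)) / (2.0 * a), 0.0, 1.0)
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    if kind == "bcd":
        g = cfg.gradient
        field_ = g.b_max * np.exp(-x_over_l / g.lam) + g.offset
    else:
        m = cfg.mrna
        field_ = m.plateau_level * expit((m.x_b - x_over_l) / m.w) + m.offset

    img = np.where(inside, field_, 0.0)
    if noise:
        img = _apply_noise(img[None], cfg, _as_rng(rng))[0]
    return img.astype(np.float32)


def binned_exponential_mean(b_max: float, lam: float, offset: float, i: int, n_bins: int = 50) -> float:
    """Analytic mean of b_max*exp(-x/lam)+offset over bin i of ``n_bins``."""
    lo, hi = i / n_bins, (i + 1) / n_bins
    return b_max * lam / (hi - lo) * (np.exp(-lo / lam) - np.exp(-hi / lam)) + offset


def gradient_amplitude_for(observed_bmax: float, lam: float, offset: float, n_bins: int = 50) -> float:
    """Config amplitude so the profile's maximum (anterior) bin mean equals
    ``observed_bmax``; inverts the bin-averaging of the exponential."""
    f = binned_exponential_mean(1.0, lam, 0.0, 0, n_bins)
    return (observed_bmax - offset) / f


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class EmbryoSim:
    """Deferred rendering of one cohort member (keeps cohorts out of RAM)."""

    class_label: str
    cfg: SynthConfig
    seed: int
    time_min: float
    cycle: str = "14A"

    def render(self, midsagittal: bool = False) -> tuple[EmbryoImageSet, GroundTruth]:
        rng = np.random.default_rng(self.seed)
        gt = sample_nuclei(self.cfg, self.cycle, rng)
        gt.true_time_min = self.time_min
        gt.true_height = self.cfg.height_model.height_at(self.time_min)
        imgset = render_surface(gt, self.cfg, rng)
        if midsagittal:
            mid, mtruth = render_midsagittal(self.cfg, self.time_min, rng, self.cycle)
            imgset.midsagittal = mid
            gt.true_height = mtruth.mean_height
        imgset.meta["class"] = self.class_label
        imgset.meta["seed"] = self.seed
        return imgset, gt


def class_nominal_time(label: str) -> float:
    """Nominal (midpoint) time in minutes of a t- or T-class label."""
    scheme, idx = label[0], int(label[1:])
    if scheme == "t":
        return idx - 0.5
    if scheme == "T":
        return 5.0 * idx - 2.5
    raise ValueError(f"unrecognised class label {label!r}")


def make_cohort(
    table: Mapping[str, Mapping[str, float]],
    n_per_class: int,
    seed: int,
    base_cfg: SynthConfig | None = None,
    cycle: str = "14A",
) -> list[EmbryoSim]:
    """Build a reproducible cohort specification from a calibration table.

    ``table`` maps class labels (t1..t9 or T1..T4) to overrides of the
    activity profile / gradient / mrna parameters, e.g.
    ``{"t1": {"q_plat": 0.25}}``.  Per-embryo seeds are spawned
    deterministically from ``seed``; embryo times get a uniform jitter of
    full width ``cfg.timing_jitter_min`` around the class nominal time,
    and expression amplitudes a log-normal embryo-to-embryo factor of CV
    ``cfg.embryo_cv``.
    """
    if not table:
        raise ValueError("empty calibration table")
    base = base_cfg if base_cfg is not None else SynthConfig()
    base.validate()
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    sims: list[EmbryoSim] = []
    for label in table:
        class_nominal_time(label)  # validates the label
    for label, overrides in table.items():
        t0 = class_nominal_time(label)
        for _ in range(n_per_class):
            child = master.spawn(1)[0]
            emb_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            jit = rng.uniform(-0.5, 0.5) * base.timing_jitter_min
            t = float(np.clip(t0 + jit, 0.0, 20.0))
            cfg = SynthConfig.from_dict(base.to_dict())
            for key, val in overrides.items():
                if key == "embryo_cv":
                    cfg.embryo_cv = val
                elif hasattr(cfg.activity_profile, key):
                    setattr(cfg.activity_profile, key, val)
                elif hasattr(cfg.gradient, key):
                    setattr(cfg.gradient, key, val)
                elif hasattr(cfg.mrna, key):
                    setattr(cfg.mrna, key, val)
                else:
                    raise KeyError(f"unknown calibration parameter {key!r}")
            factor = float(rng.lognormal(-0.5 * cfg.embryo_cv**2, cfg.embryo_cv))
            # embryo-to-embryo expression variability
            cfg.activity_profile.q_plat = float(
                np.clip(cfg.activity_profile.q_plat * factor, 0.0, 1.0)
            )
            cfg.activity_profile.stripe_amp = float(
                np.clip(cfg.activity_profile.stripe_amp * factor, 0.0, 1.0)
            )
            cfg.gradient.b_max *= factor
            cfg.mrna.plateau_level *= factor
            cfg.seed = emb_seed
            sims.append(EmbryoSim(label, cfg, emb_seed, t, cycle))
    return sims


# ---------------------------------------------------------------------------
# disk IO
# ---------------------------------------------------------------------------

def save_embryo(imgset: EmbryoImageSet, gt: GroundTruth, outdir) -> None:
    """Write the surface stack (and midsagittal) as TIFF, the ground truth
    as CSV plus a JSON sidecar of profile parameters."""
    import json
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # pages ordered z-major, channel-minor: (z0,env), (z0,sig), (z1,env)...
    stack = np.moveaxis(imgset.surface, 3, 1).reshape(
        -1, *imgset.surface.shape[1:3]
    )
    tifffile.imwrite(
        outdir / "surface.tif",
        stack,
        metadata={"channels": "envelope,signal", "pixel_size_um": imgset.pixel_size},
    )
    if imgset.midsagittal is not None:
        tifffile.imwrite(outdir / "midsagittal.tif", imgset.midsagittal)
    gt.nuclei.to_csv(outdir / "nuclei_truth.csv", index=False)
    if gt.dots is not None:
        gt.dots.to_csv(outdir / "dots_truth.csv", index=False)
    from dataclasses import asdict

    sidecar = {
        "cycle": gt.cycle,
        "seed": gt.seed,
        "profile_params": asdict(gt.profile_params),
        "center_px": list(gt.center_px),
        "semi_axes_px": list(gt.semi_axes_px),
        "true_height": gt.true_height,
        "true_time_min": gt.true_time_min,
        "meta": {k: v for k, v in imgset.meta.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_surface_stack(path) -> np.ndarray:
    """Read a surface TIFF written by :func:`save_embryo` back into the
    (n_z, H, W, 2) layout."""
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_z = pages.shape[0] // 2
    return np.moveaxis(pages.reshape(n_z, 2, *pages.shape[1:]), 1, 3)
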