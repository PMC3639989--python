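"""Configuration for the synthetic embryo generator.

All spatial parameters are in micrometres unless the name says ``_px``.
The defaults describe a flattened wild-type blastoderm embryo imaged at
0.31 um/pixel with the whole anterior-posterior (AP) extent in frame:
embryo length L = 1000 px (310 um), aspect ratio 2.7:1, and nucleus
densities chosen so that one imaged surface holds roughly 500, 1000 and
2000 nuclei at nuclear cycles 12, 13 and 14A (about half of the
~1500/3000/6000 nuclei on the whole periphery at those cycles).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

CYCLES = ("12", "13", "14A")

#: nuclei per um^2 of imaged surface, per nuclear cycle.  Derived from the
#: target surface counts {12: 500, 13: 1000, 14A: 2000} over the default
#: elliptical surface (a=155 um, b=57.4 um, area ~27.9e3 um^2).
DEFAULT_NUCLEUS_DENSITY = {"12": 0.0179, "13": 0.0358, "14A": 0.0716}

#: nuclei placed around the embryo outline in a midsagittal section, per
#: cycle; about half of them sit on the dorsal side.
MIDSAGITTAL_PERIPHERY_COUNT = {"12": 80, "13": 120, "14A": 150}


@dataclass
class ActivityProfile:
    """Allele-activity probability q(x) along the AP axis.

    q(x) = q_plat * logistic((x_b - x) / w)
           + stripe_amp * exp(-(x - stripe_center)^2 / (2 stripe_sigma^2))

    clipped to [0, 1].  The logistic term is the Bcd-dependent anterior
    domain with a sharp posterior boundary at ``x_b``; the Gaussian term is
    a Bcd-independent stripe (the PS4 stripe for hb, the central stripe
    for Kr).
    """

    q_plat: float = 0.5
    x_b: float = 0.48
    w: float = 0.02
    stripe_amp: float = 0.3
    stripe_center: float = 0.62
    stripe_sigma: float = 0.02

    def validate(self) -> None:
        if not 0.0 <= self.q_plat <= 1.0:
            raise ValueError(f"q_plat must be in [0, 1], got {self.q_plat}")
        if not 0.0 < self.x_b < 1.0:
            raise ValueError(f"x_b must be in (0, 1), got {self.x_b}")
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if self.stripe_amp < 0 or self.stripe_sigma <= 0:
            raise ValueError("stripe_amp must be >= 0 and stripe_sigma > 0")


@dataclass
class GradientParams:
    """Exponential anterior morphogen (Bcd-like) intensity gradient.

    intensity(x) = b_max * exp(-x / lam) + offset, in arbitrary units,
    with ``lam`` the decay length in fractions of embryo length.
    """

    b_max: float = 45.0
    lam: float = 0.2
    offset: float = 5.0

    def validate(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.b_max < 0 or self.offset < 0:
            raise ValueError("b_max and offset must be >= 0")


@dataclass
class MrnaParams:
    """Cytoplasmic mature-mRNA intensity pattern (logistic plateau)."""

    plateau_level: float = 28.0
    x_b: float = 0.48
    w: float = 0.02
    offset: float = 5.0

    def validate(self) -> None:
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")


@dataclass
class HeightModel:
    """Linear nuclear elongation during the cycle-14A interphase.

    h(t) = h0 + k * t with ``k`` defaulting to h0/15 so the apical-basal
    height doubles within 15 minutes.  ``height_sd`` is nucleus-to-nucleus
    variation within one embryo.
    """

    h0: float = 5.0
    k: float | None = None  # None -> h0 / 15
    height_sd: float = 0.15

    def validate(self) -> None:
        if self.h0 <= 0:
            raise ValueError(f"h0 must be > 0, got {self.h0}")
        if self.rate < 0:
            raise ValueError(f"k must be >= 0, got {self.rate}")

    @property
    def rate(self) -> float:
        return self.h0 / 15.0 if self.k is None else self.k

    def height_at(self, time_min: float) -> float:
        return self.h0 + self.rate * time_min

    def time_at(self, height_um: float) -> float:
        return (height_um - self.h0) / self.rate


@dataclass
class NoiseParams:
    """Additive Gaussian background plus signal-dependent (Poisson) noise.

    ``photon_scale`` is the counts-per-intensity-unit of the Poisson
    resampling step; 0 disables it.
    """

    background_mean: float = 8.0
    background_sd: float = 1.5
    photon_scale: float = 2.0


@dataclass
class SynthConfig:
    embryo_length_px: int = 1000
    pixel_size: float = 0.31  # um / pixel
    aspect: float = 2.7  # AP length over DV width of the ellipse
    margin_px: int = 12
    n_z: int = 9
    z_span: float = 4.5  # um covered by the z-stack
    nucleus_density: dict = field(
        default_factory=lambda: dict(DEFAULT_NUCLEUS_DENSITY)
    )
    allele_count: int = 2
    activity_profile: ActivityProfile = field(default_factory=ActivityProfile)
    false_dot_rate: float = 0.05  # spurious (dim) puncta per nucleus
    gradient: GradientParams = field(default_factory=GradientParams)
    mrna: MrnaParams = field(default_factory=MrnaParams)
    height_model: HeightModel = field(default_factory=HeightModel)
    noise: NoiseParams = field(default_factory=NoiseParams)
    psf_sigma: float = 0.3  # um; in-plane Gaussian width of a punctum
    ring_sigma: float = 0.2  # um; width of the envelope-stain ring stroke
    midsag_ring_sigma: float = 0.35  # um; membrane stroke width in midsagittal views
    ring_amp: float = 60.0
    dot_amp: float = 100.0  # peak intensity of a true punctum
    false_dot_amp_frac: float = 0.10  # false-dot peak, relative to dot_amp
    amp_jitter_sigma: float = 0.12  # log-normal sigma of punctum amplitudes
    embryo_cv: float = 0.12  # embryo-to-embryo CV of expression levels
    timing_jitter_min: float = 0.7  # full width of the uniform timing jitter
    seed: int = 0

    def validate(self) -> None:
        if self.embryo_length_px <= 0 or self.pixel_size <= 0:
            raise ValueError("embryo_length_px and pixel_size must be > 0")
        if not 2 <= self.n_z <= 32:
            raise ValueError(f"n_z out of range: {self.n_z}")
        if self.allele_count < 1:
            raise ValueError("allele_count must be >= 1")
        if self.false_dot_rate < 0:
            raise ValueError("false_dot_rate must be >= 0")
        self.activity_profile.validate()
        self.gradient.validate()
        self.mrna.validate()
        self.height_model.validate()

    # -- geometry helpers ------------------------------------------------
    @property
    def semi_axes_px(self) -> tuple[float, float]:
        """(a, b): AP and DV semi-axes of the embryo ellipse, pixels."""
        a = self.embryo_length_px / 2.0
        return a, a / self.aspect

    @property
    def image_shape(self) -> tuple[int, int]:
        a, b = self.semi_axes_px
        h = int(round(2 * b)) + 2 * self.margin_px
        w = int(round(2 * a)) + 2 * self.margin_px
        return h, w

    @property
    def center_px(self) -> tuple[float, float]:
        h, w = self.image_shape
        return (w - 1) / 2.0, (h - 1) / 2.0  # (cx, cy)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key, sub in (
            ("activity_profile", ActivityProfile),
            ("gradient", GradientParams),
            ("mrna", MrnaParams),
            ("height_model", HeightModel),
            ("noise", NoiseParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
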