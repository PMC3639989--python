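"""50-bin anterior-posterior profiles and their summary statistics.

Profiles bin either per-nucleus dot counts (rho = mean intron dots per
nucleus per bin) or pixel intensities against fractional embryo length
x/L, with bin i covering [i/50, (i+1)/50).  Summary statistics follow
the field's conventions: the expression boundary x_hb is the AP position
of half-maximal signal; the plateau statistic averages 5 consecutive
bins ending 0.1 x/L anterior to the boundary; the peak statistic
averages 3 consecutive bins centred on the stripe maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import AxisFrame

N_BINS = 50


class ProfileError(RuntimeError):
    pass


@dataclass
class AxisProfile:
    values: np.ndarray  # length N_BINS, NaN where no data
    n_per_bin: np.ndarray  # nuclei (or pixels) per bin
    kind: str  # "rho" | "intensity"
    n_bins: int = N_BINS

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "x_center": self.bin_centers,
                "value": self.values,
                "n": self.n_per_bin,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "rho") -> "AxisProfile":
        df = pd.read_csv(path)
        return cls(
            values=df["value"].to_numpy(float),
            n_per_bin=df["n"].to_numpy(int),
            kind=kind,
            n_bins=len(df),
        )


@dataclass
class BoundaryEstimate:
    x_hb: float
    half_level: float
    max_level: float
    crossing_bins: tuple[int, int]


@dataclass
class PlateauStat:
    value: float
    window_bins: tuple[int, ...]


@dataclass
class PeakStat:
    value: float
    peak_bin: int


def bin_rho(table: pd.DataFrame, n_bins: int = N_BINS) -> AxisProfile:
    """Mean dot count per nucleus, binned along x/L."""
    if len(table) == 0:
        return AxisProfile(
            values=np.full(n_bins, np.nan),
            n_per_bin=np.zeros(n_bins, dtype=int),
            kind="rho",
            n_bins=n_bins,
        )
    x = table["x_over_L"].to_numpy(float)
    counts = table["dot_count"].to_numpy(float)
    idx = np.floor(x * n_bins).astype(int)
    valid = (idx >= 0) & (idx < n_bins)
    idx, counts = idx[valid], counts[valid]
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=counts, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return AxisProfile(values=vals, n_per_bin=n, kind="rho", n_bins=n_bins)


def bin_intensity(
    image: np.ndarray,
    axis: AxisFrame,
    background: str | tuple[str, float] = "none",
    mask: np.ndarray | None = None,
    n_bins: int = N_BINS,
) -> AxisProfile:
    """Mean pixel intensity per AP bin over the embryo foreground.

    ``background`` is "none", ("constant", c) or "min-bin" (subtract the
    smallest non-missing bin mean); subtraction floors at 0.
    """
    img = np.asarray(image, dtype=float)
    fg = axis.mask if mask is None else np.asarray(mask) > 0
    if fg is None:
        raise ProfileError("no foreground mask available")
    ys, xs = np.nonzero(fg)
    xl = axis.x_over_L(np.column_stack([xs, ys]))
    idx = np.floor(np.clip(xl, 0.0, np.nextafter(1.0, 0.0)) * n_bins).astype(int)
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=img[ys, xs], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, s / np.maximum(n, 1), np.nan)

    if background == "none":
        pass
    elif background == "min-bin":
        vals = np.clip(vals - np.nanmin(vals), 0.0, None)
    elif isinstance(background, tuple) and background[0] == "constant":
        vals = np.clip(vals - float(background[1]), 0.0, None)
    else:
        raise ValueError(f"unknown background policy {background!r}")
    return AxisProfile(values=vals, n_per_bin=n, kind="intensity", n_bins=n_bins)


def find_boundary(
    profile: AxisProfile,
    search_window: tuple[float, float] = (0.05, 0.60),
    min_below: int = 2,
) -> BoundaryEstimate:
    """Half-maximal expression boundary position.

    The reference maximum is taken over bins whose centres lie in
    ``search_window`` (chosen to exclude the posterior stripe region);
    the boundary is the linear interpolation between the last bin at or
    above half-max and the first subsequent bin below it on the most
    anterior sustained descent (at least ``min_below`` consecutive bins
    below half, where available).
    """
    centers = profile.bin_centers
    in_win = (
        (centers >= search_window[0])
        & (centers <= search_window[1])
        & ~np.isnan(profile.values)
    )
    idxs = np.flatnonzero(in_win)
    if idxs.size < 2:
        raise ProfileError("no boundary: fewer than 2 usable bins in window")
    vals = profile.values[idxs]
    max_level = float(vals.max())
    if max_level <= 0:
        raise ProfileError("no boundary: profile is non-positive in window")
    half = max_level / 2.0

    crossing = None
    fallback = None
    for k in range(idxs.size - 1):
        if vals[k] >= half > vals[k + 1]:
            if fallback is None:
                fallback = k
            below = vals[k + 1 : k + 1 + min_below]
            if np.all(below < half):
                crossing = k
                break
    if crossing is None:
        crossing = fallback
    if crossing is None:
        raise ProfileError("no boundary: profile never descends below half max")

    i, j = idxs[crossing], idxs[crossing + 1]
    x_hb = centers[i] + (centers[j] - centers[i]) * (
        (profile.values[i] - half) / (profile.values[i] - profile.values[j])
    )
    return BoundaryEstimate(
        x_hb=float(x_hb),
        half_level=half,
        max_level=max_level,
        crossing_bins=(int(i), int(j)),
    )


def plateau_stat(
    profile: AxisProfile, boundary: BoundaryEstimate, offset: float = 0.1
) -> PlateauStat:
    """Mean over the 5 consecutive bins whose most posterior bin centre is
    nearest to x_hb - offset (ties broken anterior)."""
    centers = profile.bin_centers
    target = boundary.x_hb - offset
    # round so that exact half-bin ties are not decided by float noise;
    # argmin then takes the first (anterior) bin of a tie
    j = int(np.argmin(np.round(np.abs(centers - target), 9)))
    window = np.arange(j - 4, j + 1)
    if window[0] < 0:
        raise ProfileError(
            f"plateau window (bins {window[0]}..{j}) falls outside the profile"
        )
    vals = profile.values[window]
    if np.any(np.isnan(vals)):
        raise ProfileError(f"plateau window bins {window.tolist()} contain missing bins")
    return PlateauStat(value=float(vals.mean()), window_bins=tuple(int(k) for k in window))


def peak_stat(
    profile: AxisProfile, search_window: tuple[float, float] = (0.40, 0.75)
) -> PeakStat:
    """Mean over 3 consecutive bins centred on the stripe maximum within
    ``search_window`` (ties broken anterior)."""
    centers = profile.bin_centers
    in_win = (
        (centers >= search_window[0])
        & (centers <= search_window[1])
        & ~np.isnan(profile.values)
    )
    idxs = np.flatnonzero(in_win)
    if idxs.size < 3:
        raise ProfileError("peak: fewer than 3 usable bins in window")
    peak = int(idxs[np.argmax(profile.values[idxs])])
    if peak - 1 < 0 or peak + 1 >= profile.n_bins:
        raise ProfileError("peak at profile edge: flank bins unavailable")
    flank = profile.values[[peak - 1, peak, peak + 1]]
    if np.any(np.isnan(flank)):
        raise ProfileError("peak flank bins are missing")
    return PeakStat(value=float(flank.mean()), peak_bin=peak)


def bmax(profile: AxisProfile) -> float:
    """Maximum non-missing bin value (gradient amplitude)."""
    if np.all(np.isnan(profile.values)):
        raise ProfileError("all bins missing")
    return float(np.nanmax(profile.values))
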