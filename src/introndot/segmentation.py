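"""Nucleus segmentation, embryo-axis fitting and nuclear-height measurement.

Nuclei are delineated by an envelope (membrane) stain, so they appear as
bright rings; the segmentation finds ring interiors by thresholding the
projected envelope channel and keeping enclosed connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

class SegmentationError(RuntimeError):
    pass


@dataclass
class AxisFrame:
    """Anterior-posterior coordinate frame of one embryo.

    ``x_over_L`` maps pixel coordinates to fractional embryo length:
    0 at the anterior pole, 1 at the posterior pole.
    """

    anterior_pole_px: tuple[float, float]
    posterior_pole_px: tuple[float, float]
    L_px: float
    unit: tuple[float, float]  # anterior -> posterior direction
    mask: np.ndarray | None = None

    def x_over_L(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = xy - np.asarray(self.anterior_pole_px)
        return (d @ np.asarray(self.unit)) / self.L_px


@dataclass
class HeightMeasurement:
    heights_um: np.ndarray
    mean_height: float
    n_measured: int


def _project(stack: np.ndarray) -> np.ndarray:
    """Mean z-projection of a 2-D image, a (z, H, W) stack, or the
    envelope channel of a (z, H, W, C) stack."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 4:
        arr = arr[..., 0]
    if arr.ndim == 3:
        arr = arr.mean(axis=0)
    return arr


def _interior_labels(
    membranes: np.ndarray, min_area: int, max_area: int
) -> np.ndarray:
    """Label the enclosed interiors of a membrane mask, dropping the
    outside/cytoplasm component (touches the border or exceeds max_area)
    and sub-resolution fragments."""
    lbl, _ = ndi.label(~membranes)
    border = np.unique(
        np.concatenate([lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]])
    )
    areas = np.bincount(lbl.ravel())
    bad = np.zeros(areas.size, dtype=bool)
    bad[border] = True
    bad[(areas < min_area) | (areas > max_area)] = True
    bad[0] = True
    out = np.where(bad[lbl], 0, lbl)
    return out


def _relabel(lbl: np.ndarray) -> np.ndarray:
    ids = np.unique(lbl)
    ids = ids[ids > 0]
    remap = np.zeros(lbl.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1)
    return remap[lbl]


def _centroid_table(lbl: np.ndarray) -> pd.DataFrame:
    flat = lbl.ravel()
    n = lbl.max()
    areas = np.bincount(flat, minlength=n + 1)
    yy, xx = np.mgrid[0 : lbl.shape[0], 0 : lbl.shape[1]]
    sx = np.bincount(flat, weights=xx.ravel(), minlength=n + 1)
    sy = np.bincount(flat, weights=yy.ravel(), minlength=n + 1)
    labels = np.arange(1, n + 1)
    with np.errstate(invalid="ignore"):
        cx = sx[1:] / areas[1:]
        cy = sy[1:] / areas[1:]
    keep = areas[1:] > 0
    return pd.DataFrame(
        {
            "label": labels[keep],
            "x": cx[keep],
            "y": cy[keep],
            "area_px": areas[1:][keep],
        }
    )


def segment_nuclei(
    envelope_stack: np.ndarray,
    min_area: int = 12,
    max_area: int = 3000,
    split_oversized: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment nuclei from the envelope channel.

    Returns a nucleus table (label, centroid x/y, area) and the label
    mask.  Components larger than twice the median area are split by a
    distance-transform watershed.
    """
    proj = _project(envelope_stack)
    if proj.max() <= 0 or np.ptp(proj) == 0:
        raise SegmentationError("no nuclei: blank envelope image")
    thr = threshold_otsu(proj)
    membranes = proj > thr
    lbl = _interior_labels(membranes, min_area, max_area)
    if lbl.max() == 0:
        raise SegmentationError("no nuclei found in envelope image")

    if split_oversized:
        areas = np.bincount(lbl.ravel())[1:]
        areas = areas[areas > 0]
        median = np.median(areas)
        big_ids = [
            i
            for i, a in zip(np.unique(lbl)[1:], np.bincount(lbl.ravel())[np.unique(lbl)[1:]])
            if a > 2 * median
        ]
        for i in big_ids:
            comp = lbl == i
            dist = ndi.distance_transform_edt(comp)
            peaks = peak_local_max(
                dist, min_distance=3, labels=comp, exclude_border=False
            )
            if len(peaks) < 2:
                continue
            markers = np.zeros_like(lbl)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            ws = watershed(-dist, markers, mask=comp)
            base = lbl.max()
            lbl[comp] = 0
            lbl[ws > 0] = ws[ws > 0] + base

    lbl = _relabel(lbl)
    table = _centroid_table(lbl)
    if table.empty:
        raise SegmentationError("no nuclei found in envelope image")
    return table, lbl.astype(np.int32)


def count_nuclei_surface(table: pd.DataFrame) -> int:
    """Total nucleus count of a projected surface image."""
    return int(len(table))


def fit_axis(
    mask: np.ndarray,
    anterior: str = "left",
    orientation_image: np.ndarray | None = None,
) -> AxisFrame:
    """Fit the embryo's AP axis from a foreground or label mask.

    The major axis comes from the second moments of the foreground; the
    poles are the extreme foreground points along it.  The anterior end
    is either the configured image side or, if ``orientation_image`` is
    given, the end with the higher mean intensity (anterior-high marker).
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        raise SegmentationError("empty mask")

    ys, xs = np.nonzero(fg)
    pts = np.column_stack([xs, ys]).astype(float)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if np.sqrt(evals[0] / evals[1]) > 0.9:
        raise SegmentationError("degenerate (near-circular) mask: no major axis")
    u = evecs[:, 1]  # major axis

    proj = pts @ u
    p_lo = pts[proj.argmin()]
    p_hi = pts[proj.argmax()]

    if orientation_image is not None:
        img = _project(orientation_image)
        L = float(proj.max() - proj.min())
        lo_zone = proj <= proj.min() + 0.15 * L
        hi_zone = proj >= proj.max() - 0.15 * L
        m_lo = img[ys[lo_zone], xs[lo_zone]].mean()
        m_hi = img[ys[hi_zone], xs[hi_zone]].mean()
        flip = m_hi > m_lo
    else:
        if anterior not in ("left", "right"):
            raise ValueError("anterior must be 'left' or 'right'")
        low_is_left = (p_lo[0] <= p_hi[0])
        flip = (anterior == "left") != low_is_left

    if flip:
        p_lo, p_hi = p_hi, p_lo
        u = -u

    L_px = float(np.abs((p_hi - p_lo) @ u))
    # foreground for intensity binning: the filled embryo outline (for a
    # nucleus label mask this is the convex hull of the nucleus layout)
    from skimage.morphology import convex_hull_image

    return AxisFrame(
        anterior_pole_px=tuple(p_lo),
        posterior_pole_px=tuple(p_hi),
        L_px=L_px,
        unit=tuple(u),
        mask=convex_hull_image(fg),
    )


def attach_axis(table: pd.DataFrame, axis: AxisFrame) -> pd.DataFrame:
    """Add fractional AP coordinates (clipped to [0, 1)) to a nucleus table."""
    x = axis.x_over_L(table[["x", "y"]].to_numpy())
    table = table.copy()
    table["x_over_L"] = np.clip(x, 0.0, np.nextafter(1.0, 0.0))
    return table


# ---------------------------------------------------------------------------
# nuclear heights from midsagittal images
# ---------------------------------------------------------------------------

def _profile_height(
    img: np.ndarray, cx: float, cy: float, nx: float, ny: float, reach_px: float
) -> float | None:
    """Outer-edge-to-outer-edge membrane distance (px) along the normal
    (nx, ny) through (cx, cy); None if the two membrane crossings are not
    resolved."""
    step = 0.25
    d = np.arange(-reach_px, reach_px + step, step)
    coords = np.vstack([cy + d * ny, cx + d * nx])
    prof = ndi.map_coordinates(img, coords, order=1, mode="constant")
    half = prof.max() / 2.0
    above = prof > half
    if not above.any():
        return None
    # contiguous suprathreshold runs (membrane crossings)
    idx = np.flatnonzero(above)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    runs = [(d[s[0]], d[s[-1]]) for s in splits]
    basal = [r for r in runs if r[1] < 0]
    apical = [r for r in runs if r[0] > 0]
    if not basal or not apical:
        return None
    b = max(basal, key=lambda r: r[1])  # run just below the centre
    a = min(apical, key=lambda r: r[0])  # run just above the centre
    return a[1] - b[0]


def measure_heights(
    midsagittal: np.ndarray,
    n_target: int = 10,
    pixel_size: float = 0.31,
    lateral_halfwidth_deg: float = 30.0,
    min_area: int = 8,
) -> HeightMeasurement:
    """Measure apical-basal nuclear heights near the mid-lateral regions
    of a midsagittal envelope image.

    Selects ``n_target`` nuclei split evenly between the two sides of the
    embryo, measures each as the outer-edge distance of the detected
    membrane along the local apical-basal (normal) direction, and returns
    individual heights (um) and their mean.
    """
    img = np.asarray(midsagittal, dtype=float)
    if img.max() <= 0:
        raise SegmentationError("blank midsagittal image")
    thr = 0.5 * np.percentile(img, 99.8)
    membranes = img > thr
    lbl = _interior_labels(membranes, min_area, int(img.size * 0.5))
    table = _centroid_table(_relabel(lbl))
    if len(table) < 4:
        raise SegmentationError(
            f"fewer than 4 measurable nuclei ({len(table)}) in midsagittal image"
        )

    # embryo ellipse frame from the ring of nucleus centroids (the
    # peripheral nuclei trace the embryo outline)
    pts = table[["x", "y"]].to_numpy(float)
    c = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, 1]  # AP direction
    v = evecs[:, 0]  # DV direction
    t = (pts - c) @ u
    s = (pts - c) @ v
    a_ell = float(np.abs(t).max())
    b_ell = float(np.abs(s).max())

    rel = table[["x", "y"]].to_numpy() - c
    tu = rel @ u
    sv = rel @ v
    ang = np.degrees(np.arctan2(sv, tu))  # 0 = posterior/anterior axis
    d_top = np.abs(ang - 90.0)
    d_bot = np.abs(ang + 90.0)
    side = np.where(d_top < d_bot, 1, -1)
    dev = np.minimum(d_top, d_bot)

    heights = []
    for sgn in (1, -1):
        cand = np.flatnonzero((side == sgn) & (dev <= lateral_halfwidth_deg))
        cand = cand[np.argsort(dev[cand])]
        taken = 0
        for i in cand:
            if taken >= n_target // 2 + n_target % 2:
                break
            row = table.iloc[i]
            # local outward normal of the embryo ellipse
            nx_l = tu[i] / a_ell**2
            ny_l = sv[i] / b_ell**2
            nvec = nx_l * u + ny_l * v
            nvec = nvec / np.hypot(*nvec)
            h = _profile_height(
                img, row["x"], row["y"], nvec[0], nvec[1], reach_px=b_ell * 0.45
            )
            if h is not None:
                heights.append(h * pixel_size)
                taken += 1

    if len(heights) < 4:
        raise SegmentationError(
            f"fewer than 4 measurable nuclei ({len(heights)}) near mid-lateral regions"
        )
    heights = np.asarray(heights)
    return HeightMeasurement(
        heights_um=heights,
        mean_height=float(heights.mean()),
        n_measured=int(heights.size),
    )


def count_nuclei_midsagittal_dorsal(midsagittal: np.ndarray, min_area: int = 8) -> int:
    """Count detected nuclei on the dorsal (upper) side of a midsagittal
    image; used for nuclear-cycle determination."""
    img = np.asarray(midsagittal, dtype=float)
    thr = 0.5 * np.percentile(img, 99.8)
    lbl = _interior_labels(img > thr, min_area, int(img.size * 0.5))
    table = _centroid_table(_relabel(lbl))
    if table.empty:
        raise SegmentationError("no nuclei in midsagittal image")
    cy = table["y"].mean()
    return int((table["y"] < cy).sum())
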