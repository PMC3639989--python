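"""Nuclear-cycle calls and height-based time classes for early cycle 14A.

Embryos are staged by counting nuclei (midsagittal dorsal count or
projected surface count) and, within cycle 14A, by their mean apical-
basal nuclear height: height grows nearly linearly in interphase time
(doubling in under 15 min), so ranking embryos by mean height orders
them in time.  Classes are ~1-min bins (t1..t9) or ~5-min bins (T1..T4);
heights are mapped to minutes through the linear height model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .config import HeightModel
from .segmentation import HeightMeasurement

#: midsagittal dorsal nucleus-count ranges per cycle
MIDSAG_RANGES: Mapping[str, tuple[int, int]] = {
    "12": (25, 50),
    "13": (55, 65),
    "14A": (70, 80),
}
#: projected-surface nucleus-count ranges per cycle
SURFACE_RANGES: Mapping[str, tuple[int, int]] = {
    "12": (350, 700),
    "13": (787, 1296),
    "14A": (1530, 2463),
}

SCHEMES = {"t": (1.0, 9), "T": (5.0, 4)}  # minutes per class, class count


class CycleUndeterminedError(RuntimeError):
    pass


class InconsistentEvidenceError(RuntimeError):
    pass


@dataclass
class CycleCall:
    cycle: str
    evidence: dict


@dataclass
class TimeClassAssignment:
    scheme: str
    class_index: int
    mean_height: float
    est_time_min: float
    rank: int

    @property
    def label(self) -> str:
        return f"{self.scheme}{self.class_index}"


def _range_call(count: int, ranges: Mapping[str, tuple[int, int]]) -> str | None:
    for cyc, (lo, hi) in ranges.items():
        if lo <= count <= hi:
            return cyc
    return None


def call_cycle(
    midsagittal_dorsal_count: int | None = None,
    surface_count: int | None = None,
    midsag_ranges: Mapping[str, tuple[int, int]] = MIDSAG_RANGES,
    surface_ranges: Mapping[str, tuple[int, int]] = SURFACE_RANGES,
) -> CycleCall:
    """Determine the nuclear cycle from nucleus counts.

    Uses the midsagittal dorsal count and/or the projected surface count;
    raises if the two disagree or if neither falls in a known range.
    """
    if midsagittal_dorsal_count is None and surface_count is None:
        raise ValueError("at least one count must be provided")
    calls = {}
    if midsagittal_dorsal_count is not None:
        calls["midsagittal"] = _range_call(midsagittal_dorsal_count, midsag_ranges)
    if surface_count is not None:
        calls["surface"] = _range_call(surface_count, surface_ranges)
    made = {k: v for k, v in calls.items() if v is not None}
    if not made:
        raise CycleUndeterminedError(
            f"counts {midsagittal_dorsal_count}/{surface_count} outside all known ranges"
        )
    if len(set(made.values())) > 1:
        raise InconsistentEvidenceError(
            f"inconsistent evidence: {made} "
            f"(midsagittal={midsagittal_dorsal_count}, surface={surface_count})"
        )
    return CycleCall(
        cycle=next(iter(made.values())),
        evidence={
            "midsagittal_dorsal_count": midsagittal_dorsal_count,
            "surface_count": surface_count,
        },
    )


def assign_classes(
    cohort_heights: Iterable[HeightMeasurement | float],
    scheme: str = "t",
    height_model: HeightModel | None = None,
    tolerance_min: float = 0.5,
) -> list[TimeClassAssignment]:
    """Assign time classes to a cohort from mean nuclear heights.

    Heights map to minutes through the linear model t = (h - h0)/k; the
    class is the 1-min (scheme "t") or 5-min (scheme "T") bin of that
    time, clipped to t1..t9 / T1..T4.  Ranks follow the height order.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be 't' or 'T', got {scheme!r}")
    hm = height_model if height_model is not None else HeightModel()
    delta, n_classes = SCHEMES[scheme]
    heights = [
        float(h.mean_height) if isinstance(h, HeightMeasurement) else float(h)
        for h in cohort_heights
    ]
    if not heights:
        raise ValueError("empty cohort")
    ranks = np.argsort(np.argsort(heights)) + 1  # 1 = shortest (earliest)
    out = []
    for h, rank in zip(heights, ranks):
        t = hm.time_at(h)
        if t < -tolerance_min:
            raise ValueError(
                f"height {h:.2f} um implies pre-interphase time ({t:.2f} min)"
            )
        t = float(np.clip(t, 0.0, 20.0))
        cls = int(np.clip(np.ceil(t / delta), 1, n_classes))
        out.append(
            TimeClassAssignment(
                scheme=scheme,
                class_index=cls,
                mean_height=h,
                est_time_min=t,
                rank=int(rank),
            )
        )
    return out


def class_time_map(scheme: str) -> dict[str, float]:
    """Nominal (midpoint) time in minutes for each class of a scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be 't' or 'T', got {scheme!r}")
    delta, n_classes = SCHEMES[scheme]
    return {
        f"{scheme}{k}": delta * k - delta / 2.0 for k in range(1, n_classes + 1)
    }
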