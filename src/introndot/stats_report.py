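"""Per-class statistics, shutdown timing, and the end-to-end pipeline.

Aggregates per-embryo summary statistics (rho_plat, rho_peak, hb_plat,
B_max) by time class, compares classes with Student's t-test (pooled
variance, as in the original analyses), locates the transcription-
shutdown half-time on the class-mean trajectory, and checks whether the
shutdown is position-independent across the five plateau bins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import axisprofile as ap
from . import segmentation as seg
from . import spotcall as sc
from . import synthgen as sg
from .config import SynthConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# class summaries and tests
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    class_a: str
    class_b: str
    t_statistic: float
    p_value: float


@dataclass
class ShutdownTiming:
    peak_class: str
    half_time_min: float | None
    background_class: str | None


def summarize(values_by_class: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-class n, arithmetic mean and sample SD (n-1 denominator).

    Classes with a single value get a missing SD.  NaN values (embryos
    whose statistic could not be computed) are dropped.
    """
    rows = []
    for cls, vals in values_by_class.items():
        v = np.asarray(list(vals), dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"class {cls!r} has no usable values")
        rows.append(
            {
                "class": cls,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ttest(
    values_a: Sequence[float], values_b: Sequence[float], labels=("a", "b")
) -> ComparisonResult:
    """Two-sample Student's t-test with pooled variance, two-sided.

    Degenerate zero-variance inputs give p=1 for equal means and p=0
    otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(labels[0], labels[1], float(t), float(p))


def all_pairs_ttests(values_by_class: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Raw (uncorrected) pairwise Student's t-tests between all classes."""
    keys = list(values_by_class)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            r = ttest(values_by_class[ka], values_by_class[kb], labels=(ka, kb))
            rows.append(
                {"class_a": ka, "class_b": kb, "t": r.t_statistic, "p": r.p_value}
            )
    return pd.DataFrame(rows)


def shutdown_timing(
    values_by_class: Mapping[str, Sequence[float]],
    time_map: Mapping[str, float],
    alpha: float = 0.05,
) -> ShutdownTiming:
    """Locate the shutdown on the class-mean trajectory.

    peak_class: class with the highest mean.  half_time_min: linear
    interpolation of the mean trajectory (vs nominal class times) at half
    the peak mean, on the post-peak descent.  background_class: first
    post-peak class whose mean no longer differs from the next class's by
    Student's t-test at ``alpha`` (the level at which transcription has
    reached an unchanging background).
    """
    classes = sorted(values_by_class, key=lambda c: time_map[c])
    if len(classes) < 3:
        raise ValueError("need at least 3 classes")
    means = np.array(
        [np.nanmean(np.asarray(list(values_by_class[c]), float)) for c in classes]
    )
    times = np.array([time_map[c] for c in classes])
    peak = int(np.argmax(means))
    half = means[peak] / 2.0

    half_time = None
    for k in range(peak, len(classes) - 1):
        if means[k] >= half > means[k + 1]:
            half_time = times[k] + (times[k + 1] - times[k]) * (
                (means[k] - half) / (means[k] - means[k + 1])
            )
            break

    background = None
    for k in range(peak, len(classes) - 1):
        a = np.asarray(list(values_by_class[classes[k]]), float)
        b = np.asarray(list(values_by_class[classes[k + 1]]), float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            continue
        if ttest(a, b).p_value > alpha:
            background = classes[k]
            break

    return ShutdownTiming(
        peak_class=classes[peak],
        half_time_min=None if half_time is None else float(half_time),
        background_class=background,
    )


@dataclass
class PositionIndependence:
    table: pd.DataFrame  # class x {bin_1..bin_5, pooled}
    dispersion_index: float  # max over classes of (bin range / pooled mean)


def position_independence(
    plateau_values_by_class: Mapping[str, Sequence[Sequence[float]]],
    time_map: Mapping[str, float] | None = None,
) -> PositionIndependence:
    """Per-bin trajectories across the five plateau bins.

    ``plateau_values_by_class`` maps each class to a list of per-embryo
    5-vectors (the plateau window's bin values, anterior to posterior).
    The dispersion index -- the largest across classes of (range of the
    five bin means / pooled class mean) -- flags position-dependent decay;
    it is this pipeline's own diagnostic, not a published statistic.
    """
    classes = list(plateau_values_by_class)
    if time_map is not None:
        classes = sorted(classes, key=lambda c: time_map[c])
    rows = []
    disp = 0.0
    for cls in classes:
        mat = np.asarray(
            [v for v in plateau_values_by_class[cls] if not np.any(np.isnan(v))],
            dtype=float,
        )
        if mat.ndim != 2 or mat.shape[1] != 5 or mat.shape[0] == 0:
            raise ValueError(f"class {cls!r}: need per-embryo 5-bin plateau vectors")
        bin_means = mat.mean(axis=0)
        pooled = float(mat.mean())
        row = {"class": cls, "n": mat.shape[0], "pooled": pooled}
        row.update({f"bin_{i + 1}": float(m) for i, m in enumerate(bin_means)})
        rows.append(row)
        if pooled > 0:
            disp = max(disp, float(np.ptp(bin_means) / pooled))
    return PositionIndependence(table=pd.DataFrame(rows), dispersion_index=disp)


# ---------------------------------------------------------------------------
# end-to-end analysis of simulated cohorts
# ---------------------------------------------------------------------------

@dataclass
class AnalysisParams:
    """Tunable analysis settings for one cohort run."""

    kind: str = "hb"  # "hb" (anterior domain) or "kr" (central stripe)
    expression_domain: tuple[float, float] = (0.05, 0.53)
    boundary_window: tuple[float, float] = (0.20, 0.60)
    peak_window: tuple[float, float] = (0.40, 0.75)
    min_pixels: int = 3
    assign_radius: float = 2.0
    n_threshold_steps: int = 200
    anterior: str = "left"


@dataclass
class EmbryoAnalysis:
    class_label: str
    n_nuclei: int
    threshold: float
    statistic: float  # rho_plat (hb) or rho_peak (kr)
    x_hb: float | None
    plateau_values: np.ndarray | None  # 5 plateau-bin rho values (hb)
    profile: ap.AxisProfile
    note: str = ""


def analyze_embryo(
    imgset: sg.EmbryoImageSet,
    params: AnalysisParams,
    class_label: str = "",
) -> EmbryoAnalysis:
    """Run segment -> axis -> calibrate -> detect -> assign -> profile ->
    summary statistic on one embryo image set."""
    table, mask = seg.segment_nuclei(imgset.envelope)
    axis = seg.fit_axis(mask > 0, anterior=params.anterior)
    table = seg.attach_axis(table, axis)

    if params.kind == "kr":
        c = (params.peak_window[0] + params.peak_window[1]) / 2.0
        domain = (c - 0.10, c + 0.10)
    else:
        domain = params.expression_domain
    calib = sc.calibrate_threshold(
        imgset.signal,
        mask,
        table,
        expression_domain=domain,
        n_steps=params.n_threshold_steps,
        min_pixels=params.min_pixels,
        radius=params.assign_radius,
    )
    dots = sc.detect_dots(
        imgset.signal, calib.chosen_threshold, min_pixels=params.min_pixels
    )
    res = sc.assign_dots(dots, mask, table, radius=params.assign_radius)
    profile = ap.bin_rho(res.table)

    x_hb = None
    plateau_values = None
    note = ""
    if params.kind == "hb":
        try:
            boundary = ap.find_boundary(profile, params.boundary_window)
            plat = ap.plateau_stat(profile, boundary)
            stat = plat.value
            x_hb = boundary.x_hb
            plateau_values = profile.values[list(plat.window_bins)]
        except ap.ProfileError as exc:
            stat = np.nan
            note = str(exc)
    elif params.kind == "kr":
        try:
            stat = ap.peak_stat(profile, params.peak_window).value
        except ap.ProfileError as exc:
            stat = np.nan
            note = str(exc)
    else:
        raise ValueError(f"unknown kind {params.kind!r}")

    return EmbryoAnalysis(
        class_label=class_label,
        n_nuclei=len(table),
        threshold=calib.chosen_threshold,
        statistic=stat,
        x_hb=x_hb,
        plateau_values=plateau_values,
        profile=profile,
        note=note,
    )


def analyze_cohort(
    sims: Sequence[sg.EmbryoSim], params: AnalysisParams
) -> tuple[pd.DataFrame, dict[str, list[np.ndarray]]]:
    """Analyze a simulated cohort embryo by embryo (rendering lazily).

    Returns the per-embryo result table and, for hb cohorts, the
    per-class lists of 5-bin plateau vectors for the position-
    independence diagnostic.
    """
    rows = []
    plateau: dict[str, list[np.ndarray]] = {}
    for i, sim in enumerate(sims):
        imgset, gt = sim.render()
        r = analyze_embryo(imgset, params, class_label=sim.class_label)
        rows.append(
            {
                "embryo": i,
                "class": r.class_label,
                "seed": sim.seed,
                "true_time_min": sim.time_min,
                "n_nuclei": r.n_nuclei,
                "threshold": r.threshold,
                "statistic": r.statistic,
                "x_hb": r.x_hb,
                "note": r.note,
            }
        )
        if r.plateau_values is not None:
            plateau.setdefault(r.class_label, []).append(r.plateau_values)
        del imgset, gt
    return pd.DataFrame(rows), plateau


def analyze_intensity_cohort(
    sims: Sequence[sg.EmbryoSim],
    kind: str,
    boundary_window: tuple[float, float] = (0.20, 0.60),
) -> pd.DataFrame:
    """Render and profile smooth intensity channels for a cohort.

    kind="mrna": background-subtracted (min-bin) plateau statistic
    (hb_plat); kind="bcd": raw profile maximum (B_max).
    """
    rows = []
    for i, sim in enumerate(sims):
        rng = np.random.default_rng(sim.seed)
        img = sg.render_intensity_channel(sim.cfg, kind, rng=rng)
        mask = sg.ellipse_mask(sim.cfg)
        axis = seg.fit_axis(mask, anterior="left")
        if kind == "mrna":
            prof = ap.bin_intensity(img, axis, background="min-bin", mask=mask)
            boundary = ap.find_boundary(prof, boundary_window)
            stat = ap.plateau_stat(prof, boundary).value
        else:
            prof = ap.bin_intensity(img, axis, background="none", mask=mask)
            stat = ap.bmax(prof)
        rows.append(
            {
                "embryo": i,
                "class": sim.class_label,
                "seed": sim.seed,
                "statistic": stat,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str, out_dir) -> dict:
    """Execute simulate -> segment -> spots -> profile -> summarize end to
    end from a config dict or YAML path, writing the report bundle.

    Outputs: per_embryo.csv, class_summary.csv, comparisons.csv,
    shutdown.json, position_independence.csv, run.log and a report.json
    manifest.
    """
    from pathlib import Path

    import yaml

    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        base = SynthConfig.from_dict(
            {**SynthConfig().to_dict(), **config.get("synth", {})}
        )
        cohort_cfg = config["cohort"]
        params = AnalysisParams(**config.get("analysis", {}))
        sims = sg.make_cohort(
            cohort_cfg["table"],
            cohort_cfg["n_per_class"],
            cohort_cfg["seed"],
            base_cfg=base,
            cycle=cohort_cfg.get("cycle", "14A"),
        )
        log.info(
            "cohort: %d embryos, %d classes, seed %s",
            len(sims),
            len(cohort_cfg["table"]),
            cohort_cfg["seed"],
        )
        per_embryo, plateau = analyze_cohort(sims, params)
        per_embryo.to_csv(out / "per_embryo.csv", index=False)

        values = {
            cls: grp["statistic"].to_numpy()
            for cls, grp in per_embryo.groupby("class", sort=False)
        }
        scheme = next(iter(values))[0]
        from .staging import class_time_map

        tmap = class_time_map(scheme)
        order = sorted(values, key=lambda c: tmap[c])
        values = {c: values[c] for c in order}

        summary = summarize(values)
        summary.to_csv(out / "class_summary.csv", index=False)
        comparisons = all_pairs_ttests(values)
        comparisons.to_csv(out / "comparisons.csv", index=False)

        report = {
            "files": {
                "per_embryo": "per_embryo.csv",
                "class_summary": "class_summary.csv",
                "comparisons": "comparisons.csv",
            },
            "seed": cohort_cfg["seed"],
            "kind": params.kind,
        }
        if len(values) >= 3:
            timing = shutdown_timing(values, tmap)
            with open(out / "shutdown.json", "w") as fh:
                json.dump(
                    {
                        "peak_class": timing.peak_class,
                        "half_time_min": timing.half_time_min,
                        "background_class": timing.background_class,
                    },
                    fh,
                    indent=2,
                )
            report["files"]["shutdown"] = "shutdown.json"
        if plateau:
            pi = position_independence(plateau, tmap)
            pi.table.to_csv(out / "position_independence.csv", index=False)
            report["files"]["position_independence"] = "position_independence.csv"
            report["dispersion_index"] = pi.dispersion_index

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("pipeline complete: %s", report["files"])
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
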