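"""End-to-end orchestration: detect -> germination -> growth -> fits -> stats.

One :func:`analyze_stack` call turns a single time-lapse stack into per-spore
records; :func:`run_pipeline` runs any number of stacks grouped by condition
label, pools records per condition, and — when exactly two conditions are
present — compares them metric-by-metric with the F-then-t protocol.  All
outputs are delimited text keyed by spore id, so every number in a summary
can be traced back to one spore in one stack.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import plots
from .detect import apply_exclusions, detect_spores, resolve_thresholds
from .fitting import default_fit_window, fit_generation_time
from .germination import detect_germination, extract_trace, summarize_germination
from .growth import detect_burst, detect_first_division, outgrowth_time, track_all_areas
from .simulate import (
    GroundTruthManifest,
    PopulationParams,
    sample_population,
    simulate_movie,
)
from .stack_io import RunConfig, TimeLapseStack, read_stack, write_records, write_stack
from .stats import (
    TIMING_METRICS,
    SporeRecord,
    classify_fates,
    compare_conditions,
    condition_deltas,
)

__all__ = [
    "StackEntry",
    "RunManifest",
    "StackResult",
    "analyze_stack",
    "run_pipeline",
    "summarize_condition",
    "simulate_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackEntry:
    """One field of view: stack path plus acquisition metadata."""

    path: str
    condition: str
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be nonempty")


@dataclass
class RunManifest:
    """All fields of view of one experiment plus the output location."""

    entries: list[StackEntry]
    output_dir: str
    config_path: str | None = None


@dataclass
class StackResult:
    """Everything measured on one stack (records plus raw traces/events)."""

    origin_name: str
    condition: str
    records: list[SporeRecord]
    intensity_traces: list = field(default_factory=list)
    area_traces: list = field(default_factory=list)


def _resolved_config(stack: TimeLapseStack, config: RunConfig) -> RunConfig:
    """Pin the auto-derived thresholds to numbers for this stack."""
    bright, dark = resolve_thresholds(stack, config)
    return dataclasses.replace(config, bright_threshold=bright, dark_threshold=dark)


def analyze_stack(
    stack: TimeLapseStack,
    config: RunConfig,
    condition: str = "",
    exclusions: Sequence[int] = (),
    manual_divisions: dict[int, float] | None = None,
    manual_windows: dict[int, tuple[float, float]] | None = None,
) -> StackResult:
    """Run the three analysis steps on one stack and build spore records.

    Manual tables override the automatic first-division detection and the
    automatic fit windows per spore id; their use is recorded in the output
    (``division_source`` column).
    """
    manual_divisions = manual_divisions or {}
    manual_windows = manual_windows or {}
    cfg = _resolved_config(stack, config)

    markers = detect_spores(stack, cfg)
    if exclusions:
        markers = apply_exclusions(markers, list(exclusions))

    records: list[SporeRecord] = []
    itraces = []

    # markers whose centre region is clipped by the boundary are excluded
    usable = []
    for m in markers:
        if not m.included:
            records.append(
                SporeRecord(
                    spore_id=m.spore_id, fate="excluded",
                    censor_reason="manual_exclusion",
                    origin_name=stack.origin_name, condition=condition,
                )
            )
            continue
        try:
            trace = extract_trace(stack, m, cfg.center_radius_px)
        except ValueError:
            records.append(
                SporeRecord(
                    spore_id=m.spore_id, fate="excluded",
                    censor_reason="boundary_clip",
                    origin_name=stack.origin_name, condition=condition,
                )
            )
            continue
        usable.append((m, trace))
        itraces.append(trace)

    area_traces = track_all_areas(stack, [m for m, _ in usable], cfg)

    for m, trace in usable:
        event = detect_germination(trace, cfg)
        atrace = area_traces[m.spore_id]
        if event.pre_germinated:
            records.append(
                SporeRecord(
                    spore_id=m.spore_id, fate="pre_germinated",
                    censor_reason=atrace.censor_reason,
                    origin_name=stack.origin_name, condition=condition,
                )
            )
            continue
        if not event.detected:
            records.append(
                SporeRecord(
                    spore_id=m.spore_id, fate="dormant",
                    censor_reason=atrace.censor_reason,
                    origin_name=stack.origin_name, condition=condition,
                )
            )
            continue

        division = detect_first_division(
            stack, atrace, m, cfg,
            manual_t_division_min=manual_divisions.get(m.spore_id),
            scan_from_min=event.t_end_min,
        )
        bursts = detect_burst(atrace, event, division, cfg)
        if division is None:
            records.append(
                SporeRecord(
                    spore_id=m.spore_id, fate="germinate_only",
                    t_start_min=event.t_start_min,
                    germ_duration_min=event.duration_min,
                    burst_times_min=[b.t_burst_min for b in bursts],
                    censor_reason=atrace.censor_reason,
                    origin_name=stack.origin_name, condition=condition,
                )
            )
            continue

        out_time = outgrowth_time(event, division)
        gen_time = None
        r_value = None
        window = manual_windows.get(m.spore_id) or default_fit_window(
            atrace, division, cfg
        )
        if window is not None:
            try:
                fit = fit_generation_time(atrace, window, cfg.fit_min_r)
            except ValueError:
                fit = None
            if fit is not None:
                r_value = fit.r_value
                if not fit.flagged:
                    gen_time = fit.generation_time_min
        records.append(
            SporeRecord(
                spore_id=m.spore_id, fate="outgrow",
                t_start_min=event.t_start_min,
                germ_duration_min=event.duration_min,
                outgrowth_time_min=out_time,
                generation_time_min=gen_time,
                fit_r_value=r_value,
                burst_times_min=[b.t_burst_min for b in bursts],
                censor_reason=atrace.censor_reason,
                division_source=division.source,
                origin_name=stack.origin_name, condition=condition,
            )
        )

    records.sort(key=lambda r: r.spore_id)
    return StackResult(
        origin_name=stack.origin_name,
        condition=condition,
        records=records,
        intensity_traces=itraces,
        area_traces=[area_traces[m.spore_id] for m, _ in usable],
    )


def _metric_values(records: Sequence[SporeRecord], metric: str) -> np.ndarray:
    vals = [getattr(r, metric) for r in records]
    return np.array([v for v in vals if v is not None], dtype=float)


def summarize_condition(records: Sequence[SporeRecord]) -> dict[str, float]:
    """Flat summary of one condition: fractions plus per-metric means/n."""
    fates = classify_fates(records)
    out: dict[str, float] = {
        "n_assessed": float(fates.n_assessed),
        "fraction_germinated_pct": fates.fraction_germinated_pct,
        "fraction_outgrown_pct": fates.fraction_outgrown_pct,
    }
    for metric in TIMING_METRICS:
        vals = _metric_values(records, metric)
        out[f"mean_{metric}"] = float(vals.mean()) if vals.size else float("nan")
        out[f"sd_{metric}"] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        out[f"n_{metric}"] = float(vals.size)
    return out


def run_pipeline(
    manifest: RunManifest,
    config: RunConfig,
    make_plots: bool = True,
) -> dict[str, pd.DataFrame]:
    """Analyze every stack, pool per condition, compare two conditions.

    Writes, under ``manifest.output_dir``: a master ``records.csv``, one
    ``summary_<condition>.csv`` per condition, and — for exactly two
    conditions — ``comparisons.csv`` (F-then-t per metric) and ``deltas.csv``.
    Deterministic given identical inputs and configuration.
    """
    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    by_condition: dict[str, list[SporeRecord]] = {}
    intervals: dict[str, set[float]] = {}
    all_records: list[SporeRecord] = []
    results: list[StackResult] = []

    for entry in manifest.entries:
        stack = read_stack(entry.path, entry.frame_interval_s, entry.pixel_size_um)
        intervals.setdefault(entry.condition, set()).add(entry.frame_interval_s)
        if len(intervals[entry.condition]) > 1:
            log.warning(
                "condition %r mixes frame intervals %s",
                entry.condition, sorted(intervals[entry.condition]),
            )
        result = analyze_stack(stack, config, condition=entry.condition)
        if not result.records:
            log.warning("stack %s: zero spores detected; skipped", entry.path)
            continue
        results.append(result)
        by_condition.setdefault(entry.condition, []).extend(result.records)
        all_records.extend(result.records)

    outputs: dict[str, pd.DataFrame] = {}
    write_records(all_records, outdir / "records.csv")

    summaries: dict[str, dict[str, float]] = {}
    for cond in sorted(by_condition):
        summary = summarize_condition(by_condition[cond])
        summaries[cond] = summary
        df = pd.DataFrame([summary])
        df.insert(0, "condition", cond)
        df.to_csv(outdir / f"summary_{cond}.csv", index=False)
        outputs[f"summary_{cond}"] = df

    if len(by_condition) == 2:
        cond_a, cond_b = sorted(by_condition)
        rows = []
        for metric in TIMING_METRICS:
            va = _metric_values(by_condition[cond_a], metric)
            vb = _metric_values(by_condition[cond_b], metric)
            if len(va) < 2 or len(vb) < 2:
                log.warning("metric %s: too few values to compare", metric)
                continue
            cmp = compare_conditions(va, vb, metric_name=metric)
            rows.append(dataclasses.asdict(cmp))
        cmp_df = pd.DataFrame(rows)
        cmp_df.insert(0, "condition_a", cond_a)
        cmp_df.insert(1, "condition_b", cond_b)
        cmp_df.to_csv(outdir / "comparisons.csv", index=False)
        outputs["comparisons"] = cmp_df

        deltas = condition_deltas(summaries[cond_a], summaries[cond_b])
        delta_df = pd.DataFrame([deltas])
        delta_df.insert(0, "delta", f"{cond_b} - {cond_a}")
        delta_df.to_csv(outdir / "deltas.csv", index=False)
        outputs["deltas"] = delta_df

    if make_plots:
        plotdir = outdir / "plots"
        plotdir.mkdir(exist_ok=True)
        for result in results:
            tag = f"{result.condition}_{result.origin_name}"
            plots.plot_intensity_traces(
                result.intensity_traces, plotdir / f"intensity_{tag}.png", title=tag
            )
            plots.plot_area_traces(
                result.area_traces, plotdir / f"area_{tag}.png", title=tag
            )
        for metric in TIMING_METRICS:
            values = {
                cond: _metric_values(recs, metric)
                for cond, recs in sorted(by_condition.items())
            }
            if any(len(v) for v in values.values()):
                plots.plot_metric_histograms(
                    values, plotdir / f"hist_{metric}.png", metric.replace("_", " ")
                )

    outputs["records"] = pd.DataFrame([dataclasses.asdict(r) for r in all_records])
    return outputs


def simulate_experiment(
    output_dir: str | os.PathLike,
    n_spores: int = 90,
    params: PopulationParams | None = None,
    condition: str = "control",
    n_frames: int = 300,
    shape: tuple[int, int] = (512, 512),
    frame_interval_s: float = 60.0,
    pixel_size_um: float = 0.065,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Simulate one movie and write it plus its ground truth to disk.

    Returns (tiff_path, manifest_yaml_path); a ground-truth CSV sits next to
    them.  The defaults mirror a typical experiment: ~90 starting spores
    followed for 5 h at one frame per minute.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = sample_population(
        n_spores,
        params or PopulationParams(),
        shape=shape,
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        noise_sd=noise_sd,
        seed=seed,
    )
    stack = simulate_movie(manifest, n_frames=n_frames, shape=shape, seed=seed)
    tiff_path = outdir / f"{condition}.tif"
    yaml_path = outdir / f"{condition}_truth.yaml"
    write_stack(stack, tiff_path)
    manifest.to_yaml(yaml_path)
    manifest.scripts_frame().to_csv(outdir / f"{condition}_truth.csv", index=False)
    return tiff_path, yaml_path
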