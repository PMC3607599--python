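"""Static overview plots: trace overlays and metric histograms.

These replace interactive movie navigation with per-spore static plots whose
spore ids link back to the record tables.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .germination import IntensityTrace
from .growth import AreaTrace

__all__ = [
    "plot_intensity_traces",
    "plot_area_traces",
    "plot_metric_histograms",
    "freedman_diaconis_bins",
]


def plot_intensity_traces(
    traces: Sequence[IntensityTrace], path: str | os.PathLike, title: str = ""
) -> None:
    """Overlay of all centre-intensity traces (brightness vs time)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for tr in traces:
        ax.plot(tr.times_min, tr.values, lw=0.8, alpha=0.6)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("centre intensity")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)


def plot_area_traces(
    traces: Sequence[AreaTrace], path: str | os.PathLike, title: str = ""
) -> None:
    """Overlay of log2(area) vs time for all tracked colonies."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for tr in traces:
        if tr.times_min.size:
            ax.plot(tr.times_min, np.log2(tr.areas_px2), lw=0.8, alpha=0.6)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("log2 area (px$^2$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)


def freedman_diaconis_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis rule, clipped to [5, 100] bins."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 5
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0 or np.ptp(x) == 0:
        return 5
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    return int(np.clip(np.ceil(np.ptp(x) / width), 5, 100))


def plot_metric_histograms(
    values_by_condition: Mapping[str, np.ndarray],
    path: str | os.PathLike,
    metric_label: str,
    bins: int | None = None,
) -> None:
    """Frequency distributions of one metric, one histogram per condition."""
    fig, ax = plt.subplots(figsize=(6, 4))
    pooled = np.concatenate([np.asarray(v, float) for v in values_by_condition.values() if len(v)])
    if bins is None:
        bins = freedman_diaconis_bins(pooled) if pooled.size else 5
    edges = np.histogram_bin_edges(pooled, bins=bins) if pooled.size else bins
    for label, vals in values_by_condition.items():
        if len(vals):
            ax.hist(vals, bins=edges, alpha=0.5, label=f"{label} (n={len(vals)})")
    ax.set_xlabel(metric_label)
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)
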