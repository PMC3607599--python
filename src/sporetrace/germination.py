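"""Step 2: centre-intensity traces and bright-to-dark germination events.

Germination (water influx and dipicolinic-acid release) turns a phase-bright
spore phase-dark.  On a centre-intensity trace this is a monotone drop
between two settled plateaus.  The *drop range* is the difference between the
settled pre- and post-transition intensities; the event is timed by when the
trace crosses 90% of the drop range (start of germination) and 10% (end of
germination), each refined by linear interpolation between the bracketing
frames.  The duration of the 90%-to-10% interval is the germination time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import SporeMarker, resolve_thresholds
from .stack_io import RunConfig, TimeLapseStack

__all__ = [
    "IntensityTrace",
    "GerminationEvent",
    "extract_trace",
    "detect_germination",
    "summarize_germination",
]

log = logging.getLogger(__name__)

# Plateau window lengths (frames): the pre-plateau estimate uses the first
# frames of the movie, the post-plateau the first frames after the trace has
# settled near its minimum.
_PRE_ESTIMATE_FRAMES = 5
_POST_PLATEAU_FRAMES = 10


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame mean intensity over a small disk at a spore's centre."""

    spore_id: int
    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GerminationEvent:
    """Timing of one spore's phase-bright to phase-dark transition."""

    spore_id: int
    detected: bool
    i_pre: float | None = None
    i_post: float | None = None
    drop_range: float | None = None
    t_start_min: float | None = None  # 90%-level crossing
    t_end_min: float | None = None  # 10%-level crossing
    duration_min: float | None = None
    pre_germinated: bool = False


def extract_trace(
    stack: TimeLapseStack, marker: SporeMarker, center_radius_px: int
) -> IntensityTrace:
    """Mean intensity over a disk of ``center_radius_px`` at the marker centre.

    Raises
    ------
    ValueError
        If the disk would be clipped by the image boundary (such a marker
        should be excluded instead).
    """
    cy, cx = marker.centroid
    r = center_radius_px
    ny, nx = stack.shape
    if cy - r < -0.5 or cx - r < -0.5 or cy + r > ny - 0.5 or cx + r > nx - 0.5:
        raise ValueError(
            f"centre region of spore {marker.spore_id} clipped by image boundary"
        )
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not mask.any():
        mask = np.zeros((ny, nx), dtype=bool)
        mask[int(round(cy)), int(round(cx))] = True
    values = stack.frames[:, mask].mean(axis=1).astype(float)
    return IntensityTrace(
        spore_id=marker.spore_id, times_min=stack.times_min, values=values
    )


def _settled_plateaus(
    values: np.ndarray, settle_tolerance: float
) -> tuple[float, float]:
    """Median settled intensities (pre, post) around the transition.

    Two-pass: the pre-plateau estimate is the median of the first frames;
    the pre-plateau proper is every frame before the trace first leaves that
    estimate downward by more than the settle tolerance.  The post-plateau
    starts at the first frame within the settle tolerance of the trace
    minimum and spans a short window.
    """
    i_pre_est = float(np.median(values[:_PRE_ESTIMATE_FRAMES]))
    below = np.flatnonzero(values < i_pre_est - settle_tolerance)
    first_drop = int(below[0]) if below.size else len(values)
    if first_drop == 0:
        i_pre = i_pre_est
    else:
        i_pre = float(np.median(values[:first_drop]))
    vmin = float(values.min())
    settled = np.flatnonzero(values <= vmin + settle_tolerance)
    j0 = int(settled[0])
    i_post = float(np.median(values[j0 : j0 + _POST_PLATEAU_FRAMES]))
    return i_pre, i_post


def _down_crossing(
    times: np.ndarray, values: np.ndarray, level: float, i: int
) -> float:
    """Linearly interpolated time of the down-crossing on segment [i, i+1]."""
    v0, v1 = values[i], values[i + 1]
    frac = (v0 - level) / (v0 - v1)
    return float(times[i] + frac * (times[i + 1] - times[i]))


def detect_germination(trace: IntensityTrace, config: RunConfig) -> GerminationEvent:
    """Detect and time the bright-to-dark transition of one trace.

    A spore is a germination candidate only if its trace ever falls below the
    dark threshold.  For candidates the settled plateaus define the drop
    range; the start time is the last down-crossing of the 90% level before
    the transition midpoint and the end time the first down-crossing of the
    10% level after it, both linearly interpolated.
    """
    t, v = trace.times_min, trace.values
    dark = config.dark_threshold
    if dark is None:
        raise ValueError("detect_germination needs an explicit dark_threshold")
    if v.min() >= dark:
        return GerminationEvent(spore_id=trace.spore_id, detected=False)

    i_pre, i_post = _settled_plateaus(v, config.settle_tolerance)
    if i_pre < dark:
        # already phase-dark at frame 0: germinated before the movie started
        log.warning("spore %d is phase-dark at frame 0 (pre-germinated)", trace.spore_id)
        return GerminationEvent(
            spore_id=trace.spore_id, detected=False, pre_germinated=True
        )
    drop = i_pre - i_post
    if drop <= 0:
        return GerminationEvent(spore_id=trace.spore_id, detected=False)
    lvl90 = i_post + 0.9 * drop
    lvl10 = i_post + 0.1 * drop
    mid = i_post + 0.5 * drop

    below_mid = np.flatnonzero(v < mid)
    m = int(below_mid[0])  # first frame past the transition midpoint
    # last down-crossing of the 90% level at or before the midpoint frame
    start_seg = None
    for i in range(m - 1, -1, -1):
        if v[i] >= lvl90 and v[i + 1] < lvl90:
            start_seg = i
            break
    t_start = None
    if start_seg is not None:
        t_start = _down_crossing(t, v, lvl90, start_seg)
    elif v[0] < lvl90:  # trace starts between the 90% level and the midpoint
        t_start = float(t[0])
    # first down-crossing of the 10% level after the midpoint
    end_seg = None
    for i in range(max(m - 1, 0), len(v) - 1):
        if v[i] >= lvl10 and v[i + 1] < lvl10:
            end_seg = i
            break
    if t_start is None or end_seg is None:
        log.warning("spore %d: transition has no clean 90%%/10%% crossings", trace.spore_id)
        return GerminationEvent(spore_id=trace.spore_id, detected=False)

    t_end = _down_crossing(t, v, lvl10, end_seg)
    if not t_start < t_end:
        return GerminationEvent(spore_id=trace.spore_id, detected=False)
    # warn on recoveries after the transition (multiple large drops)
    after = v[end_seg + 1 :]
    if after.size and after.max() > i_pre - 0.1 * drop:
        log.warning(
            "spore %d: intensity recovers after the transition; using first sustained drop",
            trace.spore_id,
        )
    return GerminationEvent(
        spore_id=trace.spore_id,
        detected=True,
        i_pre=i_pre,
        i_post=i_post,
        drop_range=drop,
        t_start_min=t_start,
        t_end_min=t_end,
        duration_min=t_end - t_start,
    )


def summarize_germination(
    events: list[GerminationEvent],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectors (start times, durations) over detected events only.

    These are the per-population inputs to the distribution fits and the
    two-condition comparisons.
    """
    detected = [e for e in events if e.detected]
    starts = np.array([e.t_start_min for e in detected], dtype=float)
    durations = np.array([e.duration_min for e in detected], dtype=float)
    return starts, durations
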