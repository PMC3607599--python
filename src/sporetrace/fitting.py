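"""Generation times from log2(area)-vs-time fits.

During balanced exponential growth the microcolony footprint doubles once
per generation, so log2(area) is linear in time and the generation time is
the reciprocal of the slope (in doublings per minute).  The fit window runs
from the first division to the end of the linear part of the log2(area)
curve; the end of linearity is found automatically by expanding the
window block-by-block while the trace stays on the fitted line, and manual
windows override.

The same machinery serves vegetative-cell movies, where cells are marked at
t=0 and the window starts at the beginning of the movie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import SporeMarker
from .growth import AreaTrace, DivisionEvent, track_all_areas
from .stack_io import RunConfig, TimeLapseStack

__all__ = [
    "GrowthFit",
    "fit_generation_time",
    "default_fit_window",
    "vegetative_mode",
]

log = logging.getLogger(__name__)

# rolling-window length (frames) used to find the end of the linear part
_ROLL_FRAMES = 10
_MIN_FIT_POINTS = 4


@dataclass(frozen=True)
class GrowthFit:
    """One least-squares fit of log2(area) on time.

    ``slope_doublings_per_min`` is in doublings/min, so
    ``generation_time_min = 1 / slope``; ``r_value`` is the Pearson
    correlation of the fit.  Fits whose |r| falls below the configured
    minimum, or whose slope is not positive, are ``flagged`` and carry no
    generation time.
    """

    spore_id: int
    window_start_min: float
    window_end_min: float
    slope_doublings_per_min: float
    intercept: float
    r_value: float
    generation_time_min: float | None
    flagged: bool
    n_points: int


def fit_generation_time(
    area_trace: AreaTrace,
    window: tuple[float, float],
    fit_min_r: float = 0.99,
) -> GrowthFit:
    """Ordinary least squares of log2(area) on time over ``window``.

    Raises
    ------
    ValueError
        If the window holds fewer than four uncensored points.
    """
    start, end = window
    if not start < end:
        raise ValueError(f"empty fit window ({start}, {end})")
    t, a = area_trace.times_min, area_trace.areas_px2
    sel = (t >= start) & (t <= end)
    if sel.sum() < _MIN_FIT_POINTS:
        raise ValueError(
            f"spore {area_trace.spore_id}: only {int(sel.sum())} points in "
            f"window ({start}, {end}); need >= {_MIN_FIT_POINTS}"
        )
    tt, log2a = t[sel], np.log2(a[sel])
    res = stats.linregress(tt, log2a)
    slope = float(res.slope)
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    flagged = slope <= 0 or abs(r) < fit_min_r
    if slope <= 0:
        log.warning(
            "spore %d: non-positive growth slope %.4g; no generation time",
            area_trace.spore_id, slope,
        )
    return GrowthFit(
        spore_id=area_trace.spore_id,
        window_start_min=float(tt[0]),
        window_end_min=float(tt[-1]),
        slope_doublings_per_min=slope,
        intercept=float(res.intercept),
        r_value=r,
        generation_time_min=(1.0 / slope) if slope > 0 else None,
        flagged=flagged,
        n_points=int(sel.sum()),
    )


def default_fit_window(
    area_trace: AreaTrace,
    division_event: DivisionEvent | None,
    config: RunConfig,
    start_min: float | None = None,
) -> tuple[float, float] | None:
    """Window from first division to the end of the linear log2(area) part.

    Starting at the division time (or ``start_min``), the window grows in
    blocks of frames while each new block stays on the straight line fitted
    so far (within the rasterization tolerance of the measured areas); the
    window must finally satisfy ``|r| >= fit_min_r`` as a whole.  Returns
    None when no qualifying window exists (the spore is then excluded from
    generation-time statistics).
    """
    if start_min is None:
        if division_event is None:
            return None
        start_min = division_event.t_division_min
    t, a = area_trace.times_min, area_trace.areas_px2
    sel = t >= start_min
    if sel.sum() < _MIN_FIT_POINTS:
        return None
    tt, aa = t[sel], a[sel]
    log2a = np.log2(aa)
    n = len(tt)

    # Expand the window in blocks: each new block must stay within the
    # rasterization tolerance of the straight line fitted to the window so
    # far.  (A per-block correlation test is blind here: for a small colony
    # the pixel-quantised area can sit constant across a whole block even
    # during perfectly exponential growth.)  The tolerance per point is the
    # log2 effect of a perimeter-sized area error, which shrinks as the
    # colony grows — so a plateau is caught within about one block.
    j = min(_ROLL_FRAMES, n)
    while j < n:
        nxt = min(j + _ROLL_FRAMES, n)
        slope, intercept = np.polyfit(tt[:j], log2a[:j], 1)
        pred = intercept + slope * tt[j:nxt]
        resid = log2a[j:nxt] - pred
        tol = np.log2(1.0 + np.sqrt(np.pi * aa[j:nxt]) / aa[j:nxt])
        bad = np.flatnonzero(np.abs(resid) > tol)
        if bad.size:
            j = j + int(bad[0])  # window ends where the line is first left
            break
        j = nxt
    if j < _MIN_FIT_POINTS:
        return None
    res = stats.linregress(tt[:j], log2a[:j])
    r = res.rvalue if np.isfinite(res.rvalue) else 0.0
    if abs(r) < config.fit_min_r or res.slope <= 0:
        return None  # no qualifying linear window
    return float(tt[0]), float(tt[j - 1])


def vegetative_mode(
    stack: TimeLapseStack,
    manual_markers: list[tuple[float, float]],
    config: RunConfig,
) -> list[GrowthFit]:
    """Generation times for vegetative-cell movies.

    Cells are marked manually at t=0 (no germination step); each marker's
    area is tracked and the linear part of log2(area) from the start of the
    movie is fitted.  Flat or non-exponential traces come back flagged with
    no generation time.
    """
    ny, nx = stack.shape
    markers = []
    for i, (cy, cx) in enumerate(manual_markers):
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"marker {i} at ({cy}, {cx}) outside image bounds")
        markers.append(
            SporeMarker(
                spore_id=i, centroid=(float(cy), float(cx)),
                area_px=0, mean_intensity=float("nan"),
            )
        )
    traces = track_all_areas(stack, markers, config)
    fits: list[GrowthFit] = []
    for m in markers:
        trace = traces[m.spore_id]
        if trace.times_min.size < _MIN_FIT_POINTS:
            continue
        window = default_fit_window(
            trace, None, config, start_min=float(trace.times_min[0])
        )
        if window is None:
            # keep a flagged record of the failed fit over the whole trace
            window = (float(trace.times_min[0]), float(trace.times_min[-1]))
            fit = fit_generation_time(trace, window, config.fit_min_r)
            fits.append(fit)
            continue
        fits.append(fit_generation_time(trace, window, config.fit_min_r))
    return fits
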