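"""Step 1: detect phase-bright spores in frame 0 and mark them.

Dormant spores have a low water content and scatter light into the phase
ring, so they appear as bright disks on the mid-gray background of the first
frame.  Detection is a global intensity threshold (researcher-set, or Otsu's
method on frame 0 by default) followed by connected-component labelling and
an area filter.  Touching spores are kept as one marker — the analysis is
meant for isolated spores, and merged objects are censored downstream when
their colonies collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .stack_io import RunConfig, TimeLapseStack

__all__ = ["SporeMarker", "detect_spores", "apply_exclusions", "resolve_thresholds"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SporeMarker:
    """A detected phase-bright object in frame 0."""

    spore_id: int
    centroid: tuple[float, float]  # (y, x)
    area_px: int
    mean_intensity: float
    included: bool = True


def resolve_thresholds(
    stack: TimeLapseStack, config: RunConfig
) -> tuple[float, float]:
    """Resolve (bright, dark) intensity thresholds for this stack.

    ``bright`` defaults to Otsu's threshold on frame 0; ``dark`` defaults to
    the frame-0 background median minus a quarter of the bright/background
    contrast, i.e. a level a germinated (phase-dark) core will undershoot but
    background noise will not.
    """
    frame0 = np.asarray(stack.frames[0], dtype=float)
    bright = config.bright_threshold
    if bright is None:
        if np.ptp(frame0) == 0:
            bright = float(frame0.flat[0]) + 1.0  # constant frame: nothing is bright
        else:
            bright = float(threshold_otsu(frame0))
    background = float(np.median(frame0))
    dark = config.dark_threshold
    if dark is None:
        dark = background - 0.25 * max(bright - background, 1.0)
    if not dark < bright:
        raise ValueError(f"dark threshold {dark} not below bright threshold {bright}")
    lo, hi = float(frame0.min()), float(frame0.max())
    if not lo <= bright <= hi:
        log.warning(
            "bright threshold %.3g outside frame-0 intensity range [%.3g, %.3g]",
            bright, lo, hi,
        )
    return bright, dark


def detect_spores(stack: TimeLapseStack, config: RunConfig) -> list[SporeMarker]:
    """Detect all phase-bright spores in frame 0.

    Connected components of frame-0 pixels above the bright threshold,
    filtered to ``[min_spore_area_px, max_spore_area_px]``.  Markers are
    ordered by (row, col) of their centroid; an empty list (no detections)
    is a valid result, not an error.
    """
    frame0 = np.asarray(stack.frames[0], dtype=float)
    bright, _ = resolve_thresholds(stack, config)
    labels = measure.label(frame0 > bright, connectivity=2)
    markers: list[SporeMarker] = []
    for region in measure.regionprops(labels, intensity_image=frame0):
        if not config.min_spore_area_px <= region.area <= config.max_spore_area_px:
            continue
        markers.append(
            SporeMarker(
                spore_id=-1,  # assigned after sorting
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area_px=int(region.area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    markers.sort(key=lambda m: m.centroid)
    markers = [replace(m, spore_id=i) for i, m in enumerate(markers)]
    log.info(
        "detected %d spores in %s (bright threshold %.3g)",
        len(markers), stack.origin_name or "<stack>", bright,
    )
    return markers


def apply_exclusions(
    markers: Sequence[SporeMarker], exclusion_table: Sequence[int]
) -> list[SporeMarker]:
    """Mark manually rejected objects as excluded (``included=False``).

    Raises
    ------
    KeyError
        If an id in the table does not refer to an existing marker.
    """
    known = {m.spore_id for m in markers}
    for sid in exclusion_table:
        if sid not in known:
            raise KeyError(f"exclusion refers to unknown spore_id {sid}")
    excl = set(exclusion_table)
    out = [
        replace(m, included=False) if m.spore_id in excl else m for m in markers
    ]
    for sid in sorted(excl):
        log.info("spore %d manually excluded", sid)
    return out
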