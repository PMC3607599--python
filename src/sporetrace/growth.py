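"""Step 3: colony contours, area-in-time, censoring, division and burst.

Once an emerging cell escapes the spore coat it grows into a monolayer
microcolony whose footprint area is the growth readout.  Each frame is
segmented globally (|frame - background| above a threshold, background being
the per-frame median), components are associated to their marker by maximal
overlap with the previous frame, and a colony's measurement stops — is
*censored* — at the first frame where it would touch another colony or the
image boundary.  The censoring frame itself is excluded (half-open).

First division is detected automatically by a watershed-style split of the
tracked footprint (the protocol it automates is a manual call, so a manual
override is first-class and recorded).  A coat burst shows as a jump-like
single-frame area increase during outgrowth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

from .detect import SporeMarker, resolve_thresholds
from .germination import GerminationEvent
from .stack_io import RunConfig, TimeLapseStack

__all__ = [
    "AreaTrace",
    "DivisionEvent",
    "BurstEvent",
    "track_area",
    "track_all_areas",
    "detect_first_division",
    "detect_burst",
    "outgrowth_time",
]

log = logging.getLogger(__name__)

CensorReason = Literal["touch_colony", "touch_boundary", "end_of_movie", "lost"]

# search radius (px) for re-seeding when the component loses overlap
_SEED_SEARCH_PX = 5
# frames a component may go missing before the trace is censored as lost:
# a germinating spore crosses the background intensity mid-transition and
# briefly disappears from the above-background segmentation
_MAX_LOST_FRAMES = 5


@dataclass(frozen=True)
class AreaTrace:
    """Per-frame footprint area of one spore/colony, possibly censored."""

    spore_id: int
    times_min: np.ndarray
    areas_px2: np.ndarray
    pixel_size_um: float
    censored_at_min: float | None
    censor_reason: CensorReason

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.asarray(self.areas_px2, dtype=float)
        if t.shape != a.shape:
            raise ValueError("times and areas must be equally long")
        if np.any(a <= 0):
            raise ValueError("areas must be positive where defined")
        if self.censored_at_min is not None and t.size and t[-1] >= self.censored_at_min:
            raise ValueError("trace holds values at or after the censoring time")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "areas_px2", a)

    @property
    def areas_um2(self) -> np.ndarray:
        return self.areas_px2 * self.pixel_size_um**2


@dataclass(frozen=True)
class DivisionEvent:
    spore_id: int
    t_division_min: float
    source: Literal["auto", "manual"]

    def __post_init__(self) -> None:
        if self.t_division_min < 0:
            raise ValueError("t_division_min must be >= 0")


@dataclass(frozen=True)
class BurstEvent:
    spore_id: int
    t_burst_min: float
    relative_jump: float


def _resolve_area_threshold(stack: TimeLapseStack, config: RunConfig) -> float:
    if config.area_threshold is not None:
        return config.area_threshold
    bright, _ = resolve_thresholds(stack, config)
    background = float(np.median(np.asarray(stack.frames[0], dtype=float)))
    return 0.5 * max(bright - background, 2.0)


def _segment(frame: np.ndarray, area_threshold: float) -> np.ndarray:
    """Label connected components of above-background pixels."""
    background = float(np.median(frame))
    mask = np.abs(frame - background) > area_threshold
    return measure.label(mask, connectivity=2)


def _component_for_seed(
    labels: np.ndarray, prev_mask: np.ndarray | None, seed: tuple[float, float]
) -> int:
    """Label associated with a marker: maximal overlap with the previous
    frame's component, else the component at (or nearest) the seed point."""
    if prev_mask is not None:
        overlap = np.bincount(labels[prev_mask], minlength=labels.max() + 1)
        overlap[0] = 0
        if overlap.any():
            return int(overlap.argmax())
    sy, sx = int(round(seed[0])), int(round(seed[1]))
    ny, nx = labels.shape
    if 0 <= sy < ny and 0 <= sx < nx and labels[sy, sx]:
        return int(labels[sy, sx])
    y0, y1 = max(0, sy - _SEED_SEARCH_PX), min(ny, sy + _SEED_SEARCH_PX + 1)
    x0, x1 = max(0, sx - _SEED_SEARCH_PX), min(nx, sx + _SEED_SEARCH_PX + 1)
    window = labels[y0:y1, x0:x1]
    hit = np.argwhere(window > 0)
    if hit.size == 0:
        return 0
    d2 = (hit[:, 0] + y0 - seed[0]) ** 2 + (hit[:, 1] + x0 - seed[1]) ** 2
    return int(window[tuple(hit[int(d2.argmin())])])


def _touches_boundary(mask: np.ndarray, margin: int) -> bool:
    ys, xs = np.nonzero(mask)
    ny, nx = mask.shape
    return bool(
        ys.min() <= margin
        or xs.min() <= margin
        or ys.max() >= ny - 1 - margin
        or xs.max() >= nx - 1 - margin
    )


def _masks_collide(a: np.ndarray, b: np.ndarray, margin: int) -> bool:
    """True when the dilation of ``a`` by ``margin`` overlaps ``b``.

    Both masks are full-frame booleans; the precise dilation runs on the
    union bounding box only (cheap) and only when the margin-expanded boxes
    intersect at all.
    """
    ay, ax = np.nonzero(a)
    by, bx = np.nonzero(b)
    if ay.size == 0 or by.size == 0:
        return False
    pad = margin + 1
    if (
        ay.min() - pad > by.max()
        or by.min() - pad > ay.max()
        or ax.min() - pad > bx.max()
        or bx.min() - pad > ax.max()
    ):
        return False
    y0 = max(0, min(ay.min(), by.min()) - pad)
    y1 = min(a.shape[0], max(ay.max(), by.max()) + pad + 1)
    x0 = max(0, min(ax.min(), bx.min()) - pad)
    x1 = min(a.shape[1], max(ax.max(), bx.max()) + pad + 1)
    sub_a = a[y0:y1, x0:x1]
    if margin > 0:
        sub_a = ndi.binary_dilation(sub_a, structure=disk(margin))
    return bool(np.any(sub_a & b[y0:y1, x0:x1]))


def track_all_areas(
    stack: TimeLapseStack,
    markers: Sequence[SporeMarker],
    config: RunConfig,
) -> dict[int, AreaTrace]:
    """Track every included marker's component through the stack at once.

    Sharing the per-frame labelling across markers also makes the collision
    test well-defined: a colony is censored (reason ``touch_colony``) at the
    first frame where its component, dilated by ``collision_margin_px``,
    overlaps another tracked component — or where two markers resolve to the
    same component.
    """
    active = [m for m in markers if m.included]
    area_threshold = _resolve_area_threshold(stack, config)
    margin = config.collision_margin_px
    times = stack.times_min

    state: dict[int, dict] = {
        m.spore_id: {
            "seed": m.centroid,
            "prev": None,
            "times": [],
            "areas": [],
            "censored_at": None,
            "reason": "end_of_movie",
            "lost_since": None,  # frame index where the current gap began
        }
        for m in active
    }
    live = {m.spore_id for m in active}

    for k in range(stack.n_frames):
        if not live:
            break
        labels = _segment(np.asarray(stack.frames[k], dtype=float), area_threshold)
        frame_label: dict[int, int] = {}
        frame_mask: dict[int, np.ndarray] = {}
        for sid in sorted(live):
            st = state[sid]
            lab = _component_for_seed(labels, st["prev"], st["seed"])
            frame_label[sid] = lab
            if lab:
                frame_mask[sid] = labels == lab

        # censoring decisions for this frame; a missing component is only
        # fatal once the gap outlasts _MAX_LOST_FRAMES
        censor: dict[int, CensorReason] = {}
        gap: set[int] = set()
        by_label: dict[int, list[int]] = {}
        for sid, lab in frame_label.items():
            if lab == 0:
                st = state[sid]
                if st["lost_since"] is None:
                    st["lost_since"] = k
                if k - st["lost_since"] + 1 > _MAX_LOST_FRAMES:
                    censor[sid] = "lost"
                else:
                    gap.add(sid)
            else:
                state[sid]["lost_since"] = None
                by_label.setdefault(lab, []).append(sid)
        for lab, sids in by_label.items():
            if len(sids) > 1:  # two markers merged into one component
                for sid in sids:
                    censor[sid] = "touch_colony"
        live_ids = [
            s for s in sorted(frame_label) if s not in censor and s not in gap
        ]
        for sid in live_ids:
            if _touches_boundary(frame_mask[sid], margin):
                censor[sid] = "touch_boundary"
        live_ids = [s for s in live_ids if s not in censor]
        for i, sa in enumerate(live_ids):
            for sb in live_ids[i + 1 :]:
                if frame_label[sa] == frame_label[sb]:
                    continue
                if _masks_collide(frame_mask[sa], frame_mask[sb], margin):
                    censor.setdefault(sa, "touch_colony")
                    censor.setdefault(sb, "touch_colony")

        for sid in list(live):
            st = state[sid]
            if sid in censor:
                reason = censor[sid]
                k_censor = st["lost_since"] if reason == "lost" else k
                st["censored_at"] = float(times[k_censor])
                st["reason"] = reason
                log.info(
                    "spore %d censored at %.1f min (%s)",
                    sid, times[k_censor], reason,
                )
                live.discard(sid)
                continue
            if sid in gap:
                continue  # component missing this frame; keep the marker alive
            mask = frame_mask[sid]
            st["times"].append(float(times[k]))
            st["areas"].append(int(mask.sum()))
            st["prev"] = mask
            com = ndi.center_of_mass(mask)
            st["seed"] = (float(com[0]), float(com[1]))

    out: dict[int, AreaTrace] = {}
    for m in active:
        st = state[m.spore_id]
        out[m.spore_id] = AreaTrace(
            spore_id=m.spore_id,
            times_min=np.array(st["times"], dtype=float),
            areas_px2=np.array(st["areas"], dtype=float),
            pixel_size_um=stack.pixel_size_um,
            censored_at_min=st["censored_at"],
            censor_reason=st["reason"],
        )
    return out


def track_area(
    stack: TimeLapseStack,
    marker: SporeMarker,
    config: RunConfig,
    all_markers: Sequence[SporeMarker] | None = None,
) -> AreaTrace:
    """Track one marker's colony area (see :func:`track_all_areas`).

    ``all_markers`` supplies the other colonies for the collision test;
    when omitted only boundary censoring can occur.
    """
    markers = list(all_markers) if all_markers is not None else [marker]
    if marker.spore_id not in {m.spore_id for m in markers}:
        markers.append(marker)
    return track_all_areas(stack, markers, config)[marker.spore_id]


def _split_count(mask: np.ndarray, min_area: int) -> int:
    """Number of watershed basins (each above ``min_area``) of a footprint."""
    if mask.sum() < 2 * min_area:
        return 1
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    mask = np.pad(mask[y0:y1, x0:x1], 1)
    dist = ndi.distance_transform_edt(mask)
    r_equiv = math.sqrt(mask.sum() / math.pi)
    min_dist = max(2, int(round(0.6 * r_equiv)))
    peaks = peak_local_max(
        dist, min_distance=min_dist, labels=mask, exclude_border=False
    )
    if len(peaks) < 2:
        return 1
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        seeds[py, px] = i
    basins = watershed(-dist, seeds, mask=mask)
    sizes = np.bincount(basins.ravel())[1:]
    return int(np.sum(sizes >= min_area))


def detect_first_division(
    stack: TimeLapseStack,
    area_trace: AreaTrace,
    marker: SporeMarker,
    config: RunConfig,
    manual_t_division_min: float | None = None,
    scan_from_min: float | None = None,
) -> DivisionEvent | None:
    """Earliest persistent watershed split of the tracked footprint.

    Auto mode scans the uncensored frames for the first frame whose footprint
    splits into >= 2 sub-objects (each above ``min_spore_area_px``) and stays
    split in the following frame.  A manual time, when given, takes
    precedence verbatim (``source="manual"``).
    """
    if manual_t_division_min is not None:
        return DivisionEvent(
            spore_id=marker.spore_id,
            t_division_min=float(manual_t_division_min),
            source="manual",
        )
    if area_trace.times_min.size == 0:
        return None
    area_threshold = _resolve_area_threshold(stack, config)
    t_to_frame = {float(t): k for k, t in enumerate(stack.times_min)}
    prev_mask = None
    seed = marker.centroid
    split_streak = 0
    first_split_t = None
    for t in area_trace.times_min:
        if scan_from_min is not None and t < scan_from_min:
            continue  # division cannot precede the end of germination
        k = t_to_frame[float(t)]
        labels = _segment(np.asarray(stack.frames[k], dtype=float), area_threshold)
        lab = _component_for_seed(labels, prev_mask, seed)
        if lab == 0:
            break
        mask = labels == lab
        prev_mask = mask
        com = ndi.center_of_mass(mask)
        seed = (float(com[0]), float(com[1]))
        if _split_count(mask, config.min_spore_area_px) >= 2:
            split_streak += 1
            if split_streak == 1:
                first_split_t = float(t)
            if split_streak >= 2:
                return DivisionEvent(
                    spore_id=marker.spore_id,
                    t_division_min=first_split_t,
                    source="auto",
                )
        else:
            split_streak = 0
            first_split_t = None
    return None


def detect_burst(
    area_trace: AreaTrace,
    germination_event: GerminationEvent,
    division_event: DivisionEvent | None,
    config: RunConfig,
) -> list[BurstEvent]:
    """Jump-like area increases during outgrowth (coat burst or coat loss).

    A frame-to-frame relative area increase of at least
    ``burst_jump_fraction`` inside the window (end of germination, first
    division] is reported when it also exceeds the local growth trend (the
    median frame-to-frame ratio in a +-5-frame window).
    """
    if not germination_event.detected:
        raise ValueError("burst detection needs a detected germination event")
    t, a = area_trace.times_min, area_trace.areas_px2
    if t.size < 3:
        return []
    t_lo = germination_event.t_end_min
    t_hi = (
        division_event.t_division_min if division_event is not None else float(t[-1])
    )
    ratios = a[1:] / a[:-1]
    events: list[BurstEvent] = []
    for i, ratio in enumerate(ratios):
        t_jump = float(t[i + 1])  # first frame showing the enlarged area
        if not (t_lo < t_jump <= t_hi):
            continue
        if ratio - 1.0 < config.burst_jump_fraction:
            continue
        lo, hi = max(0, i - 5), min(len(ratios), i + 6)
        window = np.delete(ratios[lo:hi], i - lo)
        trend = float(np.median(window)) if window.size else 1.0
        if ratio / trend - 1.0 < config.burst_jump_fraction:
            continue
        events.append(
            BurstEvent(
                spore_id=area_trace.spore_id,
                t_burst_min=t_jump,
                relative_jump=float(ratio - 1.0),
            )
        )
    return events


def outgrowth_time(
    germination_event: GerminationEvent | None,
    division_event: DivisionEvent | None,
) -> float | None:
    """Outgrowth time: first division minus end of germination (minutes).

    Absent when either event is missing; a negative difference means the
    annotations are inconsistent and raises.
    """
    if (
        germination_event is None
        or not germination_event.detected
        or division_event is None
    ):
        return None
    dt = division_event.t_division_min - germination_event.t_end_min
    if dt < 0:
        raise ValueError(
            f"spore {division_event.spore_id}: first division at "
            f"{division_event.t_division_min} min precedes end of germination at "
            f"{germination_event.t_end_min} min"
        )
    return float(dt)
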