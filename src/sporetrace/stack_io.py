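"""Image-stack and tabular I/O plus the run configuration.

A time-lapse position is a single-channel grayscale stack (time, y, x) with a
known frame interval and pixel size.  Frame interval and pixel size are always
supplied by the caller rather than parsed from vendor metadata, whose dialects
vary between acquisition packages.  Times are reported in minutes from frame 0
(``t = frame_index * frame_interval_s / 60``); pixel coordinates are 0-based
``(row, col)``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TimeLapseStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_records",
    "read_records",
]


@dataclass(frozen=True)
class TimeLapseStack:
    """Ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        3-D array ``(time, y, x)``, integer or float grayscale.
    frame_interval_s
        Seconds between consecutive frames (> 0).
    pixel_size_um
        Micrometres per pixel (> 0).
    origin_name
        Free-text field-of-view label.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    origin_name: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, y, x); got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise ValueError("a time-lapse stack needs at least 2 frames")
        if not np.issubdtype(frames.dtype, np.number):
            raise ValueError(f"frames must be numeric, got dtype {frames.dtype}")
        if np.issubdtype(frames.dtype, np.complexfloating):
            raise ValueError("frames must be real-valued grayscale")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(n_rows, n_cols)``."""
        return self.frames.shape[1:]

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes from frame 0."""
        return np.arange(self.n_frames) * (self.frame_interval_s / 60.0)

    @property
    def duration_min(self) -> float:
        """Time span covered by the stack, first to last frame."""
        return float(self.times_min[-1])


@dataclass
class RunConfig:
    """Researcher-set thresholds and tolerances for one analysis run.

    The bright/dark intensity thresholds mirror the interactive thresholds a
    researcher would set by eye; ``None`` means derive them automatically from
    frame 0 (Otsu for the bright threshold, a fixed offset below the
    background median for the dark one).
    """

    bright_threshold: float | None = None
    dark_threshold: float | None = None
    center_radius_px: int = 2
    min_spore_area_px: int = 5
    max_spore_area_px: int = 5000
    settle_tolerance: float = 5.0
    burst_jump_fraction: float = 0.2
    fit_min_r: float = 0.99
    collision_margin_px: int = 2
    area_threshold: float | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if (
            self.bright_threshold is not None
            and self.dark_threshold is not None
            and not self.dark_threshold < self.bright_threshold
        ):
            raise ValueError("dark_threshold must be below bright_threshold")
        if self.burst_jump_fraction <= 0:
            raise ValueError("burst_jump_fraction must be > 0")
        if not 0 < self.fit_min_r <= 1:
            raise ValueError("fit_min_r must lie in (0, 1]")
        if self.min_spore_area_px > self.max_spore_area_px:
            raise ValueError("min_spore_area_px exceeds max_spore_area_px")
        if self.center_radius_px < 0 or self.collision_margin_px < 0:
            raise ValueError("radii and margins must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_stack(
    path: str | os.PathLike,
    frame_interval_s: float,
    pixel_size_um: float,
    origin_name: str | None = None,
) -> TimeLapseStack:
    """Read a multi-page grayscale TIFF as a :class:`TimeLapseStack`.

    Raises
    ------
    ValueError
        If the file holds fewer than two frames or is not single-channel
        grayscale.
    """
    frames = tifffile.imread(os.fspath(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path}: single-frame image, need a time series")
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale (time, y, x), got shape {frames.shape}"
        )
    if frames.shape[-1] in (3, 4) and frames.shape[-1] < min(frames.shape[:-1]):
        raise ValueError(f"{path}: looks like a color image (shape {frames.shape})")
    if origin_name is None:
        origin_name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return TimeLapseStack(
        frames=frames,
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        origin_name=origin_name,
    )


def write_stack(stack: TimeLapseStack, path: str | os.PathLike) -> None:
    """Write the stack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(os.fspath(path), stack.frames, photometric="minisblack")


# Master record table: one row per spore, the metric columns of the summary
# tables plus fate and censoring bookkeeping.
RECORD_COLUMNS = [
    "spore_id",
    "origin_name",
    "condition",
    "fate",
    "t_start_min",
    "germ_duration_min",
    "outgrowth_time_min",
    "generation_time_min",
    "fit_r_value",
    "burst_times_min",
    "censor_reason",
    "division_source",
]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert SporeRecord-like objects to a tidy DataFrame."""
    rows = []
    for rec in records:
        row = {}
        for col in RECORD_COLUMNS:
            val = getattr(rec, col, None)
            if col == "burst_times_min":
                val = ";".join(repr(float(t)) for t in (val or []))
            row[col] = val
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Sequence, path: str | os.PathLike) -> None:
    """Write spore records as a comma-delimited UTF-8 table with header.

    Floats are written with ``repr`` precision so that a read-back compares
    equal to the in-memory values.
    """
    df = records_to_frame(records)
    df.to_csv(os.fspath(path), index=False)


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    """Read a record table written by :func:`write_records`."""
    df = pd.read_csv(os.fspath(path), dtype={"burst_times_min": str})
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(f"{path}: unexpected record columns {list(df.columns)}")
    return df


def parse_burst_times(cell: object) -> list[float]:
    """Decode the semicolon-joined burst-time cell of a record table."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [float(tok) for tok in text.split(";")]
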