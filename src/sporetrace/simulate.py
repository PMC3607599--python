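"""Forward simulation of phase-contrast-like germination movies.

The simulator renders the phenomenology the analysis assumes, with per-spore
ground truth:

* dormant spores are bright disks of constant intensity on a mid-gray
  background;
* germination is a monotone logistic drop of the spore's intensity from
  ``i_bright`` to ``i_dark``, timed so that the 90%-to-10% span of the drop
  range equals the scripted germination duration exactly (the timing rule the
  detector applies therefore holds for ground truth by construction);
* after first division the colony footprint is a connected two-lobe shape
  whose total area follows ``area(t) = a0 * 2**((t - t_div) / generation_time)``;
* a coat burst is a single-frame relative jump in footprint area;
* Gaussian pixel noise is added last.

Optical realism (phase halos, shading, defocus) is deliberately out of scope:
only the statistical and geometric structure downstream measurements rely on
is modelled.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .stack_io import TimeLapseStack

__all__ = [
    "SporeScript",
    "GroundTruthManifest",
    "PopulationParams",
    "CONTROL_POPULATION",
    "HEAT_STRESSED_POPULATION",
    "logistic_center_intensity",
    "scripted_crossing_times",
    "scripted_area_px2",
    "sample_population",
    "simulate_movie",
]

Fate = Literal["outgrow", "germinate_only", "dormant", "vegetative"]

# Relative lobe separation of the post-division footprint: centres sit
# 1.6 * lobe_radius apart, leaving a clear waist for watershed splitting.
_LOBE_SEP = 1.6
# Union area of two equal disks (radius r) at that separation, in units of r^2.
_theta = math.acos(_LOBE_SEP / 2.0)
TWO_LOBE_AREA_COEF = 2.0 * math.pi - (
    2.0 * _theta - (_LOBE_SEP / 2.0) * math.sqrt(4.0 - _LOBE_SEP**2)
)
_LN9 = math.log(9.0)


@dataclass
class SporeScript:
    """Ground-truth life history of one simulated spore (or cell).

    Times are minutes from frame 0.  ``fate`` is one of ``outgrow``,
    ``germinate_only``, ``dormant`` or ``vegetative`` (a cell already
    germinated at t=0, used for vegetative-growth movies).
    """

    spore_id: int
    centroid: tuple[float, float]  # (y, x) pixels
    fate: Fate
    t_germ_start_min: float | None = None
    germ_duration_min: float | None = None
    t_first_division_min: float | None = None
    generation_time_min: float | None = None
    burst_time_min: float | None = None
    burst_jump: float = 0.4
    i_bright: float = 180.0
    i_dark: float = 40.0
    spore_radius_px: float = 3.0

    def __post_init__(self) -> None:
        if self.fate not in ("outgrow", "germinate_only", "dormant", "vegetative"):
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.i_dark >= self.i_bright:
            raise ValueError("i_dark must be below i_bright")
        if self.spore_radius_px <= 0:
            raise ValueError("spore_radius_px must be > 0")
        if self.fate in ("outgrow", "germinate_only"):
            if self.t_germ_start_min is None or self.germ_duration_min is None:
                raise ValueError(f"{self.fate} script needs germination times")
            if self.t_germ_start_min < 0:
                raise ValueError("t_germ_start_min must be >= 0")
            if self.germ_duration_min <= 0:
                raise ValueError("germ_duration_min must be > 0")
        if self.fate == "dormant":
            if self.t_germ_start_min is not None or self.t_first_division_min is not None:
                raise ValueError("dormant script carries no event times")
        if self.fate in ("outgrow", "vegetative"):
            if self.t_first_division_min is None or self.generation_time_min is None:
                raise ValueError(f"{self.fate} script needs division time and generation time")
            if self.generation_time_min <= 0:
                raise ValueError("generation_time_min must be > 0")
        if self.fate == "outgrow":
            if self.t_first_division_min <= self.t_germ_start_min + self.germ_duration_min:
                raise ValueError("first division must follow the end of germination")
        if self.fate == "germinate_only" and self.t_first_division_min is not None:
            raise ValueError("germinate_only script cannot divide")
        if self.burst_time_min is not None and self.burst_jump <= 0:
            raise ValueError("burst_jump must be > 0 when a burst is scripted")

    @property
    def t_germ_end_min(self) -> float | None:
        if self.t_germ_start_min is None or self.germ_duration_min is None:
            return None
        return self.t_germ_start_min + self.germ_duration_min

    @property
    def spore_area_px2(self) -> float:
        return math.pi * self.spore_radius_px**2


def logistic_center_intensity(
    t_min: np.ndarray | float,
    i_bright: float,
    i_dark: float,
    t_start_min: float,
    duration_min: float,
) -> np.ndarray | float:
    """Closed-form centre intensity of a germinating spore.

    Logistic drop centred at ``t_start + duration/2`` with scale chosen so the
    90% and 10% levels of the drop range are crossed exactly at ``t_start``
    and ``t_start + duration``.
    """
    t_mid = t_start_min + duration_min / 2.0
    s = duration_min / (2.0 * _LN9)
    z = np.clip((np.asarray(t_min, dtype=float) - t_mid) / s, -500, 500)
    out = i_dark + (i_bright - i_dark) / (1.0 + np.exp(z))
    return float(out) if np.isscalar(t_min) else out


def scripted_crossing_times(script: SporeScript) -> tuple[float, float]:
    """Analytic 90%- and 10%-level crossing times of the scripted sigmoid."""
    if script.t_germ_start_min is None:
        raise ValueError("script has no germination")
    return script.t_germ_start_min, script.t_germ_end_min  # by construction


def scripted_area_px2(script: SporeScript, t_min: float) -> float:
    """Scripted footprint area (px^2) at time ``t_min``.

    Dormant and pre-division spores keep the spore disk area (plus the burst
    jump once it happens); divided colonies follow the exponential law,
    continuous at division.
    """
    a = script.spore_area_px2
    if script.fate == "vegetative":
        return a * 2.0 ** (t_min / script.generation_time_min)
    if script.fate in ("dormant", "germinate_only"):
        return a
    # outgrow
    if script.burst_time_min is not None and t_min >= script.burst_time_min:
        a = a * (1.0 + script.burst_jump)
    t_div = script.t_first_division_min
    if t_min < t_div:
        return a
    a_div = script.spore_area_px2
    if script.burst_time_min is not None and script.burst_time_min <= t_div:
        a_div *= 1.0 + script.burst_jump
    return a_div * 2.0 ** ((t_min - t_div) / script.generation_time_min)


@dataclass
class GroundTruthManifest:
    """All spore scripts of one movie plus the global rendering parameters."""

    scripts: list[SporeScript]
    frame_interval_s: float = 60.0
    pixel_size_um: float = 0.065
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    min_separation_px: float = 12.0

    def __post_init__(self) -> None:
        ids = [s.spore_id for s in self.scripts]
        if len(set(ids)) != len(ids):
            raise ValueError("spore_ids must be unique")
        pts = np.array([s.centroid for s in self.scripts], dtype=float)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(np.hypot(*(pts[i] - pts[j])))
                if d < self.min_separation_px:
                    raise ValueError(
                        f"spores {ids[i]} and {ids[j]} are {d:.1f} px apart "
                        f"(min {self.min_separation_px})"
                    )

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path: str | os.PathLike) -> None:
        doc = dataclasses.asdict(self)
        doc["scripts"] = [
            {**s, "centroid": list(s["centroid"])} for s in doc["scripts"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "GroundTruthManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scripts = [
            SporeScript(**{**s, "centroid": tuple(s["centroid"])})
            for s in doc.pop("scripts")
        ]
        return cls(scripts=scripts, **doc)

    def scripts_frame(self) -> pd.DataFrame:
        """Ground-truth table, one row per spore (for joins against results)."""
        rows = []
        for s in self.scripts:
            rows.append(
                {
                    "spore_id": s.spore_id,
                    "centroid_y": s.centroid[0],
                    "centroid_x": s.centroid[1],
                    "fate": s.fate,
                    "t_germ_start_min": s.t_germ_start_min,
                    "germ_duration_min": s.germ_duration_min,
                    "t_first_division_min": s.t_first_division_min,
                    "generation_time_min": s.generation_time_min,
                    "burst_time_min": s.burst_time_min,
                }
            )
        return pd.DataFrame(rows)


# -- population sampling -------------------------------------------------


@dataclass(frozen=True)
class PopulationParams:
    """Distribution parameters for sampling a spore population.

    Defaults describe an untreated, heat-activated population: 94% of spores
    germinate and 84.7% grow out within the observation window; start of
    germination is lognormal (mean 63 min, sd 56 min — a normal with sd of
    the order of the mean would put substantial mass below zero), germination
    lasts 3.5 +- 0.9 min, outgrowth (end of germination to first division)
    254 +- 34 min and the subsequent generation time is 62 +- 14 min.
    """

    germinated_fraction: float = 0.940
    outgrown_fraction: float = 0.847
    start_mean_min: float = 63.0
    start_sd_min: float = 56.0
    duration_mean_min: float = 3.5
    duration_sd_min: float = 0.9
    outgrowth_mean_min: float = 254.0
    outgrowth_sd_min: float = 34.0
    generation_mean_min: float = 62.0
    generation_sd_min: float = 14.0
    burst_probability: float = 0.5
    burst_jump: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.outgrown_fraction <= self.germinated_fraction <= 1.0:
            raise ValueError(
                "need 0 <= outgrown_fraction <= germinated_fraction <= 1"
            )


CONTROL_POPULATION = PopulationParams()
#: Wet-heat-stressed population: fewer spores germinate (52.9%) and grow out
#: (36.3%); germination starts later (82 +- 68 min) and lasts longer
#: (5.3 +- 1.7 min); outgrowth and generation times barely move.
HEAT_STRESSED_POPULATION = PopulationParams(
    germinated_fraction=0.529,
    outgrown_fraction=0.363,
    start_mean_min=82.0,
    start_sd_min=68.0,
    duration_mean_min=5.3,
    duration_sd_min=1.7,
    outgrowth_mean_min=263.0,
    outgrowth_sd_min=34.0,
    generation_mean_min=62.0,
    generation_sd_min=13.0,
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _grid_centroids(
    n: int, shape: tuple[int, int], margin_px: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Jittered grid placement guaranteeing pairwise separation."""
    if n == 0:
        return []
    ny, nx = shape
    cols = math.ceil(math.sqrt(n * nx / ny))
    rows = math.ceil(n / cols)
    ys = np.linspace(margin_px, ny - 1 - margin_px, rows)
    xs = np.linspace(margin_px, nx - 1 - margin_px, cols)
    pitch = min(
        ys[1] - ys[0] if rows > 1 else ny,
        xs[1] - xs[0] if cols > 1 else nx,
    )
    jitter = max(0.0, (pitch - 2 * margin_px) / 2.0) * 0.3
    pts = []
    for iy in ys:
        for ix in xs:
            if len(pts) == n:
                break
            dy, dx = rng.uniform(-jitter, jitter, size=2)
            pts.append((float(iy + dy), float(ix + dx)))
    order = rng.permutation(n)
    return [pts[i] for i in order]


def sample_population(
    n_spores: int,
    params: PopulationParams = CONTROL_POPULATION,
    *,
    shape: tuple[int, int] = (512, 512),
    frame_interval_s: float = 60.0,
    pixel_size_um: float = 0.065,
    noise_sd: float = 0.0,
    spore_radius_px: float = 3.0,
    margin_px: float = 15.0,
    seed: int = 0,
) -> GroundTruthManifest:
    """Sample a ground-truth manifest for ``n_spores`` spores.

    Fate counts are deterministic (``round(fraction * n)``) so scripted
    population fractions are exact; which spore gets which fate, the event
    times and the placement are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_germ = int(round(params.germinated_fraction * n_spores))
    n_out = int(round(params.outgrown_fraction * n_spores))
    fates = (
        ["outgrow"] * n_out
        + ["germinate_only"] * (n_germ - n_out)
        + ["dormant"] * (n_spores - n_germ)
    )
    rng.shuffle(fates)
    centroids = _grid_centroids(n_spores, shape, margin_px, rng)

    mu, sigma = _lognormal_params(params.start_mean_min, params.start_sd_min)
    scripts: list[SporeScript] = []
    for i, (fate, c) in enumerate(zip(fates, centroids)):
        kwargs: dict = {}
        if fate in ("outgrow", "germinate_only"):
            t0 = float(rng.lognormal(mu, sigma))
            dur = float(
                max(0.5, rng.normal(params.duration_mean_min, params.duration_sd_min))
            )
            kwargs.update(t_germ_start_min=t0, germ_duration_min=dur)
        if fate == "outgrow":
            out = float(
                max(10.0, rng.normal(params.outgrowth_mean_min, params.outgrowth_sd_min))
            )
            gen = float(
                max(10.0, rng.normal(params.generation_mean_min, params.generation_sd_min))
            )
            kwargs.update(
                t_first_division_min=kwargs["t_germ_start_min"]
                + kwargs["germ_duration_min"]
                + out,
                generation_time_min=gen,
            )
            if rng.uniform() < params.burst_probability:
                t_end = kwargs["t_germ_start_min"] + kwargs["germ_duration_min"]
                kwargs["burst_time_min"] = float(
                    rng.uniform(t_end + 1.0, kwargs["t_first_division_min"] - 1.0)
                )
                kwargs["burst_jump"] = params.burst_jump
        scripts.append(
            SporeScript(
                spore_id=i,
                centroid=c,
                fate=fate,
                spore_radius_px=spore_radius_px,
                **kwargs,
            )
        )
    return GroundTruthManifest(
        scripts=scripts,
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        noise_sd=noise_sd,
        min_separation_px=min(12.0, 2 * spore_radius_px + 2),
    )


# -- rendering -----------------------------------------------------------


def _disk_mask(
    shape: tuple[int, int], cy: float, cx: float, radius: float
) -> np.ndarray:
    ny, nx = shape
    y0 = max(0, int(math.floor(cy - radius - 1)))
    y1 = min(ny, int(math.ceil(cy + radius + 2)))
    x0 = max(0, int(math.floor(cx - radius - 1)))
    x1 = min(nx, int(math.ceil(cx + radius + 2)))
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def footprint_mask(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    area_px2: float,
    divided: bool,
) -> np.ndarray:
    """Rasterise a scripted footprint of the given analytic area.

    Pre-division: a filled disk of radius ``sqrt(area/pi)``.  Post-division:
    two overlapping disks (centres ``1.6 r`` apart along x) whose analytic
    union area equals ``area_px2``.
    """
    if not divided:
        return _disk_mask(shape, cy, cx, math.sqrt(area_px2 / math.pi))
    r = math.sqrt(area_px2 / TWO_LOBE_AREA_COEF)
    off = _LOBE_SEP * r / 2.0
    return _disk_mask(shape, cy, cx - off, r) | _disk_mask(shape, cy, cx + off, r)


def _render_script(
    img: np.ndarray, script: SporeScript, t_min: float
) -> None:
    cy, cx = script.centroid
    shape = img.shape
    if script.fate == "dormant":
        img[_disk_mask(shape, cy, cx, script.spore_radius_px)] = script.i_bright
        return
    if script.fate == "vegetative":
        area = scripted_area_px2(script, t_min)
        divided = t_min >= script.t_first_division_min
        img[footprint_mask(shape, cy, cx, area, divided)] = script.i_dark
        return
    # germinating spore: sigmoid intensity on the spore disk
    intensity = logistic_center_intensity(
        t_min,
        script.i_bright,
        script.i_dark,
        script.t_germ_start_min,
        script.germ_duration_min,
    )
    if script.fate == "germinate_only" or t_min < script.t_germ_end_min:
        img[_disk_mask(shape, cy, cx, script.spore_radius_px)] = intensity
        return
    # outgrow, past germination: dark footprint following the area law
    area = scripted_area_px2(script, t_min)
    divided = t_min >= script.t_first_division_min
    img[footprint_mask(shape, cy, cx, area, divided)] = script.i_dark


def simulate_movie(
    manifest: GroundTruthManifest,
    n_frames: int,
    shape: tuple[int, int],
    seed: int = 0,
) -> TimeLapseStack:
    """Render the manifest into a :class:`TimeLapseStack`.

    Deterministic for a fixed seed (which drives only the pixel noise; all
    event times come from the manifest).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    ny, nx = shape
    for s in manifest.scripts:
        cy, cx = s.centroid
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"spore {s.spore_id} centroid {s.centroid} outside {shape}")
    for i, a in enumerate(manifest.scripts):
        for b in manifest.scripts[i + 1 :]:
            d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
            if d < a.spore_radius_px + b.spore_radius_px:
                raise ValueError(
                    f"spores {a.spore_id} and {b.spore_id} overlap at t=0"
                )
    rng = np.random.default_rng(seed)
    dt_min = manifest.frame_interval_s / 60.0
    frames = np.empty((n_frames, ny, nx), dtype=np.float32)
    for k in range(n_frames):
        img = np.full((ny, nx), manifest.background_intensity, dtype=np.float64)
        for script in manifest.scripts:
            _render_script(img, script, k * dt_min)
        if manifest.noise_sd > 0:
            img = img + rng.normal(0.0, manifest.noise_sd, size=(ny, nx))
        frames[k] = img.astype(np.float32)
    return TimeLapseStack(
        frames=frames,
        frame_interval_s=manifest.frame_interval_s,
        pixel_size_um=manifest.pixel_size_um,
        origin_name="synthetic",
    )
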