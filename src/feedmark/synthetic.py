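"""Synthetic feeding assays with exact ground truth.

Two generators make every pipeline stage testable without real scans:

* :func:`simulate_area_series` turns a scripted feeding schedule directly
  into a leaf-area time series (plus optional Gaussian measurement
  noise), bypassing imaging entirely — the oracle for event detection.
* :func:`render_sequence` renders the schedule as a time-lapse image
  stack: an elliptical leaf whose pixels are removed radially around
  each event's feeding site at the scripted rate, a moving larva blob
  whose color can collide with leaf or background, and per-pixel sensor
  noise — the oracle for segmentation and spatial analysis.

Both scenes of the assay hardware are emulated: ``reflective`` (green
leaf and larva on a near-black background, where a leaf-colored larva
defeats plain color thresholding) and ``transmissive`` (back-lit: dark
silhouettes on white, where any larva color works).

Scripted quantities are exact; rendered consumption is pixel-quantized,
so rendered truth areas differ from scripted ones by less than one pixel
per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ScriptValidationError
from .imaging_io import FrameSeries, LeafAreaSeries, MaskSeries

# ---------------------------------------------------------------------------
# Scripts and scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted feeding event."""

    start_min: float
    duration_min: float
    rate_mm2_per_min: float
    site: tuple[int, int] | None = None  # (row, col) feeding site in the rendered scene

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min

    @property
    def area_mm2(self) -> float:
        return self.rate_mm2_per_min * self.duration_min


@dataclass
class BehaviorScript:
    """A feeding/resting schedule plus larva movement.

    ``larva_path`` gives the larva's (row, col) center per frame, or
    ``None`` for frames where the larva is hidden (e.g. under the lid
    rim). Events must be non-overlapping in time and sorted.
    """

    events: list[ScriptedEvent]
    larva_path: list[tuple[int, int] | None] = field(default_factory=list)
    seed: int = 0

    def validate(self, initial_area_mm2: float) -> None:
        evs = self.events
        if any(e.duration_min <= 0 or e.rate_mm2_per_min <= 0 for e in evs):
            raise ScriptValidationError("event durations and rates must be positive")
        for a, b in zip(evs, evs[1:]):
            if b.start_min < a.end_min:
                raise ScriptValidationError(
                    f"events overlap in time at t={b.start_min} min"
                )
        total = sum(e.area_mm2 for e in evs)
        if total > initial_area_mm2:
            raise ScriptValidationError(
                f"scripted consumption {total:.1f} mm² exceeds leaf area "
                f"{initial_area_mm2:.1f} mm²"
            )


# Default 8-bit colors per scan mode. In reflective scans the leaf and a
# Pieris-style larva are both green on a near-black background; a
# Spodoptera-style larva carries black patches indistinguishable from
# that background. In transmissive scans everything opaque is dark on
# white.
_COLORS = {
    "reflective": {
        "background": (12, 12, 12),
        "leaf": (60, 150, 62),
        "larva_leaf_like": (72, 158, 70),
        "larva_dark_base": (55, 55, 48),
        "larva_dark_patch": (8, 8, 8),
    },
    "transmissive": {
        "background": (250, 250, 250),
        "leaf": (52, 62, 43),
        "larva_leaf_like": (70, 90, 60),
        "larva_dark_base": (70, 60, 55),
        "larva_dark_patch": (20, 18, 16),
    },
}


@dataclass
class SceneSpec:
    """Geometry, optics and noise of a rendered assay scene."""

    height: int = 220
    width: int = 300
    dpi: float = 254.0  # 0.1 mm per pixel
    scan_mode: str = "reflective"
    leaf_center: tuple[int, int] | None = None  # defaults to image center
    leaf_axes: tuple[int, int] = (80, 110)  # ellipse semi-axes (rows, cols)
    larva_palette: str = "leaf_like"  # or "dark_patterned"
    larva_axes: tuple[int, int] = (7, 14)
    noise_sd: float = 2.0  # 8-bit units, per channel

    def __post_init__(self) -> None:
        if self.scan_mode not in _COLORS:
            raise ScriptValidationError(f"unknown scan_mode {self.scan_mode!r}")
        if self.larva_palette not in ("leaf_like", "dark_patterned"):
            raise ScriptValidationError(f"unknown larva palette {self.larva_palette!r}")
        if self.leaf_center is None:
            self.leaf_center = (self.height // 2, self.width // 2)

    @property
    def mm_per_px(self) -> float:
        return 25.4 / self.dpi


@dataclass
class TrueEvent:
    """Ground-truth parameters of one event, as scripted (and as rendered)."""

    start_min: float
    duration_min: float
    rate_mm2_per_min: float
    area_mm2: float
    site: tuple[int, int] | None = None
    mark_mask: np.ndarray | None = None
    centroid: tuple[float, float] | None = None  # (row, col)


@dataclass
class GroundTruth:
    """Exact per-frame and per-event truth for a synthetic assay."""

    initial_area_mm2: float
    area_series_mm2: np.ndarray  # true remaining area per frame
    events: list[TrueEvent]
    intervals_min: list[float]  # gap end(k) -> start(k+1)
    remaining_masks: np.ndarray | None = None  # (n, h, w) bool, rendered only

    @property
    def mask_series(self) -> MaskSeries:
        if self.remaining_masks is None:
            raise ScriptValidationError("this ground truth carries no rendered masks")
        return MaskSeries(self.remaining_masks, stage="mask2")


# ---------------------------------------------------------------------------
# Script builders
# ---------------------------------------------------------------------------


def random_behavior_script(
    rng: np.random.Generator,
    n_events: tuple[int, int] = (8, 15),
    rate_range: tuple[float, float] = (0.3, 1.5),
    duration_range: tuple[int, int] = (2, 10),
    gap_range: tuple[int, int] = (5, 60),
    first_start: int = 5,
    molting_gap_min: float | None = None,
) -> BehaviorScript:
    """Draw a random feeding schedule on the whole-minute grid.

    Defaults emulate young-larva feeding bouts on Arabidopsis: 8–15
    events per assay, rates 0.3–1.5 mm² min⁻¹, bouts of 2–10 min
    separated by 5–60 min rests. ``molting_gap_min`` optionally replaces
    one mid-schedule gap with a long molting pause.
    """
    k = int(rng.integers(n_events[0], n_events[1] + 1))
    events = []
    t = first_start
    molt_at = int(rng.integers(1, k)) if molting_gap_min is not None else -1
    for i in range(k):
        duration = int(rng.integers(duration_range[0], duration_range[1] + 1))
        rate = float(rng.uniform(*rate_range))
        events.append(ScriptedEvent(float(t), float(duration), rate))
        gap = (
            float(molting_gap_min)
            if i + 1 == molt_at
            else int(rng.integers(gap_range[0], gap_range[1] + 1))
        )
        t += duration + gap
    return BehaviorScript(events=events, seed=int(rng.integers(2**31)))


def linear_path(
    start: tuple[int, int], end: tuple[int, int], n_frames: int
) -> list[tuple[int, int]]:
    """A straight larva walk from start to end over n_frames frames."""
    rows = np.linspace(start[0], end[0], n_frames)
    cols = np.linspace(start[1], end[1], n_frames)
    return [(int(round(r)), int(round(c))) for r, c in zip(rows, cols)]


# ---------------------------------------------------------------------------
# Series-level simulation
# ---------------------------------------------------------------------------


def _consumed_mm2(events: list[ScriptedEvent], minutes: np.ndarray) -> np.ndarray:
    """Cumulative scripted consumption at each time point."""
    total = np.zeros_like(minutes, dtype=float)
    for e in events:
        total += e.rate_mm2_per_min * np.clip(minutes - e.start_min, 0.0, e.duration_min)
    return total


def _script_truth(script: BehaviorScript, initial_area_mm2: float, minutes: np.ndarray) -> GroundTruth:
    events = [
        TrueEvent(e.start_min, e.duration_min, e.rate_mm2_per_min, e.area_mm2, e.site)
        for e in script.events
    ]
    intervals = [
        b.start_min - a.end_min for a, b in zip(script.events, script.events[1:])
    ]
    return GroundTruth(
        initial_area_mm2=initial_area_mm2,
        area_series_mm2=initial_area_mm2 - _consumed_mm2(script.events, minutes),
        events=events,
        intervals_min=intervals,
    )


def simulate_area_series(
    script: BehaviorScript,
    n_frames: int | None = None,
    initial_area_mm2: float = 400.0,
    noise_sd: float = 0.0,
    frame_interval: float = 1.0,
    roi_label: str = "sim",
    rng: np.random.Generator | None = None,
) -> tuple[LeafAreaSeries, GroundTruth]:
    """Simulate a leaf-area series directly from a feeding schedule.

    S(t) = S(0) − cumulative scripted consumption + i.i.d. N(0, noise_sd)
    measurement noise (mm²). The default initial area is in the range of
    a mature Arabidopsis rosette leaf. The same script, seed and shape
    give identical output.
    """
    script.validate(initial_area_mm2)
    if n_frames is None:
        last = script.events[-1].end_min if script.events else 0.0
        n_frames = int(np.ceil(last / frame_interval)) + 11
    minutes = np.arange(n_frames) * frame_interval
    truth = _script_truth(script, initial_area_mm2, minutes)
    s = truth.area_series_mm2.copy()
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(script.seed)
        s = s + rng.normal(0.0, noise_sd, size=n_frames)
    # the series generator reports mm² directly; use unit calibration
    series = LeafAreaSeries(
        roi_label=roi_label, area_px=s, mm_per_px=1.0, frame_interval=frame_interval
    )
    return series, truth


# ---------------------------------------------------------------------------
# Rendered image stacks
# ---------------------------------------------------------------------------


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _ordered_site_pixels(
    available: np.ndarray, site: tuple[int, int]
) -> np.ndarray:
    """Available pixels ordered by distance from the feeding site.

    Ties break deterministically by (distance, row, col) so renders are
    reproducible across platforms.
    """
    rows, cols = np.nonzero(available)
    d2 = (rows - site[0]) ** 2 + (cols - site[1]) ** 2
    order = np.lexsort((cols, rows, d2))
    return np.stack([rows[order], cols[order]], axis=1)


def _draw_larva(
    img: np.ndarray, center: tuple[int, int], scene: SceneSpec, colors: dict
) -> None:
    body = _ellipse_mask(img.shape[:2], center, scene.larva_axes)
    if scene.larva_palette == "leaf_like":
        img[body] = colors["larva_leaf_like"]
        return
    img[body] = colors["larva_dark_base"]
    # transverse dark stripes, the Spodoptera-style banding
    rr, cc = np.nonzero(body)
    stripe = ((cc - center[1]) // 4) % 2 == 0
    img[rr[stripe], cc[stripe]] = colors["larva_dark_patch"]


def render_sequence(
    script: BehaviorScript,
    scene: SceneSpec,
    n_frames: int | None = None,
    frame_interval: float = 1.0,
    out_dir: str | Path | None = None,
) -> tuple[FrameSeries, GroundTruth]:
    """Render a feeding schedule as a time-lapse image stack with truth.

    Leaf pixels are removed radially around each event's site at the
    scripted rate (pixel-quantized); the larva ellipse is drawn on top
    along ``script.larva_path``; Gaussian sensor noise is added per
    pixel and channel. With ``out_dir`` set, frames are written as
    serial-numbered PNGs beside a machine-readable truth manifest.
    """
    colors = _COLORS[scene.scan_mode]
    px_mm2 = scene.mm_per_px**2
    shape = (scene.height, scene.width)
    leaf0 = _ellipse_mask(shape, scene.leaf_center, scene.leaf_axes)
    initial_area = float(leaf0.sum()) * px_mm2
    script.validate(initial_area)

    if n_frames is None:
        last = script.events[-1].end_min if script.events else 0.0
        n_frames = int(np.ceil(last / frame_interval)) + 11
    minutes = np.arange(n_frames) * frame_interval

    # allocate pixels to events in temporal order, radially from each site
    consumed_global = np.zeros(shape, dtype=bool)
    alloc: list[np.ndarray] = []  # per event: ordered (row, col) pixel list
    for e in script.events:
        if e.site is None:
            raise ScriptValidationError("rendered events need a feeding site")
        if not leaf0[e.site]:
            raise ScriptValidationError(f"feeding site {e.site} is outside the leaf")
        target_px = int(round(e.area_mm2 / px_mm2))
        avail = leaf0 & ~consumed_global
        ordered = _ordered_site_pixels(avail, e.site)
        if target_px > len(ordered):
            raise ScriptValidationError(
                f"event at t={e.start_min} consumes {target_px} px but only "
                f"{len(ordered)} leaf px remain"
            )
        chosen = ordered[:target_px]
        consumed_global[chosen[:, 0], chosen[:, 1]] = True
        alloc.append(chosen)

    # per-frame consumed prefix count for each event
    rng = np.random.default_rng(script.seed)
    remaining = np.empty((n_frames, *shape), dtype=bool)
    frames = np.empty((n_frames, *shape, 3), dtype=np.uint8)
    path = list(script.larva_path)
    for t, m in enumerate(minutes):
        consumed_t = np.zeros(shape, dtype=bool)
        for e, chosen in zip(script.events, alloc):
            frac = np.clip(m - e.start_min, 0.0, e.duration_min) * e.rate_mm2_per_min
            k = min(int(round(frac / px_mm2)), len(chosen))
            if k:
                consumed_t[chosen[:k, 0], chosen[:k, 1]] = True
        remaining[t] = leaf0 & ~consumed_t

        img = np.empty((*shape, 3), dtype=np.uint8)
        img[:] = colors["background"]
        img[remaining[t]] = colors["leaf"]
        if t < len(path) and path[t] is not None:
            _draw_larva(img, path[t], scene, colors)
        if scene.noise_sd > 0:
            noisy = img.astype(float) + rng.normal(0, scene.noise_sd, img.shape)
            img = np.clip(noisy, 0, 255).astype(np.uint8)
        frames[t] = img

    # rendered (pixel-quantized) per-event truth
    events = []
    for e, chosen in zip(script.events, alloc):
        mark = np.zeros(shape, dtype=bool)
        mark[chosen[:, 0], chosen[:, 1]] = True
        centroid = (
            (float(chosen[:, 0].mean()), float(chosen[:, 1].mean()))
            if len(chosen)
            else None
        )
        events.append(
            TrueEvent(
                start_min=e.start_min,
                duration_min=e.duration_min,
                rate_mm2_per_min=e.rate_mm2_per_min,
                area_mm2=len(chosen) * px_mm2,
                site=e.site,
                mark_mask=mark,
                centroid=centroid,
            )
        )
    truth = GroundTruth(
        initial_area_mm2=initial_area,
        area_series_mm2=remaining.sum(axis=(1, 2)) * px_mm2,
        events=events,
        intervals_min=[
            b.start_min - a.end_min for a, b in zip(script.events, script.events[1:])
        ],
        remaining_masks=remaining,
    )
    series = FrameSeries(
        frames=frames,
        frame_index=np.arange(1, n_frames + 1),
        frame_interval=frame_interval,
        mm_per_px=scene.mm_per_px,
        scan_mode=scene.scan_mode,
    )
    if out_dir is not None:
        _write_rendered(series, truth, script, scene, Path(out_dir))
    return series, truth


def _write_rendered(
    series: FrameSeries,
    truth: GroundTruth,
    script: BehaviorScript,
    scene: SceneSpec,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(series.frames, start=1):
        iio.imwrite(out_dir / f"frame_{i:05d}.png", frame)
    mask_dir = out_dir / "truth_masks"
    mask_dir.mkdir(exist_ok=True)
    for i, mask in enumerate(truth.remaining_masks, start=1):
        iio.imwrite(mask_dir / f"truth_{i:05d}.png", mask.astype(np.uint8) * 255)
    manifest = {
        "n_frames": len(series),
        "frame_interval_min": series.frame_interval,
        "dpi": scene.dpi,
        "mm_per_px": series.mm_per_px,
        "scan_mode": scene.scan_mode,
        "seed": script.seed,
        "initial_area_mm2": truth.initial_area_mm2,
        "events": [
            {
                "start_min": e.start_min,
                "duration_min": e.duration_min,
                "rate_mm2_per_min": e.rate_mm2_per_min,
                "area_mm2": e.area_mm2,
                "site": list(e.site) if e.site else None,
                "centroid_row_col": list(e.centroid) if e.centroid else None,
            }
            for e in truth.events
        ],
        "intervals_min": truth.intervals_min,
        "area_series_mm2": [float(a) for a in truth.area_series_mm2],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
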