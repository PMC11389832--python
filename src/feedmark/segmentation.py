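"""Leaf segmentation: color thresholding and cumulative time-difference masking.

The raw color threshold (mask1) keeps every pixel whose constrained
channels fall inside the configured ranges; on a scan it therefore picks
up the leaf *and* anything leaf-colored, including the larva. Cumulative
time-difference masking (mask2) then enforces the biological assumption
that consumed leaf never grows back: a pixel that is background at frame
t stays background at every later frame. Under that rule a larva-shaped
false positive survives only as long as the larva does not move, so the
mask2 area series converges onto the true remaining-leaf area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .errors import ConfigError, InputFormatError
from .imaging_io import FrameSeries, LeafAreaSeries, MaskSeries, RectROI

# Channel ranges: RGB channels on the 0-255 scale, HSV on 0-1 (skimage).
# A hue range with lo > hi is interpreted circularly (wraps through 0).


@dataclass
class ThresholdSpec:
    """A color-threshold specification.

    ``channels`` maps channel names (``"r" "g" "b"`` or ``"h" "s" "v"``)
    to inclusive ``(lo, hi)`` ranges; a pixel is foreground iff every
    constrained channel lies in range. At least one channel must be
    constrained and all names must belong to a single color space.
    """

    channels: dict[str, tuple[float, float]]
    mode_preset: str | None = None

    _RGB = ("r", "g", "b")
    _HSV = ("h", "s", "v")

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("threshold spec constrains no channels")
        names = set(self.channels)
        if names <= set(self._RGB):
            self.color_space = "rgb"
        elif names <= set(self._HSV):
            self.color_space = "hsv"
        else:
            raise ConfigError(f"mixed or unknown channel names {sorted(names)}")
        for name, (lo, hi) in self.channels.items():
            if name != "h" and lo > hi:
                raise ConfigError(f"channel {name!r}: min {lo} > max {hi}")

    @classmethod
    def preset(cls, name: str) -> "ThresholdSpec":
        """Named presets for the two scanning geometries.

        ``reflective``: green leaf and larva on a dark background — a hue
        window around green with minimum saturation and value.
        ``transmissive``: back-lit dark silhouettes on a white background
        — low value (lightness) alone.
        """
        if name == "reflective":
            return cls(
                channels={"h": (0.16, 0.50), "s": (0.20, 1.0), "v": (0.10, 1.0)},
                mode_preset="reflective",
            )
        if name == "transmissive":
            return cls(channels={"v": (0.0, 0.55)}, mode_preset="transmissive")
        raise ConfigError(f"unknown threshold preset {name!r}")


def _threshold_frame(img: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    if spec.color_space == "hsv":
        if img.ndim != 3:
            raise ConfigError("HSV threshold requires color (3-channel) frames")
        data = rgb2hsv(img)
        index = {"h": 0, "s": 1, "v": 2}
    else:
        if img.ndim == 2:
            data = img[:, :, None].astype(float)
            index = {"r": 0, "g": 0, "b": 0}
        else:
            data = img.astype(float)
            index = {"r": 0, "g": 1, "b": 2}
    mask = np.ones(img.shape[:2], dtype=bool)
    for name, (lo, hi) in spec.channels.items():
        ch = data[:, :, index[name]]
        if name == "h" and lo > hi:  # circular hue window through 0
            mask &= (ch >= lo) | (ch <= hi)
        else:
            mask &= (ch >= lo) & (ch <= hi)
    return mask


def color_threshold(frames: FrameSeries, spec: ThresholdSpec) -> MaskSeries:
    """Apply the color threshold to every frame, producing mask1.

    No morphological cleanup is applied; robustness to insect-body false
    positives is delegated to :func:`cumulative_mask`.
    """
    masks = np.stack([_threshold_frame(f, spec) for f in frames.frames])
    return MaskSeries(masks, stage="mask1")


def cumulative_mask(mask1: MaskSeries) -> MaskSeries:
    """Cumulative time-difference masking: mask1 → mask2.

    mask2(1) = mask1(1) and mask2(t+1) = mask1(t+1) ∧ mask2(t): any pixel
    that is background once stays background, so the foreground sets are
    nested over time. Note that a single background flicker of a noisy
    pixel deletes it permanently — an inherent property of the rule,
    mitigated only by the choice of threshold.
    """
    if len(mask1) == 0:
        raise InputFormatError("cannot cumulative-mask an empty series")
    return MaskSeries(np.logical_and.accumulate(mask1.masks, axis=0), stage="mask2")


def measure_roi_areas(
    masks: MaskSeries,
    rois: list[RectROI],
    mm_per_px: float,
    frame_interval: float = 1.0,
) -> list[LeafAreaSeries]:
    """Count foreground pixels per ROI per frame and convert to mm².

    Masking is applied to full frames upstream; only the measurement is
    ROI-restricted, so ROIs never influence each other.
    """
    out = []
    for roi in rois:
        roi.check_bounds(masks.masks.shape[1:])
        rs, cs = roi.slices()
        counts = masks.masks[:, rs, cs].sum(axis=(1, 2))
        out.append(
            LeafAreaSeries(
                roi_label=roi.label,
                area_px=counts,
                mm_per_px=mm_per_px,
                frame_interval=frame_interval,
            )
        )
    return out


def remove_small_components(masks: MaskSeries, min_size: int) -> MaskSeries:
    """Optional despeckling: drop connected components below min_size pixels.

    Off by default in every pipeline preset; provided for very noisy
    scans where threshold choice alone cannot prevent flicker.
    """
    from skimage.morphology import remove_small_objects

    cleaned = np.stack(
        [remove_small_objects(m, min_size=min_size) for m in masks.masks]
    )
    return MaskSeries(cleaned, stage=masks.stage)
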