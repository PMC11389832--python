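"""Reading and writing of image sequences, ROIs, masks and result tables.

Conventions used throughout the package:

* Frame order comes from the decimal serial number that terminates each
  filename stem (``leaf_0042.png`` → 42); sorting is numeric, never
  lexicographic. Frame indices reported downstream are 1-based positions
  in the sorted sequence.
* ROI coordinates are 0-based, half-open, row-major:
  ``[row0, row0 + height) × [col0, col0 + width)``.
* Calibration is millimetres per pixel edge; from a scanner resolution
  it is ``25.4 / dpi``. Areas convert as ``mm² = px × calibration²``.
"""

from __future__ import annotations

import logging
import re
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigError, InputFormatError, UnsupportedROIError

logger = logging.getLogger(__name__)

_SERIAL_RE = re.compile(r"(\d+)$")


def dpi_to_mm_per_px(dpi: float) -> float:
    """Convert a scanner resolution in dots per inch to mm per pixel."""
    if dpi <= 0:
        raise ConfigError(f"dpi must be positive, got {dpi}")
    return 25.4 / dpi


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FrameSeries:
    """An ordered, calibrated stack of scanned frames.

    Attributes
    ----------
    frames : ndarray, shape (n, h, w) or (n, h, w, 3), uint8
        The image stack; all frames share dimensions and channel count.
    frame_index : ndarray of int
        1-based serial numbers, strictly increasing. Gaps are allowed and
        are treated as consecutive frames at ``frame_interval`` spacing.
    frame_interval : float
        Minutes between consecutive frames.
    mm_per_px : float
        Calibration, mm per pixel edge.
    scan_mode : str
        ``"reflective"`` (dark background, lit objects) or
        ``"transmissive"`` (back-lit, white background, dark silhouettes).
    """

    frames: np.ndarray
    frame_index: np.ndarray
    frame_interval: float = 1.0
    mm_per_px: float = 0.1
    scan_mode: str = "reflective"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frames.ndim not in (3, 4):
            raise InputFormatError(
                f"frames must be a (n,h,w) or (n,h,w,3) stack, got shape {self.frames.shape}"
            )
        if len(self.frame_index) != len(self.frames):
            raise InputFormatError("frame_index length does not match frame count")
        if len(self.frame_index) and np.any(np.diff(self.frame_index) <= 0):
            raise InputFormatError("frame indices must be strictly increasing")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.mm_per_px <= 0:
            raise ConfigError("calibration (mm per pixel) must be positive")
        if self.scan_mode not in ("reflective", "transmissive"):
            raise ConfigError(f"unknown scan_mode {self.scan_mode!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[3]

    @property
    def minutes(self) -> np.ndarray:
        """Time of each frame in minutes, first frame at 0."""
        return np.arange(len(self)) * self.frame_interval


@dataclass(frozen=True)
class RectROI:
    """A rectangular region of interest, 0-based half-open pixel box."""

    label: str
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InputFormatError(
                f"ROI {self.label!r}: height and width must be >= 1"
            )

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        if (
            self.row0 < 0
            or self.col0 < 0
            or self.row0 + self.height > h
            or self.col0 + self.width > w
        ):
            raise InputFormatError(
                f"ROI {self.label!r} [{self.row0}:{self.row0 + self.height}, "
                f"{self.col0}:{self.col0 + self.width}) exceeds frame bounds {h}x{w}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


@dataclass
class MaskSeries:
    """Binary leaf masks aligned with a :class:`FrameSeries`.

    ``stage`` is ``"mask1"`` for the raw color-threshold output and
    ``"mask2"`` after cumulative time-difference masking. A mask2 series
    satisfies the nesting invariant: foreground at frame t+1 is a subset
    of foreground at frame t.
    """

    masks: np.ndarray
    stage: str = "mask1"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise InputFormatError(
                f"masks must be a (n,h,w) boolean stack, got shape {self.masks.shape}"
            )
        if self.stage not in ("mask1", "mask2"):
            raise ConfigError(f"unknown mask stage {self.stage!r}")

    def __len__(self) -> int:
        return len(self.masks)

    def restrict(self, roi: RectROI) -> "MaskSeries":
        roi.check_bounds(self.masks.shape[1:])
        rs, cs = roi.slices()
        return MaskSeries(self.masks[:, rs, cs].copy(), stage=self.stage)


@dataclass
class LeafAreaSeries:
    """Per-ROI leaf area as a function of frame."""

    roi_label: str
    area_px: np.ndarray
    mm_per_px: float
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.area_px = np.asarray(self.area_px, dtype=float)

    def __len__(self) -> int:
        return len(self.area_px)

    @property
    def area_mm2(self) -> np.ndarray:
        return self.area_px * self.mm_per_px**2

    @property
    def minutes(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


# ---------------------------------------------------------------------------
# Frame sequences
# ---------------------------------------------------------------------------


def parse_serial(path: Path) -> int:
    """Extract the trailing decimal serial number from a filename stem."""
    m = _SERIAL_RE.search(path.stem)
    if m is None:
        raise InputFormatError(
            f"filename {path.name!r} has no trailing serial number before the extension"
        )
    return int(m.group(1))


def read_frame_sequence(
    directory: str | Path,
    pattern: str = "*.png",
    frame_interval: float = 1.0,
    dpi: float | None = None,
    mm_per_px: float | None = None,
    scan_mode: str = "reflective",
) -> FrameSeries:
    """Read a serial-numbered image sequence into a :class:`FrameSeries`.

    Exactly one of ``dpi`` and ``mm_per_px`` must be given. Files are
    ordered by the numeric serial in the filename; gaps in the serials
    are logged and treated as consecutive frames.
    """
    if (dpi is None) == (mm_per_px is None):
        raise ConfigError("provide exactly one of dpi or mm_per_px")
    cal = dpi_to_mm_per_px(dpi) if dpi is not None else float(mm_per_px)

    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if len(paths) < 2:
        raise InputFormatError(
            f"need at least 2 frames matching {pattern!r} in {directory}, found {len(paths)}"
        )
    serials = [(parse_serial(p), p) for p in paths]
    serials.sort(key=lambda sp: sp[0])
    numbers = [s for s, _ in serials]
    if len(set(numbers)) != len(numbers):
        raise InputFormatError(f"duplicate frame serial numbers in {directory}")
    gaps = np.diff(numbers)
    if np.any(gaps > 1):
        logger.warning(
            "serial gaps in %s (e.g. skipped scans); treating frames as consecutive",
            directory,
        )

    frames = []
    shape = None
    for serial, path in serials:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InputFormatError(
                f"frame {path.name!r} has shape {img.shape}, expected {shape}"
            )
        frames.append(img)

    return FrameSeries(
        frames=np.stack(frames),
        frame_index=np.array(numbers),
        frame_interval=frame_interval,
        mm_per_px=cal,
        scan_mode=scan_mode,
    )


# ---------------------------------------------------------------------------
# ROIs: ImageJ .roi rectangle records and plain-text tables
# ---------------------------------------------------------------------------

_IJ_MAGIC = b"Iout"
_IJ_RECT_TYPE = 1
_IJ_HEADER = struct.Struct(">4sh2B4h")  # magic, version, type, pad, top/left/bottom/right


def _parse_imagej_roi(data: bytes, label: str) -> RectROI:
    if len(data) < 64 or data[:4] != _IJ_MAGIC:
        raise InputFormatError(f"ROI {label!r}: not an ImageJ .roi record")
    _, _version, roi_type, _, top, left, bottom, right = _IJ_HEADER.unpack_from(data)
    if roi_type != _IJ_RECT_TYPE:
        raise UnsupportedROIError(
            f"ROI {label!r}: only rectangle ROIs are supported (type code {roi_type})"
        )
    return RectROI(
        label=label, row0=top, col0=left, height=bottom - top, width=right - left
    )


def _encode_imagej_roi(roi: RectROI) -> bytes:
    header = bytearray(64)
    _IJ_HEADER.pack_into(
        header,
        0,
        _IJ_MAGIC,
        228,  # format version written by recent ImageJ releases
        _IJ_RECT_TYPE,
        0,
        roi.row0,
        roi.col0,
        roi.row0 + roi.height,
        roi.col0 + roi.width,
    )
    return bytes(header)


def read_rois(path: str | Path) -> list[RectROI]:
    """Read ROIs from an ImageJ ROI zip archive or a plain-text table.

    ImageJ rectangle records (top/left/bottom/right) are converted to the
    package convention: ``row0=top``, ``col0=left``, ``height=bottom-top``,
    ``width=right-left``. The text dialect is a CSV with header
    ``label,row0,col0,height,width``.
    """
    path = Path(path)
    if zipfile.is_zipfile(path):
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if not name.lower().endswith(".roi"):
                    continue
                label = Path(name).stem
                rois.append(_parse_imagej_roi(zf.read(name), label))
        if not rois:
            raise InputFormatError(f"{path} contains no .roi records")
        return rois
    # single bare .roi file
    raw = path.read_bytes()
    if raw[:4] == _IJ_MAGIC:
        return [_parse_imagej_roi(raw, path.stem)]
    return _read_roi_table(path)


def _read_roi_table(path: Path) -> list[RectROI]:
    df = pd.read_csv(path, comment="#")
    required = ["label", "row0", "col0", "height", "width"]
    if list(df.columns) != required:
        raise InputFormatError(
            f"{path}: ROI table header must be {','.join(required)}"
        )
    return [
        RectROI(str(r.label), int(r.row0), int(r.col0), int(r.height), int(r.width))
        for r in df.itertuples(index=False)
    ]


def write_rois(rois: Sequence[RectROI], path: str | Path) -> None:
    """Write ROIs as a text table, or an ImageJ zip if the suffix is .zip."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path, "w") as zf:
            for roi in rois:
                zf.writestr(f"{roi.label}.roi", _encode_imagej_roi(roi))
        return
    df = pd.DataFrame(
        [(r.label, r.row0, r.col0, r.height, r.width) for r in rois],
        columns=["label", "row0", "col0", "height", "width"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def write_mask_series(masks: MaskSeries, directory: str | Path, prefix: str = "mask") -> list[Path]:
    """Write masks as single-channel PNGs, foreground=255; lossless."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(masks.masks, start=1):
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_mask_series(directory: str | Path, pattern: str = "*.png", stage: str = "mask1") -> MaskSeries:
    """Read a directory of serial-numbered mask PNGs back into a stack."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern), key=parse_serial)
    if not paths:
        raise InputFormatError(f"no masks matching {pattern!r} in {directory}")
    stack = np.stack([np.asarray(iio.imread(p)) > 127 for p in paths])
    return MaskSeries(stack, stage=stage)


# ---------------------------------------------------------------------------
# CSV result tables
# ---------------------------------------------------------------------------

AREA_COLUMNS = ["frame", "minutes", "roi_label", "area_mm2", "area_px"]
EVENT_COLUMNS = [
    "roi_label",
    "event_id",
    "start_frame",
    "end_frame",
    "duration_min",
    "area_mm2",
    "rate_mm2_per_min",
    "interval_to_next_min",
    "interval_excluded",
]
MARK_COLUMNS = [
    "roi_label",
    "event_id",
    "centroid_row",
    "centroid_col",
    "centroid_x_mm",
    "centroid_y_mm",
    "start_frame",
    "end_frame",
    "dist_from_prev_mm",
]


def _write_csv(df: pd.DataFrame, path: str | Path, comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def write_area_csv(
    series: Iterable[LeafAreaSeries], path: str | Path, comment: str | None = None
) -> None:
    """Write per-ROI area series with columns frame,minutes,roi_label,area_mm2,area_px."""
    rows = []
    for s in series:
        mm2 = s.area_mm2
        minutes = s.minutes
        for i in range(len(s)):
            rows.append((i + 1, minutes[i], s.roi_label, mm2[i], s.area_px[i]))
    df = pd.DataFrame(rows, columns=AREA_COLUMNS)
    _write_csv(df, path, comment)


def read_area_csv(path: str | Path) -> dict[str, LeafAreaSeries]:
    """Read an area CSV back into per-ROI series.

    The calibration is recovered from the stored mm² / px ratio; frame
    interval from the minutes column.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(AREA_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing area CSV columns {sorted(missing)}")
    out: dict[str, LeafAreaSeries] = {}
    for label, sub in df.groupby("roi_label", sort=False):
        sub = sub.sort_values("frame")
        px = sub["area_px"].to_numpy(dtype=float)
        mm2 = sub["area_mm2"].to_numpy(dtype=float)
        nz = px > 0
        cal = float(np.sqrt(np.median(mm2[nz] / px[nz]))) if nz.any() else 1.0
        minutes = sub["minutes"].to_numpy(dtype=float)
        interval = float(minutes[1] - minutes[0]) if len(minutes) > 1 else 1.0
        out[str(label)] = LeafAreaSeries(
            roi_label=str(label), area_px=px, mm_per_px=cal, frame_interval=interval
        )
    return out


def write_events_csv(
    events_by_roi: dict[str, Sequence],
    path: str | Path,
    comment: str | None = None,
) -> None:
    """Write detected feeding events; header-only file when no events."""
    rows = []
    for label, events in events_by_roi.items():
        for ev in events:
            rows.append(
                (
                    label,
                    ev.event_id,
                    ev.start_frame,
                    ev.end_frame,
                    ev.duration_min,
                    ev.area_mm2,
                    ev.rate_mm2_per_min,
                    "" if ev.interval_to_next_min is None else ev.interval_to_next_min,
                    ev.interval_excluded,
                )
            )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    _write_csv(df, path, comment)


def write_marks_csv(
    marks_by_roi: dict[str, Sequence],
    path: str | Path,
    comment: str | None = None,
) -> None:
    """Write feeding-mark centroids and inter-mark distances.

    mm coordinates have their origin at the ROI's top-left corner with
    x along columns and y along rows.
    """
    rows = []
    for label, marks in marks_by_roi.items():
        for m in marks:
            rows.append(
                (
                    label,
                    m.event_id,
                    m.centroid_row,
                    m.centroid_col,
                    m.centroid_x_mm,
                    m.centroid_y_mm,
                    m.start_frame,
                    m.end_frame,
                    "" if m.dist_from_prev_mm is None else m.dist_from_prev_mm,
                )
            )
    df = pd.DataFrame(rows, columns=MARK_COLUMNS)
    _write_csv(df, path, comment)
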