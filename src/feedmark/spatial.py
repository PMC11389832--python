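"""Feeding-mark extraction, centroids, distances, and overlay rendering.

A feeding mark is the set of pixels consumed during one feeding event,
obtained by differencing the filtered leaf masks at the frame before the
event's first observed drop and at its last frame. Because mask2 is
monotone non-increasing this difference is exactly the pixels lost
during the event, and marks of distinct events are pixel-disjoint.

mm coordinates have their origin at the top-left corner of the analysed
region (the ROI when marks are extracted per ROI), with x along columns
and y along rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, DegenerateMarkError
from .events import FeedingEvent
from .imaging_io import MaskSeries, RectROI


@dataclass
class FeedingMark:
    """The consumed-pixel region of one feeding event."""

    event_id: int
    mark_mask: np.ndarray  # boolean raster, pixels consumed during the event
    centroid_row: float
    centroid_col: float
    centroid_x_mm: float
    centroid_y_mm: float
    start_frame: int
    end_frame: int
    dist_from_prev_mm: float | None = None


def event_mark_mask(mask2: MaskSeries, event: FeedingEvent) -> np.ndarray:
    """Pixels consumed during one event: mask2(start-1) ∧ ¬mask2(end).

    ``start_frame - 1`` is the frame before the event's first observed
    drop (the first frame is used when the event starts at the very
    beginning of the series).
    """
    if mask2.stage != "mask2":
        raise AnalysisError("feeding marks require a cumulative-filtered mask series")
    n = len(mask2)
    if not (1 <= event.start_frame <= n and 1 <= event.end_frame <= n):
        raise AnalysisError(
            f"event {event.event_id} frames [{event.start_frame}, {event.end_frame}] "
            f"outside mask series of length {n}"
        )
    before = mask2.masks[max(event.start_frame - 1, 1) - 1]
    last = mask2.masks[event.end_frame - 1]
    return before & ~last


def mark_centroid(mark: np.ndarray, mm_per_px: float) -> tuple[float, float, float, float]:
    """Center of gravity of a mark: unweighted mean of foreground pixels.

    Returns (row, col, x_mm, y_mm); x is the column direction.
    """
    rows, cols = np.nonzero(mark)
    if len(rows) == 0:
        raise DegenerateMarkError("empty feeding mark")
    r, c = float(rows.mean()), float(cols.mean())
    return r, c, c * mm_per_px, r * mm_per_px


def consecutive_distances(marks: list[FeedingMark]) -> list[FeedingMark]:
    """Euclidean distance (mm) between centroids of consecutive marks.

    Marks must be ordered by event_id; the first mark has no distance.
    """
    for prev, cur in zip(marks, marks[1:]):
        cur.dist_from_prev_mm = float(
            np.hypot(
                cur.centroid_x_mm - prev.centroid_x_mm,
                cur.centroid_y_mm - prev.centroid_y_mm,
            )
        )
    return marks


def extract_marks(
    mask2: MaskSeries,
    events: list[FeedingEvent],
    mm_per_px: float,
    roi: RectROI | None = None,
) -> list[FeedingMark]:
    """Extract all feeding marks for one ROI's events.

    Events whose mark is empty (sub-pixel consumption) are flagged by
    omission: they stay in the events table but get no spatial row.
    """
    if roi is not None:
        mask2 = mask2.restrict(roi)
    marks: list[FeedingMark] = []
    for ev in sorted(events, key=lambda e: e.event_id):
        mark = event_mark_mask(mask2, ev)
        try:
            r, c, x, y = mark_centroid(mark, mm_per_px)
        except DegenerateMarkError:
            continue
        marks.append(
            FeedingMark(
                event_id=ev.event_id,
                mark_mask=mark,
                centroid_row=r,
                centroid_col=c,
                centroid_x_mm=x,
                centroid_y_mm=y,
                start_frame=ev.start_frame,
                end_frame=ev.end_frame,
            )
        )
    return consecutive_distances(marks)


# Overlay palette (RGB): remaining leaf black on white background,
# current event magenta, previous events cyan.
_BG = np.array([255, 255, 255], dtype=np.uint8)
_LEAF = np.array([0, 0, 0], dtype=np.uint8)
_CURRENT = np.array([255, 0, 255], dtype=np.uint8)
_PREVIOUS = np.array([0, 255, 255], dtype=np.uint8)


def render_event_overlay(
    mask2: MaskSeries, marks: list[FeedingMark], event_id: int
) -> np.ndarray:
    """Spatio-temporal overlay for one event.

    The first frame of the filtered mask series is the reference: its
    leaf pixels are black, the current event's mark magenta, the union
    of earlier marks cyan, background white.
    """
    by_id = {m.event_id: m for m in marks}
    if event_id not in by_id:
        raise AnalysisError(f"no feeding mark for event_id {event_id}")
    ref = mask2.masks[0]
    img = np.empty((*ref.shape, 3), dtype=np.uint8)
    img[:] = _BG
    img[ref] = _LEAF
    for m in marks:
        if m.event_id < event_id:
            img[m.mark_mask] = _PREVIOUS
    img[by_id[event_id].mark_mask] = _CURRENT
    return img


def _agg_axes(figsize):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def render_position_plot(marks: list[FeedingMark], path=None):
    """Centroid sequence numbered in feeding order (image-style y axis)."""
    fig, ax = _agg_axes((4, 4))
    xs = [m.centroid_x_mm for m in marks]
    ys = [m.centroid_y_mm for m in marks]
    order = np.arange(len(marks))
    sc = ax.scatter(xs, ys, c=order, cmap="viridis", zorder=3)
    ax.plot(xs, ys, color="0.7", lw=0.8, zorder=2)
    for m in marks:
        ax.annotate(str(m.event_id), (m.centroid_x_mm, m.centroid_y_mm), fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, label="feeding order")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return fig


def render_distance_plot(marks: list[FeedingMark], path=None):
    """Distance from the previous feeding mark vs feeding order."""
    fig, ax = _agg_axes((5, 3))
    with_dist = [m for m in marks if m.dist_from_prev_mm is not None]
    ids = [m.event_id for m in with_dist]
    ds = [m.dist_from_prev_mm for m in with_dist]
    ax.bar(ids, ds, color="0.4")
    ax.set_xlabel("feeding event")
    ax.set_ylabel("distance from previous mark (mm)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return fig
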