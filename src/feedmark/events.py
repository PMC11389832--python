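"""Feeding-event detection and behavioral parameters.

From the per-ROI leaf-area series S(t) (mm², one value per frame) the
negative time derivative

    D(t) = -(S(t+1) - S(t)) / frame_interval      [mm² min⁻¹]

is near zero while the larva rests and forms a peak while it feeds. A
feeding event is a maximal run of consecutive points with D strictly
above a threshold (default 0.2 mm² min⁻¹). Each event yields four
parameters: area consumed (integral of the peak), duration (width of the
peak), mean rate (area/duration), and the interval to the next event.
Intervals longer than 100 min are flagged as molting pauses and excluded
from interval statistics (the events themselves are kept).

Frame convention: D at 0-based position i compares frames i+1 and i+2
(1-based); the drop is *observed* at frame i+2, and events are labelled
by the frames at which their drops are observed. Hence
``start_frame >= 2`` always, and the pixels lost during an event are
exactly mask2(start_frame-1) minus mask2(end_frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AnalysisError, ConfigError
from .imaging_io import LeafAreaSeries

DEFAULT_THRESHOLD = 0.2  # mm² min⁻¹
DEFAULT_MAX_INTERVAL = 100.0  # min; longer gaps attributed to molting
DEFAULT_WINDOW = 999.0  # min; analysis window for per-assay medians

PARAMETERS = ("duration_min", "area_mm2", "rate_mm2_per_min", "interval_min")


@dataclass
class FeedingEvent:
    """One detected feeding event (a peak in -ΔS)."""

    event_id: int
    start_frame: int  # 1-based frame at which the first drop is observed
    end_frame: int  # 1-based frame at which the last drop is observed
    duration_min: float
    area_mm2: float
    rate_mm2_per_min: float
    interval_to_next_min: float | None = None
    interval_excluded: bool = False
    frame_interval: float = 1.0

    @property
    def start_min(self) -> float:
        """Start of the event's first consumption interval (frame 1 = minute 0)."""
        return (self.start_frame - 2) * self.frame_interval


@dataclass
class AssaySummary:
    """Per-assay medians of the four parameters over the analysis window."""

    roi_label: str
    group: str | None
    n_events: int
    medians: dict[str, float | None]


@dataclass
class GroupComparison:
    """Welch's t-test on per-assay medians between two groups."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float


def diff_series(series: LeafAreaSeries) -> np.ndarray:
    """Negative leaf-area derivative in mm² min⁻¹, length len(S) - 1."""
    s = series.area_mm2
    if len(s) < 2:
        raise AnalysisError(
            f"ROI {series.roi_label!r}: need >= 2 frames to differentiate, got {len(s)}"
        )
    return -np.diff(s) / series.frame_interval


def detect_events(
    d: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = 1,
    frame_interval: float = 1.0,
) -> list[FeedingEvent]:
    """Detect feeding events as maximal above-threshold runs in D.

    "Exceeds the threshold" is strict (>). Runs shorter than ``min_run``
    points are discarded. An empty result is valid.
    """
    if threshold <= 0:
        raise ConfigError("detection threshold must be positive")
    if min_run < 1:
        raise ConfigError("min_run must be >= 1")
    d = np.asarray(d, dtype=float)
    above = d > threshold
    events: list[FeedingEvent] = []
    # run boundaries of the boolean series
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
    for a, b in zip(starts, ends):
        if b - a < min_run:
            continue
        duration = (b - a) * frame_interval
        area = float(d[a:b].sum() * frame_interval)
        events.append(
            FeedingEvent(
                event_id=len(events) + 1,
                start_frame=a + 2,
                end_frame=b + 1,
                duration_min=duration,
                area_mm2=area,
                rate_mm2_per_min=area / duration,
                frame_interval=frame_interval,
            )
        )
    return events


def compute_intervals(
    events: list[FeedingEvent],
    max_interval: float = DEFAULT_MAX_INTERVAL,
) -> list[FeedingEvent]:
    """Set interval_to_next on each event (in place; returns the list).

    interval = (start_frame of next - end_frame of current) × frame
    interval, so a gap of one frame yields one frame interval. Intervals
    above ``max_interval`` are flagged excluded (molting) but the events
    themselves are retained.
    """
    for cur, nxt in zip(events, events[1:]):
        cur.interval_to_next_min = (
            (nxt.start_frame - cur.end_frame) * cur.frame_interval
        )
        cur.interval_excluded = cur.interval_to_next_min > max_interval
    return events


def summarize_assay(
    events: list[FeedingEvent],
    window: float = DEFAULT_WINDOW,
    roi_label: str = "",
    group: str | None = None,
) -> AssaySummary:
    """Medians of the four parameters over events starting within the window.

    The window selects events by start time (first frame at minute 0).
    Interval medians use only non-excluded intervals of qualifying
    events. With zero qualifying events the summary carries ``None``
    medians so the assay is flagged rather than silently dropped.
    """
    if window <= 0:
        raise ConfigError("analysis window must be positive")
    sel = [ev for ev in events if ev.start_min <= window]
    medians: dict[str, float | None]
    if not sel:
        medians = {p: None for p in PARAMETERS}
    else:
        intervals = [
            ev.interval_to_next_min
            for ev in sel
            if ev.interval_to_next_min is not None and not ev.interval_excluded
        ]
        medians = {
            "duration_min": float(np.median([ev.duration_min for ev in sel])),
            "area_mm2": float(np.median([ev.area_mm2 for ev in sel])),
            "rate_mm2_per_min": float(np.median([ev.rate_mm2_per_min for ev in sel])),
            "interval_min": float(np.median(intervals)) if intervals else None,
        }
    return AssaySummary(
        roi_label=roi_label, group=group, n_events=len(sel), medians=medians
    )


def analyze_series(
    series: LeafAreaSeries,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = 1,
    max_interval: float = DEFAULT_MAX_INTERVAL,
    window: float = DEFAULT_WINDOW,
    group: str | None = None,
) -> tuple[list[FeedingEvent], AssaySummary]:
    """Full per-assay analysis: differentiate, detect, intervals, summary."""
    d = diff_series(series)
    events = detect_events(
        d, threshold=threshold, min_run=min_run, frame_interval=series.frame_interval
    )
    compute_intervals(events, max_interval=max_interval)
    summary = summarize_assay(
        events, window=window, roi_label=series.roi_label, group=group
    )
    return events, summary


def compare_groups(
    summaries_a: list[AssaySummary],
    summaries_b: list[AssaySummary],
    parameter: str,
) -> GroupComparison:
    """Welch's t-test on per-assay medians of one parameter.

    Assays whose median for the parameter is undefined are dropped; both
    groups must retain at least two assays. Reports group mean ± sample
    SD (ddof=1), the Welch t statistic, Welch–Satterthwaite degrees of
    freedom, and the two-sided p-value.
    """
    if parameter not in PARAMETERS:
        raise ConfigError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    a = np.array(
        [s.medians[parameter] for s in summaries_a if s.medians[parameter] is not None],
        dtype=float,
    )
    b = np.array(
        [s.medians[parameter] for s in summaries_b if s.medians[parameter] is not None],
        dtype=float,
    )
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError(
            f"need >= 2 assays with defined {parameter!r} medians per group "
            f"(got {len(a)} and {len(b)})"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def plot_diff_series(
    series: LeafAreaSeries,
    events: list[FeedingEvent],
    path=None,
    ax=None,
):
    """Diagnostic plot of y = -ΔS vs time with detected runs highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = diff_series(series)
    minutes = series.minutes[:-1]
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 3))
    else:
        fig = ax.figure
    ax.plot(minutes, d, color="0.3", lw=0.8)
    for ev in events:
        i0, i1 = ev.start_frame - 2, ev.end_frame - 1
        ax.plot(minutes[i0:i1], d[i0:i1], color="red", lw=1.5)
        ax.annotate(
            f"{ev.area_mm2:.2g}",
            (minutes[i0], float(d[i0:i1].max())),
            fontsize=7,
            color="red",
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel(r"$-\Delta S_{leaf}$ (mm$^2$ min$^{-1}$)")
    ax.set_title(series.roi_label)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
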