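"""End-to-end pipeline driver: read → mask1 → mask2 → areas → events → marks.

The :class:`RunConfig` is the single source of parameters; the CLI only
translates flags and YAML files into one. Every run writes its effective
config next to the results and stamps each CSV with the config hash, so
a result bundle is reproducible from its own directory. The pipeline is
deterministic given inputs and config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import events as ev
from . import imaging_io as fio
from . import segmentation as seg
from . import spatial
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str = "."
    pattern: str = "*.png"
    roi_path: str | None = None
    dpi: float | None = None
    mm_per_px: float | None = None
    frame_interval: float = 1.0
    scan_mode: str = "reflective"
    threshold: object = "reflective"  # preset name or {channel: [lo, hi]} mapping
    min_component_size: int = 0
    detect_threshold: float = ev.DEFAULT_THRESHOLD
    min_run: int = 1
    max_interval: float = ev.DEFAULT_MAX_INTERVAL
    window: float = ev.DEFAULT_WINDOW
    exclude_rois: list[str] = field(default_factory=list)
    output_dir: str = "feedmark_out"
    write_masks: bool = True
    write_overlays: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def threshold_spec(self) -> seg.ThresholdSpec:
        if isinstance(self.threshold, str):
            return seg.ThresholdSpec.preset(self.threshold)
        channels = {k: (float(lo), float(hi)) for k, (lo, hi) in self.threshold.items()}
        return seg.ThresholdSpec(channels=channels)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle of in-memory objects.

    Outputs written under ``config.output_dir``: areas.csv, events.csv,
    summaries.csv, marks.csv, mask1/ and mask2/ PNG stacks, per-event
    overlays, diagnostic plots, the effective config and a run log.
    Any stage failure aborts with a stage-named message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "run_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    log_lines = [f"config_hash: {chash}"]

    def stage(name):
        logger.info("stage %s", name)
        log_lines.append(f"stage: {name}")

    try:
        stage("read")
        frames = fio.read_frame_sequence(
            config.input_dir,
            pattern=config.pattern,
            frame_interval=config.frame_interval,
            dpi=config.dpi,
            mm_per_px=config.mm_per_px,
            scan_mode=config.scan_mode,
        )
        log_lines.append(f"frames: {len(frames)}")

        if config.roi_path is not None:
            rois = fio.read_rois(config.roi_path)
        else:  # whole frame as a single ROI
            h, w = frames.frames.shape[1:3]
            rois = [fio.RectROI("frame", 0, 0, h, w)]
        rois = [r for r in rois if r.label not in set(config.exclude_rois)]
        for label in config.exclude_rois:
            log_lines.append(f"excluded_roi: {label}")
        if not rois:
            raise ConfigError("all ROIs excluded")
        log_lines.append(f"rois: {len(rois)}")

        stage("mask1")
        mask1 = seg.color_threshold(frames, config.threshold_spec())
        if config.min_component_size > 0:
            mask1 = seg.remove_small_components(mask1, config.min_component_size)
        stage("mask2")
        mask2 = seg.cumulative_mask(mask1)
        if config.write_masks:
            fio.write_mask_series(mask1, out / "mask1", prefix="mask1")
            fio.write_mask_series(mask2, out / "mask2", prefix="mask2")

        stage("areas")
        areas = seg.measure_roi_areas(
            mask2, rois, frames.mm_per_px, frames.frame_interval
        )
        fio.write_area_csv(areas, out / "areas.csv", comment=f"config_hash={chash}")

        stage("events")
        events_by_roi: dict[str, list] = {}
        summaries = []
        for s in areas:
            evs, summary = ev.analyze_series(
                s,
                threshold=config.detect_threshold,
                min_run=config.min_run,
                max_interval=config.max_interval,
                window=config.window,
            )
            events_by_roi[s.roi_label] = evs
            summaries.append(summary)
            log_lines.append(f"events[{s.roi_label}]: {len(evs)}")
            ev.plot_diff_series(s, evs, out / f"{s.roi_label}_diff.png")
        fio.write_events_csv(events_by_roi, out / "events.csv", comment=f"config_hash={chash}")
        _write_summaries(summaries, out / "summaries.csv", chash)

        stage("marks")
        marks_by_roi: dict[str, list] = {}
        for roi, s in zip(rois, areas):
            marks = spatial.extract_marks(
                mask2, events_by_roi[s.roi_label], frames.mm_per_px, roi=roi
            )
            marks_by_roi[s.roi_label] = marks
            cropped = mask2.restrict(roi)
            if config.write_overlays:
                import imageio.v3 as iio

                for m in marks:
                    iio.imwrite(
                        out / f"{s.roi_label}_event{m.event_id}.png",
                        spatial.render_event_overlay(cropped, marks, m.event_id),
                    )
            if marks:
                spatial.render_position_plot(marks, out / f"{s.roi_label}_positions.png")
                spatial.render_distance_plot(marks, out / f"{s.roi_label}_distances.png")
        fio.write_marks_csv(marks_by_roi, out / "marks.csv", comment=f"config_hash={chash}")
    except Exception as exc:
        log_lines.append(f"ABORTED: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "frames": frames,
        "mask1": mask1,
        "mask2": mask2,
        "areas": areas,
        "events": events_by_roi,
        "summaries": summaries,
        "marks": marks_by_roi,
        "config_hash": chash,
    }


def _write_summaries(summaries, path: Path, chash: str) -> None:
    import pandas as pd

    rows = []
    for s in summaries:
        row = {"roi_label": s.roi_label, "group": s.group or "", "n_events": s.n_events}
        for p in ev.PARAMETERS:
            row[f"median_{p}"] = "" if s.medians[p] is None else s.medians[p]
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def read_summaries_csv(path: str | Path) -> list[ev.AssaySummary]:
    """Read a per-assay summaries CSV back (for `feedmark compare`)."""
    import pandas as pd

    df = pd.read_csv(Path(path), comment="#")
    out = []
    for r in df.itertuples(index=False):
        medians = {}
        for p in ev.PARAMETERS:
            val = getattr(r, f"median_{p}")
            medians[p] = None if pd.isna(val) or val == "" else float(val)
        group = getattr(r, "group", "")
        out.append(
            ev.AssaySummary(
                roi_label=str(r.roi_label),
                group=None if (isinstance(group, float) or group == "") else str(group),
                n_events=int(r.n_events),
                medians=medians,
            )
        )
    return out
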