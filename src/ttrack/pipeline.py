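"""Whole-pipeline orchestration with a single config and reproducible runs.

The stages communicate through on-disk artifacts (TIFF + CSV), so a third
party can, for example, inject their own detection table and use only the
tracking stage, or use the simulator's output as a benchmark substrate.
Every run writes a manifest (config + seed + version) sufficient to
reproduce it.  These functions are the library-level equivalent of a
command-line front end; the ``examples/`` scripts drive them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml

from . import __version__ as _version
from .enhance import EnhancementConfig, stretch_contrast
from .errors import ConfigurationError, ValidationError
from .filtering import FilterCriteria, apply_filter, erase_cells
from .io import TimeLapse, read_timelapse, write_annotated, write_metadata, write_timelapse
from .segment import SegmentationConfig, segment_frame
from .summary import MOVEMENT_MEASURES, summarize
from .synthetic import SceneConfig, generate_scene, render_timelapse
from .tracking import TrackingConfig, build_tracks

__all__ = ["IOConfig", "PipelineConfig", "load_config", "simulate", "run_pipeline", "STAGES"]

log = logging.getLogger("ttrack")

STAGES = ("enhance", "segment", "filter", "track", "summarize")


@dataclass(frozen=True)
class IOConfig:
    """Input conventions: filename pattern and which phase is segmented."""

    phase_pattern: str = r"t(?P<time>\d+)_p(?P<phase>\w+)\.tiff?$"
    detection_phase: Optional[str] = None  # default: first phase alphabetically
    multipage: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    # Enhancement moves the background up the intensity range, so the
    # pipeline derives the tile-threshold constraint from each frame
    # (threshold_bounds=None) instead of using the raw-scale default.
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(threshold_bounds=None)
    )
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    summary_measures: tuple[str, ...] = tuple(MOVEMENT_MEASURES)
    io: IOConfig = field(default_factory=IOConfig)
    simulate: SceneConfig = field(default_factory=SceneConfig)


_SECTIONS = {
    "enhancement": EnhancementConfig,
    "segmentation": SegmentationConfig,
    "filter": FilterCriteria,
    "tracking": TrackingConfig,
    "io": IOConfig,
    "simulate": SceneConfig,
}


def _build_section(cls, data: dict, section: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in config section {section!r}: {sorted(unknown)}"
        )
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys anywhere are errors."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"summary"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_section(cls, data[section] or {}, section)
    if "summary" in data:
        block = data["summary"] or {}
        unknown = set(block) - {"measures"}
        if unknown:
            raise ConfigurationError(f"unknown key(s) in 'summary': {sorted(unknown)}")
        if "measures" in block:
            kwargs["summary_measures"] = tuple(block["measures"])
    return PipelineConfig(**kwargs)


def _config_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _config_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return [_config_dict(v) for v in obj]  # type: ignore[return-value]
    return obj


def _write_manifest(out_dir: Path, config: PipelineConfig, extra: dict) -> None:
    manifest = {"version": _version, "config": _config_dict(config), **extra}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def simulate(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[TimeLapse, dict]:
    """Generate and render a synthetic scene; write frames, truth and manifest.

    ``seed`` overrides the seed in the simulate config section.  Outputs:
    ``frames/`` (one TIFF per frame), ``truth.csv`` (per frame, per cell:
    position, radius, flash and visibility flags), ``masks.tif`` (uint16
    label stack) and ``manifest.json``.
    """
    scene_cfg = config.simulate
    if seed is not None:
        scene_cfg = dataclasses.replace(scene_cfg, seed=seed)
        config = dataclasses.replace(config, simulate=scene_cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = generate_scene(scene_cfg)
    timelapse, truth = render_timelapse(scene)
    write_timelapse(timelapse, out_dir / "frames", multipage=config.io.multipage)
    truth["table"].to_csv(out_dir / "truth.csv", index=False)
    tifffile.imwrite(
        out_dir / "masks.tif", np.stack(truth["masks"]), photometric="minisblack"
    )
    _write_manifest(out_dir, config, {"command": "simulate", "seed": scene_cfg.seed})
    log.info("simulate: %d frames, %d cells", scene_cfg.n_frames, scene.n_cells)
    return timelapse, truth


def run_pipeline(
    config: PipelineConfig,
    in_path: str | Path,
    out_dir: str | Path,
    stages: Sequence[str] = STAGES,
) -> dict:
    """Run a prefix of enhance → segment → filter → track → summarize.

    Stage artifacts are written under ``out_dir``; the returned dict maps
    stage names to their in-memory products.  ``stages`` must form a prefix
    of the pipeline order, since each stage consumes its predecessor's
    output.
    """
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise ConfigurationError(f"unknown stage {s!r}; choose from {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    if tuple(ordered) != tuple(STAGES[: len(ordered)]):
        first = ordered[0] if ordered else "<none>"
        missing = STAGES[: STAGES.index(ordered[-1])] if ordered else ()
        missing = [s for s in missing if s not in ordered]
        raise ConfigurationError(
            f"stage {ordered[-1]!r} requires prior stage(s) {missing}: "
            "stages must form a prefix of the pipeline order"
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    timelapse = read_timelapse(in_path, config.io.phase_pattern)
    phase = config.io.detection_phase or timelapse.phase_labels[0]

    if "enhance" in ordered:
        enhanced = TimeLapse(
            [stretch_contrast(f, config.enhancement) for f in timelapse.frames]
        )
        write_timelapse(enhanced, out_dir / "enhanced", multipage=config.io.multipage)
        results["enhance"] = enhanced
        log.info("enhance: %d frames", len(enhanced.frames))

    if "segment" in ordered:
        detections = [
            segment_frame(f, config.segmentation)
            for f in results["enhance"].phase(phase)
        ]
        flat = [d for dets in detections for d in dets]
        write_metadata(flat, out_dir / "detections.csv")
        results["segment"] = detections
        log.info("segment: %d detections over %d frames", len(flat), len(detections))

    if "filter" in ordered:
        kept_all, cleaned_frames = [], []
        n_discarded = 0
        for f, dets in zip(results["enhance"].phase(phase), results["segment"]):
            kept, discarded = apply_filter(dets, config.filter)
            kept_all.append(kept)
            n_discarded += len(discarded)
            cleaned_frames.append(erase_cells(f, discarded))
        write_timelapse(
            TimeLapse(cleaned_frames), out_dir / "cleaned", multipage=config.io.multipage
        )
        write_metadata([d for dets in kept_all for d in dets], out_dir / "detections_kept.csv")
        results["filter"] = kept_all
        log.info("filter: discarded %d detections", n_discarded)

    if "track" in ordered:
        tracks = build_tracks(results["filter"], config.tracking)
        write_metadata(tracks, out_dir / "tracks.csv")
        write_annotated(
            TimeLapse([f.copy() for f in results["enhance"].phase(phase)]),
            tracks,
            out_dir / "annotated",
        )
        results["track"] = tracks
        log.info("track: %d tracks", len(tracks))

    if "summarize" in ordered:
        table = summarize(results["track"], config.summary_measures)
        table.to_csv(out_dir / "summary.csv")
        results["summarize"] = table
        log.info("summarize: %d measures", len(table.table))

    _write_manifest(out_dir, config, {"command": "run", "stages": ordered, "input": str(in_path)})
    return results
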