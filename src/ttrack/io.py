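"""Time-lapse TIFF input/output, per-cell metadata export and annotated renders.

A :class:`Frame` is a single grayscale image at one time point in one
acquisition phase (e.g. the phase-contrast morphology channel or a
fluorescence channel); a :class:`TimeLapse` is the ordered collection of
frames for a whole acquisition.  All raster I/O goes through ``tifffile``;
metadata tables are plain CSV; annotated overlays are rendered to PNG.

Coordinate convention: 0-based ``(row, col)`` with row 0 at the top of the
image; centroids are real-valued with pixel centers at integer coordinates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .errors import ValidationError

__all__ = [
    "Frame",
    "TimeLapse",
    "read_timelapse",
    "write_timelapse",
    "write_metadata",
    "write_annotated",
    "METADATA_COLUMNS",
]

#: Columns of the per-cell metadata CSV, one row per (cell, time point).
METADATA_COLUMNS = [
    "track_id",
    "time_index",
    "centroid_row",
    "centroid_col",
    "area",
    "perimeter",
    "major_axis",
    "minor_axis",
    "extent",
    "eccentricity",
    "max_intensity",
    "mean_intensity",
    "distance_from_previous",
]

_DTYPES = {8: np.uint8, 16: np.uint16}

#: Default filename pattern mapping a file name to (time, phase).
DEFAULT_PHASE_PATTERN = r"t(?P<time>\d+)_p(?P<phase>\w+)\.tiff?$"


@dataclass
class Frame:
    """One grayscale image: intensity raster plus its place in the series.

    Pixels are non-negative integers within ``[0, 2**bit_depth - 1]``; the
    raster must be at least one 32x32 tile in each dimension.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    time_index: int = 0
    phase_label: str = "phase1"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in _DTYPES:
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.ndim != 2:
            raise ValidationError("Frame pixels must be a 2-D array")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValidationError(
                f"Frame must be at least 32x32 (one tile), got {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError("Frame pixels must be integer-typed")
        if self.pixels.size and (
            int(self.pixels.min()) < 0 or int(self.pixels.max()) > self.max_value
        ):
            raise ValidationError(
                f"pixel values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        if self.time_index < 0:
            raise ValidationError("time_index must be >= 0")
        self.pixels = self.pixels.astype(_DTYPES[self.bit_depth], copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity (255 or 65535)."""
        return (1 << self.bit_depth) - 1

    def copy(self) -> "Frame":
        return Frame(self.pixels.copy(), self.bit_depth, self.time_index, self.phase_label)


@dataclass
class TimeLapse:
    """Ordered frames grouped by time point, then phase.

    Invariants: all frames share shape and bit depth; time indices are
    consecutive from 0; every time point carries the same set of phases.
    """

    frames: list[Frame]
    pixel_resolution_note: str | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            return
        shape = self.frames[0].shape
        depth = self.frames[0].bit_depth
        by_time: dict[int, set[str]] = {}
        for f in self.frames:
            if f.shape != shape:
                raise ValidationError(
                    f"inconsistent frame dimensions: {f.shape} vs {shape} "
                    f"(time {f.time_index}, phase {f.phase_label})"
                )
            if f.bit_depth != depth:
                raise ValidationError("inconsistent bit depth across frames")
            by_time.setdefault(f.time_index, set())
            if f.phase_label in by_time[f.time_index]:
                raise ValidationError(
                    f"duplicate frame for time {f.time_index} phase {f.phase_label}"
                )
            by_time[f.time_index].add(f.phase_label)
        times = sorted(by_time)
        if times != list(range(len(times))):
            raise ValidationError(
                f"time_index values must be consecutive from 0, got {times}"
            )
        phases = by_time[times[0]]
        for t in times:
            missing = phases - by_time[t]
            extra = by_time[t] - phases
            if missing or extra:
                raise ValidationError(
                    f"time point {t} phase mismatch: missing {sorted(missing)}, "
                    f"unexpected {sorted(extra)}"
                )
        self.frames.sort(key=lambda f: (f.time_index, f.phase_label))

    @property
    def n_timepoints(self) -> int:
        return 1 + self.frames[-1].time_index if self.frames else 0

    @property
    def phase_labels(self) -> list[str]:
        if not self.frames:
            return []
        return sorted({f.phase_label for f in self.frames if f.time_index == 0})

    def get(self, time_index: int, phase_label: str | None = None) -> Frame:
        if phase_label is None:
            phase_label = self.phase_labels[0]
        for f in self.frames:
            if f.time_index == time_index and f.phase_label == phase_label:
                return f
        raise KeyError((time_index, phase_label))

    def phase(self, phase_label: str) -> list[Frame]:
        """All frames of one phase, in time order."""
        return [f for f in self.frames if f.phase_label == phase_label]


def _depth_from_dtype(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValidationError(f"{path}: unsupported TIFF dtype {arr.dtype} (need uint8/uint16)")


def read_timelapse(
    source_path: str | Path,
    phase_pattern: str = DEFAULT_PHASE_PATTERN,
) -> TimeLapse:
    """Read a time lapse from a multi-page TIFF or a directory of TIFFs.

    ``phase_pattern`` is a regex with a ``time`` group and an optional
    ``phase`` group applied to each file name in a directory; a single
    multi-page TIFF is read as one phase with pages as time points.  Frame
    order is a deterministic function of the parsed (time, phase) keys,
    never of directory listing order.
    """
    source_path = Path(source_path)
    if not source_path.exists():
        raise FileNotFoundError(f"no such file or directory: {source_path}")
    frames: list[Frame] = []
    if source_path.is_dir():
        pat = re.compile(phase_pattern)
        entries = []
        for p in sorted(source_path.iterdir()):
            m = pat.search(p.name)
            if m is None:
                continue
            t = int(m.group("time"))
            phase = m.groupdict().get("phase") or "phase1"
            entries.append((t, phase, p))
        if not entries:
            raise ValidationError(
                f"{source_path}: no files matching pattern {phase_pattern!r}"
            )
        entries.sort(key=lambda e: (e[0], e[1]))
        times = sorted({t for t, _, _ in entries})
        remap = {t: i for i, t in enumerate(times)}
        phases = sorted({ph for _, ph, _ in entries})
        seen = {(t, ph) for t, ph, _ in entries}
        gaps = [
            (t, ph) for t in times for ph in phases if (t, ph) not in seen
        ]
        if gaps:
            desc = ", ".join(f"time {t} / phase {ph}" for t, ph in gaps)
            raise ValidationError(f"{source_path}: missing frames for {desc}")
        for t, phase, p in entries:
            arr = tifffile.imread(p)
            if arr.ndim != 2:
                raise ValidationError(f"{p}: expected a single-page 2-D TIFF")
            frames.append(Frame(arr, _depth_from_dtype(arr, p), remap[t], phase))
    else:
        arr = tifffile.imread(source_path)
        if arr.ndim == 2:
            arr = arr[None]
        depth = _depth_from_dtype(arr, source_path)
        for t in range(arr.shape[0]):
            frames.append(Frame(arr[t], depth, t, "phase1"))
    return TimeLapse(frames)


def write_timelapse(
    timelapse: TimeLapse,
    dest_path: str | Path,
    multipage: bool = False,
) -> None:
    """Write a time lapse losslessly as TIFF.

    With ``multipage=False`` (default) one file per frame named
    ``t{time:03d}_p{phase}.tif`` is written under ``dest_path`` (a
    directory); with ``multipage=True`` one multi-page TIFF per phase.
    """
    if not timelapse.frames:
        raise ValidationError("cannot write an empty TimeLapse")
    dest_path = Path(dest_path)
    dest_path.mkdir(parents=True, exist_ok=True)
    if multipage:
        for phase in timelapse.phase_labels:
            stack = np.stack([f.pixels for f in timelapse.phase(phase)])
            tifffile.imwrite(dest_path / f"{phase}.tif", stack, photometric="minisblack")
    else:
        for f in timelapse.frames:
            tifffile.imwrite(dest_path / f"t{f.time_index:03d}_p{f.phase_label}.tif", f.pixels)


def _feature_row(det, track_id: str, distance) -> dict:
    feats = det.features
    if feats is None:
        raise ValidationError(
            f"detection {det.detection_id!r} at time {det.frame_time} has no features"
        )
    for name in (
        "centroid", "area", "perimeter", "major_axis", "minor_axis",
        "extent", "eccentricity", "max_intensity", "mean_intensity",
    ):
        value = getattr(feats, name)
        if value is None or (
            not isinstance(value, tuple) and not math.isfinite(float(value))
        ):
            raise ValidationError(
                f"incomplete feature record: field {name!r} on detection "
                f"{det.detection_id!r} at time {det.frame_time}"
            )
    return {
        "track_id": track_id,
        "time_index": det.frame_time,
        "centroid_row": feats.centroid[0],
        "centroid_col": feats.centroid[1],
        "area": feats.area,
        "perimeter": feats.perimeter,
        "major_axis": feats.major_axis,
        "minor_axis": feats.minor_axis,
        "extent": feats.extent,
        "eccentricity": feats.eccentricity,
        "max_intensity": feats.max_intensity,
        "mean_intensity": feats.mean_intensity,
        "distance_from_previous": "" if distance is None else distance,
    }


def write_metadata(detections_or_tracks: Iterable, dest_path: str | Path) -> None:
    """Export per-cell metadata as CSV, one row per (cell, time point).

    Accepts a collection of untracked ``CellDetection`` records (blank
    ``track_id`` and ``distance_from_previous``) or of ``Track`` objects
    (rows keyed by track id; the per-step centroid displacement fills
    ``distance_from_previous`` from the second detected entry on).  Floats
    are printed at full ``repr`` precision so the file re-parses exactly.
    """
    rows: list[dict] = []
    for item in detections_or_tracks:
        if hasattr(item, "entries"):  # Track
            prev = None
            for t, det in item.entries:
                if det is None:
                    continue
                dist = None
                if prev is not None:
                    dc = np.subtract(det.features.centroid, prev.features.centroid)
                    dist = float(np.hypot(dc[0], dc[1]))
                rows.append(_feature_row(det, item.track_id, dist))
                prev = det
        else:
            rows.append(_feature_row(item, "", None))
    dest_path = Path(dest_path)
    dest_path.parent.mkdir(parents=True, exist_ok=True)
    with open(dest_path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(METADATA_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(_csv_cell(row[c]) for c in METADATA_COLUMNS) + "\n")


def _csv_cell(value) -> str:
    if value is None or value == "":
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return repr(float(value))


def _to_rgb(frame: Frame) -> np.ndarray:
    scale = 255.0 / frame.max_value
    gray = (frame.pixels.astype(np.float64) * scale).round().astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)


_OUTLINE = (255, 64, 64)
_PATH = (64, 160, 255)


def write_annotated(
    timelapse: TimeLapse,
    detections_or_tracks: Iterable,
    dest_path: str | Path,
    phase_label: str | None = None,
) -> None:
    """Render one annotated PNG per time point.

    Detected cell outlines are drawn in red on the (already enhanced) frame;
    tracked input additionally gets a persistent per-track label and a
    trailing centroid path.
    """
    items = list(detections_or_tracks)
    dest_path = Path(dest_path)
    dest_path.mkdir(parents=True, exist_ok=True)
    frames = timelapse.phase(phase_label or timelapse.phase_labels[0])
    n_t = len(frames)

    per_time: dict[int, list] = {t: [] for t in range(n_t)}  # (det, label, trail)
    for item in items:
        if hasattr(item, "entries"):
            trail: list[tuple[float, float]] = []
            for t, det in item.entries:
                if det is None:
                    continue
                if t < 0 or t >= n_t:
                    raise ValidationError(
                        f"track {item.track_id}: time {t} outside [0, {n_t})"
                    )
                trail = trail + [det.features.centroid]
                per_time[t].append((det, item.track_id, list(trail)))
        else:
            t = item.frame_time
            if t < 0 or t >= n_t:
                raise ValidationError(
                    f"detection {item.detection_id!r}: time {t} outside [0, {n_t})"
                )
            per_time[t].append((item, None, None))

    for frame in frames:
        rgb = _to_rgb(frame)
        for det, _label, _trail in per_time[frame.time_index]:
            for r, c in _outline_pixels(det):
                if 0 <= r < rgb.shape[0] and 0 <= c < rgb.shape[1]:
                    rgb[r, c] = _OUTLINE
        img = Image.fromarray(rgb)
        draw = ImageDraw.Draw(img)
        for det, label, trail in per_time[frame.time_index]:
            if label is None:
                continue
            if trail and len(trail) > 1:
                draw.line([(c, r) for r, c in trail], fill=_PATH, width=1)
            br, bc = det.features.centroid
            draw.text((bc + 4, br - 10), str(label), fill=(255, 255, 0))
        img.save(dest_path / f"t{frame.time_index:03d}.png")


def _outline_pixels(det) -> np.ndarray:
    """Boundary pixels of a detection (pixels with a non-member 4-neighbour)."""
    px = np.asarray(sorted(map(tuple, det.pixel_set)))
    members = set(map(tuple, px))
    out = []
    for r, c in px:
        if (
            (r - 1, c) not in members
            or (r + 1, c) not in members
            or (r, c - 1) not in members
            or (r, c + 1) not in members
        ):
            out.append((r, c))
    return np.asarray(out)
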