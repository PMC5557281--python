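"""Frame-to-frame identity linking of detections into tracks.

Consecutive frames are linked by a gated minimum-cost assignment: a pair of
detections is admissible when their centroids are within the gate radius,
its cost is the centroid distance plus weighted normalized feature
differences (area, mean intensity, major axis), and the solver returns the
minimum-total-cost matching among maximum-cardinality matchings over
admissible pairs.  Unmatched detections start new tracks (cells entering
the field of view); a track may coast through a bounded number of missed
frames with a proportionally enlarged gate before it is terminated (cells
leaving the field, or briefly lost to segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .features import compute_distance
from .segment import CellDetection

__all__ = ["TrackingConfig", "Track", "link_frames", "build_tracks"]

_FORBIDDEN = 1e9  # uniform penalty: cardinality dominates any admissible cost sum


@dataclass(frozen=True)
class TrackingConfig:
    """Gate radius (px/frame), feature weights and missed-frame tolerance.

    feature_weights apply to the normalized differences of (area,
    mean_intensity, major_axis); each difference is |Δx| / max(x_i, x_j),
    dimensionless in [0, 1).  The 20 px default gate matches the largest
    per-step displacement observed in the source imagery.
    """

    gate_radius: float = 20.0
    feature_weights: tuple[float, float, float] = (1.0, 1.0, 0.5)
    max_missed_frames: int = 2

    def __post_init__(self) -> None:
        if not self.gate_radius > 0:
            raise ValidationError("gate_radius must be positive")
        if any(w < 0 for w in self.feature_weights):
            raise ValidationError("feature weights must be non-negative")
        if self.max_missed_frames < 0:
            raise ValidationError("max_missed_frames must be >= 0")


@dataclass
class Track:
    """An identity-linked sequence of detections with per-step displacement.

    entries holds (time_index, detection-or-None); None marks a frame the
    track coasted through undetected.  per_step_distance pairs consecutive
    *detected* entries.
    """

    track_id: str
    entries: list[tuple[int, Optional[CellDetection]]] = field(default_factory=list)

    @property
    def per_step_distance(self) -> list[float]:
        dets = [d for _, d in self.entries if d is not None]
        return [
            compute_distance(a.features.centroid, b.features.centroid)
            for a, b in zip(dets, dets[1:])
        ]

    @property
    def start_time(self) -> int:
        return self.entries[0][0]

    @property
    def end_time(self) -> int:
        return self.entries[-1][0]

    @property
    def detections(self) -> list[CellDetection]:
        return [d for _, d in self.entries if d is not None]


def _pair_cost(a: CellDetection, b: CellDetection, config: TrackingConfig) -> float:
    dist = compute_distance(a.features.centroid, b.features.centroid)
    wa, wi, wm = config.feature_weights
    fa, fb = a.features, b.features
    cost = dist
    if wa:
        cost += wa * abs(fa.area - fb.area) / max(fa.area, fb.area, 1)
    if wi:
        cost += wi * abs(fa.mean_intensity - fb.mean_intensity) / max(
            fa.mean_intensity, fb.mean_intensity, 1.0
        )
    if wm:
        cost += wm * abs(fa.major_axis - fb.major_axis) / max(
            fa.major_axis, fb.major_axis, 1e-9
        )
    return cost


def link_frames(
    dets_t: Sequence[CellDetection],
    dets_next: Sequence[CellDetection],
    config: TrackingConfig | None = None,
    gate_scale: float = 1.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal gated one-to-one assignment between two detection lists.

    Returns ``(pairs, unmatched_t, unmatched_next)`` with pairs as index
    tuples into the input sequences.  The objective is maximum cardinality
    over gate-admissible pairs, then minimum total cost; both lists may be
    empty.  ``gate_scale`` enlarges the gate when bridging missed frames.
    """
    config = config or TrackingConfig()
    n, m = len(dets_t), len(dets_next)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    gate = config.gate_radius * gate_scale
    cost = np.full((n, m), _FORBIDDEN, dtype=np.float64)
    for i, a in enumerate(dets_t):
        for j, b in enumerate(dets_next):
            d = compute_distance(a.features.centroid, b.features.centroid)
            if d <= gate:
                cost[i, j] = _pair_cost(a, b, config)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _FORBIDDEN
    ]
    matched_t = {i for i, _ in pairs}
    matched_n = {j for _, j in pairs}
    return (
        sorted(pairs),
        [i for i in range(n) if i not in matched_t],
        [j for j in range(m) if j not in matched_n],
    )


def build_tracks(
    frames_detections: Sequence[Sequence[CellDetection]],
    config: TrackingConfig | None = None,
) -> list[Track]:
    """Link per-time-point detection lists into tracks.

    frames_detections[t] holds the detections of time point t (one phase);
    detection frame_time fields, when set, must equal their list index.
    Every detection ends up in exactly one track; unmatched detections are
    births, tracks missing for more than ``max_missed_frames`` die, and a
    coasting track re-links within a gate enlarged in proportion to the gap.
    """
    config = config or TrackingConfig()
    for t, dets in enumerate(frames_detections):
        for d in dets:
            if d.frame_time != t:
                raise ValidationError(
                    f"detection {d.detection_id!r} has frame_time {d.frame_time} "
                    f"but sits at time point {t}; time indices must be consecutive"
                )

    tracks: list[Track] = []
    # active: list of (track, last_detection, missed_count)
    active: list[list] = []
    next_id = 0

    def _new_track(t: int, det: CellDetection) -> None:
        nonlocal next_id
        tr = Track(track_id=f"T{next_id:04d}", entries=[(t, det)])
        next_id += 1
        tracks.append(tr)
        active.append([tr, det, 0])

    for det in frames_detections[0] if frames_detections else []:
        _new_track(0, det)

    for t in range(1, len(frames_detections)):
        dets_next = list(frames_detections[t])
        # Match nearest-gap tracks first: gap 0, then 1, ... so a live track
        # cannot be displaced by one that is coasting.
        remaining = list(range(len(dets_next)))
        matched_next: dict[int, None] = {}
        for gap in range(0, config.max_missed_frames + 1):
            cand = [entry for entry in active if entry[2] == gap]
            if not cand or not remaining:
                continue
            pairs, _, _ = link_frames(
                [entry[1] for entry in cand],
                [dets_next[j] for j in remaining],
                config,
                gate_scale=float(gap + 1),
            )
            taken = set()
            for ci, rj in pairs:
                entry = cand[ci]
                j = remaining[rj]
                tr, prev, _missed = entry
                for miss_t in range(prev.frame_time + 1, t):
                    tr.entries.append((miss_t, None))
                tr.entries.append((t, dets_next[j]))
                entry[1] = dets_next[j]
                entry[2] = -1  # flag: matched this round; reset below
                matched_next[j] = None
                taken.add(rj)
            remaining = [j for k, j in enumerate(remaining) if k not in taken]
        for entry in active:
            if entry[2] == -1:
                entry[2] = 0
            else:
                entry[2] += 1
        active[:] = [e for e in active if e[2] <= config.max_missed_frames]
        for j in remaining:
            _new_track(t, dets_next[j])

    return tracks
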