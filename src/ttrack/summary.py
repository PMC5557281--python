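"""Per-dataset summary statistics over detections or tracks.

Produces the min / mean / max / standard-deviation table for the measure
set, pooled over all (cell, time point) records.  Per-step displacement
("distance") is defined only on tracked input, over consecutive detected
pairs within each track.  A migration-style dataset reports distance; a
locked-in-place interaction dataset omits it and reports eccentricity
instead — the measure set is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SummaryTable", "summarize", "MOVEMENT_MEASURES", "INTERACTION_MEASURES"]

#: Measure set for freely migrating cells (per-step distance included).
MOVEMENT_MEASURES = (
    "area", "perimeter", "major_axis", "minor_axis",
    "distance", "extent", "max_intensity", "mean_intensity",
)
#: Measure set for immobilized-cell interaction data (eccentricity instead).
INTERACTION_MEASURES = (
    "area", "perimeter", "major_axis", "minor_axis",
    "eccentricity", "extent", "max_intensity", "mean_intensity",
)

_FEATURE_MEASURES = (
    "area", "perimeter", "major_axis", "minor_axis",
    "extent", "eccentricity", "max_intensity", "mean_intensity",
)


@dataclass
class SummaryTable:
    """One row per measure: n, min, mean, max, sample standard deviation."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, measure: str) -> pd.Series:
        match = self.table[self.table["measure"] == measure]
        if match.empty:
            raise KeyError(measure)
        return match.iloc[0]


def _stats(values: Sequence[float]) -> dict:
    arr = np.asarray(list(values), dtype=np.float64)
    n = arr.size
    if n == 0:
        return {"n": 0, "min": np.nan, "mean": np.nan, "max": np.nan, "sd": np.nan}
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return {
        "n": int(n),
        "min": float(arr.min()),
        "mean": float(arr.mean()),
        "max": float(arr.max()),
        "sd": sd,
    }


def summarize(
    detections_or_tracks: Iterable,
    measure_set: Sequence[str] = MOVEMENT_MEASURES,
) -> SummaryTable:
    """Pool all (cell, time point) records and tabulate per-measure statistics.

    Accepts a collection of detections or of tracks; requesting the
    ``distance`` measure on untracked input is an error, since per-step
    displacement needs identity links.
    """
    items = list(detections_or_tracks)
    tracked = bool(items) and hasattr(items[0], "entries")
    if "distance" in measure_set and items and not tracked:
        raise ValidationError("the distance measure requires tracked input")

    if tracked:
        detections = [d for tr in items for d in tr.detections]
        distances = [step for tr in items for step in tr.per_step_distance]
    else:
        detections = items
        distances = []

    rows = []
    for measure in measure_set:
        if measure == "distance":
            values = distances
        elif measure in _FEATURE_MEASURES:
            values = [getattr(d.features, measure) for d in detections]
        else:
            raise ValidationError(f"unknown measure {measure!r}")
        rows.append({"measure": measure, **_stats(values)})
    return SummaryTable(pd.DataFrame(rows, columns=["measure", "n", "min", "mean", "max", "sd"]))
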