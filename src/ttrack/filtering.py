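"""Noise-cell removal: declarative expert criteria plus pixel erasure.

Detections that fall outside expert-specified per-feature acceptance
intervals (not T cells, no calcium activity, debris) are discarded, and
their pixels can be reset to a background value on a copy of the frame so
that downstream passes no longer see them.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import Frame
from .segment import CellDetection

__all__ = ["FilterCriteria", "apply_filter", "erase_cells", "activation_floor"]

Interval = tuple[float, float]

_INTERVAL_FEATURES = (
    "area",
    "extent",
    "eccentricity",
    "max_intensity",
    "mean_intensity",
    "major_axis",
    "minor_axis",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Closed acceptance intervals per feature; unset intervals are vacuous.

    With ``require_activity`` set, a detection must additionally reach
    ``activity_floor`` in max intensity — the configurable stand-in for
    "shows calcium activity".
    """

    area: Optional[Interval] = None
    extent: Optional[Interval] = None
    eccentricity: Optional[Interval] = None
    max_intensity: Optional[Interval] = None
    mean_intensity: Optional[Interval] = None
    major_axis: Optional[Interval] = None
    minor_axis: Optional[Interval] = None
    require_activity: bool = False
    activity_floor: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _INTERVAL_FEATURES:
            iv = getattr(self, name)
            if iv is None:
                continue
            lo, hi = iv
            if not lo <= hi:
                raise ValidationError(
                    f"criteria interval for {name!r} has lower > upper: {iv}"
                )
        if self.require_activity and self.activity_floor is None:
            raise ValidationError(
                "require_activity needs an activity_floor "
                "(see activation_floor() for the default rule)"
            )

    def accepts(self, det: CellDetection) -> bool:
        feats = det.features
        if feats is None:
            raise ValidationError("detection has no feature record")
        for name in _INTERVAL_FEATURES:
            iv = getattr(self, name)
            if iv is None:
                continue
            value = getattr(feats, name)
            if not (iv[0] <= value <= iv[1]):
                return False
        if self.require_activity and feats.max_intensity < self.activity_floor:
            return False
        return True


def apply_filter(
    detections: Sequence[CellDetection], criteria: FilterCriteria
) -> tuple[list[CellDetection], list[CellDetection]]:
    """Split detections into (kept, discarded), preserving order.

    A detection is kept iff every specified interval contains its feature
    value (closed intervals: endpoints are kept) and, when required, its
    max intensity reaches the activation floor.
    """
    kept, discarded = [], []
    for det in detections:
        (kept if criteria.accepts(det) else discarded).append(det)
    return kept, discarded


def _modal_intensity(frame: Frame) -> int:
    values, counts = np.unique(frame.pixels, return_counts=True)
    return int(values[int(np.argmax(counts))])


def activation_floor(frame: Frame, n_sigmas: float = 3.0) -> float:
    """Default calcium-activity floor: background mode + 3 robust sigmas.

    The noise scale is the median absolute deviation from the modal
    background value, scaled by 1.4826 to estimate a Gaussian sigma.
    """
    mode = _modal_intensity(frame)
    mad = float(np.median(np.abs(frame.pixels.astype(np.float64) - mode)))
    return mode + n_sigmas * 1.4826 * mad


def erase_cells(
    frame: Frame,
    discarded: Sequence[CellDetection],
    background_value: int | None = None,
) -> Frame:
    """Copy the frame with discarded cells' pixels reset to background.

    The input frame is untouched; exactly the union of the discarded pixel
    sets is set to ``background_value`` (default: the frame's modal
    intensity).  Idempotent for fixed arguments.
    """
    if background_value is None:
        background_value = _modal_intensity(frame)
    if not 0 <= background_value <= frame.max_value:
        raise ValidationError("background_value outside the frame's bit range")
    out = frame.copy()
    h, w = frame.shape
    for det in discarded:
        px = det.pixel_set
        if (
            px[:, 0].min() < 0 or px[:, 1].min() < 0
            or px[:, 0].max() >= h or px[:, 1].max() >= w
        ):
            raise ValidationError(
                f"detection {det.detection_id!r} has pixels outside the frame"
            )
        out.pixels[px[:, 0], px[:, 1]] = background_value
    return out
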