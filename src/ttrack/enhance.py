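"""Contrast enhancement: two-sided saturating linear stretch.

The first processing step of the pipeline.  Intensities are remapped so
that a fixed fraction of pixels saturates at each end of the output range
(default 1% low, 1% high), which boosts the contrast of dim phase-contrast
cells before thresholding.  Each frame is stretched independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io import Frame

__all__ = ["EnhancementConfig", "stretch_contrast"]


@dataclass(frozen=True)
class EnhancementConfig:
    """Parameters of the contrast stretch.

    saturation_fraction is the fraction of pixels driven to each end of the
    output range; it must be < 0.5 so the low and high clip sets cannot
    cross the median.
    """

    saturation_fraction: float = 0.01

    def __post_init__(self) -> None:
        f = self.saturation_fraction
        if not (0.0 <= f < 0.5):
            raise ConfigurationError(
                f"saturation_fraction must be in [0, 0.5), got {f}"
            )


def stretch_contrast(frame: Frame, config: EnhancementConfig | None = None) -> Frame:
    """Linearly map the [lo, hi] quantile band onto the full output range.

    lo / hi are the ``saturation_fraction`` and ``1 - saturation_fraction``
    order-statistic quantiles (linear interpolation).  Pixels at or below lo
    map to 0, pixels at or above hi map to the range maximum, and the
    interior follows the linear map (rounded to the integer grid), so the
    mapping is monotone non-decreasing.  A constant (or otherwise
    degenerate, lo == hi) frame passes through unchanged with a warning so
    that one blank time point cannot abort a batch.
    """
    config = config or EnhancementConfig()
    f = config.saturation_fraction
    x = frame.pixels.astype(np.float64)
    lo, hi = np.quantile(x, [f, 1.0 - f])
    if hi <= lo:
        warnings.warn(
            f"degenerate frame at time {frame.time_index} ({frame.phase_label}): "
            "intensity quantiles coincide; returning the frame unchanged",
            stacklevel=2,
        )
        return frame.copy()
    maxv = frame.max_value
    out = (x - lo) / (hi - lo) * maxv
    out = np.clip(np.rint(out), 0, maxv)
    return Frame(
        out.astype(frame.pixels.dtype),
        frame.bit_depth,
        frame.time_index,
        frame.phase_label,
    )
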