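"""Synthetic ground-truth time-lapse scenes.

Generates the phenomenology the pipeline must cope with — round-ish cells
of 8–30 px diameter on a noisy background, spatially varying illumination,
Brownian-plus-drift motility, transient whole-cell fluorescence flashes
(the calcium-indicator "green flash"), and cells entering or leaving the
field of view — together with exact per-frame ground truth (cell centres,
radii, flash state, visibility, label masks) against which detection and
tracking are scored.

Not simulated: microscope optics (point-spread function, phase-contrast
halo), photobleaching, cell-cell contact dynamics and shape change beyond a
fixed optional eccentricity.  See docs/methods.md for what a green test on
these scenes does and does not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import Frame, TimeLapse

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "render_timelapse"]

# Scripted boundary crossings run at 8 px/frame: fast against the
# detector's component-area floor, so the field-of-view entry/exit frame is
# sharply defined (a cell cannot hover half-visible at the edge for several
# frames), and brief against the sequence, so a crossing cell has little
# time to collide with residents.
_CROSSING_SPEED = 8.0


@dataclass(frozen=True)
class SceneConfig:
    """Stated world of a synthetic scene.

    Intensities are in raw camera units of the configured bit depth;
    lengths in pixels; motion_sd is the per-axis Gaussian step per frame.
    illumination_gradient is the amplitude of a linear left-to-right ramp
    as a fraction of cell_contrast.  n_entering / n_exiting script cells
    that cross the field-of-view boundary (forcing entry_exit semantics).
    """

    frame_shape: tuple[int, int] = (512, 512)
    n_frames: int = 60
    n_cells: int = 25
    radius_range: tuple[float, float] = (5.0, 12.0)
    cell_contrast: float = 10000.0
    background_level: float = 4000.0
    noise_sd: float = 1000.0
    illumination_gradient: float = 0.0
    motion_sd: float = 1.5
    drift: tuple[float, float] = (0.0, 0.0)
    flash_probability: float = 0.02
    flash_gain: float = 2.0
    entry_exit: bool = False
    n_entering: int = 0
    n_exiting: int = 0
    eccentricity: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        maxv = (1 << self.bit_depth) - 1
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if not (0 <= self.background_level <= maxv):
            raise ConfigurationError("background_level outside bit range")
        if self.cell_contrast < 0 or self.noise_sd < 0 or self.motion_sd < 0:
            raise ConfigurationError("contrast, noise_sd and motion_sd must be >= 0")
        if not (0.0 <= self.flash_probability <= 1.0):
            raise ConfigurationError("flash_probability must be in [0, 1]")
        if self.flash_gain < 1.0:
            raise ConfigurationError("flash_gain must be >= 1")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ConfigurationError("eccentricity must be in [0, 1)")
        r_min, r_max = self.radius_range
        if not (0 < r_min <= r_max):
            raise ConfigurationError("radius_range must satisfy 0 < r_min <= r_max")
        if self.n_cells < 0 or self.n_frames < 1:
            raise ConfigurationError("need n_cells >= 0 and n_frames >= 1")
        if self.n_entering < 0 or self.n_exiting < 0:
            raise ConfigurationError("n_entering / n_exiting must be >= 0")
        if self.n_entering + self.n_exiting > 0 and not self.entry_exit:
            object.__setattr__(self, "entry_exit", True)
        if self.n_entering + self.n_exiting > self.n_cells:
            raise ConfigurationError("more scripted entries/exits than cells")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class SyntheticScene:
    """Ground-truth cell states from which frames are rendered.

    centers has shape (n_frames, n_cells, 2) in (row, col); flashing and
    visible are (n_frames, n_cells) booleans.  A cell invisible in frame t
    has its centre outside the frame bounds — it is never silently dropped.
    """

    config: SceneConfig
    radii: np.ndarray
    orientations: np.ndarray
    centers: np.ndarray
    flashing: np.ndarray
    entering_ids: tuple[int, ...] = ()
    exiting_ids: tuple[int, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.radii.shape[0]

    @property
    def visible(self) -> np.ndarray:
        h, w = self.config.frame_shape
        r, c = self.centers[..., 0], self.centers[..., 1]
        return (r >= 0) & (r < h) & (c >= 0) & (c < w)

    def truth_table(self) -> pd.DataFrame:
        """Long-form per (frame, cell) ground truth."""
        rows = []
        vis = self.visible
        for t in range(self.config.n_frames):
            for i in range(self.n_cells):
                rows.append(
                    {
                        "frame": t,
                        "cell_id": i,
                        "row": self.centers[t, i, 0],
                        "col": self.centers[t, i, 1],
                        "radius": self.radii[i],
                        "flashing": bool(self.flashing[t, i]),
                        "visible": bool(vis[t, i]),
                    }
                )
        return pd.DataFrame(rows)


def _rngs(config: SceneConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    scene_ss, render_ss = ss.spawn(2)
    return np.random.default_rng(scene_ss), np.random.default_rng(render_ss)


def _sample_positions(
    rng: np.random.Generator, config: SceneConfig, n: int, sep: float
) -> np.ndarray:
    h, w = config.frame_shape
    margin = config.radius_range[1] + 1.0
    if h <= 2 * margin or w <= 2 * margin:
        raise ConfigurationError("frame too small for the configured cell radii")
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 5000 * max(n, 1):
            raise ConfigurationError(
                "could not place cells with the required pairwise separation; "
                "lower n_cells or the cell radius"
            )
        p = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(p - q)) >= sep for q in out):
            out.append(p)
    return np.asarray(out).reshape(n, 2)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Simulate cell states for every frame; deterministic given the seed.

    Initial centres are rejection-sampled to a pairwise separation of at
    least twice the maximum radius; per-frame motion is an isotropic
    Gaussian step plus the global drift.  Scripted entering cells start
    outside the field with a constant inward drift (crossing the boundary
    mid-sequence); scripted exiting cells acquire an outward drift partway
    through, fast enough to leave before the sequence ends.
    """
    rng, _ = _rngs(config)
    h, w = config.frame_shape
    n = config.n_cells
    T = config.n_frames
    r_min, r_max = config.radius_range

    radii = rng.uniform(r_min, r_max, size=n)
    orientations = rng.uniform(0.0, np.pi, size=n)
    n_inside = n - config.n_entering
    positions = _sample_positions(rng, config, n_inside, 2.0 * r_max)

    # Scheduled per-cell velocity fields, added to Brownian steps + drift.
    sched_v = np.zeros((T, n, 2))
    start = np.zeros((n, 2))
    start[:n_inside] = positions

    # Scripted exits are drawn from cells starting well inside the field:
    # a cell seeded near the border can diffuse out on its own before its
    # scheduled, fast crossing, leaving a slow ill-defined exit instead.
    if config.n_exiting:
        p = positions
        edge_dist = np.minimum.reduce(
            [p[:, 0], h - 1 - p[:, 0], p[:, 1], w - 1 - p[:, 1]]
        )
        deep = np.flatnonzero(edge_dist >= min(80.0, min(h, w) / 4.0))
        if deep.size < config.n_exiting:
            deep = np.argsort(-edge_dist)[: max(config.n_exiting, 1)]
        exit_ids = list(rng.choice(deep, size=config.n_exiting, replace=False))
    else:
        exit_ids = []
    for i in exit_ids:
        t0 = int(rng.integers(T // 3, max(T // 3 + 1, 2 * T // 3)))
        p = positions[i]
        dists = np.array([p[0], h - 1 - p[0], p[1], w - 1 - p[1]])
        edge = int(np.argmin(dists))
        direction = np.array(
            [(-1.0, 0.0), (1.0, 0.0), (0.0, -1.0), (0.0, 1.0)][edge]
        )
        speed = max(_CROSSING_SPEED, (dists[edge] + radii[i] + 5.0) / max(1, T - 1 - t0))
        sched_v[t0:, i] = direction * speed

    entry_points: list[np.ndarray] = []
    for k in range(config.n_entering):
        i = n_inside + k
        t_entry = int(rng.integers(max(1, T // 6), max(2, T // 2)))
        margin = r_max + 1.0
        # Entry points are kept apart so scripted cells do not enter on top
        # of each other and merge on arrival.
        for _ in range(1000):
            edge = int(rng.integers(0, 4))
            along = rng.uniform(margin, (h if edge >= 2 else w) - margin)
            if edge == 0:  # enter from top, moving down
                point, direction = np.array([0.0, along]), np.array([1.0, 0.0])
            elif edge == 1:  # from bottom
                point, direction = np.array([h - 1.0, along]), np.array([-1.0, 0.0])
            elif edge == 2:  # from left
                point, direction = np.array([along, 0.0]), np.array([0.0, 1.0])
            else:  # from right
                point, direction = np.array([along, w - 1.0]), np.array([0.0, -1.0])
            if all(np.hypot(*(point - q)) >= 4.0 * r_max for q in entry_points):
                break
        else:
            raise ConfigurationError("could not separate scripted entry points")
        entry_points.append(point)
        start[i] = point - direction * _CROSSING_SPEED * t_entry
        # Drift inward only until well inside the field, then move like any
        # resident cell (constant ploughing would force collisions).
        t_stop = min(T, t_entry + int(np.ceil(3.0 * r_max / _CROSSING_SPEED)))
        sched_v[:t_stop, i] = direction * _CROSSING_SPEED

    steps = rng.normal(0.0, config.motion_sd, size=(T - 1, n, 2)) if T > 1 else np.zeros((0, n, 2))
    centers = np.empty((T, n, 2))
    centers[0] = start
    drift = np.asarray(config.drift, dtype=np.float64)
    for t in range(1, T):
        centers[t] = centers[t - 1] + steps[t - 1] + drift + sched_v[t]

    flashing = rng.random(size=(T, n)) < config.flash_probability
    return SyntheticScene(
        config,
        radii,
        orientations,
        centers,
        flashing,
        entering_ids=tuple(range(n_inside, n)),
        exiting_ids=tuple(int(i) for i in sorted(exit_ids)),
    )


def _cell_coverage(
    shape: tuple[int, int],
    center: np.ndarray,
    radius: float,
    eccentricity: float,
    orientation: float,
) -> tuple[slice, slice, np.ndarray] | None:
    """Anti-aliased coverage of one cell within its bounding box.

    Returns (row slice, col slice, coverage in [0, 1]) or None when the
    cell does not intersect the frame.  The rim is smoothed over 1 px.
    """
    h, w = shape
    b = radius * np.sqrt(1.0 - eccentricity**2)
    reach = radius + 1.0
    r0 = int(np.floor(center[0] - reach))
    r1 = int(np.ceil(center[0] + reach)) + 1
    c0 = int(np.floor(center[1] - reach))
    c1 = int(np.ceil(center[1] + reach)) + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return None
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    u = rr - center[0]
    v = cc - center[1]
    if eccentricity > 0:
        co, si = np.cos(orientation), np.sin(orientation)
        u, v = co * u + si * v, -si * u + co * v
        dist = np.sqrt((u / radius) ** 2 + (v / b) ** 2) * min(radius, b)
        edge = min(radius, b)
    else:
        dist = np.sqrt(u * u + v * v)
        edge = radius
    cov = np.clip(edge + 0.5 - dist, 0.0, 1.0)
    if not cov.any():
        return None
    return slice(r0, r1), slice(c0, c1), cov


def render_timelapse(scene: SyntheticScene) -> tuple[TimeLapse, dict]:
    """Render the scene to a single-phase TimeLapse plus truth tables.

    Each frame is background + illumination ramp + anti-aliased per-cell
    disks of height cell_contrast (times flash_gain while flashing) +
    additive Gaussian noise, clipped to the bit range.  The returned truth
    dict carries the long-form state table and per-frame uint16 label masks
    (pixel labelled cell_id + 1 where the cell's coverage is >= 0.5).
    """
    config = scene.config
    _, render_rng = _rngs(config)
    h, w = config.frame_shape
    maxv = config.max_value
    ramp = (
        config.illumination_gradient
        * config.cell_contrast
        * (np.arange(w, dtype=np.float64) / max(w - 1, 1))
    )
    base = config.background_level + ramp[None, :]

    frames: list[Frame] = []
    masks: list[np.ndarray] = []
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    for t in range(config.n_frames):
        img = np.broadcast_to(base, (h, w)).copy()
        mask = np.zeros((h, w), dtype=np.uint16)
        for i in range(scene.n_cells):
            res = _cell_coverage(
                (h, w),
                scene.centers[t, i],
                float(scene.radii[i]),
                config.eccentricity,
                float(scene.orientations[i]),
            )
            if res is None:
                continue
            rs, cs, cov = res
            gain = config.flash_gain if scene.flashing[t, i] else 1.0
            img[rs, cs] += config.cell_contrast * gain * cov
            sub = mask[rs, cs]  # view: slices share memory with mask
            sub[(cov >= 0.5) & (sub == 0)] = i + 1
        if config.noise_sd > 0:
            img = img + render_rng.normal(0.0, config.noise_sd, size=(h, w))
        img = np.clip(np.rint(img), 0, maxv).astype(dtype)
        frames.append(Frame(img, config.bit_depth, t, "phase1"))
        masks.append(mask)
    truth = {"table": scene.truth_table(), "masks": masks}
    return TimeLapse(frames), truth
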