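import numpy as np
import pytest

from ttrack import Frame, SceneConfig, generate_scene, render_timelapse


def make_frame(pixels, bit_depth=16, time_index=0, phase="phase1"):
    return Frame(np.asarray(pixels), bit_depth, time_index, phase)


def disk_frame(shape, disks, background=1000, bit_depth=16):
    """A frame with hard-edged bright disks: disks = [(row, col, radius, level)]."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=np.float64)
    for r, c, rad, level in disks:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = level
    return make_frame(img.astype(np.uint16), bit_depth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered scene shared by I/O and pipeline tests."""
    cfg = SceneConfig(frame_shape=(128, 128), n_frames=4, n_cells=3, seed=7)
    scene = generate_scene(cfg)
    timelapse, truth = render_timelapse(scene)
    return scene, timelapse, truth
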