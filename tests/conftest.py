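import numpy as np
import pytest

from fluoroi.image_io import ImageStack
from fluoroi.roi_detect import ROIMask
from fluoroi.synthgen import ResponseSpec, SceneSpec, make_blob_image, make_movie


@pytest.fixture(scope="session")
def blob_scene():
    """Standard 20-blob detection scene: 10x brightness over a gradient."""
    return make_blob_image(SceneSpec(seed=0))


@pytest.fixture(scope="session")
def silent_movie():
    """Small movie of static blobs with planted integer jitter."""
    scene = SceneSpec(
        shape=(64, 64), n_blobs=5, noise_sd=0.1, min_separation=10, margin=6, seed=3
    )
    responses = ResponseSpec(classes=["silent"] * 5, stim_window=(10, 20), seed=3)
    return make_movie(scene, responses, n_frames=50, jitter_px=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    return ImageStack(
        data=rng.uniform(0, 100, size=(8, 16, 16)),
        pixel_size_xy=0.5,
        frame_interval=0.2,
    )


@pytest.fixture
def two_roi_mask():
    """16x16 mask with a 3x3 ROI at top-left and a 2x2 ROI lower right."""
    labels = np.ones((16, 16), dtype=np.int32)
    labels[1:4, 1:4] = -1
    labels[10:12, 10:12] = -2
    return ROIMask(labels)
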