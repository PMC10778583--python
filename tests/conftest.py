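import numpy as np
import pytest

from mitomotion import Calibration, PipelineConfig, SceneConfig


@pytest.fixture
def calibration() -> Calibration:
    return Calibration(pixel_size=0.2, frame_interval=4.0)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_scene() -> SceneConfig:
    """A quick-to-render scene for pipeline-level tests."""
    return SceneConfig(
        seed=7, field_px=256, n_frames=13, n_mitochondria=25, name="small"
    )


def gaussian_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: float,
    amplitude: float = 100.0,
    background: float = 0.0,
) -> np.ndarray:
    """Isotropic Gaussian test image; center is (x, y) in pixels."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = center
    return background + amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )
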