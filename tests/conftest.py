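import numpy as np
import pytest

from camura.geometry import SystemGeometry
from camura.mask import generate_mura, mosaic_of
from camura.study import RunConfig


@pytest.fixture(scope="session")
def paper_geometry() -> SystemGeometry:
    """Full-scale reference geometry (1 mm holes, 664 mm detector)."""
    return SystemGeometry()


@pytest.fixture(scope="session")
def desk_geometry() -> SystemGeometry:
    """Reduced-scale geometry used by the study defaults."""
    return RunConfig().system_geometry()


@pytest.fixture(scope="session")
def mosaic5():
    return mosaic_of(generate_mura(5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config() -> RunConfig:
    """A seconds-scale study configuration for pipeline bookkeeping tests."""
    cfg = RunConfig()
    cfg.mask.rank = 7
    cfg.mask.hole_size = 9.0
    cfg.geometry.detector_pitch = 8.0
    cfg.phantom.voxel_size = 1.0
    cfg.phantom.duct_depth = 2
    cfg.projector.detected_counts = 1.0e5
    cfg.recon.iterations = 3
    cfg.recon.estimate_extent_mm = 640.0
    cfg.seed = 11
    return cfg
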