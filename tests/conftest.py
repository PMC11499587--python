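import numpy as np
import pytest

from plotpheno.simulate import SyntheticFieldConfig, generate_field


def coarse_config(**overrides) -> SyntheticFieldConfig:
    """Field-1 proportions at a coarse GSD so rasters stay desk-sized."""
    base = dict(
        rows=3,
        cols=3,
        gsd_mm_per_px=10.0,
        panicle_density_per_m2=0.0,
        seed=0,
    )
    base.update(overrides)
    return SyntheticFieldConfig(**base)


@pytest.fixture(scope="session")
def small_field():
    """A 3x3 unrotated, jitter-free field shared by read-only tests."""
    cfg = coarse_config(seed=1)
    mosaic, truth = generate_field(cfg)
    return cfg, mosaic, truth


@pytest.fixture(scope="session")
def rotated_field():
    """A 4x4 field at 5 degrees with mild placement jitter."""
    cfg = coarse_config(rows=4, cols=4, rotation_deg=5.0, center_jitter_frac=0.01, seed=2)
    mosaic, truth = generate_field(cfg)
    return cfg, mosaic, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
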