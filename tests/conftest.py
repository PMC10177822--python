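import numpy as np
import pytest

from ctiq import phantom, profiles


def aligned_spec(**overrides) -> phantom.PhantomSpec:
    """Phantom geometry whose ramp kinks fall exactly on pixel centers
    (161 px at 0.25 mm -> center and kinks on the grid), so bilinear
    sampling reproduces the analytic template exactly on axis-aligned edges."""
    kw = dict(width_mm=40.25, height_mm=40.25, pixel_spacing_mm=0.25,
              hu_high=50.0, hu_low=-100.0, edge_slope_hu_per_mm=-150.0,
              edge_angle_deg=90.0, noise_sd_hu=0.0, seed=0)
    kw.update(overrides)
    return phantom.PhantomSpec(**kw)


def centered_border(spec: phantom.PhantomSpec, length_mm: float = 9.0,
                    **kw) -> profiles.BorderSpec:
    p0, p1 = phantom.default_border_points(spec, length_mm)
    return profiles.BorderSpec(p0, p1, **kw)


@pytest.fixture
def noiseless_phantom():
    spec = aligned_spec()
    image, truth = phantom.generate_edge_phantom(spec)
    return spec, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20230424)
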