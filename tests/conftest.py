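import logging

import numpy as np
import pytest

import flimchip as fc

logging.getLogger("flimchip").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def acq():
    return fc.AcquisitionConfig()


@pytest.fixture(scope="session")
def irf(acq):
    return fc.make_irf(244.0, 1000.0, acq)


@pytest.fixture(scope="session")
def small_geometry():
    """A small chamber frame (60 x 25 px) for fast rendering tests."""
    return fc.ChamberGeometry(width_mm=6.0, height_mm=2.5, pixel_size_um=100.0,
                              distal_offset_mm=5.0)


def make_scene(density="low", condition="CTL", seed=0, **kwargs):
    return fc.generate_scene(
        fc.SceneConfig(density_label=density, condition=condition, seed=seed, **kwargs)
    )


@pytest.fixture(scope="session")
def low_ctl_scene():
    return make_scene("low", "CTL", seed=1)


@pytest.fixture(scope="session")
def low_ctl_nadph(low_ctl_scene, irf, acq):
    stack, true_intensity = fc.render_flim_stack(low_ctl_scene, "NADPH", irf, acq, seed=2)
    return stack, true_intensity
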