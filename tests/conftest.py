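"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

import sted_restore as sr


@pytest.fixture(scope="session")
def filament_phantom():
    return sr.make_phantom("filaments", (128, 128), pixel_size=20.0,
                           n_structures=10, seed=11)


@pytest.fixture(scope="session")
def optics():
    # 240 nm confocal FWHM depleted 15x over saturation -> 60 nm effective
    return sr.OpticsModel(confocal_fwhm=240.0, sted_power_fraction=15.0,
                          saturation_power_fraction=1.0)


@pytest.fixture(scope="session")
def noiseless_scene(filament_phantom, optics):
    return sr.blur(sr.render_phantom(filament_phantom), optics,
                   filament_phantom.pixel_size)


@pytest.fixture(scope="session")
def training_pair(filament_phantom, optics):
    return sr.simulate_pair(filament_phantom, optics, seed=5)


@pytest.fixture(scope="session")
def tiny_config():
    return sr.NetworkConfig(dims=2, unet_base_filters=8, unet_depth=2,
                            rcan_filters=8, n_residual_groups=1,
                            n_cab_per_group=2, seed=3)


@pytest.fixture(scope="session")
def bead_image(optics):
    """Bright 20 nm-bead-like field imaged at the 60 nm effective FWHM."""
    phantom = sr.make_phantom("puncta", (512, 512), pixel_size=20.0,
                              n_structures=250, seed=4)
    scene = sr.blur(sr.render_phantom(phantom), optics, 20.0)
    acq = sr.AcquisitionModel(dwell_time=2.3, brightness=800.0,
                              background=0.1, seed=1)
    return sr.acquire(scene, acq)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
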