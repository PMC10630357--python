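"""Shared fixtures: a small optical configuration and a noiseless
microchannel hologram pair, reconstructed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import sixpackholo as sp
from sixpackholo.simulate import fov_shift

GRID = (256, 256)
FOV_SHIFT = 64


@pytest.fixture(scope="session")
def config() -> sp.OpticsConfig:
    return sp.OpticsConfig(grid_shape=GRID)


@pytest.fixture(scope="session")
def carriers(config) -> sp.CarrierSet:
    return sp.default_carrier_set(config)


@pytest.fixture(scope="session")
def channel_phantom(config) -> sp.PhantomOPD:
    return sp.make_channel_phantom(config)


@pytest.fixture(scope="session")
def hologram_pair(config, carriers, channel_phantom):
    """Noiseless sample/background six-pack frames of the 7 um channel."""
    noise = sp.NoiseSpec(seed=11)
    sample = sp.synthesize_hologram(
        channel_phantom, config, carriers, noise=noise, fov_shift_px=FOV_SHIFT
    )
    background = sp.synthesize_background(
        config, carriers, noise=noise, fov_shift_px=FOV_SHIFT
    )
    return sample, background


@pytest.fixture(scope="session")
def wavefronts(config, carriers, hologram_pair):
    """Reconstructed six channels, denoising bypassed (noiseless input)."""
    sample, background = hologram_pair
    return sp.reconstruct_all(sample, background, carriers, apply_wft=False)


@pytest.fixture(scope="session")
def left_stack(config, wavefronts):
    return sp.nine_map_stack(
        [wavefronts[(wl, "left")] for wl in config.wavelengths_nm]
    )


def shifted_mask(phantom: sp.PhantomOPD, name: str, fov: str) -> np.ndarray:
    """Phantom mask expressed in a given FOV's frame."""
    return np.roll(phantom.masks[name], fov_shift(fov, FOV_SHIFT), axis=1)
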