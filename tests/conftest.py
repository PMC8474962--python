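import numpy as np
import pytest

from petquant.imgcore import FrameSchedule, ImageVolume, Units, VOIMask
from petquant.phantom import AIFParams, TwoTCParams


@pytest.fixture(scope="session")
def hour_schedule() -> FrameSchedule:
    """The 1-h dynamic framing: 5x2 s, 5x10 s, 2x120 s, 3x300 s, 4x600 s."""
    return FrameSchedule.one_hour_scheme()


@pytest.fixture(scope="session")
def default_aif() -> AIFParams:
    return AIFParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_volume(values, spacing=(0.4, 0.4, 0.4), units=Units.SUV) -> ImageVolume:
    return ImageVolume(values=np.asarray(values, float), spacing=spacing, units=units)


def full_mask(vol: ImageVolume, label="search") -> VOIMask:
    return VOIMask.like(vol, np.ones(vol.shape, dtype=bool), label=label)
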