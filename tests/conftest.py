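import numpy as np
import pytest

from imaudit.records import (
    AcquisitionRecord,
    Band,
    ChannelSpec,
    DigitizationSpec,
    Modality,
    ObjectiveSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def confocal_record():
    """A fully reported 3-D confocal acquisition."""
    return AcquisitionRecord(
        modality=Modality.CONFOCAL_LASER_SCANNING,
        is_3d=True,
        is_fluorescence=True,
        instrument_model="Nikon Eclipse Ti-E",
        objective=ObjectiveSpec(magnification=100, numerical_aperture=1.45),
        digitization=DigitizationSpec(pixel_size_xy_um=0.03, z_step_um=0.1),
        channels=[
            ChannelSpec(
                excitation_nm=Band(center_nm=488),
                emission_nm=Band(center_nm=520, width_nm=35),
            )
        ],
    )
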