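"""Randomized acquisition records for property tests and fixture corpora.

Values are drawn from ranges a core-facility scientist would recognise as
realistic bench settings: dry to high-NA oil objectives, visible-range
fluorophores, camera pixel sizes of tens to hundreds of nanometres.
Numbers are rounded to few decimals so they survive text round-trips.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .records import (
    AcquisitionRecord,
    Band,
    ChannelSpec,
    DigitizationSpec,
    Immersion,
    Modality,
    ObjectiveSpec,
)

_MAGNIFICATIONS = [10, 20, 25, 40, 60, 63, 100]
_INSTRUMENTS = [
    "Nikon Eclipse Ti-E",
    "Zeiss Axio Observer 7",
    "Olympus IX83",
    "Leica DMi8",
    "Nikon Eclipse Ti2",
]
_CAMERAS = [
    "Andor iXon EM-CCD",
    "Hamamatsu ORCA-Flash4.0",
    "Photometrics Prime 95B",
    "Andor Zyla 4.2",
    "PCO Edge 5.5",
]
_CORRECTIONS = ["Plan Apochromat", "Plan Fluor", "Apochromat", "Plan Neofluar"]
_SOFTWARE = ["NIS Elements", "MetaMorph", "ZEN", "Fiji", "Micro-Manager"]
_FLUOROPHORES = ["GFP", "mCherry", "DAPI", "Alexa 488", "Alexa 568", "Cy5", "YFP"]
# silicone immersion is avoided: it has no faithful OME enumeration value
_IMMERSIONS = [Immersion.OIL, Immersion.WATER, Immersion.AIR, Immersion.GLYCEROL]

_FLUOR_MODALITIES = [
    Modality.WIDEFIELD_FLUORESCENCE,
    Modality.CONFOCAL_LASER_SCANNING,
    Modality.SPINNING_DISK_CONFOCAL,
    Modality.SUPERRESOLUTION,
]


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def random_channel(rng: np.random.Generator) -> ChannelSpec:
    ex = int(rng.integers(350, 650))
    width = _pick(rng, [0, 25, 35, 50])
    return ChannelSpec(
        fluorophore_name=_pick(rng, _FLUOROPHORES),
        excitation_nm=Band(center_nm=float(ex)),
        emission_nm=Band(center_nm=float(ex + int(rng.integers(20, 80))), width_nm=float(width)),
        exposure_time_s=round(float(rng.uniform(0.01, 2.0)), 3),
    )


def random_complete_record(
    rng: np.random.Generator,
    modality: Optional[Modality] = None,
    n_channels: Optional[int] = None,
    is_3d: Optional[bool] = None,
    ome_safe: bool = False,
) -> AcquisitionRecord:
    """A fluorescence record with every rubric-relevant parameter reported.

    With ``ome_safe`` the record stays inside the OME-mappable subset
    (single wavelengths, no zoom/pinhole), so write->read round-trips are
    lossless on that subset.
    """
    if modality is None:
        modality = _pick(rng, _FLUOR_MODALITIES)
    if n_channels is None:
        n_channels = int(rng.integers(1, 4))
    if is_3d is None:
        is_3d = bool(rng.integers(0, 2))
    channels = [random_channel(rng) for _ in range(n_channels)]
    if ome_safe:
        for ch in channels:
            ch.emission_nm = Band(center_nm=ch.emission_nm.center_nm)
    confocal = modality in (
        Modality.CONFOCAL_LASER_SCANNING,
        Modality.SPINNING_DISK_CONFOCAL,
    )
    dig = DigitizationSpec(
        pixel_size_xy_um=round(float(rng.uniform(0.03, 0.4)), 4),
        z_step_um=round(float(rng.uniform(0.1, 1.0)), 2) if is_3d else None,
        camera_model=None if (confocal and not ome_safe) else _pick(rng, _CAMERAS),
        scan_zoom=(round(float(rng.uniform(1, 4)), 1) if confocal and not ome_safe else None),
        pinhole_au=(round(float(rng.uniform(0.5, 2.0)), 1) if confocal and not ome_safe else None),
    )
    return AcquisitionRecord(
        modality=modality,
        is_3d=is_3d,
        is_fluorescence=True,
        instrument_model=_pick(rng, _INSTRUMENTS),
        software=_pick(rng, _SOFTWARE),
        objective=ObjectiveSpec(
            magnification=float(_pick(rng, _MAGNIFICATIONS)),
            numerical_aperture=round(float(rng.uniform(0.25, 1.45)), 2),
            immersion_medium=_pick(rng, _IMMERSIONS),
            correction_class=_pick(rng, _CORRECTIONS),
        ),
        digitization=dig,
        channels=channels,
    )


_OMITTABLE = [
    "instrument_model",
    "software",
    "objective.magnification",
    "objective.numerical_aperture",
    "objective.immersion_medium",
    "objective.correction_class",
    "digitization.pixel_size_xy_um",
    "digitization.z_step_um",
    "digitization.camera_model",
    "channels.*.excitation_nm",
    "channels.*.emission_nm",
    "channels.*.exposure_time_s",
    "channels.*.fluorophore_name",
]


def random_record(
    rng: np.random.Generator, p_missing: float = 0.4, **kwargs
) -> AcquisitionRecord:
    """A record with each reportable parameter independently unreported
    with probability *p_missing* — the incomplete methods sections the
    rubric exists to catch."""
    from .ome import apply_omissions  # local import to avoid cycle

    rec = random_complete_record(rng, **kwargs)
    omit = [f for f in _OMITTABLE if rng.random() < p_missing]
    return apply_omissions(rec, omit)
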