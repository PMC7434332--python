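"""Reporting-quality rubric for image-acquisition methods.

The rubric audits whether a described imaging experiment could be evaluated
and replicated from the stated parameters alone.  It scores presence, not
scientific adequacy, in three optical sections plus one EM section:

* **objective** — pass iff both magnification and numerical aperture of the
  objective lens are reported (together they fix optical resolution).
* **digitization** — planar sampling must be conveyed by any one of: the
  pixel size of the digital file, the total magnification together with the
  camera model (wide-field), or the frame size together with the scan zoom
  (point-scanning confocal).  For three-dimensional acquisitions the Z step
  (or voxel size) is additionally required.
* **spectral** — for fluorescence imaging, excitation and emission
  wavelengths must be given for the fluorochromes used.
* **EM** — for TEM/SEM, a configurable set of acquisition settings
  (default: accelerating voltage, magnification, spot size) must be present.

A record obtains a **global pass** when the objective section passes
together with at least one of digitization/spectral; whole-animal optical
imaging is graded on digitization (plus spectral where applicable) only;
EM records are graded on the EM section; MRI and X-ray records are outside
the rubric's domain and are ineligible.

Sampling-adequacy helpers (Rayleigh resolution, Nyquist pixel) produce
advisory annotations only and never affect any verdict.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator

from .records import (
    AcquisitionRecord,
    Band,
    EMSpec,
    EM_MODALITIES,
    EXCLUDED_MODALITIES,
    Modality,
    QualityScore,
    SectionOutcome,
)

_DEFAULT_EM_REQUIRED = frozenset(
    {"accelerating_voltage_kv", "magnification", "spot_size"}
)


class RubricConfig(BaseModel):
    """Tunable points of the rubric.

    EM reporting was historically judged case-by-case; ``em_required_fields``
    makes the automated reading explicit and adjustable.
    """

    model_config = ConfigDict(extra="forbid")

    em_required_fields: frozenset[str] = _DEFAULT_EM_REQUIRED
    require_all_channels_spectral: bool = True
    article_aggregation: Literal["all_records_pass", "any_record_passes"] = (
        "all_records_pass"
    )

    @field_validator("em_required_fields")
    @classmethod
    def _known_em_fields(cls, v: frozenset[str]) -> frozenset[str]:
        unknown = set(v) - set(EMSpec.model_fields)
        if unknown:
            raise ValueError(f"unknown EMSpec fields: {sorted(unknown)}")
        return v


DEFAULT_CONFIG = RubricConfig()


@dataclasses.dataclass(frozen=True)
class SectionScore:
    """Outcome of one rubric section with the parameters it found missing."""

    outcome: SectionOutcome
    missing: tuple[str, ...] = ()


_NO_OBJECTIVE_SECTION = EM_MODALITIES | EXCLUDED_MODALITIES | {
    Modality.WHOLE_ANIMAL_OPTICAL
}


def score_objective(record: AcquisitionRecord) -> SectionScore:
    """Pass iff both objective magnification and NA are reported."""
    if record.modality in _NO_OBJECTIVE_SECTION:
        return SectionScore(SectionOutcome.NOT_APPLICABLE)
    missing = []
    obj = record.objective
    if obj is None or obj.magnification is None:
        missing.append("objective.magnification")
    if obj is None or obj.numerical_aperture is None:
        missing.append("objective.numerical_aperture")
    if missing:
        return SectionScore(SectionOutcome.FAIL, tuple(missing))
    return SectionScore(SectionOutcome.PASS)


def score_digitization(record: AcquisitionRecord) -> SectionScore:
    """Any one planar-sampling route passes; 3-D additionally needs the Z step."""
    if record.modality in EXCLUDED_MODALITIES:
        return SectionScore(SectionOutcome.NOT_APPLICABLE)
    dig = record.digitization
    planar = dig is not None and (
        dig.pixel_size_xy_um is not None
        or (dig.total_magnification is not None and dig.camera_model is not None)
        or (dig.frame_size_px is not None and dig.scan_zoom is not None)
    )
    missing = []
    if not planar:
        missing.append(
            "digitization.pixel_size_xy_um "
            "(or total_magnification+camera_model, or frame_size_px+scan_zoom)"
        )
    if record.is_3d and (dig is None or dig.z_step_um is None):
        missing.append("z_step_um")
    if missing:
        return SectionScore(SectionOutcome.FAIL, tuple(missing))
    return SectionScore(SectionOutcome.PASS)


def _channel_complete(ch) -> bool:
    return ch.excitation_nm is not None and ch.emission_nm is not None


def score_spectral(
    record: AcquisitionRecord, config: RubricConfig = DEFAULT_CONFIG
) -> SectionScore:
    """Excitation and emission must be documented for the fluorochromes used.

    A record asserting fluorescence with zero documented channels fails:
    the technique is claimed but entirely undescribed.
    """
    if not record.is_fluorescence:
        return SectionScore(SectionOutcome.NOT_APPLICABLE)
    channels = record.channels or []
    if not channels:
        return SectionScore(
            SectionOutcome.FAIL,
            ("channels.excitation_nm", "channels.emission_nm"),
        )
    ok = (
        all(map(_channel_complete, channels))
        if config.require_all_channels_spectral
        else any(map(_channel_complete, channels))
    )
    if ok:
        return SectionScore(SectionOutcome.PASS)
    missing = []
    for i, ch in enumerate(channels):
        if ch.excitation_nm is None:
            missing.append(f"channels[{i}].excitation_nm")
        if ch.emission_nm is None:
            missing.append(f"channels[{i}].emission_nm")
    return SectionScore(SectionOutcome.FAIL, tuple(missing))


def score_em(
    record: AcquisitionRecord, config: RubricConfig = DEFAULT_CONFIG
) -> SectionScore:
    if record.modality not in EM_MODALITIES:
        return SectionScore(SectionOutcome.NOT_APPLICABLE)
    missing = tuple(
        f"em.{name}"
        for name in sorted(config.em_required_fields)
        if record.em is None or getattr(record.em, name) is None
    )
    if missing:
        return SectionScore(SectionOutcome.FAIL, missing)
    return SectionScore(SectionOutcome.PASS)


def score_record(
    record: AcquisitionRecord, config: RubricConfig = DEFAULT_CONFIG
) -> QualityScore:
    """Section verdicts plus the global pass/fail grade for one record."""
    obj = score_objective(record)
    dig = score_digitization(record)
    spec = score_spectral(record, config)
    em = score_em(record, config)
    sections = (obj, dig, spec, em)

    eligible = record.modality not in EXCLUDED_MODALITIES and any(
        s.outcome is not SectionOutcome.NOT_APPLICABLE for s in sections
    )
    if not eligible:
        global_pass = False
    elif record.modality in EM_MODALITIES:
        global_pass = em.outcome is SectionOutcome.PASS
    elif record.modality is Modality.WHOLE_ANIMAL_OPTICAL:
        global_pass = dig.outcome is SectionOutcome.PASS and spec.outcome in (
            SectionOutcome.PASS,
            SectionOutcome.NOT_APPLICABLE,
        )
    else:
        global_pass = obj.outcome is SectionOutcome.PASS and (
            dig.outcome is SectionOutcome.PASS or spec.outcome is SectionOutcome.PASS
        )

    missing: list[str] = []
    for s in sections:
        if s.outcome is SectionOutcome.FAIL:
            missing.extend(m for m in s.missing if m not in missing)
    return QualityScore(
        objective_section=obj.outcome,
        digitization_section=dig.outcome,
        spectral_section=spec.outcome,
        em_section=em.outcome,
        global_pass=global_pass,
        eligible=eligible,
        missing_items=missing,
    )


_OUTCOME_WORST_ORDER = {
    SectionOutcome.FAIL: 0,
    SectionOutcome.PASS: 1,
    SectionOutcome.NOT_APPLICABLE: 2,
}


def _worst(outcomes: list[SectionOutcome]) -> SectionOutcome:
    return min(outcomes, key=_OUTCOME_WORST_ORDER.__getitem__)


def score_article(
    records: list[AcquisitionRecord], config: RubricConfig = DEFAULT_CONFIG
) -> QualityScore:
    """Aggregate record scores into one article-level verdict.

    Articles whose imaging is exclusively MRI/X-ray are ineligible.  Under
    the default ``all_records_pass`` aggregation, one undocumented
    experiment fails the whole article even if another is fully described.
    Section outcomes are reported worst-case across records.
    """
    if not records:
        raise ValueError("score_article requires at least one record")
    if all(r.modality in EXCLUDED_MODALITIES for r in records):
        na = SectionOutcome.NOT_APPLICABLE
        return QualityScore(
            objective_section=na,
            digitization_section=na,
            spectral_section=na,
            em_section=na,
            global_pass=False,
            eligible=False,
        )
    scores = [
        score_record(r, config)
        for r in records
        if r.modality not in EXCLUDED_MODALITIES
    ]
    if config.article_aggregation == "all_records_pass":
        global_pass = all(s.global_pass for s in scores)
    else:
        global_pass = any(s.global_pass for s in scores)
    missing: list[str] = []
    for s in scores:
        missing.extend(m for m in s.missing_items if m not in missing)
    return QualityScore(
        objective_section=_worst([s.objective_section for s in scores]),
        digitization_section=_worst([s.digitization_section for s in scores]),
        spectral_section=_worst([s.spectral_section for s in scores]),
        em_section=_worst([s.em_section for s in scores]),
        global_pass=global_pass,
        eligible=True,
        missing_items=missing,
    )


# ---------------------------------------------------------------------------
# Sampling adequacy (advisory)

def _center_nm(wavelength: Union[float, Band]) -> float:
    if isinstance(wavelength, Band):
        return wavelength.center_nm
    return float(wavelength)


def lateral_resolution_um(emission_nm: Union[float, Band], na: float) -> float:
    """Rayleigh lateral resolution 0.61*lambda/NA, in micrometres."""
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    lam = _center_nm(emission_nm)
    if not 300.0 <= lam <= 900.0:
        raise ValueError("emission wavelength must lie in 300-900 nm")
    return 0.61 * lam / na / 1000.0


def nyquist_pixel_um(emission_nm: Union[float, Band], na: float) -> float:
    """Largest pixel size (um) that still samples the optics at Nyquist."""
    return lateral_resolution_um(emission_nm, na) / 2.0


def sampling_annotation(
    pixel_size_um: float, emission_nm: Union[float, Band], na: float
) -> str:
    """Advisory comparison of a reported pixel size against the Nyquist pixel.

    Never affects pass/fail: the rubric audits reporting, not optical
    correctness.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    nyq = nyquist_pixel_um(emission_nm, na)
    ratio = nyq / pixel_size_um
    if ratio >= 1.25:
        return f"finer than Nyquist (≈{round(ratio):d}×)"
    if ratio >= 0.8:
        return "approximately Nyquist-sampled"
    return f"undersampled (pixel ≈{1 / ratio:.1f}× larger than Nyquist)"


def annotate_sampling(record: AcquisitionRecord) -> Optional[str]:
    """Sampling-adequacy annotation for a record, when computable."""
    if (
        record.digitization is None
        or record.digitization.pixel_size_xy_um is None
        or record.objective is None
        or record.objective.numerical_aperture is None
    ):
        return None
    emissions = [
        ch.emission_nm for ch in record.channels if ch.emission_nm is not None
    ]
    if not emissions:
        return None
    # shortest emission wavelength bounds the finest resolvable detail
    lam = min(emissions, key=lambda b: b.center_nm)
    return sampling_annotation(
        record.digitization.pixel_size_xy_um, lam, record.objective.numerical_aperture
    )
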