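"""Domain model for microscopy acquisition reporting.

Every parameter a methods section *should* report about how an image was
acquired is represented here as an optional field: absence means "not
reported", never a sentinel value.  The reporting-quality rubric
(:mod:`imaudit.rubric`) scores presence/absence of these fields; the OME
metadata layer (:mod:`imaudit.ome`) and the free-text miner
(:mod:`imaudit.textmine`) populate them.

Validation is deliberately two-tiered: pydantic enforces only *types* at
construction, while :func:`validate_record` reports domain-rule violations
(positivity, wavelength ranges, modality consistency) as data.  An audit
tool must be able to hold an erroneous record (e.g. an NA of 2.3 transcribed
from a paper) without refusing to represent it.
"""

from __future__ import annotations

import enum
import json
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator


class Modality(str, enum.Enum):
    """Imaging technique of one acquisition.

    Sub-flavours of super-resolution (STED, SIM, localization) are not
    distinguished; they share one rubric and go under ``superresolution``
    with details in the free-text instrument/software fields.
    """

    WIDEFIELD_FLUORESCENCE = "widefield_fluorescence"
    CONFOCAL_LASER_SCANNING = "confocal_laser_scanning"
    SPINNING_DISK_CONFOCAL = "spinning_disk_confocal"
    SUPERRESOLUTION = "superresolution"
    BRIGHTFIELD = "brightfield"
    TEM = "TEM"
    SEM = "SEM"
    WHOLE_ANIMAL_OPTICAL = "whole_animal_optical"
    MRI = "MRI"
    XRAY = "xray"
    OTHER = "other"


#: Modalities whose records are never scored (outside the rubric's domain).
EXCLUDED_MODALITIES = frozenset({Modality.MRI, Modality.XRAY})

#: Electron-microscopy modalities, scored by the EM section only.
EM_MODALITIES = frozenset({Modality.TEM, Modality.SEM})

#: Optical fluorescence modalities (used for defaulting ``is_fluorescence``).
FLUORESCENCE_MODALITIES = frozenset(
    {
        Modality.WIDEFIELD_FLUORESCENCE,
        Modality.CONFOCAL_LASER_SCANNING,
        Modality.SPINNING_DISK_CONFOCAL,
        Modality.SUPERRESOLUTION,
        Modality.WHOLE_ANIMAL_OPTICAL,
    }
)


class Immersion(str, enum.Enum):
    AIR = "air"
    WATER = "water"
    OIL = "oil"
    SILICONE = "silicone"
    GLYCEROL = "glycerol"
    UNKNOWN = "unknown"


class SectionOutcome(str, enum.Enum):
    """Verdict of one rubric section."""

    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


class Band(BaseModel):
    """A wavelength or wavelength band in nm.

    Papers report both discrete laser lines ("488 nm") and filter bands
    ("520/35" = 520 nm center, 35 nm width); a single wavelength is a band
    of width 0.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    center_nm: float
    width_nm: float = 0.0

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, v: Any) -> Any:
        if isinstance(v, (int, float)):
            return {"center_nm": float(v)}
        if isinstance(v, (tuple, list)) and len(v) == 2:
            return {"center_nm": float(v[0]), "width_nm": float(v[1])}
        return v

    def __str__(self) -> str:  # "520/35 nm" or "488 nm"
        c = f"{self.center_nm:g}"
        if self.width_nm:
            return f"{c}/{self.width_nm:g} nm"
        return f"{c} nm"


class ObjectiveSpec(BaseModel):
    """Objective lens characteristics; magnification and NA drive the rubric."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    magnification: Optional[float] = None
    numerical_aperture: Optional[float] = None
    immersion_medium: Optional[Immersion] = None
    correction_class: Optional[str] = None


class ChannelSpec(BaseModel):
    """One fluorescence channel: spectral settings and exposure."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    fluorophore_name: Optional[str] = None
    excitation_nm: Optional[Band] = None
    emission_nm: Optional[Band] = None
    exposure_time_s: Optional[float] = None
    illumination_power_mw: Optional[float] = None


class DigitizationSpec(BaseModel):
    """How optical signal was sampled into a digital file.

    Planar sampling may be conveyed directly (pixel size), via total
    magnification plus camera model (wide-field), or via frame size plus
    scan zoom (point-scanning confocal); axial sampling via the Z step.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    pixel_size_xy_um: Optional[float] = None
    z_step_um: Optional[float] = None
    frame_size_px: Optional[tuple[int, int]] = None
    scan_zoom: Optional[float] = None
    camera_model: Optional[str] = None
    total_magnification: Optional[float] = None
    pinhole_au: Optional[float] = None


class EMSpec(BaseModel):
    """Electron-microscopy acquisition settings and preparation notes.

    Acquisition settings (voltage, gun bias, magnification, spot size)
    determine contrast, resolution and signal-to-noise and are scoreable;
    preparation fields are free text and reported in checklists only —
    their adequacy is expert visual judgment, never scored automatically.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    instrument_model: Optional[str] = None
    accelerating_voltage_kv: Optional[float] = None
    gun_bias: Optional[str] = None
    magnification: Optional[float] = None
    spot_size: Optional[float] = None
    prep_fixation: Optional[str] = None
    prep_dehydration: Optional[str] = None
    prep_embedding: Optional[str] = None
    prep_sectioning: Optional[str] = None


class AcquisitionRecord(BaseModel):
    """All reportable acquisition parameters for one imaging experiment."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    modality: Modality = Modality.OTHER
    is_3d: bool = False
    is_fluorescence: bool = False
    instrument_model: Optional[str] = None
    software: Optional[str] = None
    objective: Optional[ObjectiveSpec] = None
    digitization: Optional[DigitizationSpec] = None
    channels: list[ChannelSpec] = []
    em: Optional[EMSpec] = None


class QualityScore(BaseModel):
    """Per-section and global reporting-quality verdicts for one record
    or one article."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    objective_section: SectionOutcome
    digitization_section: SectionOutcome
    spectral_section: SectionOutcome
    em_section: SectionOutcome
    global_pass: bool
    eligible: bool
    missing_items: list[str] = []


class Violation(BaseModel):
    """One domain-rule violation found in a record; data, not an exception."""

    field: str
    value: Any
    rule: str


def _num(v: Any) -> Optional[float]:
    try:
        if v is None or isinstance(v, bool):
            return None
        return float(v)
    except (TypeError, ValueError):
        return None


def _positive(violations: list[Violation], field: str, value: Any) -> None:
    if value is None:
        return
    n = _num(value)
    if n is None or not n > 0:
        violations.append(Violation(field=field, value=value, rule="must be > 0"))


def _band_ok(violations: list[Violation], field: str, band: Any) -> None:
    if band is None:
        return
    center = _num(getattr(band, "center_nm", None))
    width = _num(getattr(band, "width_nm", 0.0))
    if center is None or not 300.0 <= center <= 900.0:
        violations.append(
            Violation(field=field, value=center, rule="wavelength must lie in 300-900 nm")
        )
    if width is None or width < 0:
        violations.append(
            Violation(field=f"{field}.width_nm", value=width, rule="band width must be >= 0")
        )


def validate_record(record: AcquisitionRecord) -> list[Violation]:
    """Check every domain invariant of *record*; return violations as data.

    Total: never raises, whatever the field values — auditing an erroneous
    source text must be possible.  Empty list iff the record is clean.
    """
    v: list[Violation] = []
    obj = record.objective
    if obj is not None:
        _positive(v, "objective.magnification", obj.magnification)
        na = _num(obj.numerical_aperture)
        if obj.numerical_aperture is not None and (na is None or not 0 < na <= 1.7):
            v.append(
                Violation(
                    field="objective.numerical_aperture",
                    value=obj.numerical_aperture,
                    rule="NA must lie in (0, 1.7]",
                )
            )
    for i, ch in enumerate(record.channels or []):
        _band_ok(v, f"channels[{i}].excitation_nm", ch.excitation_nm)
        _band_ok(v, f"channels[{i}].emission_nm", ch.emission_nm)
        _positive(v, f"channels[{i}].exposure_time_s", ch.exposure_time_s)
        _positive(v, f"channels[{i}].illumination_power_mw", ch.illumination_power_mw)
    dig = record.digitization
    if dig is not None:
        for name in (
            "pixel_size_xy_um",
            "z_step_um",
            "scan_zoom",
            "total_magnification",
            "pinhole_au",
        ):
            _positive(v, f"digitization.{name}", getattr(dig, name, None))
        fs = dig.frame_size_px
        if fs is not None:
            try:
                w, h = fs
            except (TypeError, ValueError):
                w = h = None
            if _num(w) is None or _num(h) is None or not (_num(w) > 0 and _num(h) > 0):
                v.append(
                    Violation(
                        field="digitization.frame_size_px",
                        value=fs,
                        rule="frame size must be a positive (width, height) pair",
                    )
                )
    if record.em is not None:
        _positive(v, "em.accelerating_voltage_kv", record.em.accelerating_voltage_kv)
    if record.is_fluorescence and record.modality in (
        EM_MODALITIES | EXCLUDED_MODALITIES
    ):
        v.append(
            Violation(
                field="is_fluorescence",
                value=record.modality,
                rule="fluorescence is incompatible with EM/MRI/X-ray modalities",
            )
        )
    if record.is_3d and record.modality in EXCLUDED_MODALITIES:
        v.append(
            Violation(
                field="is_3d",
                value=record.modality,
                rule="is_3d applies to optical or EM tomographic modalities only",
            )
        )
    return v


# ---------------------------------------------------------------------------
# JSON / CSV interchange

def record_to_json(record: AcquisitionRecord, **kwargs: Any) -> str:
    """Canonical JSON document form (units: um/nm/s/kV; absent fields null)."""
    return record.model_dump_json(**kwargs)


def record_from_json(doc: str | bytes) -> AcquisitionRecord:
    return AcquisitionRecord.model_validate_json(doc)


_FLAT_SUBMODELS = {
    "objective": ObjectiveSpec,
    "digitization": DigitizationSpec,
    "em": EMSpec,
}


def record_to_flat(record: AcquisitionRecord) -> dict[str, Any]:
    """Flatten a record into one CSV row (dotted column names; channels as
    a compact JSON column)."""
    row: dict[str, Any] = {
        "modality": record.modality.value,
        "is_3d": record.is_3d,
        "is_fluorescence": record.is_fluorescence,
        "instrument_model": record.instrument_model,
        "software": record.software,
    }
    for prefix, model in _FLAT_SUBMODELS.items():
        sub = getattr(record, prefix)
        for name in model.model_fields:
            val = getattr(sub, name) if sub is not None else None
            if name == "frame_size_px" and val is not None:
                val = f"{val[0]}x{val[1]}"
            if isinstance(val, Immersion):
                val = val.value
            row[f"{prefix}.{name}"] = val
    row["channels"] = (
        json.dumps([ch.model_dump(exclude_none=True) for ch in record.channels])
        if record.channels
        else None
    )
    return row


def record_from_flat(row: dict[str, Any]) -> AcquisitionRecord:
    def clean(v: Any) -> Any:
        return None if v is None or (isinstance(v, float) and pd.isna(v)) else v

    data: dict[str, Any] = {
        "modality": clean(row.get("modality")) or Modality.OTHER,
        "is_3d": bool(clean(row.get("is_3d")) or False),
        "is_fluorescence": bool(clean(row.get("is_fluorescence")) or False),
        "instrument_model": clean(row.get("instrument_model")),
        "software": clean(row.get("software")),
    }
    for prefix, model in _FLAT_SUBMODELS.items():
        sub: dict[str, Any] = {}
        for name in model.model_fields:
            val = clean(row.get(f"{prefix}.{name}"))
            if name == "frame_size_px" and isinstance(val, str):
                w, h = val.lower().split("x")
                val = (int(w), int(h))
            if val is not None:
                sub[name] = val
        data[prefix] = model(**sub) if sub else None
    ch = clean(row.get("channels"))
    data["channels"] = [ChannelSpec(**c) for c in json.loads(ch)] if ch else []
    return AcquisitionRecord(**data)


def records_to_csv(records: list[AcquisitionRecord], path: Any) -> None:
    pd.DataFrame([record_to_flat(r) for r in records]).to_csv(path, index=False)


def records_from_csv(path: Any) -> list[AcquisitionRecord]:
    df = pd.read_csv(path)
    return [record_from_flat(row) for row in df.to_dict(orient="records")]
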