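"""Publication-ready methods-paragraph generation from acquisition records.

The inverse of :mod:`imaudit.textmine`: given a structured
:class:`~imaudit.records.AcquisitionRecord`, render a paragraph suitable
for a materials-and-methods section.  A reporting gap is never hidden —
every required parameter that is absent appears in the output as a visible
``[NOT RECORDED: <field>]`` marker plus a warning, so generated text can
only ever *expose* incomplete metadata.

Two built-in profiles cover the two most common fluorescence experiment
types, wide-field and laser-scanning confocal; both are plain data and
can be copied and customised.  Output is deterministic: identical record
and profile yield byte-identical text.
"""

from __future__ import annotations

import dataclasses
import string
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .records import (
    AcquisitionRecord,
    Band,
    EXCLUDED_MODALITIES,
    Modality,
)

Requirement = Literal["required", "optional", "required_if_3d"]

#: placeholder name -> AcquisitionRecord field path (for gap markers)
FIELD_PATHS = {
    "instrument_model": "instrument_model",
    "software": "software",
    "magnification": "objective.magnification",
    "numerical_aperture": "objective.numerical_aperture",
    "immersion_medium": "objective.immersion_medium",
    "correction_class": "objective.correction_class",
    "pixel_size_xy_um": "digitization.pixel_size_xy_um",
    "z_step_um": "digitization.z_step_um",
    "camera_model": "digitization.camera_model",
    "scan_zoom": "digitization.scan_zoom",
    "frame_size_px": "digitization.frame_size_px",
    "pinhole_au": "digitization.pinhole_au",
    "channels": "channels",
}


class TemplateProfile(BaseModel):
    """Sentence templates plus per-placeholder requirements for one modality."""

    model_config = ConfigDict(extra="forbid")

    name: str
    modality: Modality
    accepts: list[Modality]
    sentence_templates: list[str]
    placeholder_requirements: dict[str, Requirement]
    checklist_items: list[tuple[str, str]]  # (human label, placeholder name)


WIDEFIELD_PROFILE = TemplateProfile(
    name="widefield",
    modality=Modality.WIDEFIELD_FLUORESCENCE,
    accepts=[
        Modality.WIDEFIELD_FLUORESCENCE,
        Modality.SUPERRESOLUTION,
        Modality.WHOLE_ANIMAL_OPTICAL,
        Modality.BRIGHTFIELD,
        Modality.OTHER,
    ],
    sentence_templates=[
        "Images were acquired on a {instrument_model} wide-field fluorescence "
        "microscope{software_clause}.",
        "A {magnification}x{correction_clause} objective lens "
        "(NA {numerical_aperture}{immersion_clause}) was used.",
        "Images were digitized {camera_clause}at a pixel size of "
        "{pixel_size_xy_um} µm.",
        "Z-stacks were acquired with a Z step of {z_step_um} µm.",
        "{channels}",
    ],
    placeholder_requirements={
        "instrument_model": "optional",
        "software": "optional",
        "magnification": "required",
        "correction_class": "optional",
        "numerical_aperture": "required",
        "immersion_medium": "optional",
        "camera_model": "optional",
        "pixel_size_xy_um": "required",
        "z_step_um": "required_if_3d",
        # channel completeness is handled inside the channels text itself
        "channels": "optional",
    },
    checklist_items=[
        ("Microscope model", "instrument_model"),
        ("Acquisition software", "software"),
        ("Objective magnification", "magnification"),
        ("Objective numerical aperture", "numerical_aperture"),
        ("Immersion medium", "immersion_medium"),
        ("Objective correction class", "correction_class"),
        ("Camera model", "camera_model"),
        ("Pixel size (planar sampling)", "pixel_size_xy_um"),
        ("Z step (axial sampling)", "z_step_um"),
        ("Excitation wavelengths", "excitation"),
        ("Emission wavelengths", "emission"),
        ("Exposure times", "exposure"),
    ],
)

CONFOCAL_PROFILE = TemplateProfile(
    name="confocal",
    modality=Modality.CONFOCAL_LASER_SCANNING,
    accepts=[
        Modality.CONFOCAL_LASER_SCANNING,
        Modality.SPINNING_DISK_CONFOCAL,
        Modality.SUPERRESOLUTION,
    ],
    sentence_templates=[
        "Images were acquired on a {instrument_model} laser-scanning confocal "
        "microscope{software_clause}.",
        "A {magnification}x{correction_clause} objective lens "
        "(NA {numerical_aperture}{immersion_clause}) was used.",
        "Images were acquired at a pixel size of {pixel_size_xy_um} µm"
        "{frame_clause}{zoom_clause}{pinhole_clause}.",
        "Z-stacks were acquired with a Z step of {z_step_um} µm.",
        "{channels}",
    ],
    placeholder_requirements={
        "instrument_model": "optional",
        "software": "optional",
        "magnification": "required",
        "correction_class": "optional",
        "numerical_aperture": "required",
        "immersion_medium": "optional",
        "pixel_size_xy_um": "required",
        "frame_size_px": "optional",
        "scan_zoom": "optional",
        "pinhole_au": "optional",
        "z_step_um": "required_if_3d",
        "channels": "optional",
    },
    checklist_items=[
        ("Microscope model", "instrument_model"),
        ("Acquisition software", "software"),
        ("Objective magnification", "magnification"),
        ("Objective numerical aperture", "numerical_aperture"),
        ("Immersion medium", "immersion_medium"),
        ("Objective correction class", "correction_class"),
        ("Pixel size (planar sampling)", "pixel_size_xy_um"),
        ("Z step (axial sampling)", "z_step_um"),
        ("Excitation wavelengths", "excitation"),
        ("Emission wavelengths", "emission"),
        ("Pinhole diameter", "pinhole_au"),
    ],
)

PROFILES = {"widefield": WIDEFIELD_PROFILE, "confocal": CONFOCAL_PROFILE}

_CONFOCAL_FAMILY = {
    Modality.CONFOCAL_LASER_SCANNING,
    Modality.SPINNING_DISK_CONFOCAL,
}


def profile_for(record: AcquisitionRecord) -> TemplateProfile:
    """Pick the built-in profile matching a record's modality family."""
    return CONFOCAL_PROFILE if record.modality in _CONFOCAL_FAMILY else WIDEFIELD_PROFILE


def _g(v: Optional[float]) -> Optional[str]:
    return None if v is None else f"{v:g}"


def _band_text(band: Optional[Band]) -> Optional[str]:
    if band is None:
        return None
    if band.width_nm:
        return f"{band.center_nm:g}/{band.width_nm:g} nm"
    return f"{band.center_nm:g} nm"


def _marker(placeholder: str) -> str:
    return f"[NOT RECORDED: {FIELD_PATHS.get(placeholder, placeholder)}]"


def _channels_text(record: AcquisitionRecord, warnings: list[str]) -> Optional[str]:
    if not record.channels:
        if record.is_fluorescence:
            warnings.append("channels: fluorescence record has no channel information")
            return "[NOT RECORDED: channels]"
        return None
    parts = []
    for i, ch in enumerate(record.channels):
        name = f" ({ch.fluorophore_name})" if ch.fluorophore_name else ""
        ex = _band_text(ch.excitation_nm)
        em = _band_text(ch.emission_nm)
        if ex is None:
            ex = f"[NOT RECORDED: channels[{i}].excitation_nm]"
            warnings.append(f"channels[{i}].excitation_nm: not recorded")
        if em is None:
            em = f"[NOT RECORDED: channels[{i}].emission_nm]"
            warnings.append(f"channels[{i}].emission_nm: not recorded")
        sentence = (
            f"Channel {i + 1}{name} was excited at {ex} and its emission was "
            f"collected at {em}"
        )
        if ch.exposure_time_s is not None:
            sentence += f", with an exposure time of {ch.exposure_time_s:g} s"
        parts.append(sentence + ".")
    return " ".join(parts)


def _build_context(
    record: AcquisitionRecord, warnings: list[str]
) -> dict[str, Optional[str]]:
    obj = record.objective
    dig = record.digitization
    ctx: dict[str, Optional[str]] = {
        "instrument_model": record.instrument_model,
        "software": record.software,
        "magnification": _g(obj.magnification) if obj else None,
        "numerical_aperture": (
            f"{obj.numerical_aperture:.2f}"
            if obj and obj.numerical_aperture is not None
            else None
        ),
        "immersion_medium": (
            obj.immersion_medium.value if obj and obj.immersion_medium else None
        ),
        "correction_class": obj.correction_class if obj else None,
        "pixel_size_xy_um": _g(dig.pixel_size_xy_um) if dig else None,
        "z_step_um": _g(dig.z_step_um) if dig else None,
        "camera_model": dig.camera_model if dig else None,
        "scan_zoom": _g(dig.scan_zoom) if dig else None,
        "pinhole_au": _g(dig.pinhole_au) if dig else None,
        "frame_size_px": (
            f"{dig.frame_size_px[0]} x {dig.frame_size_px[1]} pixels"
            if dig and dig.frame_size_px
            else None
        ),
        "channels": _channels_text(record, warnings),
    }
    # decoration clauses: empty when the underlying field is absent
    ctx["software_clause"] = (
        f" using {ctx['software']} software" if ctx["software"] else ""
    )
    ctx["correction_clause"] = (
        f" {ctx['correction_class']}" if ctx["correction_class"] else ""
    )
    ctx["immersion_clause"] = (
        f", {ctx['immersion_medium']} immersion" if ctx["immersion_medium"] else ""
    )
    ctx["camera_clause"] = (
        f"using a {ctx['camera_model']} camera " if ctx["camera_model"] else ""
    )
    ctx["frame_clause"] = (
        f", a frame size of {ctx['frame_size_px']}" if ctx["frame_size_px"] else ""
    )
    ctx["zoom_clause"] = f", a scan zoom of {ctx['scan_zoom']}" if ctx["scan_zoom"] else ""
    ctx["pinhole_clause"] = (
        f" and a {ctx['pinhole_au']} AU pinhole" if ctx["pinhole_au"] else ""
    )
    return ctx


_FORMATTER = string.Formatter()


def _placeholders(template: str) -> list[str]:
    return [field for _, field, _, _ in _FORMATTER.parse(template) if field]


def render_methods(
    record: AcquisitionRecord, profile: Optional[TemplateProfile] = None
) -> tuple[str, list[str]]:
    """Render a methods paragraph for *record*; returns (text, warnings).

    Raises :class:`ValueError` when the record's modality is outside the
    profile's remit.  Mentions every present field; absent required fields
    surface as ``[NOT RECORDED: ...]`` markers, one warning each.
    """
    if profile is None:
        profile = profile_for(record)
    if record.modality not in profile.accepts:
        raise ValueError(
            f"profile {profile.name!r} does not cover modality {record.modality.value!r}"
        )
    warnings: list[str] = []
    ctx = _build_context(record, warnings)
    reqs = profile.placeholder_requirements

    sentences = []
    for template in profile.sentence_templates:
        names = _placeholders(template)
        core = [n for n in names if n in reqs]

        def required(n: str) -> bool:
            r = reqs.get(n, "optional")
            return r == "required" or (r == "required_if_3d" and record.is_3d)

        any_present = any(ctx.get(n) not in (None, "") for n in names)
        any_required_missing = any(ctx.get(n) is None and required(n) for n in core)
        if not any_present and not any_required_missing:
            continue  # nothing to say in this sentence
        filled = {}
        for n in names:
            v = ctx.get(n)
            if v is None:
                if required(n):
                    v = _marker(n)
                    warnings.append(f"{FIELD_PATHS.get(n, n)}: not recorded")
                else:
                    v = ""
            filled[n] = v
        sentences.append(template.format(**filled))
    return " ".join(s for s in sentences if s), warnings


@dataclasses.dataclass(frozen=True)
class ChecklistRow:
    """One minimal-reporting checklist item and its status for a record."""

    item: str
    field: str
    status: Literal["reported", "missing", "not_applicable"]


def render_checklist(
    record: AcquisitionRecord, profile: Optional[TemplateProfile] = None
) -> list[ChecklistRow]:
    """Gap report: one row per checklist item of the profile.

    The row set depends only on the profile; statuses on the record.  For
    modalities outside the rubric (MRI, X-ray) every row is not-applicable.
    """
    if profile is None:
        profile = profile_for(record)
    excluded = record.modality in EXCLUDED_MODALITIES
    warnings: list[str] = []
    ctx = _build_context(record, warnings)
    channels = record.channels or []
    rows = []
    for label, key in profile.checklist_items:
        if excluded:
            rows.append(ChecklistRow(label, key, "not_applicable"))
            continue
        if key in ("excitation", "emission", "exposure"):
            if not record.is_fluorescence:
                status = "not_applicable"
            elif not channels:
                status = "missing"
            else:
                attr = {
                    "excitation": "excitation_nm",
                    "emission": "emission_nm",
                    "exposure": "exposure_time_s",
                }[key]
                status = (
                    "reported"
                    if all(getattr(c, attr) is not None for c in channels)
                    else "missing"
                )
            rows.append(ChecklistRow(label, f"channels.*.{key}", status))
            continue
        if key == "z_step_um" and not record.is_3d:
            rows.append(ChecklistRow(label, FIELD_PATHS[key], "not_applicable"))
            continue
        if key == "pixel_size_xy_um":
            dig = record.digitization
            planar = dig is not None and (
                dig.pixel_size_xy_um is not None
                or (dig.total_magnification is not None and dig.camera_model is not None)
                or (dig.frame_size_px is not None and dig.scan_zoom is not None)
            )
            rows.append(
                ChecklistRow(label, FIELD_PATHS[key], "reported" if planar else "missing")
            )
            continue
        status = "reported" if ctx.get(key) not in (None, "") else "missing"
        rows.append(ChecklistRow(label, FIELD_PATHS.get(key, key), status))
    return rows
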