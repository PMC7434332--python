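"""Methods-text quantification and parameter mining.

Two jobs: (1) quantify methods prose — whitespace-token word counts and
the percentage of a methods section devoted to image acquisition; (2) mine
acquisition parameters (magnification, NA, pixel size, Z step, excitation
and emission wavelengths, pinhole, camera and instrument models ...) out
of free-text methods passages so the rubric can grade text exactly as it
grades structured records.

Extraction is deterministic pattern matching — no language model — so an
audit is reproducible and every extracted value carries the span of text
it came from.  Unmatched text populates nothing.
"""

from __future__ import annotations

import re
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .records import (
    AcquisitionRecord,
    Band,
    ChannelSpec,
    DigitizationSpec,
    FLUORESCENCE_MODALITIES,
    Modality,
    ObjectiveSpec,
    QualityScore,
)
from .rubric import DEFAULT_CONFIG, RubricConfig, score_record


def count_words(text: str) -> int:
    """Number of maximal non-whitespace runs (word-processor-style count)."""
    return len(text.split())


class MethodsPassage(BaseModel):
    """A methods text with its image-acquisition spans annotated by a curator."""

    model_config = ConfigDict(extra="forbid")

    full_text: str
    imaging_spans: list[tuple[int, int]] = []
    source_id: str = ""

    @model_validator(mode="after")
    def _spans_valid(self) -> "MethodsPassage":
        prev_end = -1
        for start, end in sorted(self.imaging_spans):
            if not (0 <= start < end <= len(self.full_text)):
                raise ValueError(f"span ({start}, {end}) out of bounds")
            if start < prev_end:
                raise ValueError("imaging spans overlap")
            prev_end = end
        return self


def imaging_text_fraction(passage: MethodsPassage) -> float:
    """Percentage of words lying inside the imaging spans.

    A word straddling a span boundary counts as inside iff it starts inside.
    """
    if not passage.full_text.strip():
        raise ValueError("imaging_text_fraction requires non-empty text")
    spans = sorted(passage.imaging_spans)
    total = 0
    inside = 0
    for m in re.finditer(r"\S+", passage.full_text):
        total += 1
        if any(s <= m.start() < e for s, e in spans):
            inside += 1
    return 100.0 * inside / total


class ExtractionHit(BaseModel):
    """One recognised parameter: where it was found and what it parsed to."""

    model_config = ConfigDict(extra="forbid")

    parameter: str  # dotted field path into AcquisitionRecord
    value: Any  # unit-normalized (um, nm, s)
    span: tuple[int, int]
    pattern_id: str
    matched_text: str


# ---------------------------------------------------------------------------
# patterns

_UM = r"(?:µm|μm|um|microns?)"
_NM_IN_UM = {"nm": 1e-3}

_MAG_RE = re.compile(r"\b(\d{1,3}(?:\.\d+)?)\s?[xX×](?:O\b)?(?![A-Za-z0-9.])")
_MAG_CONTEXT = re.compile(
    r"objective|lens|magnif|immersion|microscope|camera|apochromat|fluor", re.I
)

_NA_RES = [
    ("na_prefixed", re.compile(r"\bNA\s*=?\s*(\d\.\d+)")),
    ("na_glued", re.compile(r"\bNA(\d\.\d+)")),
    ("na_spelled", re.compile(r"numerical aperture\s*(?:of\s*|[:=]\s*)?(\d\.\d+)", re.I)),
    ("na_suffixed", re.compile(r"(\d\.\d+)\s*NA\b")),
]

_PIXEL_RES = [
    ("pixel_dxdy", re.compile(rf"d[xy]\s*=\s*d[xy]\s*=\s*(\d*\.?\d+)\s*({_UM}|nm)")),
    ("pixel_size_post", re.compile(rf"(\d*\.?\d+)\s*({_UM}|nm)\s*pixel size", re.I)),
    ("pixel_size_pre", re.compile(rf"pixel size of\s*(\d*\.?\d+)\s*({_UM}|nm)", re.I)),
    ("pixel_size_near", re.compile(rf"pixel size[^.\d]{{0,15}}(\d*\.?\d+)\s*({_UM}|nm)", re.I)),
]

_Z_RES = [
    ("z_dz", re.compile(rf"dz\s*=\s*(\d*\.?\d+)\s*({_UM}|nm)")),
    ("z_step_of", re.compile(rf"[zZ][\- ]?step of\s*(\d*\.?\d+)\s*({_UM}|nm)")),
    ("z_intervals", re.compile(rf"(\d*\.?\d+)\s*({_UM}|nm)\s*(?:intervals|steps)", re.I)),
]

_EX_RES = [
    ("ex_verb", re.compile(r"excited\s+(?:by|at|with|using)[^.]{0,40}?(\d{3})\s*nm", re.I)),
    ("ex_source", re.compile(r"(\d{3})\s*nm\s+(?:laser|diode|LED|excitation)", re.I)),
    ("ex_spelled", re.compile(r"excitation(?:\s+wavelength)?(?:\s+of)?\s*[:=]?\s*(\d{3})\s*nm", re.I)),
]

_EM_RES = [
    ("em_band", re.compile(r"\b(\d{3})/(\d{1,3})\b")),
    ("em_collected", re.compile(r"collected at\s*(\d{3})(?:/(\d{1,3}))?\s*nm", re.I)),
    ("em_spelled", re.compile(r"emission[^.]{0,40}?(\d{3})(?:/(\d{1,3}))?\s*nm", re.I)),
]

_PINHOLE_RES = [
    ("pinhole_au", re.compile(r"(\d*\.?\d+)\s*AU\s+pinhole", re.I)),
    ("pinhole_near", re.compile(r"pinhole[^.]{0,25}?(\d*\.?\d+)\s*(?:AU|airy units?)", re.I)),
]

_EXPOSURE_RE = re.compile(
    r"exposure(?:\s+times?)?(?:\s+of)?\s*[:=]?\s*(\d*\.?\d+)\s*(ms|s|milliseconds?|seconds?)\b",
    re.I,
)
_ZOOM_RE = re.compile(r"(?:laser |scan )?zoom\s*(?:of\s*|[:=]\s*)?(\d*\.?\d+)", re.I)
_FRAME_RE = re.compile(r"(\d{3,4})\s*[x×]\s*(\d{3,4})\s*pixels?", re.I)

_CAMERA_VENDORS = (
    "Andor|Hamamatsu|Photometrics|PCO|QImaging|Teledyne|Zeiss|Leica|Nikon|Olympus|Yokogawa"
)
_CAMERA_RES = [
    # model tokens may embed decimals ("Xyla 4.2") but never sentence stops
    ("camera_vendor", re.compile(
        rf"\b({_CAMERA_VENDORS})\s+((?:[A-Za-z0-9][\w\-]*(?:\.\d+)?\s+){{1,4}}?)camera\b"
    )),
    ("camera_paren", re.compile(rf"camera\s*\(([A-Z][\w\-]+);\s*({_CAMERA_VENDORS})")),
]

_INSTRUMENT_RES = [
    ("scope_prefix", re.compile(r"((?:[A-Z][\w\-]*\s+){1,3})(?:inverted |upright |confocal )*microscope\b")),
    ("scope_paren", re.compile(rf"microscope\s*\(([\w\-]+);\s*({_CAMERA_VENDORS})")),
]

_SOFTWARE_RE = re.compile(
    r"\b(NIS[ \-]?Elements|MetaMorph|ZEN(?: Blue| Black)?|Fiji|ImageJ|LAS[ \-]?X|"
    r"SlideBook|Micro[ \-]?Manager|cellSens|Imaris)\b"
)
_FLUOROPHORE_RE = re.compile(
    r"\b(e?GFP|m?Cherry|DAPI|FITC|TRITC|Cy[2357](?:\.5)?|Alexa(?: Fluor)?\s?\d{3}|"
    r"RFP|YFP|CFP|Hoechst\s?\d*|tdTomato)\b"
)
_IMMERSION_RE = re.compile(r"\b(oil|water|air|silicone|glycerol)([\- ])immersion", re.I)
_CORRECTION_RE = re.compile(
    r"\b(Plan[ \-]?Apochromat|Plan[ \-]?Apo\b|Plan[ \-]?Fluor|Plan[ \-]?Neofluar|"
    r"Apochromat|Achromat|Fluotar|UPLSAPO\w*)"
)
_FLUOR_HINT_RE = re.compile(
    r"fluorescen|confocal|laser|immunostain|immunofluorescen|GFP|DAPI|Alexa", re.I
)
_3D_HINT_RE = re.compile(r"[zZ][\- ]?\s?(?:stacks?|series|step)|optical sections?|volumes?\b")

_UNIT_FACTORS_UM = {"nm": 1e-3}
_TIME_FACTORS = {"ms": 1e-3, "millisecond": 1e-3, "milliseconds": 1e-3}


def _hit(parameter: str, value: Any, m: re.Match, pattern_id: str) -> ExtractionHit:
    return ExtractionHit(
        parameter=parameter,
        value=value,
        span=m.span(),
        pattern_id=pattern_id,
        matched_text=m.group(0),
    )


def _scan_length(text: str, patterns, parameter: str) -> list[ExtractionHit]:
    """Scan length-valued patterns (value group 1, unit group 2), in um."""
    hits = []
    for pid, rx in patterns:
        for m in rx.finditer(text):
            unit = (m.group(2) or "µm").lower()
            factor = _UNIT_FACTORS_UM.get(unit, 1.0)
            hits.append(_hit(parameter, round(float(m.group(1)) * factor, 6), m, pid))
    return hits


def _dedupe(hits: list[ExtractionHit]) -> list[ExtractionHit]:
    """Keep one hit per parameter mention: same-parameter hits with
    overlapping spans describe the same token run, so only the first
    (longest at its position) survives."""
    hits = sorted(hits, key=lambda h: (h.span[0], -(h.span[1] - h.span[0])))
    kept: list[ExtractionHit] = []
    for h in hits:
        overlaps = any(
            k.parameter == h.parameter
            and k.span[0] < h.span[1]
            and h.span[0] < k.span[1]
            for k in kept
        )
        if not overlaps:
            kept.append(h)
    return kept


def extract_parameters(
    text: str, modality_hint: Optional[Modality] = None
) -> tuple[AcquisitionRecord, list[ExtractionHit]]:
    """Mine acquisition parameters out of *text*.

    Returns a draft :class:`AcquisitionRecord` plus one
    :class:`ExtractionHit` per recognised parameter.  Numbers adjacent to
    "x/X" count as magnifications only when <= 400 with objective-context
    vocabulary nearby, so "2X integration" or "4X binning" never become
    lens magnifications.
    """
    hits: list[ExtractionHit] = []

    # --- objective ---------------------------------------------------------
    for m in _MAG_RE.finditer(text):
        value = float(m.group(1))
        window = text[max(0, m.start() - 80) : m.end() + 80]
        if 1 < value <= 400 and value == int(value) and _MAG_CONTEXT.search(window):
            hits.append(_hit("objective.magnification", value, m, "magnification_x"))
    for pid, rx in _NA_RES:
        for m in rx.finditer(text):
            hits.append(_hit("objective.numerical_aperture", float(m.group(1)), m, pid))
    m = _IMMERSION_RE.search(text)
    if m:
        hits.append(_hit("objective.immersion_medium", m.group(1).lower(), m, "immersion"))
    m = _CORRECTION_RE.search(text)
    if m:
        hits.append(_hit("objective.correction_class", m.group(1), m, "correction"))

    # --- digitization ------------------------------------------------------
    hits += _scan_length(text, _PIXEL_RES, "digitization.pixel_size_xy_um")
    hits += _scan_length(text, _Z_RES, "digitization.z_step_um")
    for pid, rx in _PINHOLE_RES:
        for m in rx.finditer(text):
            hits.append(_hit("digitization.pinhole_au", float(m.group(1)), m, pid))
    for m in _ZOOM_RE.finditer(text):
        hits.append(_hit("digitization.scan_zoom", float(m.group(1)), m, "scan_zoom"))
    for m in _FRAME_RE.finditer(text):
        hits.append(
            _hit(
                "digitization.frame_size_px",
                (int(m.group(1)), int(m.group(2))),
                m,
                "frame_size",
            )
        )
    for pid, rx in _CAMERA_RES:
        for m in rx.finditer(text):
            if pid == "camera_vendor":
                model = _trim_model_tokens(m.group(2))
                value = f"{m.group(1)} {model}".strip() if model else m.group(1)
            else:
                value = f"{m.group(2)} {m.group(1)}"
            hits.append(_hit("digitization.camera_model", value, m, pid))

    # --- spectral ----------------------------------------------------------
    for pid, rx in _EX_RES:
        for m in rx.finditer(text):
            hits.append(
                _hit("channels.excitation_nm", (float(m.group(1)), 0.0), m, pid)
            )
    for pid, rx in _EM_RES:
        for m in rx.finditer(text):
            center = float(m.group(1))
            width = float(m.group(2)) if m.lastindex and m.lastindex >= 2 and m.group(2) else 0.0
            if not 300 <= center <= 900:
                continue
            hits.append(_hit("channels.emission_nm", (center, width), m, pid))
    for m in _EXPOSURE_RE.finditer(text):
        unit = m.group(2).lower()
        factor = _TIME_FACTORS.get(unit, 1.0)
        hits.append(
            _hit("channels.exposure_time_s", round(float(m.group(1)) * factor, 6), m, "exposure")
        )
    for m in _FLUOROPHORE_RE.finditer(text):
        hits.append(_hit("channels.fluorophore_name", m.group(1), m, "fluorophore"))

    # --- instrument & software --------------------------------------------
    for pid, rx in _INSTRUMENT_RES:
        m = rx.search(text)
        if m:
            if pid == "scope_prefix":
                value = m.group(1).strip()
                if value.lower() in {"the", "a", "an"} or len(value) < 3:
                    continue
            else:
                value = f"{m.group(2)} {m.group(1)}"
            hits.append(_hit("instrument_model", value, m, pid))
            break
    m = _SOFTWARE_RE.search(text)
    if m:
        hits.append(_hit("software", m.group(1), m, "software"))

    hits = _dedupe(hits)
    record = _assemble(text, hits, modality_hint)
    return record, hits


def _trim_model_tokens(raw: str) -> str:
    """Keep model-like tokens (containing uppercase/digits); stop at the
    first plain-lowercase word ('scientific', 'digital', ...)."""
    kept = []
    for tok in raw.split():
        if tok.islower():
            break
        kept.append(tok)
    return " ".join(kept)


def _first(hits: list[ExtractionHit], parameter: str) -> Optional[ExtractionHit]:
    for h in hits:
        if h.parameter == parameter:
            return h
    return None


def _all(hits: list[ExtractionHit], parameter: str) -> list[ExtractionHit]:
    return [h for h in hits if h.parameter == parameter]


def _assemble(
    text: str, hits: list[ExtractionHit], modality_hint: Optional[Modality]
) -> AcquisitionRecord:
    mag = _first(hits, "objective.magnification")
    na = _first(hits, "objective.numerical_aperture")
    imm = _first(hits, "objective.immersion_medium")
    corr = _first(hits, "objective.correction_class")
    objective = None
    if any(h is not None for h in (mag, na, imm, corr)):
        objective = ObjectiveSpec(
            magnification=mag.value if mag else None,
            numerical_aperture=na.value if na else None,
            immersion_medium=imm.value if imm else None,
            correction_class=corr.value if corr else None,
        )

    pixel = _first(hits, "digitization.pixel_size_xy_um")
    z = _first(hits, "digitization.z_step_um")
    pinhole = _first(hits, "digitization.pinhole_au")
    zoom = _first(hits, "digitization.scan_zoom")
    frame = _first(hits, "digitization.frame_size_px")
    camera = _first(hits, "digitization.camera_model")
    digitization = None
    if any(h is not None for h in (pixel, z, pinhole, zoom, frame, camera, mag)):
        digitization = DigitizationSpec(
            pixel_size_xy_um=pixel.value if pixel else None,
            z_step_um=z.value if z else None,
            pinhole_au=pinhole.value if pinhole else None,
            scan_zoom=zoom.value if zoom else None,
            frame_size_px=frame.value if frame else None,
            camera_model=camera.value if camera else None,
            # a stated objective magnification is taken at face value as the
            # total magnification unless a separate total is reported
            total_magnification=mag.value if mag else None,
        )

    exs = _all(hits, "channels.excitation_nm")
    ems = _all(hits, "channels.emission_nm")
    exps = _all(hits, "channels.exposure_time_s")
    names = _all(hits, "channels.fluorophore_name")
    seen: set[str] = set()
    names = [h for h in names if not (h.value in seen or seen.add(h.value))]
    n_channels = max(len(exs), len(ems))
    channels = []
    for i in range(n_channels):
        channels.append(
            ChannelSpec(
                fluorophore_name=names[i].value if i < len(names) else None,
                excitation_nm=Band(center_nm=exs[i].value[0]) if i < len(exs) else None,
                emission_nm=(
                    Band(center_nm=ems[i].value[0], width_nm=ems[i].value[1])
                    if i < len(ems)
                    else None
                ),
                exposure_time_s=(
                    exps[i].value if i < len(exps) else (exps[0].value if exps else None)
                ),
            )
        )

    is_fluorescence = (
        (modality_hint in FLUORESCENCE_MODALITIES)
        or bool(channels)
        or bool(_FLUOR_HINT_RE.search(text))
    )
    is_3d = z is not None or bool(_3D_HINT_RE.search(text))
    if modality_hint is not None:
        modality = modality_hint
    elif re.search(r"confocal", text, re.I):
        modality = Modality.CONFOCAL_LASER_SCANNING
    elif is_fluorescence:
        modality = Modality.WIDEFIELD_FLUORESCENCE
    else:
        modality = Modality.OTHER

    instrument = _first(hits, "instrument_model")
    software = _first(hits, "software")
    return AcquisitionRecord(
        modality=modality,
        is_3d=is_3d,
        is_fluorescence=is_fluorescence,
        instrument_model=instrument.value if instrument else None,
        software=software.value if software else None,
        objective=objective,
        digitization=digitization,
        channels=channels,
    )


class TextAudit(BaseModel):
    """A rubric verdict on free text, carrying the evidence behind it."""

    model_config = ConfigDict(extra="forbid")

    score: QualityScore
    record: AcquisitionRecord
    hits: list[ExtractionHit]


def audit_text(
    text: str,
    modality_hint: Optional[Modality] = None,
    config: RubricConfig = DEFAULT_CONFIG,
) -> TextAudit:
    """Mine *text* for acquisition parameters and grade the draft record."""
    record, hits = extract_parameters(text, modality_hint)
    return TextAudit(score=score_record(record, config), record=record, hits=hits)
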