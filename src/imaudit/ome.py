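"""OME-XML / OME-TIFF metadata extraction and synthetic fixture writing.

Reads acquisition metadata from standalone OME-XML documents or from TIFFs
whose ImageDescription tag holds OME-XML, mapping the OME 2016-06 data
model onto :class:`~imaudit.records.AcquisitionRecord`.  Extraction never
invents values: a populated output field always corresponds to an element
or attribute of the input document, and absent elements yield absent
fields, never defaults.

The writer produces synthetic metadata documents with *controlled
completeness* — any schema field can be omitted on request — plus a JSON
manifest recording the per-file ground truth, forming a test bed for the
extractor and for the downstream rubric.

Only the OME model is targeted; proprietary vendor dialects (ND2, CZI,
LIF) are out of scope.
"""

from __future__ import annotations

import copy
import json
import os
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
from lxml import etree
from pydantic import BaseModel, ConfigDict, field_validator
import tifffile

from .records import (
    AcquisitionRecord,
    Band,
    ChannelSpec,
    DigitizationSpec,
    EMSpec,
    Immersion,
    ObjectiveSpec,
)

OME_NS = "http://www.openmicroscopy.org/Schemas/OME/2016-06"

#: Field paths of :class:`AcquisitionRecord` representable in the OME slice
#: this module reads and writes.  Fields outside this subset (frame size,
#: scan zoom, pinhole, total magnification, EM settings, band widths) have
#: no faithful OME counterpart here and are carried only by manifests.
OME_MAPPED_FIELDS = (
    "instrument_model",
    "objective.magnification",
    "objective.numerical_aperture",
    "objective.immersion_medium",
    "objective.correction_class",
    "digitization.pixel_size_xy_um",
    "digitization.z_step_um",
    "digitization.camera_model",
    "channels.fluorophore_name",
    "channels.excitation_nm",
    "channels.emission_nm",
    "channels.exposure_time_s",
)


class OMEParseError(ValueError):
    """Raised for malformed XML (message carries line/column offsets)."""


class UnsupportedFormatError(ValueError):
    """Raised when a document is valid XML but not in the OME namespace."""


# ---------------------------------------------------------------------------
# unit handling

_LENGTH_TO_UM = {
    "m": 1e6,
    "mm": 1e3,
    "µm": 1.0,
    "um": 1.0,
    "nm": 1e-3,
    "Å": 1e-4,
    "pm": 1e-6,
}
_LENGTH_TO_NM = {k: v * 1e3 for k, v in _LENGTH_TO_UM.items()}
_TIME_TO_S = {"s": 1.0, "ms": 1e-3, "µs": 1e-6, "us": 1e-6, "min": 60.0}

_IMMERSION_TO_OME = {
    Immersion.AIR: "Air",
    Immersion.WATER: "Water",
    Immersion.OIL: "Oil",
    Immersion.GLYCEROL: "Glycerol",
    Immersion.SILICONE: "Other",
    Immersion.UNKNOWN: "Other",
}
_IMMERSION_FROM_OME = {
    "Air": Immersion.AIR,
    "Water": Immersion.WATER,
    "WaterDipping": Immersion.WATER,
    "Oil": Immersion.OIL,
    "Glycerol": Immersion.GLYCEROL,
    "Multi": Immersion.UNKNOWN,
    "Other": Immersion.UNKNOWN,
}


def _attr_float(el: Optional[etree._Element], name: str) -> Optional[float]:
    if el is None:
        return None
    raw = el.get(name)
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _attr_quantity(
    el: Optional[etree._Element], name: str, factors: dict[str, float], default_unit: str
) -> Optional[float]:
    value = _attr_float(el, name)
    if value is None:
        return None
    unit = el.get(f"{name}Unit", default_unit)
    return value * factors.get(unit, factors[default_unit])


# ---------------------------------------------------------------------------
# reading

def _q(tag: str) -> str:
    return f"{{{OME_NS}}}{tag}"


def _parse_document(document: Union[str, bytes, os.PathLike]) -> etree._Element:
    data: bytes
    if isinstance(document, (str, os.PathLike)) and not (
        isinstance(document, str) and document.lstrip().startswith("<")
    ):
        path = Path(document)
        if path.suffix.lower() in {".tif", ".tiff"}:
            with tifffile.TiffFile(path) as tif:
                desc = tif.pages[0].description
            if not desc:
                raise UnsupportedFormatError(
                    f"{path}: TIFF ImageDescription holds no OME-XML"
                )
            data = desc.encode("utf-8")
        else:
            data = path.read_bytes()
    else:
        data = document.encode("utf-8") if isinstance(document, str) else bytes(document)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        raise OMEParseError(
            f"malformed XML at line {line}, column {col} (byte offset ~{col}): {exc.msg}"
        ) from exc
    if "openmicroscopy.org/Schemas/OME" not in (etree.QName(root).namespace or ""):
        raise UnsupportedFormatError(
            f"root element {root.tag!r} is not in the OME namespace"
        )
    return root


def read_metadata(document: Union[str, bytes, os.PathLike]) -> list[AcquisitionRecord]:
    """Extract one :class:`AcquisitionRecord` per OME ``Image`` element.

    *document* may be OME-XML text/bytes, a path to a standalone ``.ome.xml``
    file, or a path to a TIFF whose ImageDescription holds OME-XML.

    Multi-image documents produce one record per Image with no merging;
    ``is_fluorescence`` is set iff any channel carries excitation or
    emission information (OME does not encode modality reliably, so
    modality itself is left for the caller).
    """
    root = _parse_document(document)

    instruments: dict[str, etree._Element] = {
        inst.get("ID", ""): inst for inst in root.iter(_q("Instrument"))
    }
    records = []
    for image in root.iter(_q("Image")):
        inst = None
        ref = image.find(_q("InstrumentRef"))
        if ref is not None and ref.get("ID") in instruments:
            inst = instruments[ref.get("ID")]
        elif len(instruments) == 1:
            inst = next(iter(instruments.values()))
        records.append(_image_to_record(image, inst))
    return records


def _image_to_record(
    image: etree._Element, inst: Optional[etree._Element]
) -> AcquisitionRecord:
    instrument_model = None
    camera_model = None
    objective = None
    if inst is not None:
        micro = inst.find(_q("Microscope"))
        if micro is not None:
            instrument_model = micro.get("Model")
        det = inst.find(_q("Detector"))
        if det is not None:
            camera_model = det.get("Model")
        obj_el = None
        settings = image.find(_q("ObjectiveSettings"))
        for cand in inst.iter(_q("Objective")):
            if settings is None or cand.get("ID") == settings.get("ID"):
                obj_el = cand
                break
        if obj_el is not None:
            imm = obj_el.get("Immersion")
            objective = ObjectiveSpec(
                magnification=_attr_float(obj_el, "NominalMagnification"),
                numerical_aperture=_attr_float(obj_el, "LensNA"),
                immersion_medium=_IMMERSION_FROM_OME.get(imm) if imm else None,
                correction_class=obj_el.get("Correction"),
            )
            if all(v is None for v in objective.model_dump().values()):
                objective = None

    pixels = image.find(_q("Pixels"))
    digitization = None
    channels: list[ChannelSpec] = []
    is_3d = False
    if pixels is not None:
        px = _attr_quantity(pixels, "PhysicalSizeX", _LENGTH_TO_UM, "µm")
        pz = _attr_quantity(pixels, "PhysicalSizeZ", _LENGTH_TO_UM, "µm")
        size_z = _attr_float(pixels, "SizeZ")
        is_3d = bool(size_z and size_z > 1)
        if px is not None or pz is not None or camera_model is not None:
            digitization = DigitizationSpec(
                pixel_size_xy_um=px, z_step_um=pz, camera_model=camera_model
            )
        exposures = _exposures_by_channel(pixels)
        for idx, ch in enumerate(pixels.iter(_q("Channel"))):
            ex = _attr_quantity(ch, "ExcitationWavelength", _LENGTH_TO_NM, "nm")
            em = _attr_quantity(ch, "EmissionWavelength", _LENGTH_TO_NM, "nm")
            # an all-absent channel is still appended: count stays faithful
            channels.append(
                ChannelSpec(
                    fluorophore_name=ch.get("Name"),
                    excitation_nm=Band(center_nm=ex) if ex is not None else None,
                    emission_nm=Band(center_nm=em) if em is not None else None,
                    exposure_time_s=exposures.get(idx),
                )
            )
    elif camera_model is not None:
        digitization = DigitizationSpec(camera_model=camera_model)

    return AcquisitionRecord(
        is_3d=is_3d,
        is_fluorescence=any(
            c.excitation_nm is not None or c.emission_nm is not None for c in channels
        ),
        instrument_model=instrument_model,
        objective=objective,
        digitization=digitization,
        channels=channels,
    )


def _exposures_by_channel(pixels: etree._Element) -> dict[int, float]:
    out: dict[int, float] = {}
    for plane in pixels.iter(_q("Plane")):
        exp = _attr_quantity(plane, "ExposureTime", _TIME_TO_S, "s")
        the_c = plane.get("TheC")
        if exp is not None and the_c is not None and int(the_c) not in out:
            out[int(the_c)] = exp
    return out


# ---------------------------------------------------------------------------
# writing

def record_to_ome_xml(record: AcquisitionRecord) -> str:
    """Serialize the OME-mappable slice of *record* as an OME-XML document."""
    nsmap = {None: OME_NS}
    root = etree.Element(_q("OME"), nsmap=nsmap)
    root.set("Creator", "imaudit")

    dig = record.digitization
    obj = record.objective
    has_instrument = (
        record.instrument_model is not None
        or obj is not None
        or (dig is not None and dig.camera_model is not None)
    )
    if has_instrument:
        inst = etree.SubElement(root, _q("Instrument"), ID="Instrument:0")
        if record.instrument_model is not None:
            etree.SubElement(inst, _q("Microscope"), Model=record.instrument_model)
        if dig is not None and dig.camera_model is not None:
            etree.SubElement(
                inst, _q("Detector"), ID="Detector:0", Model=dig.camera_model
            )
        if obj is not None:
            attrs = {"ID": "Objective:0"}
            if obj.magnification is not None:
                attrs["NominalMagnification"] = f"{obj.magnification:g}"
            if obj.numerical_aperture is not None:
                attrs["LensNA"] = f"{obj.numerical_aperture:g}"
            if obj.immersion_medium is not None:
                attrs["Immersion"] = _IMMERSION_TO_OME[obj.immersion_medium]
            if obj.correction_class is not None:
                attrs["Correction"] = obj.correction_class
            etree.SubElement(inst, _q("Objective"), **attrs)

    image = etree.SubElement(root, _q("Image"), ID="Image:0")
    if has_instrument:
        etree.SubElement(image, _q("InstrumentRef"), ID="Instrument:0")
        if obj is not None:
            etree.SubElement(image, _q("ObjectiveSettings"), ID="Objective:0")

    n_c = max(1, len(record.channels))
    size_z = 2 if record.is_3d else 1
    fs = dig.frame_size_px if dig is not None and dig.frame_size_px else (16, 16)
    pattrs = {
        "ID": "Pixels:0",
        "DimensionOrder": "XYCZT",
        "Type": "uint8",
        "SizeX": str(fs[0]),
        "SizeY": str(fs[1]),
        "SizeC": str(n_c),
        "SizeZ": str(size_z),
        "SizeT": "1",
    }
    if dig is not None and dig.pixel_size_xy_um is not None:
        pattrs["PhysicalSizeX"] = f"{dig.pixel_size_xy_um:g}"
        pattrs["PhysicalSizeXUnit"] = "µm"
        pattrs["PhysicalSizeY"] = f"{dig.pixel_size_xy_um:g}"
        pattrs["PhysicalSizeYUnit"] = "µm"
    if dig is not None and dig.z_step_um is not None:
        pattrs["PhysicalSizeZ"] = f"{dig.z_step_um:g}"
        pattrs["PhysicalSizeZUnit"] = "µm"
    pixels = etree.SubElement(image, _q("Pixels"), **pattrs)
    for i, ch in enumerate(record.channels):
        cattrs = {"ID": f"Channel:0:{i}"}
        if ch.fluorophore_name is not None:
            cattrs["Name"] = ch.fluorophore_name
        if ch.excitation_nm is not None:
            cattrs["ExcitationWavelength"] = f"{ch.excitation_nm.center_nm:g}"
            cattrs["ExcitationWavelengthUnit"] = "nm"
        if ch.emission_nm is not None:
            cattrs["EmissionWavelength"] = f"{ch.emission_nm.center_nm:g}"
            cattrs["EmissionWavelengthUnit"] = "nm"
        etree.SubElement(pixels, _q("Channel"), **cattrs)
    etree.SubElement(pixels, _q("MetadataOnly"))
    for i, ch in enumerate(record.channels):
        if ch.exposure_time_s is not None:
            etree.SubElement(
                pixels,
                _q("Plane"),
                TheC=str(i),
                TheZ="0",
                TheT="0",
                ExposureTime=f"{ch.exposure_time_s:g}",
                ExposureTimeUnit="s",
            )
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# fixtures with controlled completeness

class FixtureSpec(BaseModel):
    """Recipe for a batch of synthetic metadata documents.

    ``omit_fields`` are dotted paths (e.g. ``"objective.numerical_aperture"``,
    ``"channels.0.excitation_nm"``, ``"channels.*.emission_nm"``) removed
    from the written metadata while the manifest keeps the full ground truth.
    """

    model_config = ConfigDict(extra="forbid")

    base_record: AcquisitionRecord
    omit_fields: list[str] = []
    n_files: int = 1
    seed: int = 0
    as_tiff: bool = False

    @field_validator("n_files")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_files must be >= 1")
        return v

    @field_validator("omit_fields")
    @classmethod
    def _paths_exist(cls, v: list[str]) -> list[str]:
        for path in v:
            _check_field_path(path)
        return v


_SUBMODELS = {"objective": ObjectiveSpec, "digitization": DigitizationSpec, "em": EMSpec}
_TOP_FIELDS = set(AcquisitionRecord.model_fields)


def _check_field_path(path: str) -> None:
    parts = path.split(".")
    head = parts[0]
    if head not in _TOP_FIELDS:
        raise ValueError(f"unknown field path {path!r}")
    if head in _SUBMODELS:
        if len(parts) == 1:
            return
        if len(parts) != 2 or parts[1] not in _SUBMODELS[head].model_fields:
            raise ValueError(f"unknown field path {path!r}")
    elif head == "channels":
        if len(parts) == 1:
            return
        if len(parts) != 3 or parts[2] not in ChannelSpec.model_fields:
            raise ValueError(f"unknown field path {path!r}")
        if parts[1] != "*" and not parts[1].isdigit():
            raise ValueError(f"unknown field path {path!r}")
    elif len(parts) != 1:
        raise ValueError(f"unknown field path {path!r}")


def apply_omissions(
    record: AcquisitionRecord, omit_fields: list[str]
) -> AcquisitionRecord:
    """Return a copy of *record* with every ``omit_fields`` path set absent."""
    rec = copy.deepcopy(record)
    for path in omit_fields:
        _check_field_path(path)
        parts = path.split(".")
        head = parts[0]
        if head == "channels":
            if len(parts) == 1:
                rec.channels = []
            else:
                idx, field = parts[1], parts[2]
                targets = (
                    rec.channels
                    if idx == "*"
                    else rec.channels[int(idx) : int(idx) + 1]
                )
                for ch in targets:
                    setattr(ch, field, None)
        elif head in _SUBMODELS and len(parts) == 2:
            sub = getattr(rec, head)
            if sub is not None:
                setattr(sub, parts[1], None)
        else:
            setattr(rec, head, None if head not in ("is_3d", "is_fluorescence") else False)
    # an entirely unreported sub-model means absence, not an empty shell
    for name in _SUBMODELS:
        sub = getattr(rec, name)
        if sub is not None and all(
            v is None for v in sub.__dict__.values()
        ):
            setattr(rec, name, None)
    return rec


def write_fixture(spec: FixtureSpec, out_dir: Union[str, os.PathLike]) -> list[Path]:
    """Write ``spec.n_files`` OME documents plus a ``manifest.json``.

    Every schema-mapped field of ``base_record`` not named in
    ``omit_fields`` appears in the written metadata; omitted fields are
    absent.  The manifest records, per file, the full ground-truth record
    and the omitted paths.  Output is deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = apply_omissions(spec.base_record, spec.omit_fields)
    xml = record_to_ome_xml(written)
    rng = np.random.default_rng(spec.seed)

    paths: list[Path] = []
    manifest_files: dict[str, Any] = {}
    for i in range(spec.n_files):
        if spec.as_tiff:
            name = f"fixture_{i:03d}.tif"
            path = out / name
            payload = rng.integers(0, 255, size=(16, 16), dtype=np.uint8)
            # TIFF ImageDescription must be 7-bit ASCII; escape µ etc. as
            # XML character references (equivalent XML document)
            ascii_xml = xml.encode("ascii", "xmlcharrefreplace").decode("ascii")
            tifffile.imwrite(path, payload, description=ascii_xml)
        else:
            name = f"fixture_{i:03d}.ome.xml"
            path = out / name
            path.write_text(xml, encoding="utf-8")
        paths.append(path)
        manifest_files[name] = {
            "record": json.loads(spec.base_record.model_dump_json()),
            "omitted": list(spec.omit_fields),
        }
    manifest = {"seed": spec.seed, "files": manifest_files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def read_manifest(out_dir: Union[str, os.PathLike]) -> dict[str, Any]:
    return json.loads((Path(out_dir) / "manifest.json").read_text(encoding="utf-8"))


def ome_mapped_view(record: AcquisitionRecord) -> dict[str, Any]:
    """Project *record* onto the OME-mapped field subset, for equality checks."""
    view: dict[str, Any] = {"instrument_model": record.instrument_model}
    obj = record.objective
    view["objective"] = (
        None
        if obj is None
        else {
            "magnification": obj.magnification,
            "numerical_aperture": obj.numerical_aperture,
            "immersion_medium": obj.immersion_medium,
            "correction_class": obj.correction_class,
        }
    )
    dig = record.digitization
    view["digitization"] = (
        None
        if dig is None
        else {
            "pixel_size_xy_um": dig.pixel_size_xy_um,
            "z_step_um": dig.z_step_um,
            "camera_model": dig.camera_model,
        }
    )
    view["channels"] = [
        {
            "fluorophore_name": ch.fluorophore_name,
            "excitation_nm": ch.excitation_nm.center_nm if ch.excitation_nm else None,
            "emission_nm": ch.emission_nm.center_nm if ch.emission_nm else None,
            "exposure_time_s": ch.exposure_time_s,
        }
        for ch in record.channels
    ]
    # normalize empty submodels to None so absence compares as absence
    for key in ("objective", "digitization"):
        if view[key] is not None and all(v is None for v in view[key].values()):
            view[key] = None
    return view
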