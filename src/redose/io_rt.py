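"""Read/write the standard formats the workflow touches.

DICOM RT Dose, RT Structure Set and RT Plan via pydicom; NIfTI volumes via
nibabel as a TPS-neutral alternative; the case bundle (``case.json`` plus one
volume file per course) and the append-only case log (``caselog.jsonl``).

Only the overwhelmingly common RT Dose dialect is supported: axis-aligned
orientation and uniformly spaced frames. Anything else is rejected with a
:class:`~redose.errors.FormatError` rather than silently mis-scaled; every
missing geometry tag is a hard error.
"""

from __future__ import annotations

import datetime
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .accumulation import CourseRecord
from .errors import FormatError
from .grid import (
    DoseGrid,
    DoseKind,
    GridGeometry,
    SpatialTransform,
    StructureMask,
    TransformKind,
    rasterize_contours,
)
from .radiobiology import DoseScalingFactor, FractionationScheme

__all__ = [
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtplan",
    "write_rtplan",
    "read_nifti",
    "write_nifti",
    "read_transform",
    "CaseBundle",
    "write_case_bundle",
    "load_case_bundle",
    "append_case_log",
    "read_case_log",
    "geometry_to_dict",
    "geometry_from_dict",
]

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
CASE_SCHEMA = "redose-case/1"


def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _as_uid(frame_id: str) -> str:
    # frame labels are opaque; only valid DICOM UIDs are stored verbatim
    if re.fullmatch(r"[0-9.]{1,64}", frame_id or ""):
        return frame_id
    return generate_uid()


def _require(ds: Dataset, tag: str):
    if not hasattr(ds, tag):
        raise FormatError(f"required tag {tag} missing")
    return getattr(ds, tag)


# ---------------------------------------------------------------------------
# RT Dose
# ---------------------------------------------------------------------------

def write_rtdose(grid: DoseGrid, path: str | Path) -> None:
    """Write a dose grid as an RT Dose object.

    Values are stored as 32-bit unsigned integers with
    ``DoseGridScaling = max / (2^32 - 1)``; EQD2 grids are marked with
    ``DoseType = EFFECTIVE`` and ``DoseComment = EQD2`` so the dose kind
    survives a round trip.
    """
    if not grid.geometry.is_axis_aligned():
        raise FormatError("only axis-aligned grids can be written to RT Dose")
    path = Path(path)
    ds = FileDataset(str(path), {}, file_meta=_file_meta(_RTDOSE_SOP), preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = _as_uid(grid.geometry.frame_id)
    ds.PatientName = ds.PatientID = "redose"

    nx, ny, nz = grid.geometry.shape
    sx, sy, sz = grid.geometry.spacing
    ds.ImagePositionPatient = [float(v) for v in grid.geometry.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(sy), float(sx)]  # row (y), column (x)
    ds.GridFrameOffsetVector = [float(k * sz) for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    if grid.dose_kind is DoseKind.EQD2:
        ds.DoseType = "EFFECTIVE"
        ds.DoseComment = "EQD2"
    else:
        ds.DoseType = "PHYSICAL"

    vmax = float(grid.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    ints = np.round(grid.values / scaling).astype(np.uint32)
    # array (x, y, z) -> DICOM (frame=z, row=y, col=x)
    ds.PixelData = np.ascontiguousarray(ints.transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read an RT Dose object into a :class:`DoseGrid`."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object")
    units = _require(ds, "DoseUnits")
    if units != "GY":
        raise FormatError(f"unsupported DoseUnits {units!r}; expected GY")
    if getattr(ds, "DoseSummationType", "PLAN") != "PLAN":
        warnings.warn(
            f"DoseSummationType {ds.DoseSummationType!r}; treating as a full plan dose",
            stacklevel=2,
        )
    iop = np.asarray(_require(ds, "ImageOrientationPatient"), dtype=float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise FormatError("only axis-aligned RT Dose grids are supported")
    offsets = np.asarray(_require(ds, "GridFrameOffsetVector"), dtype=float)
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], atol=1e-6) or steps[0] <= 0:
            raise FormatError("non-uniform slice offsets are not supported")
        sz = float(steps[0])
    else:
        sz = 1.0
    scaling = float(_require(ds, "DoseGridScaling"))
    origin = [float(v) for v in _require(ds, "ImagePositionPatient")]
    origin[2] += float(offsets[0])
    sy, sx = (float(v) for v in _require(ds, "PixelSpacing"))
    raw = ds.pixel_array.astype(float)  # (z, y, x) or (y, x) for single frame
    if raw.ndim == 2:
        raw = raw[None]
    values = (raw * scaling).transpose(2, 1, 0)
    geom = GridGeometry(
        origin=tuple(origin),
        spacing=(sx, sy, sz),
        shape=values.shape,
        frame_id=str(getattr(ds, "FrameOfReferenceUID", "")),
    )
    kind = DoseKind.EQD2 if (
        getattr(ds, "DoseType", "PHYSICAL") == "EFFECTIVE"
        or getattr(ds, "DoseComment", "") == "EQD2"
    ) else DoseKind.PHYSICAL
    return DoseGrid(geometry=geom, values=values, dose_kind=kind)


# ---------------------------------------------------------------------------
# RT Structure Set
# ---------------------------------------------------------------------------

def write_rtstruct(masks: Sequence[StructureMask], path: str | Path) -> None:
    """Write masks as an RT Structure Set of closed planar contours.

    Per-slice contours are traced from the mask boundary (marching squares at
    the 0.5 level) and closed; volumes round-trip within about one voxel
    layer.
    """
    path = Path(path)
    ds = FileDataset(str(path), {}, file_meta=_file_meta(_RTSTRUCT_SOP), preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_SOP
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.PatientName = ds.PatientID = "redose"
    ds.StructureSetLabel = "redose"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []

    for number, m in enumerate(masks, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = m.name
        roi.ReferencedFrameOfReferenceUID = _as_uid(m.geometry.frame_id)
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        geom = m.geometry
        for k in range(geom.shape[2]):
            sl = m.mask[:, :, k]
            if not sl.any():
                continue
            padded = np.pad(sl.astype(float), 1)
            for loop in measure.find_contours(padded, 0.5):
                idx2 = loop - 1.0  # undo padding; (ix, iy) continuous indices
                if len(idx2) < 3:
                    continue
                idx3 = np.column_stack(
                    [idx2[:, 0], idx2[:, 1], np.full(len(idx2), float(k))]
                )
                pts = geom.indices_to_physical(idx3)
                cont = Dataset()
                cont.ContourGeometricType = "CLOSED_PLANAR"
                cont.NumberOfContourPoints = len(pts)
                cont.ContourData = [float(v) for v in pts.ravel()]
                rc.ContourSequence.append(cont)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def read_rtstruct(path: str | Path, target: GridGeometry) -> list[StructureMask]:
    """Read an RT Structure Set and rasterize each ROI onto ``target``.

    ROI names are kept verbatim; duplicates are suffixed ``_2``, ``_3``, ...
    deterministically. A ROI without contours yields an empty mask with a
    warning.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path}: not an RT Structure Set")
    names_by_number: dict[int, str] = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names_by_number[int(roi.ROINumber)] = str(roi.ROIName)
    seen: dict[str, int] = {}
    masks: list[StructureMask] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names_by_number.get(number, f"ROI_{number}")
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}_{seen[name]}"
        contours = []
        for cont in getattr(rc, "ContourSequence", []):
            pts = np.asarray(cont.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
        if not contours:
            warnings.warn(f"ROI {name!r} has no contours; empty mask", stacklevel=2)
        masks.append(rasterize_contours(contours, target, name=name))
    return masks


# ---------------------------------------------------------------------------
# RT Plan
# ---------------------------------------------------------------------------

def write_rtplan(scheme: FractionationScheme, path: str | Path) -> None:
    """Write a minimal RT Plan carrying the fractionation scheme."""
    path = Path(path)
    ds = FileDataset(str(path), {}, file_meta=_file_meta(_RTPLAN_SOP), preamble=b"\0" * 128)
    ds.SOPClassUID = _RTPLAN_SOP
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.PatientName = ds.PatientID = "redose"
    ds.RTPlanLabel = "redose"
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = scheme.n_fractions
    ds.FractionGroupSequence = [fg]
    if scheme.prescription_total is not None:
        dr = Dataset()
        dr.DoseReferenceNumber = 1
        dr.DoseReferenceStructureType = "SITE"
        dr.DoseReferenceType = "TARGET"
        dr.TargetPrescriptionDose = float(scheme.prescription_total)
        ds.DoseReferenceSequence = [dr]
    ds.save_as(path, enforce_file_format=True)


def read_rtplan(path: str | Path) -> FractionationScheme:
    """Read the fractionation scheme from an RT Plan."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTPLAN":
        raise FormatError(f"{path}: not an RT Plan")
    groups = getattr(ds, "FractionGroupSequence", None)
    if not groups:
        raise FormatError("RT Plan has no fraction group")
    if len(groups) > 1:
        raise FormatError(
            f"RT Plan has {len(groups)} fraction groups; select one explicitly"
        )
    n = int(groups[0].NumberOfFractionsPlanned)
    if n < 1:
        raise FormatError(f"invalid NumberOfFractionsPlanned {n}")
    prescription = None
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dr, "TargetPrescriptionDose"):
            prescription = float(dr.TargetPrescriptionDose)
            break
    return FractionationScheme(n_fractions=n, prescription_total=prescription)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(values: np.ndarray, geometry: GridGeometry, path: str | Path) -> None:
    """Write a volume (dose values or a mask) as float32 NIfTI."""
    affine = np.eye(4)
    affine[:3, :3] = geometry.rotation * np.asarray(geometry.spacing)
    affine[:3, 3] = geometry.origin
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path, frame_id: str = "") -> tuple[np.ndarray, GridGeometry]:
    """Read a NIfTI volume; returns (float32 values, geometry)."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float32)
    A = img.affine
    spacing = np.linalg.norm(A[:3, :3], axis=0)
    R = A[:3, :3] / spacing
    geom = GridGeometry(
        origin=tuple(A[:3, 3]),
        spacing=tuple(spacing),
        shape=values.shape[:3],
        orientation=tuple(map(tuple, R)),
        frame_id=frame_id,
    )
    return values, geom


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def read_transform(spec: dict, base_dir: Path | None = None) -> SpatialTransform:
    """Build a transform from its JSON description.

    ``{"kind": "identity"}``; ``{"kind": "affine", "matrix": [[...]x4]}``
    (row-major 4x4, mm); or ``{"kind": "dvf", "path": "dvf.nii.gz"}`` where
    the file is a 4D volume with displacement components (mm) last.
    """
    kind = TransformKind(spec.get("kind", "identity"))
    if kind is TransformKind.IDENTITY:
        return SpatialTransform.identity()
    if kind is TransformKind.AFFINE:
        if "matrix" not in spec:
            raise FormatError("affine transform requires a 'matrix' entry")
        return SpatialTransform(kind=kind, affine=np.asarray(spec["matrix"], dtype=float))
    path = Path(spec["path"])
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError("DVF volume must be 4D with 3 displacement components")
    A = img.affine
    spacing = np.linalg.norm(A[:3, :3], axis=0)
    geom = GridGeometry(
        origin=tuple(A[:3, 3]),
        spacing=tuple(spacing),
        shape=data.shape[:3],
        orientation=tuple(map(tuple, A[:3, :3] / spacing)),
    )
    return SpatialTransform(kind=kind, dvf=data, dvf_geometry=geom)


# ---------------------------------------------------------------------------
# Case bundle
# ---------------------------------------------------------------------------

def geometry_to_dict(g: GridGeometry) -> dict:
    return {
        "origin": list(g.origin),
        "spacing": list(g.spacing),
        "shape": list(g.shape),
        "orientation": [list(r) for r in g.orientation],
        "frame_id": g.frame_id,
    }


def geometry_from_dict(d: dict) -> GridGeometry:
    return GridGeometry(
        origin=tuple(d["origin"]),
        spacing=tuple(d["spacing"]),
        shape=tuple(d["shape"]),
        orientation=tuple(map(tuple, d.get("orientation", np.eye(3).tolist()))),
        frame_id=d.get("frame_id", ""),
    )


@dataclass
class CaseBundle:
    """An in-memory reirradiation case: prior courses + current-plan geometry."""

    case_id: str
    geometry: GridGeometry
    structures: dict[str, StructureMask]
    courses: list[CourseRecord]
    meta: dict = field(default_factory=dict)


def write_case_bundle(bundle: CaseBundle, out_dir: str | Path) -> Path:
    """Write a case bundle directory: case.json + NIfTI volumes."""
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    (out_dir / "courses").mkdir(parents=True, exist_ok=True)

    struct_entries = {}
    for name, mask in bundle.structures.items():
        rel = f"structures/{name}.nii.gz"
        write_nifti(mask.mask.astype(np.float32), mask.geometry, out_dir / rel)
        struct_entries[name] = rel

    course_entries = []
    for course in bundle.courses:
        rel = f"courses/{course.course_id}_dose.nii.gz"
        write_nifti(course.dose.values, course.dose.geometry, out_dir / rel)
        t = course.transform
        if t.kind is TransformKind.IDENTITY:
            tspec: dict = {"kind": "identity"}
        elif t.kind is TransformKind.AFFINE:
            tspec = {"kind": "affine", "matrix": t.affine.tolist()}
        else:
            trel = f"courses/{course.course_id}_dvf.nii.gz"
            write_nifti(t.dvf, t.dvf_geometry, out_dir / trel)
            tspec = {"kind": "dvf", "path": trel}
        course_entries.append(
            {
                "course_id": course.course_id,
                "dose_path": rel,
                "dose_geometry": geometry_to_dict(course.dose.geometry),
                "n_fractions": course.scheme.n_fractions,
                "prescription_total": course.scheme.prescription_total,
                "dsf": {"value": course.dsf.value, "structure": course.dsf.structure},
                "transform": tspec,
                "source_tps": course.source_tps,
            }
        )
    case = {
        "schema": CASE_SCHEMA,
        "case_id": bundle.case_id,
        "current": {
            "geometry": geometry_to_dict(bundle.geometry),
            "structures": struct_entries,
        },
        "courses": course_entries,
        "meta": bundle.meta,
    }
    (out_dir / "case.json").write_text(json.dumps(case, indent=2, sort_keys=True))
    return out_dir


def load_case_bundle(bundle_dir: str | Path) -> CaseBundle:
    """Load a case bundle directory written by :func:`write_case_bundle`."""
    bundle_dir = Path(bundle_dir)
    case_path = bundle_dir / "case.json"
    if not case_path.exists():
        raise FormatError(f"{bundle_dir}: no case.json found")
    case = json.loads(case_path.read_text())
    if case.get("schema") != CASE_SCHEMA:
        raise FormatError(f"unsupported case schema {case.get('schema')!r}")
    geom = geometry_from_dict(case["current"]["geometry"])
    structures = {}
    for name, rel in case["current"]["structures"].items():
        values, _ = read_nifti(bundle_dir / rel, frame_id=geom.frame_id)
        structures[name] = StructureMask(name=name, geometry=geom, mask=values > 0.5)
    courses = []
    for entry in case["courses"]:
        cgeom = geometry_from_dict(entry["dose_geometry"])
        values, _ = read_nifti(bundle_dir / entry["dose_path"])
        dose = DoseGrid(
            geometry=cgeom,
            values=values.astype(float),
            dose_kind=DoseKind.PHYSICAL,
            course_id=entry["course_id"],
        )
        courses.append(
            CourseRecord(
                course_id=entry["course_id"],
                dose=dose,
                scheme=FractionationScheme(
                    entry["n_fractions"], entry.get("prescription_total")
                ),
                transform=read_transform(entry["transform"], base_dir=bundle_dir),
                dsf=DoseScalingFactor(
                    value=entry["dsf"]["value"], structure=entry["dsf"].get("structure")
                ),
                source_tps=entry.get("source_tps", ""),
            )
        )
    return CaseBundle(
        case_id=case["case_id"],
        geometry=geom,
        structures=structures,
        courses=courses,
        meta=case.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Case log
# ---------------------------------------------------------------------------

def append_case_log(path: str | Path, entry: dict) -> dict:
    """Append a timestamped entry to the JSONL case log (never destructive)."""
    path = Path(path)
    record = dict(entry)
    record.setdefault(
        "logged_at", datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    with path.open("a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
    return record


def read_case_log(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        return []
    return [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
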