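"""Grid geometry, dose grids, structure masks and spatial transforms.

Conventions
-----------
* Arrays are indexed ``values[ix, iy, iz]`` with 0-based voxel indices.
* A voxel center's physical position (mm) is
  ``origin + orientation @ (index * spacing)``.
* Geometries used for masks are axis-aligned (identity orientation); oblique
  grids are supported only as resampling *sources*.
* Spatial transforms follow the pull-back convention: they map a point in the
  CURRENT frame to the corresponding point in the PRIOR-course frame, so
  resampling prior dose onto the current grid needs no transform inversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .errors import (
    ContractError,
    GeometryError,
    MalformedContourError,
    TransformError,
)

__all__ = [
    "GridGeometry",
    "DoseKind",
    "DoseGrid",
    "StructureMask",
    "TransformKind",
    "SpatialTransform",
    "ResampledDose",
    "resample_dose",
    "rasterize_contours",
    "BooleanOp",
    "boolean_op",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D grid geometry: origin, spacing, shape, orientation, frame.

    Parameters
    ----------
    origin : (3,) array-like
        Physical position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) array-like
        Voxel size (mm) along each array axis; all components > 0.
    shape : (3,) ints
        Number of voxels along each axis; all >= 1.
    orientation : (3, 3) array-like, optional
        Direction cosines; column ``j`` is the physical direction of array
        axis ``j``. Must be orthonormal. Defaults to identity.
    frame_id : str
        Opaque frame-of-reference label; geometries in different frames never
        compare equal.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    orientation: tuple = field(
        default=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    )
    frame_id: str = ""

    def __post_init__(self):
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        orientation = tuple(
            tuple(float(v) for v in row) for row in np.asarray(self.orientation)
        )
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "orientation", orientation)
        if len(origin) != 3 or len(spacing) != 3 or len(shape) != 3:
            raise GeometryError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise GeometryError(f"shape must be >= 1 per axis, got {shape}")
        R = np.asarray(orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("orientation must be a 3x3 orthonormal matrix")

    # -- derived quantities -------------------------------------------------

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def rotation(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    def is_axis_aligned(self, tol: float = _ORTHO_TOL) -> bool:
        return bool(np.allclose(self.rotation, np.eye(3), atol=tol))

    # -- coordinate mappings ------------------------------------------------

    def indices_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) continuous voxel indices to physical points in mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.rotation.T

    def physical_to_indices(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) physical points in mm to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - np.asarray(self.origin)) @ self.rotation
        return local / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center physical positions, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.indices_to_physical(idx).reshape(*self.shape, 3)

    def same_as(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.frame_id == other.frame_id
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )


def _require_same_geometry(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if not a.same_as(b):
        raise GeometryError(f"{what}: geometries differ")


class DoseKind(str, enum.Enum):
    PHYSICAL = "PHYSICAL"
    EQD2 = "EQD2"


@dataclass
class DoseGrid:
    """A scalar dose distribution on a :class:`GridGeometry`.

    ``dose_kind`` tags whether values are physical dose or EQD2; operations
    that only make sense for one kind enforce the tag.
    """

    geometry: GridGeometry
    values: np.ndarray
    dose_kind: DoseKind = DoseKind.PHYSICAL
    course_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.dose_kind = DoseKind(self.dose_kind)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ContractError("dose values must be finite")
        if np.any(self.values < 0):
            raise ContractError("dose values must be non-negative")

    def max(self) -> float:
        return float(self.values.max())

    def with_values(self, values: np.ndarray, dose_kind: DoseKind | None = None) -> "DoseGrid":
        return DoseGrid(
            geometry=self.geometry,
            values=values,
            dose_kind=self.dose_kind if dose_kind is None else dose_kind,
            course_id=self.course_id,
        )


@dataclass
class StructureMask:
    """A named boolean voxel mask aligned to a grid geometry."""

    name: str
    geometry: GridGeometry
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * self.geometry.voxel_volume_cc

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def dilate(self, margin_mm: float) -> "StructureMask":
        """Euclidean dilation by ``margin_mm`` on voxel centers."""
        if margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        if margin_mm == 0 or not self.mask.any():
            return StructureMask(self.name, self.geometry, self.mask.copy())
        dist = ndimage.distance_transform_edt(
            ~self.mask, sampling=self.geometry.spacing
        )
        return StructureMask(self.name, self.geometry, dist <= margin_mm)


class TransformKind(str, enum.Enum):
    IDENTITY = "identity"
    AFFINE = "affine"
    DVF = "dvf"


@dataclass
class SpatialTransform:
    """Maps a point in the current frame to the prior-course frame (pull-back).

    ``affine`` is a 4x4 homogeneous matrix (row-major, mm). ``dvf`` is a
    displacement field in mm with array layout ``(*dvf_geometry.shape, 3)``;
    the mapped point is ``p + dvf(p)`` with the displacement trilinearly
    interpolated at ``p`` (zero displacement outside the field's extent).
    """

    kind: TransformKind = TransformKind.IDENTITY
    affine: np.ndarray | None = None
    dvf: np.ndarray | None = None
    dvf_geometry: GridGeometry | None = None

    def __post_init__(self):
        self.kind = TransformKind(self.kind)
        if self.kind is TransformKind.AFFINE:
            A = np.asarray(self.affine, dtype=float)
            if A.shape != (4, 4):
                raise TransformError("affine must be a 4x4 homogeneous matrix")
            if abs(np.linalg.det(A[:3, :3])) <= 1e-12:
                raise TransformError("affine linear part is not invertible")
            self.affine = A
        elif self.kind is TransformKind.DVF:
            if self.dvf is None or self.dvf_geometry is None:
                raise TransformError("DVF transform requires dvf and dvf_geometry")
            self.dvf = np.asarray(self.dvf, dtype=float)
            if self.dvf.shape != (*self.dvf_geometry.shape, 3):
                raise TransformError(
                    f"dvf shape {self.dvf.shape} must be (*geometry.shape, 3)"
                )
            if not np.all(np.isfinite(self.dvf)):
                raise TransformError("dvf components must be finite")

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind=TransformKind.IDENTITY)

    @classmethod
    def translation(cls, shift_mm: Sequence[float]) -> "SpatialTransform":
        A = np.eye(4)
        A[:3, 3] = np.asarray(shift_mm, dtype=float)
        return cls(kind=TransformKind.AFFINE, affine=A)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) current-frame points to prior-frame points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind is TransformKind.IDENTITY:
            return pts
        if self.kind is TransformKind.AFFINE:
            return pts @ self.affine[:3, :3].T + self.affine[:3, 3]
        # DVF: interpolate each displacement component at the current points
        idx = self.dvf_geometry.physical_to_indices(pts)
        disp = np.empty_like(pts)
        for c in range(3):
            disp[:, c] = ndimage.map_coordinates(
                self.dvf[..., c], idx.T, order=1, mode="constant", cval=0.0
            )
        return pts + disp


class ResampledDose(NamedTuple):
    """Resampled dose plus the out-of-extent voxel tally.

    ``out_of_extent_voxels`` counts target voxels whose mapped point fell
    outside the prior grid's voxel-center bounding box (those voxels are
    assigned 0 Gy). A large tally flags inadequate prior grid coverage or a
    misregistration.
    """

    dose: DoseGrid
    out_of_extent_voxels: int


def resample_dose(
    prior: DoseGrid,
    transform: SpatialTransform,
    target: GridGeometry,
) -> ResampledDose:
    """Map a prior-course physical dose grid onto the current planning geometry.

    Each target voxel center is pulled back through ``transform`` into the
    prior frame and the prior dose is trilinearly interpolated there. Points
    outside the prior grid's extent map to 0 Gy and are tallied.

    Raises
    ------
    ContractError
        If ``prior`` is already EQD2 — physical dose is mapped first and
        converted to EQD2 on the current geometry afterward.
    """
    if prior.dose_kind is not DoseKind.PHYSICAL:
        raise ContractError(
            "resample_dose maps PHYSICAL dose; convert to EQD2 after mapping"
        )
    pts = target.voxel_centers().reshape(-1, 3)
    prior_pts = transform.apply(pts)
    idx = prior.geometry.physical_to_indices(prior_pts)
    upper = np.asarray(prior.geometry.shape, dtype=float) - 1.0
    inside = np.all((idx >= 0.0) & (idx <= upper), axis=1)
    vals = np.zeros(len(idx), dtype=float)
    if inside.any():
        vals[inside] = ndimage.map_coordinates(
            prior.values, idx[inside].T, order=1, mode="nearest"
        )
    out = DoseGrid(
        geometry=target,
        values=vals.reshape(target.shape),
        dose_kind=DoseKind.PHYSICAL,
        course_id=prior.course_id,
    )
    return ResampledDose(out, int((~inside).sum()))


# ---------------------------------------------------------------------------
# Contour rasterization
# ---------------------------------------------------------------------------

def rasterize_contours(
    planar_contours: Sequence[np.ndarray],
    target: GridGeometry,
    name: str = "",
) -> StructureMask:
    """Rasterize closed planar contours to a boolean voxel mask.

    Each contour is an (N, 3) array of mm points with (near-)constant z,
    assigned to the nearest target slice within half a slice spacing. A voxel
    is inside if its center is inside the polygon under the even-odd rule;
    multiple contours on one slice XOR together, so holes and disjoint
    islands both work. The empty contour list gives an all-false mask.
    """
    if not target.is_axis_aligned():
        raise GeometryError("rasterization requires an axis-aligned geometry")
    mask = np.zeros(target.shape, dtype=bool)
    nx, ny, nz = target.shape
    # voxel-center xy coordinates in index space: integers
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    for cont in planar_contours:
        pts = np.asarray(cont, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise MalformedContourError(
                "each contour must be an (N>=3, 3) array of mm points"
            )
        idx = target.physical_to_indices(pts)
        z = float(np.mean(idx[:, 2]))
        k = int(round(z))
        if abs(z - k) > 0.5 + 1e-9 or k < 0 or k >= nz:
            # off-grid slice: precondition says contours lie on/near planes
            import warnings

            warnings.warn(
                f"contour at slice index {z:.2f} is not near a grid slice; skipped",
                stacklevel=2,
            )
            continue
        path = MplPath(idx[:, :2], closed=True)
        inside = path.contains_points(centers).reshape(nx, ny)
        mask[:, :, k] ^= inside
    return StructureMask(name=name, geometry=target, mask=mask)


class BooleanOp(str, enum.Enum):
    UNION = "union"
    INTERSECT = "intersect"
    SUBTRACT = "subtract"


def boolean_op(a: StructureMask, b: StructureMask, op: BooleanOp | str) -> StructureMask:
    """Voxel-wise boolean combination; SUBTRACT(a, b) = a AND NOT b."""
    _require_same_geometry(a.geometry, b.geometry, "boolean_op")
    op = BooleanOp(op)
    if op is BooleanOp.UNION:
        out = a.mask | b.mask
    elif op is BooleanOp.INTERSECT:
        out = a.mask & b.mask
    else:
        out = a.mask & ~b.mask
    return StructureMask(
        name=f"{a.name}_{op.value}_{b.name}", geometry=a.geometry, mask=out
    )
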