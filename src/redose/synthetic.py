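"""Deterministic synthetic reirradiation cases for testing every stage.

Each prior course's dose is a flat high-dose core with a Gaussian shoulder:

    dose(x) = peak * exp(-max(0, |x - center| - core_radius)^2 / (2 sigma^2))

which is smooth, has analytically known isodose surfaces (spheres), and so
makes the optimization-structure shells checkable in closed form. Structures
are spheres or cuboids rasterized analytically on voxel centers. All
randomness (optional center jitter) sits behind a single seed; the default
generation is fully deterministic and byte-identical for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .accumulation import CourseRecord
from .errors import ParameterError
from .grid import DoseGrid, DoseKind, GridGeometry, SpatialTransform, StructureMask
from .io_rt import CaseBundle
from .radiobiology import DoseScalingFactor, FractionationScheme, eqd2_inverse

__all__ = [
    "CourseSpec",
    "ShapeSpec",
    "SyntheticSpec",
    "make_case",
    "make_worked_example_case",
    "WORKED_EXAMPLE_P",
    "WORKED_EXAMPLE_R",
    "WORKED_EXAMPLE_A",
]

# Worked-example inputs: prior near-target Dmax P, new prescription R and
# cumulative constraint A, all in EQD2 Gy.
WORKED_EXAMPLE_P = 57.0
WORKED_EXAMPLE_R = 60.0
WORKED_EXAMPLE_A = 60.0


@dataclass(frozen=True)
class CourseSpec:
    """One synthetic prior course: a flat-core Gaussian-shoulder dose ball."""

    course_id: str
    center_mm: tuple[float, float, float]
    peak_gy: float
    core_radius_mm: float
    falloff_sigma_mm: float
    n_fractions: int
    dsf: float = 1.0

    def __post_init__(self):
        if self.peak_gy < 0:
            raise ParameterError("peak dose must be >= 0")
        if self.falloff_sigma_mm <= 0:
            raise ParameterError("falloff sigma must be > 0")


@dataclass(frozen=True)
class ShapeSpec:
    """A sphere ('sphere', size = radius) or cuboid ('box', size = half-widths)."""

    name: str
    kind: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.kind not in ("sphere", "box"):
            raise ParameterError(f"unknown shape kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic multi-course reirradiation case.

    Defaults describe a typical two-course overlap case on a 2 mm grid:
    a prior 60 Gy / 30 fx course whose high-dose core abuts the new target,
    with an OAR straddling the prior dose falloff.
    """

    shape: tuple[int, int, int] = (36, 36, 24)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    courses: tuple[CourseSpec, ...] = (
        CourseSpec(
            course_id="prior1",
            center_mm=(0.0, 0.0, 0.0),
            peak_gy=60.0,
            core_radius_mm=10.0,
            falloff_sigma_mm=8.0,
            n_fractions=30,
        ),
    )
    structures: tuple[ShapeSpec, ...] = (
        ShapeSpec("OAR", "sphere", (2.0, 13.0, 0.0), (11.0, 11.0, 11.0)),
        ShapeSpec("PTV", "sphere", (16.0, 0.0, 0.0), (6.0, 6.0, 6.0)),
    )
    jitter_mm: float = 0.0
    seed: int = 0
    frame_id: str = "synthetic-current"

    def geometry(self) -> GridGeometry:
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing_mm)
        origin = -(shape - 1) / 2.0 * spacing  # grid centered on the origin
        return GridGeometry(
            origin=tuple(origin),
            spacing=tuple(spacing),
            shape=tuple(int(n) for n in shape),
            frame_id=self.frame_id,
        )


def _dose_field(centers: np.ndarray, spec: CourseSpec) -> np.ndarray:
    dist = np.linalg.norm(centers - np.asarray(spec.center_mm), axis=-1)
    shoulder = np.maximum(0.0, dist - spec.core_radius_mm)
    return spec.peak_gy * np.exp(-(shoulder**2) / (2.0 * spec.falloff_sigma_mm**2))


def _shape_mask(centers: np.ndarray, spec: ShapeSpec) -> np.ndarray:
    rel = centers - np.asarray(spec.center_mm)
    if spec.kind == "sphere":
        return np.linalg.norm(rel, axis=-1) <= spec.size_mm[0]
    return np.all(np.abs(rel) <= np.asarray(spec.size_mm), axis=-1)


def make_case(spec: SyntheticSpec) -> CaseBundle:
    """Build a deterministic case bundle from a synthetic spec.

    Raises if any structure or dose core lies outside the grid extent.
    """
    geom = spec.geometry()
    centers = geom.voxel_centers()
    extent_lo = np.asarray(geom.origin)
    extent_hi = extent_lo + (np.asarray(geom.shape) - 1) * np.asarray(geom.spacing)

    rng = np.random.default_rng(spec.seed)

    structures: dict[str, StructureMask] = {}
    for s in spec.structures:
        c = np.asarray(s.center_mm)
        if np.any(c - np.asarray(s.size_mm) < extent_lo) or np.any(
            c + np.asarray(s.size_mm) > extent_hi
        ):
            raise ParameterError(f"structure {s.name!r} extends outside the grid")
        structures[s.name] = StructureMask(s.name, geom, _shape_mask(centers, s))

    courses: list[CourseRecord] = []
    for c in spec.courses:
        cspec = c
        if spec.jitter_mm > 0:
            offset = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
            cspec = replace(c, center_mm=tuple(np.asarray(c.center_mm) + offset))
        center = np.asarray(cspec.center_mm)
        if np.any(center < extent_lo) or np.any(center > extent_hi):
            raise ParameterError(f"course {c.course_id!r} core center outside the grid")
        dose = DoseGrid(
            geometry=geom,
            values=_dose_field(centers, cspec),
            dose_kind=DoseKind.PHYSICAL,
            course_id=c.course_id,
        )
        courses.append(
            CourseRecord(
                course_id=c.course_id,
                dose=dose,
                scheme=FractionationScheme(c.n_fractions),
                transform=SpatialTransform.identity(),
                dsf=DoseScalingFactor(value=c.dsf),
                source_tps="synthetic",
            )
        )
    return CaseBundle(
        case_id=f"synthetic-{spec.seed}",
        geometry=geom,
        structures=structures,
        courses=courses,
        meta={"generator": "redose.synthetic", "seed": spec.seed},
    )


def make_worked_example_case(
    n_fractions: int = 30, alpha_beta: float = 3.0, seed: int = 0
) -> CaseBundle:
    """A two-structure case whose prior near-target OAR Dmax is 57.0 EQD2 Gy.

    The prior course's flat core intersects the OAR, so the OAR's maximum
    EQD2 equals the core EQD2 exactly; the peak physical dose is chosen as
    the inverse conversion of 57 EQD2 Gy at the course fractionation, making
    the calibration analytic rather than fitted. The OAR extends into the
    Gaussian falloff so a genuine dose gradient crosses it, which exercises
    the nested-shell generation end-to-end.
    """
    peak = eqd2_inverse(WORKED_EXAMPLE_P, n_fractions, alpha_beta)
    spec = SyntheticSpec(
        courses=(
            CourseSpec(
                course_id="prior1",
                center_mm=(0.0, 0.0, 0.0),
                peak_gy=peak,
                core_radius_mm=10.0,
                falloff_sigma_mm=8.0,
                n_fractions=n_fractions,
            ),
        ),
        structures=(
            ShapeSpec("OAR", "sphere", (2.0, 13.0, 0.0), (11.0, 11.0, 11.0)),
            ShapeSpec("PTV", "sphere", (16.0, 0.0, 0.0), (6.0, 6.0, 6.0)),
        ),
        seed=seed,
    )
    bundle = make_case(spec)
    bundle.case_id = f"worked-example-{seed}"
    bundle.meta["preset"] = "worked-example"
    bundle.meta["alpha_beta"] = alpha_beta
    return bundle
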