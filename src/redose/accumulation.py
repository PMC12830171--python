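"""Multi-course dose accumulation onto the current planning geometry.

For each prior course: resample physical dose onto the current grid through
the supplied registration result, convert to EQD2 using the CURRENT plan's
structure set and alpha/beta table (prior contours are never used for EQD2
conversion), apply any dose scaling factor, then sum all courses voxel-wise.
Provenance (transform kind, scaling, out-of-extent tallies) is kept per
course so the result is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, RedoseError, StructureNotFoundError
from .grid import (
    DoseGrid,
    DoseKind,
    GridGeometry,
    SpatialTransform,
    StructureMask,
    resample_dose,
)
from .radiobiology import (
    AlphaBetaMap,
    DoseScalingFactor,
    FractionationScheme,
    apply_dsf,
    eqd2_convert_grid,
    sum_eqd2,
)

__all__ = [
    "CourseRecord",
    "AccumulationResult",
    "accumulate",
    "FeasibilityFlag",
    "FeasibilityRow",
    "feasibility_screen",
]


@dataclass
class CourseRecord:
    """One prior treatment course: dose, fractionation, registration, scaling."""

    course_id: str
    dose: DoseGrid
    scheme: FractionationScheme
    transform: SpatialTransform = field(default_factory=SpatialTransform.identity)
    dsf: DoseScalingFactor = field(default_factory=DoseScalingFactor)
    source_tps: str = ""

    def __post_init__(self):
        if self.dose.dose_kind is not DoseKind.PHYSICAL:
            raise ParameterError(
                f"course {self.course_id!r}: dose must be PHYSICAL"
            )


@dataclass
class AccumulationResult:
    """Summed EQD2 on the current geometry plus per-course grids and provenance."""

    summed_eqd2: DoseGrid
    per_course_eqd2: list[DoseGrid]
    provenance: list[dict]

    @property
    def geometry(self) -> GridGeometry:
        return self.summed_eqd2.geometry


def accumulate(
    courses: Sequence[CourseRecord],
    current_geometry: GridGeometry,
    current_structures: Sequence[StructureMask],
    ab_map: AlphaBetaMap,
) -> AccumulationResult:
    """Run the per-course map -> EQD2 -> scale chain, then sum.

    Raises with the offending ``course_id`` in the message if any stage fails.
    """
    if not courses:
        raise ParameterError("accumulate requires at least one course")
    structures = {s.name: s for s in current_structures}
    per_course: list[DoseGrid] = []
    provenance: list[dict] = []
    for course in courses:
        try:
            mapped, n_out = resample_dose(
                course.dose, course.transform, current_geometry
            )
            eqd2 = eqd2_convert_grid(
                mapped, course.scheme, ab_map, current_structures
            )
            scope = None
            if course.dsf.structure is not None:
                scope = structures.get(course.dsf.structure)
                if scope is None:
                    raise StructureNotFoundError(
                        course.dsf.structure, list(structures)
                    )
            eqd2 = apply_dsf(eqd2, course.dsf, scope)
        except RedoseError as exc:
            raise type(exc)(f"course {course.course_id!r}: {exc}") from exc
        eqd2.course_id = course.course_id
        per_course.append(eqd2)
        provenance.append(
            {
                "course_id": course.course_id,
                "transform_kind": course.transform.kind.value,
                "dsf_value": course.dsf.value,
                "dsf_structure": course.dsf.structure,
                "n_fractions": course.scheme.n_fractions,
                "alpha_beta_map_version": ab_map.version,
                "out_of_extent_voxels": n_out,
                "source_tps": course.source_tps,
            }
        )
    return AccumulationResult(
        summed_eqd2=sum_eqd2(per_course),
        per_course_eqd2=per_course,
        provenance=provenance,
    )


class FeasibilityFlag:
    """Three-way outcome of the pre-planning screen for one constraint."""

    ACHIEVABLE = "ACHIEVABLE"            # full prescription fits under the limit
    GRADIENT_REQUIRED = "GRADIENT_REQUIRED"  # fits only with a sculpted gradient
    INFEASIBLE = "INFEASIBLE"            # prior dose alone reaches the limit


@dataclass(frozen=True)
class FeasibilityRow:
    structure: str
    metric: str
    limit_eqd2: float
    prior_value_eqd2: float
    remaining_budget_eqd2: float
    flag: str


def feasibility_screen(
    result: AccumulationResult,
    constraints: Sequence,
    new_prescription_eqd2: float,
    structures: Sequence[StructureMask],
) -> list[FeasibilityRow]:
    """Worst-case screen of cumulative constraints before planning starts.

    For each constraint the prior metric value is read from the summed EQD2;
    the flag assumes the full new prescription could land on the worst voxel:
    INFEASIBLE when the prior value already reaches the limit, ACHIEVABLE
    when prior + prescription fits within it, GRADIENT_REQUIRED otherwise.
    """
    from .dvh import evaluate_metric  # local import to avoid a cycle

    if new_prescription_eqd2 < 0:
        raise ParameterError("new_prescription_eqd2 must be >= 0")
    by_name = {s.name: s for s in structures}
    rows: list[FeasibilityRow] = []
    for c in constraints:
        mask = by_name.get(c.structure)
        if mask is None:
            raise StructureNotFoundError(c.structure, list(by_name))
        prior = evaluate_metric(result.summed_eqd2, mask, c.metric)
        budget = max(c.limit - prior, 0.0)
        if prior >= c.limit:
            flag = FeasibilityFlag.INFEASIBLE
        elif prior + new_prescription_eqd2 <= c.limit:
            flag = FeasibilityFlag.ACHIEVABLE
        else:
            flag = FeasibilityFlag.GRADIENT_REQUIRED
        rows.append(
            FeasibilityRow(
                structure=c.structure,
                metric=str(c.metric),
                limit_eqd2=float(c.limit),
                prior_value_eqd2=float(prior),
                remaining_budget_eqd2=float(budget),
                flag=flag,
            )
        )
    return rows
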