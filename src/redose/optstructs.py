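"""Nested isodose optimization structures for reirradiation planning.

Given the prior summed EQD2 distribution, an OAR, the new-plan prescription
``R`` and the cumulative constraint ``A`` (all EQD2 Gy), the method builds
``N`` nested shells of the prior isodose within the OAR and assigns each a
dose limit for the new plan:

* ``P`` is the prior Dmax to the OAR within the region near the target.
* If ``P + R <= A`` no structures are needed — the full prescription can be
  delivered over the OAR without exceeding the constraint.
* Otherwise the step is ``d = ((P + R) - A) / N`` and the shells are the
  isodose bands at thresholds ``D_i = P - i*d`` (``i = 1..N``, clamped at 0),
  each minus the shells above it. Shell ``S_i`` is assumed to have received
  ``D_{i-1}`` (with ``D_0 = P``), so its new-plan EQD2 limit is
  ``A - D_{i-1}``, converted to a physical limit for the prescribed
  fractionation. Every voxel's assumed prior dose is at least its actual
  prior dose, so the limits are conservative. Remaining OAR voxels (the
  ``rest`` mask) can be planned without regard to the prior course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RedoseError
from .grid import DoseGrid, DoseKind, StructureMask
from .radiobiology import FractionationScheme, eqd2_inverse

__all__ = [
    "OptStructParams",
    "OptStructure",
    "OptStructureSet",
    "compute_near_target_dmax",
    "generate",
    "export_structures",
]


@dataclass(frozen=True)
class OptStructParams:
    """Inputs to structure generation.

    R : new-plan prescription in EQD2 Gy for the nearby target.
    A : cumulative OAR constraint in EQD2 Gy.
    N : number of structures (more structures = smoother gradient; default 3).
    near_margin_mm : target expansion defining "near the target" for P.
    restrict_to_oar : build shells from OAR-cropped isodose regions (default)
        or whole-grid isodose shells.
    """

    R: float
    A: float
    N: int = 3
    near_margin_mm: float = 20.0
    restrict_to_oar: bool = True

    def __post_init__(self):
        if self.R < 0:
            raise ParameterError("prescription R must be >= 0")
        if self.A <= 0:
            raise ParameterError("constraint A must be > 0")
        if int(self.N) != self.N or self.N < 1:
            raise ParameterError("N must be a positive integer")
        object.__setattr__(self, "N", int(self.N))
        if self.near_margin_mm < 0:
            raise ParameterError("near_margin_mm must be >= 0")


@dataclass
class OptStructure:
    """One nested shell S_i with its threshold and dose limits."""

    index: int                 # 1..N
    mask: StructureMask
    threshold: float           # D_i, EQD2 Gy: outer isodose boundary
    assumed_prior: float       # D_{i-1} (D_0 = P), EQD2 Gy
    eqd2_limit: float          # A - assumed_prior
    physical_limit: float      # eqd2_inverse(eqd2_limit) for the new scheme


@dataclass
class OptStructureSet:
    """Ordered shells S_1..S_N plus the rest of the OAR.

    Empty (no structures) when ``P + R <= A``. ``rest_mask`` holds the OAR
    voxels below the lowest threshold, plannable without considering prior
    treatment.
    """

    P: float
    d: float
    structures: list[OptStructure] = field(default_factory=list)
    rest_mask: StructureMask | None = None

    @property
    def is_empty(self) -> bool:
        return not self.structures

    def limits_table(self):
        """Per-structure limits as a DataFrame (plus the rest row)."""
        import pandas as pd

        rows = [
            {
                "structure": f"S{s.index}",
                "threshold_eqd2": s.threshold,
                "assumed_prior_eqd2": s.assumed_prior,
                "limit_eqd2": s.eqd2_limit,
                "limit_physical": s.physical_limit,
                "n_voxels": s.mask.n_voxels,
            }
            for s in self.structures
        ]
        if self.rest_mask is not None:
            rows.append(
                {
                    "structure": "rest",
                    "threshold_eqd2": np.nan,
                    "assumed_prior_eqd2": 0.0,
                    "limit_eqd2": np.nan,
                    "limit_physical": np.nan,
                    "n_voxels": self.rest_mask.n_voxels,
                }
            )
        return pd.DataFrame(rows)


def compute_near_target_dmax(
    summed_eqd2: DoseGrid,
    oar: StructureMask,
    target: StructureMask,
    near_margin_mm: float = 20.0,
) -> float:
    """Prior Dmax (EQD2, post-DSF) to the OAR within the region near the target.

    The near region is the target dilated by ``near_margin_mm``. If the OAR
    does not intersect it, the max over the whole OAR is returned with a
    warning (conservative fallback).
    """
    for m in (oar, target):
        if not m.geometry.same_as(summed_eqd2.geometry):
            raise RedoseError(f"mask {m.name!r} not on the summed dose geometry")
    if not oar.mask.any():
        raise ParameterError(f"OAR {oar.name!r} is empty")
    near = target.dilate(near_margin_mm)
    region = oar.mask & near.mask
    if not region.any():
        warnings.warn(
            f"OAR {oar.name!r} does not intersect the near-target region; "
            "using Dmax over the whole OAR",
            stacklevel=2,
        )
        region = oar.mask
    return float(summed_eqd2.values[region].max())


def generate(
    params: OptStructParams,
    P: float,
    summed_eqd2: DoseGrid,
    oar: StructureMask,
    scheme: FractionationScheme,
    alpha_beta: float,
) -> OptStructureSet:
    """Build the nested optimization-structure set for one OAR.

    Returns an empty set when ``P + R <= A`` (at equality the step ``d``
    would be 0 and the shells degenerate). Thresholds are clamped below at
    0 Gy; a 0 Gy threshold captures all remaining OAR voxels.
    """
    if summed_eqd2.dose_kind is not DoseKind.EQD2:
        raise ParameterError("generate expects the summed EQD2 grid")
    if not oar.geometry.same_as(summed_eqd2.geometry):
        raise RedoseError("OAR mask not on the summed dose geometry")
    if P < 0:
        raise ParameterError("P must be >= 0")

    if P + params.R <= params.A:
        return OptStructureSet(P=float(P), d=0.0, structures=[], rest_mask=None)

    d = ((P + params.R) - params.A) / params.N
    geom = oar.geometry
    domain = oar.mask if params.restrict_to_oar else np.ones(geom.shape, dtype=bool)
    taken = np.zeros(geom.shape, dtype=bool)
    structures: list[OptStructure] = []
    prev_threshold = float(P)  # D_0 = P
    for i in range(1, params.N + 1):
        D_i = max(P - i * d, 0.0)
        raw = domain & (summed_eqd2.values >= D_i)
        shell = raw & ~taken
        taken |= shell
        eqd2_limit = params.A - prev_threshold
        structures.append(
            OptStructure(
                index=i,
                mask=StructureMask(f"S{i}", geom, shell),
                threshold=D_i,
                assumed_prior=prev_threshold,
                eqd2_limit=eqd2_limit,
                physical_limit=eqd2_inverse(
                    max(eqd2_limit, 0.0), scheme.n_fractions, alpha_beta
                ),
                )
        )
        prev_threshold = D_i
    rest = StructureMask("rest", geom, oar.mask & ~taken)
    return OptStructureSet(P=float(P), d=float(d), structures=structures, rest_mask=rest)


def export_structures(
    struct_set: OptStructureSet, name_prefix: str
) -> list[StructureMask]:
    """Name the shells for handoff: ``{prefix}_S1..SN`` plus ``{prefix}_rest``.

    Each returned mask carries its physical dose limit in a ``limit_physical``
    attribute so downstream writers can annotate it. An empty set exports
    nothing (with a notice).
    """
    if struct_set.is_empty:
        warnings.warn("optimization structure set is empty; nothing to export",
                      stacklevel=2)
        return []
    out: list[StructureMask] = []
    for s in struct_set.structures:
        m = StructureMask(f"{name_prefix}_S{s.index}", s.mask.geometry, s.mask.mask)
        m.limit_physical = s.physical_limit
        m.limit_eqd2 = s.eqd2_limit
        out.append(m)
    rest = StructureMask(
        f"{name_prefix}_rest", struct_set.rest_mask.geometry, struct_set.rest_mask.mask
    )
    rest.limit_physical = None
    rest.limit_eqd2 = None
    out.append(rest)
    return out
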