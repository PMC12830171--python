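"""Linear-quadratic EQD2 conversion, dose scaling, summation and feasibility.

The equieffective dose in 2 Gy fractions of a total dose ``D`` delivered in
``n`` equal fractions to tissue with fractionation sensitivity ``alpha_beta``
(Gy) is

    EQD2 = D * (d + alpha_beta) / (2 + alpha_beta),    d = D / n.

The inverse — the physical dose deliverable in ``n`` fractions that is
equieffective to a given EQD2 — is the non-negative root of the quadratic
``D^2/n + alpha_beta*D - EQD2*(2 + alpha_beta) = 0``.

Point-dose feasibility follows the worksheet logic used clinically: given a
cumulative constraint ``A`` and the prior accumulated point dose ``P`` (both
EQD2), the remaining budget is ``B = max(A - P, 0)`` and the allowable new
physical dose is the inverse conversion of ``B`` at the new plan's
fractionation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, GeometryError, ParameterError
from .grid import DoseGrid, DoseKind, StructureMask

__all__ = [
    "FractionationScheme",
    "AlphaBetaEntry",
    "AlphaBetaMap",
    "DoseScalingFactor",
    "FeasibilityResult",
    "eqd2_forward",
    "eqd2_inverse",
    "eqd2_convert_grid",
    "apply_dsf",
    "sum_eqd2",
    "point_dose_feasibility",
    "fill_worksheet",
    "WORKSHEET_INPUT_COLUMNS",
    "WORKSHEET_OUTPUT_COLUMNS",
]


@dataclass(frozen=True)
class FractionationScheme:
    """Number of fractions and (optionally) the prescribed total dose in Gy."""

    n_fractions: int
    prescription_total: float | None = None

    def __post_init__(self):
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ParameterError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if self.prescription_total is not None and self.prescription_total < 0:
            raise ParameterError("prescription_total must be >= 0")


@dataclass(frozen=True)
class AlphaBetaEntry:
    structure: str
    ab: float          # alpha/beta in Gy
    priority: int      # 1 = highest; wins on overlap

    def __post_init__(self):
        if self.ab <= 0:
            raise ParameterError(f"alpha/beta must be > 0, got {self.ab}")


@dataclass
class AlphaBetaMap:
    """Per-structure alpha/beta assignments with overlap priorities.

    A voxel inside several listed structures takes the alpha/beta of the
    entry with the smallest priority rank; voxels in no listed structure take
    ``default_ab``. Priority ranks must be unique so the assignment is
    deterministic.
    """

    entries: list[AlphaBetaEntry] = field(default_factory=list)
    default_ab: float = 3.0
    version: str = "default"

    def __post_init__(self):
        self.entries = [
            e if isinstance(e, AlphaBetaEntry) else AlphaBetaEntry(**e)
            for e in self.entries
        ]
        if self.default_ab <= 0:
            raise ParameterError("default_ab must be > 0")
        ranks = [e.priority for e in self.entries]
        if len(set(ranks)) != len(ranks):
            raise ParameterError("alpha/beta priority ranks must be unique")

    def lookup(self, structure: str) -> float:
        for e in self.entries:
            if e.structure == structure:
                return e.ab
        return self.default_ab

    def voxel_map(self, structures: Sequence[StructureMask], shape: tuple) -> np.ndarray:
        """Per-voxel alpha/beta array; highest-priority structure wins."""
        ab = np.full(shape, float(self.default_ab))
        by_name = {s.name: s for s in structures}
        # apply lowest priority first so higher priorities overwrite
        for entry in sorted(self.entries, key=lambda e: -e.priority):
            mask = by_name.get(entry.structure)
            if mask is None:
                warnings.warn(
                    f"alpha/beta entry for {entry.structure!r} has no matching "
                    "structure; skipped",
                    stacklevel=2,
                )
                continue
            ab[mask.mask] = entry.ab
        return ab


@dataclass(frozen=True)
class DoseScalingFactor:
    """Static multiplier in (0, 1] modelling partial tissue recovery.

    ``structure`` restricts the scaling to one structure; ``None`` means the
    whole course.
    """

    value: float = 1.0
    structure: str | None = None

    def __post_init__(self):
        if not (0.0 < self.value <= 1.0):
            raise ParameterError(f"dose scaling factor must be in (0, 1], got {self.value}")


def eqd2_forward(total_dose, n_fractions: int, alpha_beta: float):
    """EQD2 of ``total_dose`` Gy in ``n_fractions``; scalar or array."""
    if alpha_beta <= 0:
        raise ParameterError(f"alpha/beta must be > 0, got {alpha_beta}")
    if int(n_fractions) != n_fractions or n_fractions < 1:
        raise ParameterError("n_fractions must be a positive integer")
    D = np.asarray(total_dose, dtype=float)
    if np.any(D < 0):
        raise ParameterError("total_dose must be >= 0")
    out = D * (D / n_fractions + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if np.isscalar(total_dose) else out


def eqd2_inverse(target_eqd2, n_fractions: int, alpha_beta: float):
    """Physical dose in ``n_fractions`` equieffective to ``target_eqd2``.

    The unique non-negative root of ``D^2/n + ab*D - E*(2+ab) = 0``:
    ``D = (n/2) * (-ab + sqrt(ab^2 + 4*E*(2+ab)/n))``.
    """
    if alpha_beta <= 0:
        raise ParameterError(f"alpha/beta must be > 0, got {alpha_beta}")
    if int(n_fractions) != n_fractions or n_fractions < 1:
        raise ParameterError("n_fractions must be a positive integer")
    E = np.asarray(target_eqd2, dtype=float)
    if np.any(E < 0):
        raise ParameterError("target EQD2 must be >= 0")
    n = float(n_fractions)
    D = (n / 2.0) * (
        -alpha_beta + np.sqrt(alpha_beta**2 + 4.0 * E * (2.0 + alpha_beta) / n)
    )
    D = np.maximum(D, 0.0)  # guard tiny negative round-off at E = 0
    return float(D) if np.isscalar(target_eqd2) else D


def eqd2_convert_grid(
    dose: DoseGrid,
    scheme: FractionationScheme,
    ab_map: AlphaBetaMap,
    structures: Sequence[StructureMask] = (),
) -> DoseGrid:
    """Voxel-wise EQD2 conversion of a physical dose grid.

    Per-voxel dose per fraction is ``voxel dose / n_fractions`` (uniform
    fractionation across the course). Each voxel's alpha/beta comes from the
    highest-priority structure containing it, else the map's default.
    """
    if dose.dose_kind is not DoseKind.PHYSICAL:
        raise ContractError("eqd2_convert_grid expects a PHYSICAL dose grid")
    for s in structures:
        if not s.geometry.same_as(dose.geometry):
            raise GeometryError(f"structure {s.name!r} is not on the dose geometry")
    ab = ab_map.voxel_map(structures, dose.geometry.shape)
    D = dose.values
    vals = D * (D / scheme.n_fractions + ab) / (2.0 + ab)
    return dose.with_values(vals, dose_kind=DoseKind.EQD2)


def apply_dsf(
    eqd2: DoseGrid,
    dsf: DoseScalingFactor,
    scope_mask: StructureMask | None = None,
) -> DoseGrid:
    """Scale an EQD2 grid by a dose scaling factor, optionally within a mask."""
    if eqd2.dose_kind is not DoseKind.EQD2:
        raise ContractError("apply_dsf operates on EQD2 grids (Fig-2 ordering)")
    if scope_mask is not None and not scope_mask.geometry.same_as(eqd2.geometry):
        raise GeometryError("scope mask geometry differs from dose geometry")
    vals = eqd2.values.copy()
    if scope_mask is None:
        vals *= dsf.value
    else:
        vals[scope_mask.mask] *= dsf.value
    return eqd2.with_values(vals)


def sum_eqd2(grids: Iterable[DoseGrid]) -> DoseGrid:
    """Voxel-wise sum of EQD2 grids sharing one geometry."""
    grids = list(grids)
    if not grids:
        raise ParameterError("sum_eqd2 requires at least one grid")
    ref = grids[0]
    total = np.zeros(ref.geometry.shape)
    for g in grids:
        if g.dose_kind is not DoseKind.EQD2:
            raise ContractError("sum_eqd2 requires all grids tagged EQD2")
        if not g.geometry.same_as(ref.geometry):
            raise GeometryError("sum_eqd2 requires a shared geometry")
        total += g.values
    return DoseGrid(
        geometry=ref.geometry, values=total, dose_kind=DoseKind.EQD2, course_id="sum"
    )


@dataclass(frozen=True)
class FeasibilityResult:
    """Point-dose budget for a new plan at one evaluation point.

    ``budget_B = max(constraint_A - prior_P, 0)`` in EQD2 Gy; ``allowed_total``
    is the physical dose in ``n_fractions`` whose EQD2 equals the budget.
    """

    constraint_A: float
    prior_P: float
    budget_B: float
    allowed_per_fraction: float
    allowed_total: float
    alpha_beta: float
    n_fractions: int


def point_dose_feasibility(
    A: float,
    P: float,
    scheme: FractionationScheme,
    alpha_beta: float,
) -> FeasibilityResult:
    """Remaining allowable dose at a point given constraint ``A`` and prior ``P``."""
    if A < 0 or P < 0:
        raise ParameterError("constraint and prior EQD2 must be >= 0")
    B = max(A - P, 0.0)
    total = eqd2_inverse(B, scheme.n_fractions, alpha_beta)
    return FeasibilityResult(
        constraint_A=float(A),
        prior_P=float(P),
        budget_B=B,
        allowed_per_fraction=total / scheme.n_fractions,
        allowed_total=total,
        alpha_beta=float(alpha_beta),
        n_fractions=scheme.n_fractions,
    )


WORKSHEET_INPUT_COLUMNS = ["oar", "constraint_A_eqd2", "prior_P_eqd2", "n_fractions", "alpha_beta"]
WORKSHEET_OUTPUT_COLUMNS = ["budget_B_eqd2", "allowed_per_fraction_Gy", "allowed_total_Gy"]


def fill_worksheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Fill the calculated columns of a point-dose worksheet.

    The user supplies one row per OAR with columns
    ``oar, constraint_A_eqd2, prior_P_eqd2, n_fractions, alpha_beta``; the
    calculated columns ``budget_B_eqd2, allowed_per_fraction_Gy,
    allowed_total_Gy`` are (re)computed and returned in a new frame.
    """
    missing = [c for c in WORKSHEET_INPUT_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParameterError(f"worksheet is missing input columns: {missing}")
    out = sheet.copy()
    results = [
        point_dose_feasibility(
            float(row.constraint_A_eqd2),
            float(row.prior_P_eqd2),
            FractionationScheme(int(row.n_fractions)),
            float(row.alpha_beta),
        )
        for row in sheet.itertuples()
    ]
    out["budget_B_eqd2"] = [r.budget_B for r in results]
    out["allowed_per_fraction_Gy"] = [r.allowed_per_fraction for r in results]
    out["allowed_total_Gy"] = [r.allowed_total for r in results]
    return out
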