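"""Cumulative DVH curves, dose metrics, constraint scorecards and reports.

Metrics follow the usual clinical definitions: Dmax / Dmean are the max /
mean over the structure; D_cc(x) is the minimum dose within the hottest
``x`` cm^3 (so D0.01cc is the near-maximum point dose); D_pct(x) the minimum
dose within the hottest ``x`` % of the volume; V_Gy(x) the percent of the
volume receiving at least ``x`` Gy. The D_cc estimator accumulates whole
voxel volumes without sub-voxel interpolation — conservative and exactly
reproducible.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, StructureNotFoundError
from .grid import DoseGrid, StructureMask

__all__ = [
    "Constraint",
    "DVHCurve",
    "ScorecardRow",
    "Scorecard",
    "compute_dvh",
    "metric_dmax",
    "metric_dmean",
    "metric_d_cc",
    "metric_d_pct",
    "metric_v_gy",
    "evaluate_metric",
    "evaluate_scorecard",
    "render_report",
]

_METRIC_RE = re.compile(
    r"^(DMAX|DMEAN|D([0-9.]+)CC|D([0-9.]+)%|V([0-9.]+)GY)$", re.IGNORECASE
)


@dataclass(frozen=True)
class Constraint:
    """One cumulative dose constraint on a named structure.

    ``metric`` is a compact spec string: ``DMAX``, ``DMEAN``, ``D0.01CC``,
    ``D2%`` or ``V50GY``. ``limit`` is in EQD2 Gy for dose metrics and in
    percent volume for V_Gy metrics.
    """

    structure: str
    metric: str
    limit: float
    alpha_beta: float = 3.0

    def __post_init__(self):
        if self.limit < 0:
            raise ParameterError("constraint limit must be >= 0")
        m = _METRIC_RE.match(self.metric.strip())
        if not m:
            raise ParameterError(
                f"unrecognized metric {self.metric!r} "
                "(expected DMAX, DMEAN, D<x>CC, D<x>%, or V<x>GY)"
            )
        object.__setattr__(self, "metric", self.metric.strip().upper())


@dataclass
class DVHCurve:
    """Cumulative DVH: percent of structure volume receiving >= each dose."""

    structure: str
    dose_bins: np.ndarray          # uniform bin edges, Gy
    cumulative_volume_pct: np.ndarray

    def volume_at_dose(self, dose: float) -> float:
        """Percent volume receiving at least ``dose`` Gy.

        Between bin edges the next edge's value is used (a lower bound on
        the true volume, consistent with the curve being non-increasing).
        """
        i = int(np.searchsorted(self.dose_bins, dose, side="left"))
        i = max(0, min(i, len(self.cumulative_volume_pct) - 1))
        return float(self.cumulative_volume_pct[i])


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if not mask.geometry.same_as(dose.geometry):
        raise ParameterError(f"mask {mask.name!r} not on the dose geometry")
    if not mask.mask.any():
        raise ParameterError(f"structure {mask.name!r} is empty")
    return dose.values[mask.mask]


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative dose-volume histogram of ``mask`` on ``dose``.

    Bins are uniform from 0 to just past the structure max; the curve starts
    at 100 % at 0 Gy and ends at 0 % above the max dose.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    doses = _masked_doses(dose, mask)
    n_bins = int(np.ceil(doses.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # percent of voxels with dose >= each edge (equal voxel volumes)
    pct = np.array([(doses >= e).mean() * 100.0 for e in edges])
    return DVHCurve(structure=mask.name, dose_bins=edges, cumulative_volume_pct=pct)


def metric_dmax(dose: DoseGrid, mask: StructureMask) -> float:
    return float(_masked_doses(dose, mask).max())


def metric_dmean(dose: DoseGrid, mask: StructureMask) -> float:
    return float(_masked_doses(dose, mask).mean())


def metric_d_cc(dose: DoseGrid, mask: StructureMask, x_cc: float) -> float:
    """Minimum dose within the hottest ``x_cc`` cm^3 of the structure.

    Voxel doses are sorted descending and whole voxel volumes accumulated;
    the dose of the voxel at which the running volume first reaches ``x_cc``
    is returned. If the structure is smaller than ``x_cc`` the minimum
    structure dose is returned with a warning.
    """
    if x_cc <= 0:
        raise ParameterError("x_cc must be > 0")
    doses = np.sort(_masked_doses(dose, mask))[::-1]
    vox_cc = mask.geometry.voxel_volume_cc
    total = len(doses) * vox_cc
    if total < x_cc:
        warnings.warn(
            f"structure {mask.name!r} volume {total:.3f} cc < {x_cc} cc; "
            "returning minimum structure dose",
            stacklevel=2,
        )
        return float(doses[-1])
    k = int(np.ceil(x_cc / vox_cc))  # voxels needed to reach x_cc
    return float(doses[k - 1])


def metric_d_pct(dose: DoseGrid, mask: StructureMask, x_pct: float) -> float:
    """Minimum dose within the hottest ``x_pct`` percent of the volume."""
    if not (0 < x_pct <= 100):
        raise ParameterError("x_pct must be in (0, 100]")
    doses = np.sort(_masked_doses(dose, mask))[::-1]
    k = max(1, int(np.ceil(len(doses) * x_pct / 100.0)))
    return float(doses[k - 1])


def metric_v_gy(dose: DoseGrid, mask: StructureMask, x_gy: float) -> float:
    """Percent of structure volume receiving at least ``x_gy`` Gy."""
    if x_gy < 0:
        raise ParameterError("x_gy must be >= 0")
    doses = _masked_doses(dose, mask)
    return float((doses >= x_gy).mean() * 100.0)


def evaluate_metric(dose: DoseGrid, mask: StructureMask, metric: str) -> float:
    """Dispatch a compact metric string to its estimator."""
    m = _METRIC_RE.match(metric.strip())
    if not m:
        raise ParameterError(f"unrecognized metric {metric!r}")
    token = metric.strip().upper()
    if token == "DMAX":
        return metric_dmax(dose, mask)
    if token == "DMEAN":
        return metric_dmean(dose, mask)
    if m.group(2) is not None:
        return metric_d_cc(dose, mask, float(m.group(2)))
    if m.group(3) is not None:
        return metric_d_pct(dose, mask, float(m.group(3)))
    return metric_v_gy(dose, mask, float(m.group(4)))


@dataclass(frozen=True)
class ScorecardRow:
    structure: str
    metric: str
    achieved: float
    limit: float
    status: str          # "PASS" | "FAIL"
    margin: float        # limit - achieved


@dataclass
class Scorecard:
    rows: list[ScorecardRow] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(r.status == "PASS" for r in self.rows)

    def to_records(self) -> list[dict]:
        return [vars(r) | {} for r in self.rows]


def evaluate_scorecard(
    summed: DoseGrid,
    masks: Sequence[StructureMask],
    constraints: Sequence[Constraint],
) -> Scorecard:
    """Evaluate each cumulative constraint on the summed EQD2 distribution.

    PASS at exact equality: the limit is a "<=" constraint.
    """
    by_name = {m.name: m for m in masks}
    rows = []
    for c in constraints:
        mask = by_name.get(c.structure)
        if mask is None:
            raise StructureNotFoundError(c.structure, list(by_name))
        achieved = evaluate_metric(summed, mask, c.metric)
        status = "PASS" if achieved <= c.limit else "FAIL"
        rows.append(
            ScorecardRow(
                structure=c.structure,
                metric=c.metric,
                achieved=achieved,
                limit=c.limit,
                status=status,
                margin=c.limit - achieved,
            )
        )
    return Scorecard(rows=rows)


REPORT_SCHEMA = "redose-report/1"


def render_report(
    accum,
    scorecard: Scorecard | None,
    dvhs: Sequence[DVHCurve],
    case_log: dict | None,
    out_dir: str | Path,
    timestamp: str = "",
) -> dict:
    """Write the dose-sum report: report.json, report.md, dvh.csv, dvh.png.

    Content is deterministic given the inputs; any timestamp is isolated to
    the single ``generated_at`` field. Returns the report dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema": REPORT_SCHEMA,
        "generated_at": timestamp,
        "provenance": accum.provenance if accum is not None else [],
        "dose_summary": {},
        "scorecard": [],
        "notices": [],
    }
    if accum is not None:
        report["dose_summary"] = {
            "summed_eqd2_max_gy": float(accum.summed_eqd2.max()),
            "n_courses": len(accum.per_course_eqd2),
        }
    if scorecard is None or not scorecard.rows:
        report["notices"].append("no constraints evaluated")
    else:
        report["scorecard"] = scorecard.to_records()
    report["dvh_structures"] = [d.structure for d in dvhs]

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    # dvh.csv: long format
    frames = [
        pd.DataFrame(
            {
                "structure": d.structure,
                "dose_gy": d.dose_bins,
                "volume_pct": d.cumulative_volume_pct,
            }
        )
        for d in dvhs
    ]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(out_dir / "dvh.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    for d in dvhs:
        ax.plot(d.dose_bins, d.cumulative_volume_pct, label=d.structure)
    ax.set_xlabel("EQD2 dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_title("Cumulative DVH")
    if dvhs:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "dvh.png", dpi=100)
    plt.close(fig)

    # human-readable summary
    lines = ["# Cumulative dose report", ""]
    if case_log:
        lines += [f"Case: {case_log.get('case_id', '?')}", ""]
    if accum is not None:
        lines += [
            f"Courses accumulated: {report['dose_summary'].get('n_courses', 0)}",
            f"Summed EQD2 max: {report['dose_summary'].get('summed_eqd2_max_gy', 0):.2f} Gy",
            "",
        ]
    if report["scorecard"]:
        lines.append("| structure | metric | achieved | limit | status | margin |")
        lines.append("|---|---|---|---|---|---|")
        for r in report["scorecard"]:
            lines.append(
                f"| {r['structure']} | {r['metric']} | {r['achieved']:.2f} | "
                f"{r['limit']:.2f} | {r['status']} | {r['margin']:.2f} |"
            )
    else:
        lines.append("*no constraints evaluated*")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    return report
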