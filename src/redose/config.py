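"""Run configuration: alpha/beta table, scaling factors, constraints, knobs.

The institutional tables (tissue recovery factors, alpha/beta ratios,
cumulative OAR constraints) are site policy, so they are external config
rather than shipped defaults; the only built-in default is alpha/beta = 3 Gy
for unlisted tissue. Unknown keys are rejected so typos cannot silently
drop a constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dvh import Constraint
from .errors import ParameterError
from .radiobiology import AlphaBetaEntry, AlphaBetaMap, DoseScalingFactor

__all__ = ["RunConfig", "load_config"]

_KNOWN_KEYS = {
    "alpha_beta",
    "default_ab",
    "dsf",
    "constraints",
    "dvh_bin_width",
    "near_margin_mm",
    "n_structures",
    "output_dir",
    "verbosity",
}


@dataclass
class RunConfig:
    ab_map: AlphaBetaMap = field(default_factory=AlphaBetaMap)
    dsf_entries: list[dict] = field(default_factory=list)  # {course, structure?, value}
    constraints: list[Constraint] = field(default_factory=list)
    dvh_bin_width: float = 0.1
    near_margin_mm: float = 20.0
    n_structures: int = 3
    output_dir: str = "out"
    verbosity: str = "info"

    def __post_init__(self):
        if self.dvh_bin_width <= 0:
            raise ParameterError("dvh_bin_width must be > 0")
        if self.near_margin_mm < 0:
            raise ParameterError("near_margin_mm must be >= 0")
        if self.n_structures < 1:
            raise ParameterError("n_structures must be >= 1")

    def dsf_for_course(self, course_id: str) -> DoseScalingFactor:
        for entry in self.dsf_entries:
            if entry.get("course") == course_id:
                return DoseScalingFactor(
                    value=float(entry["value"]), structure=entry.get("structure")
                )
        return DoseScalingFactor()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and schema-validate a YAML/JSON config file (None -> defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    entries = [
        AlphaBetaEntry(
            structure=e["structure"], ab=float(e["ab"]), priority=int(e["priority"])
        )
        for e in raw.get("alpha_beta", [])
    ]
    ab_map = AlphaBetaMap(
        entries=entries,
        default_ab=float(raw.get("default_ab", 3.0)),
        version=str(Path(path).name),
    )
    constraints = [
        Constraint(
            structure=c["structure"],
            metric=str(c["metric"]),
            limit=float(c["limit"]),
            alpha_beta=float(c.get("alpha_beta", ab_map.lookup(c["structure"]))),
        )
        for c in raw.get("constraints", [])
    ]
    for entry in raw.get("dsf", []):
        if "course" not in entry or "value" not in entry:
            raise ParameterError("each dsf entry needs 'course' and 'value'")
    return RunConfig(
        ab_map=ab_map,
        dsf_entries=list(raw.get("dsf", [])),
        constraints=constraints,
        dvh_bin_width=float(raw.get("dvh_bin_width", 0.1)),
        near_margin_mm=float(raw.get("near_margin_mm", 20.0)),
        n_structures=int(raw.get("n_structures", 3)),
        output_dir=str(raw.get("output_dir", "out")),
        verbosity=str(raw.get("verbosity", "info")),
    )
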