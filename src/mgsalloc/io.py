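"""Data model, CSV I/O and validation for individual-level records.

Units are fixed package-wide: centimetres for every length and distance,
milligrams for every dry weight. They are deliberately not configurable —
a silent unit mismatch between penis length and inter-individual distance
would corrupt every mating-group size downstream.

Missing organ weights are represented as ``None`` (empty CSV cell), never
imputed or zero-filled; they trigger exclusion in the analysis table, not
removal from the geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

#: Canonical column order of the individuals CSV dialect.
CSV_COLUMNS = [
    "id",
    "shell_id",
    "x_cm",
    "y_cm",
    "operculum_radius_cm",
    "penis_length_cm",
    "operculum_weight_mg",
    "testis_sv_weight_mg",
    "penis_weight_mg",
    "ovary_weight_mg",
]

#: Organ weights required for an individual to enter the analysis table.
REQUIRED_ORGANS = ("testis_sv_weight", "penis_weight", "ovary_weight")

INCLUSION_RULES = ("both_roles_isolated", "either_role_isolated")
DISTANCE_MODES = ("center", "operculum_edge")


@dataclass(frozen=True)
class IndividualRecord:
    """One barnacle: position on its shell, penis length, organ dry weights.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    shell_id : str
        Substrate shell the individual settled on. Shells are spatially
        independent; coordinates are per-shell 2-D Cartesian (cm).
    x, y : float
        Operculum-centre coordinates on the shell plane, cm.
    penis_length : float
        Resting penis length, cm (> 0).
    operculum_weight : float
        Operculum dry weight, mg (> 0); the body-size index.
    operculum_radius : float, default 0
        Operculum radius, cm; used only in ``operculum_edge`` distance mode.
    testis_sv_weight, penis_weight, ovary_weight : float or None
        Organ dry weights, mg (>= 0); ``None`` means the organ was lost
        or not weighed.
    """

    id: str
    shell_id: str
    x: float
    y: float
    penis_length: float
    operculum_weight: float
    operculum_radius: float = 0.0
    testis_sv_weight: float | None = None
    penis_weight: float | None = None
    ovary_weight: float | None = None

    def has_all_organs(self) -> bool:
        return all(getattr(self, o) is not None for o in REQUIRED_ORGANS)


@dataclass
class StudyConfig:
    """Analysis-stage configuration.

    elongation_factor
        Penis reach as a multiple of resting penis length (dimensionless,
        > 0). Default 1.82, the elongation rate measured in the congener
        *Balanus glandula* on a wave-protected shore.
    inclusion_rule
        ``both_roles_isolated`` (default): exclude an individual only when
        it has no potential partner in either role (MGSm = MGSf = 1).
        ``either_role_isolated``: exclude when isolated in at least one role.
    distance_mode
        ``center`` (default): Euclidean distance between operculum centres.
        ``operculum_edge``: centre distance minus both radii, floored at 0.
    seed
        Master seed for any randomness in a run.
    out_dir
        Output directory for pipeline artefacts (optional).
    """

    elongation_factor: float = 1.82
    inclusion_rule: str = "both_roles_isolated"
    distance_mode: str = "center"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (self.elongation_factor > 0):
            raise ValueError("elongation_factor must be > 0")
        if self.inclusion_rule not in INCLUSION_RULES:
            raise ValueError(f"inclusion_rule must be one of {INCLUSION_RULES}")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(f"distance_mode must be one of {DISTANCE_MODES}")


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from a flat YAML key-value file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a flat mapping")
    known = {f for f in StudyConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    return StudyConfig(**{k: v for k, v in data.items() if k in known})


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    """One named validation failure: which record, which field, what rule."""

    id: str
    field: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "all records valid"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  {v.id}: {v.field}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def _finite(x: float | None) -> bool:
    return x is not None and math.isfinite(x)


def validate_records(records: Iterable[IndividualRecord]) -> ValidationReport:
    """Check every record against the data-model invariants.

    Reporting only: never raises. A valid dataset yields an empty report;
    every invalid record contributes at least one violation naming the
    record id and offending field.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for rec in records:
        add = report.violations.append
        if rec.id in seen:
            add(Violation(rec.id, "id", "duplicate id"))
        seen.add(rec.id)
        if not rec.shell_id:
            add(Violation(rec.id, "shell_id", "empty shell_id"))
        for coord in ("x", "y"):
            if not _finite(getattr(rec, coord)):
                add(Violation(rec.id, coord, "non-finite coordinate"))
        if not _finite(rec.penis_length) or rec.penis_length <= 0:
            add(Violation(rec.id, "penis_length", "must be finite and > 0"))
        if not _finite(rec.operculum_weight) or rec.operculum_weight <= 0:
            add(Violation(rec.id, "operculum_weight", "must be finite and > 0"))
        if not _finite(rec.operculum_radius) or rec.operculum_radius < 0:
            add(Violation(rec.id, "operculum_radius", "must be finite and >= 0"))
        for organ in REQUIRED_ORGANS:
            w = getattr(rec, organ)
            if w is None:
                continue
            if not math.isfinite(w) or w < 0:
                add(Violation(rec.id, organ, "must be finite and >= 0 when present"))
    return report


# ---------------------------------------------------------------------------
# CSV I/O

_FIELD_TO_COLUMN = {
    "id": "id",
    "shell_id": "shell_id",
    "x": "x_cm",
    "y": "y_cm",
    "operculum_radius": "operculum_radius_cm",
    "penis_length": "penis_length_cm",
    "operculum_weight": "operculum_weight_mg",
    "testis_sv_weight": "testis_sv_weight_mg",
    "penis_weight": "penis_weight_mg",
    "ovary_weight": "ovary_weight_mg",
}
_COLUMN_TO_FIELD = {v: k for k, v in _FIELD_TO_COLUMN.items()}
_OPTIONAL_COLUMNS = {
    "operculum_radius_cm",
    "testis_sv_weight_mg",
    "penis_weight_mg",
    "ovary_weight_mg",
}


def read_individuals(
    path: str | Path, config: StudyConfig | None = None
) -> list[IndividualRecord]:
    """Read and validate the individuals CSV.

    Empty cells in organ-weight columns are preserved as missing
    (``None``), never coerced to zero. Unknown columns produce a warning
    and are ignored; structural problems (duplicate id, non-positive
    penis length, negative weight) are hard errors naming the offending
    row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: the default C float parser can be off by one ulp,
    # which would break the exact write/read round-trip contract
    df = pd.read_csv(
        path, dtype={"id": str, "shell_id": str}, float_precision="round_trip"
    )
    unknown = [c for c in df.columns if c not in _COLUMN_TO_FIELD]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {unknown}")
    missing_cols = [
        c for c in CSV_COLUMNS if c not in df.columns and c not in _OPTIONAL_COLUMNS
    ]
    if missing_cols:
        raise ValueError(f"{path.name}: missing required column(s) {missing_cols}")

    records: list[IndividualRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        def cell(col: str, default: float | None = None) -> float | None:
            if col not in df.columns:
                return default
            v = getattr(row, col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return default
            return float(v)

        rec = IndividualRecord(
            id=str(getattr(row, "id")),
            shell_id=str(getattr(row, "shell_id")),
            x=float(getattr(row, "x_cm")),
            y=float(getattr(row, "y_cm")),
            penis_length=float(getattr(row, "penis_length_cm")),
            operculum_weight=float(getattr(row, "operculum_weight_mg")),
            operculum_radius=cell("operculum_radius_cm", 0.0),
            testis_sv_weight=cell("testis_sv_weight_mg"),
            penis_weight=cell("penis_weight_mg"),
            ovary_weight=cell("ovary_weight_mg"),
        )
        row_report = validate_records([rec])
        dup = rec.id in {r.id for r in records}
        if dup:
            raise ValueError(f"{path.name}: row {i}: duplicate id {rec.id!r}")
        if not row_report.ok:
            v = row_report.violations[0]
            raise ValueError(f"{path.name}: row {i}: {v.field}: {v.message}")
        records.append(rec)
    return records


def write_individuals(
    records: Sequence[IndividualRecord], path: str | Path
) -> None:
    """Write records to the individuals CSV dialect.

    Round-trip contract: ``read_individuals(write_individuals(r)) == r``
    at full float precision. Missing organ weights become empty cells.
    """

    def fmt(v: float | str | None) -> str:
        if v is None:
            return ""
        if isinstance(v, str):
            return v
        # repr() is the shortest string that round-trips the float exactly
        return repr(float(v))

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                ",".join(fmt(getattr(rec, _COLUMN_TO_FIELD[c])) for c in CSV_COLUMNS)
                + "\n"
            )
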