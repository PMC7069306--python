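"""Reproductive-cost aggregates, sex-allocation index, analysis table.

Cost taxonomy (dry weights, mg): the ovary is the female *variable* cost,
testis + seminal vesicles the male *variable* cost, and the penis the male
*fixed* cost — a maintained structure rather than gamete investment. The
sex-allocation index is male variable cost over total variable cost; the
penis is deliberately excluded from both numerator and denominator and
enters only its own response model and the penis-fraction statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from mgsalloc.io import IndividualRecord, StudyConfig
from mgsalloc.graph import MGSRecord, apply_inclusion_filter

#: Columns of the analysis table, in output order.
TABLE_COLUMNS = [
    "id",
    "shell_id",
    "mgs_m",
    "mgs_f",
    "body_weight",
    "male_variable",
    "male_fixed",
    "female_variable",
    "sex_allocation",
]


def sex_allocation(male_variable: float, female_variable: float) -> float:
    """Male share of variable reproductive investment, in [0, 1].

    ``male_variable`` is testis + seminal-vesicle dry weight (mg),
    ``female_variable`` the ovary dry weight (mg). Endpoints are meaningful:
    0 is a pure female, 1 a pure male.
    """
    if male_variable < 0 or female_variable < 0:
        raise ValueError("organ weights must be >= 0")
    total = male_variable + female_variable
    if total <= 0:
        raise ValueError("sex allocation undefined: total variable investment is 0")
    return male_variable / total


def penis_fraction_of_male_output(penis_weight: float, male_variable: float) -> float:
    """Penis weight as a percentage of total male output.

    Total male output = male variable cost (testis + seminal vesicles)
    plus male fixed cost (penis). Returns a percentage.
    """
    if penis_weight < 0 or male_variable < 0:
        raise ValueError("weights must be >= 0")
    total = penis_weight + male_variable
    if total <= 0:
        raise ValueError("penis fraction undefined: total male output is 0")
    return 100.0 * penis_weight / total


@dataclass
class FilterCounts:
    """Audit trail of the inclusion filter."""

    n_input: int
    n_excluded_isolated: int
    n_excluded_missing_organ: int

    @property
    def n_analyzed(self) -> int:
        return self.n_input - self.n_excluded_isolated - self.n_excluded_missing_organ


def build_analysis_table(
    records: Sequence[IndividualRecord],
    mgs_records: Sequence[MGSRecord],
    config: StudyConfig,
    return_counts: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, FilterCounts]:
    """Merge records with their MGS values into the filtered analysis table.

    One row per *included* individual (isolation rule passed, all organ
    weights present), deterministically ordered by (shell_id, id).
    Raises if nothing survives filtering, reporting the exclusion counts.
    """
    flags = apply_inclusion_filter(records, mgs_records, config)
    flag_by_id = {f.id: f for f in flags}
    mgs_by_id = {m.id: m for m in mgs_records}

    counts = FilterCounts(
        n_input=len(records),
        n_excluded_isolated=sum(1 for f in flags if f.reason == "isolated"),
        n_excluded_missing_organ=sum(1 for f in flags if f.reason == "missing_organ"),
    )

    rows = []
    for rec in records:
        if not flag_by_id[rec.id].included:
            continue
        mgs = mgs_by_id[rec.id]
        rows.append(
            {
                "id": rec.id,
                "shell_id": rec.shell_id,
                "mgs_m": mgs.mgs_m,
                "mgs_f": mgs.mgs_f,
                "body_weight": rec.operculum_weight,
                "male_variable": rec.testis_sv_weight,
                "male_fixed": rec.penis_weight,
                "female_variable": rec.ovary_weight,
                "sex_allocation": sex_allocation(rec.testis_sv_weight, rec.ovary_weight),
            }
        )
    if not rows:
        raise ValueError(
            "analysis table is empty: "
            f"{counts.n_input} input, {counts.n_excluded_isolated} excluded as "
            f"isolated, {counts.n_excluded_missing_organ} excluded for missing "
            "organ weights, 0 included"
        )
    table = (
        pd.DataFrame(rows, columns=TABLE_COLUMNS)
        .sort_values(["shell_id", "id"], kind="mergesort")
        .reset_index(drop=True)
    )
    if return_counts:
        return table, counts
    return table
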