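"""Directed penis-reach graph per shell, MGS counting, inclusion filter.

The central geometric object: for every ordered within-shell pair (i, j),
there is a directed edge i -> j (i can inseminate j) iff the gap between
the two individuals is at most i's penis reach, where reach is the
elongation factor (default 1.82) times resting penis length. The graph is
generally asymmetric because penis lengths differ.

Mating group size in the male role, MGSm(i) = out-degree(i) + 1, counts
the potential sperm recipients including the focal animal itself; in the
female role, MGSf(i) = in-degree(i) + 1 counts potential donors plus self.

The graph is always built on *all* individuals: excluding an animal from
the statistical analysis (lost organ, isolation) never removes it from
its neighbours' mating groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mgsalloc.io import IndividualRecord, StudyConfig


@dataclass
class MatingGraph:
    """Per-shell directed donor -> recipient reach graph.

    ``nodes`` maps shell_id to the ordered list of individual ids on that
    shell; ``edges`` maps shell_id to the set of (donor_id, recipient_id)
    pairs. No self-edges; no cross-shell edges.
    """

    nodes: dict[str, list[str]] = field(default_factory=dict)
    edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges.values())

    def out_degree(self, shell_id: str, node: str) -> int:
        return sum(1 for d, _ in self.edges[shell_id] if d == node)

    def in_degree(self, shell_id: str, node: str) -> int:
        return sum(1 for _, r in self.edges[shell_id] if r == node)

    def write_edge_list(self, path: str | Path) -> None:
        """Dump ``shell_id,donor_id,recipient_id`` lines (sorted, with header)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("shell_id,donor_id,recipient_id\n")
            for shell_id in sorted(self.edges):
                for donor, recip in sorted(self.edges[shell_id]):
                    fh.write(f"{shell_id},{donor},{recip}\n")


@dataclass(frozen=True)
class MGSRecord:
    """Mating-group sizes of one individual (each >= 1, self included)."""

    id: str
    shell_id: str
    mgs_m: int
    mgs_f: int


def pairwise_gap(
    a: IndividualRecord, b: IndividualRecord, config: StudyConfig
) -> float:
    """Gap between two individuals on the same shell, cm.

    ``center`` mode: Euclidean distance between operculum centres.
    ``operculum_edge`` mode: centre distance minus both operculum radii,
    floored at 0 for touching or overlapping opercula. Symmetric in (a, b).
    """
    if a.shell_id != b.shell_id:
        raise ValueError(
            f"pairwise_gap: {a.id} (shell {a.shell_id}) and {b.id} "
            f"(shell {b.shell_id}) are on different shells"
        )
    d = math.hypot(a.x - b.x, a.y - b.y)
    if config.distance_mode == "operculum_edge":
        return max(0.0, d - a.operculum_radius - b.operculum_radius)
    return d


def reach_distance(a: IndividualRecord, config: StudyConfig) -> float:
    """Distance a's penis can reach, cm: elongation_factor x penis length."""
    return config.elongation_factor * a.penis_length


def build_mating_graph(
    records: Sequence[IndividualRecord], config: StudyConfig
) -> MatingGraph:
    """Build the directed reach graph over all individuals, shell by shell.

    Edge rule (inclusive threshold): i -> j iff gap(i, j) <= reach(i).
    A tie — partner exactly at full penis extension — counts as reachable.
    """
    graph = MatingGraph()
    by_shell: dict[str, list[IndividualRecord]] = {}
    for rec in records:
        by_shell.setdefault(rec.shell_id, []).append(rec)
    for shell_id, members in by_shell.items():
        graph.nodes[shell_id] = [m.id for m in members]
        edges: set[tuple[str, str]] = set()
        for i in members:
            reach_i = reach_distance(i, config)
            for j in members:
                if i.id == j.id:
                    continue
                if pairwise_gap(i, j, config) <= reach_i:
                    edges.add((i.id, j.id))
        graph.edges[shell_id] = edges
    return graph


def compute_mgs(graph: MatingGraph) -> list[MGSRecord]:
    """MGSm = out-degree + 1, MGSf = in-degree + 1 for every node."""
    out: list[MGSRecord] = []
    for shell_id, node_ids in graph.nodes.items():
        outdeg = {n: 0 for n in node_ids}
        indeg = {n: 0 for n in node_ids}
        for donor, recip in graph.edges[shell_id]:
            outdeg[donor] += 1
            indeg[recip] += 1
        for n in node_ids:
            out.append(
                MGSRecord(id=n, shell_id=shell_id, mgs_m=outdeg[n] + 1, mgs_f=indeg[n] + 1)
            )
    return out


@dataclass(frozen=True)
class InclusionFlag:
    id: str
    included: bool
    reason: str | None  # None | "isolated" | "missing_organ"


def apply_inclusion_filter(
    records: Sequence[IndividualRecord],
    mgs_records: Iterable[MGSRecord],
    config: StudyConfig,
) -> list[InclusionFlag]:
    """Flag which individuals enter the analysis table.

    Exclusion fires when the isolation rule holds (default
    ``both_roles_isolated``: MGSm = 1 AND MGSf = 1, i.e. no potential
    mating partner in either role) or when any required organ weight
    (testis+seminal vesicles, penis, ovary) is missing. Filtering is an
    analysis-table event only: the graph was built on everyone, so
    neighbours' MGS values are unaffected.
    """
    mgs_by_id: Mapping[str, MGSRecord] = {m.id: m for m in mgs_records}
    flags: list[InclusionFlag] = []
    for rec in records:
        try:
            mgs = mgs_by_id[rec.id]
        except KeyError:
            raise ValueError(f"no MGS record for individual {rec.id!r}") from None
        if config.inclusion_rule == "both_roles_isolated":
            isolated = mgs.mgs_m == 1 and mgs.mgs_f == 1
        else:  # either_role_isolated
            isolated = mgs.mgs_m == 1 or mgs.mgs_f == 1
        if isolated:
            flags.append(InclusionFlag(rec.id, False, "isolated"))
        elif not rec.has_all_organs():
            flags.append(InclusionFlag(rec.id, False, "missing_organ"))
        else:
            flags.append(InclusionFlag(rec.id, True, None))
    return flags


def write_mgs_csv(
    mgs_records: Sequence[MGSRecord],
    flags: Sequence[InclusionFlag],
    path: str | Path,
) -> None:
    """Write ``id,shell_id,mgs_m,mgs_f,included,exclusion_reason``."""
    flag_by_id = {f.id: f for f in flags}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id,shell_id,mgs_m,mgs_f,included,exclusion_reason\n")
        for m in sorted(mgs_records, key=lambda m: (m.shell_id, m.id)):
            f = flag_by_id[m.id]
            reason = f.reason or ""
            fh.write(
                f"{m.id},{m.shell_id},{m.mgs_m},{m.mgs_f},{str(f.included).lower()},{reason}\n"
            )
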