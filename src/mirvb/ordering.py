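"""Partial orderings of expression stages.

A *stage* is a named group of observations treated as replicates of one
latent expression state.  Stages are partially ordered by a parent relation
forming a DAG; a stage with no parents is an *initial* stage and receives a
vague prior instead of propagating from predecessors.

Three builders cover the standard study designs for staged samples:

* grouped-ordered (G-O): one stage per stage label, labels chained in their
  declared order, optional branch labels attached to a declared parent label;
* individual-ordered (I-O): one stage per sample, each sample preceded by
  every sample of the immediately preceding label;
* individual-reference (I-R): one stage per sample, every non-reference
  sample preceded by all reference-label samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "PartialOrder",
    "validate_order",
    "build_grouped_ordered",
    "build_individual_ordered",
    "build_individual_reference",
    "read_sample_table",
]


@dataclass(frozen=True)
class PartialOrder:
    """A DAG of stages with per-stage observation membership.

    Parameters
    ----------
    stages
        Stage identifiers (opaque, case-sensitive strings).
    parents
        Map from stage to its set of parent stages.
    members
        Map from stage to the observation (sample) identifiers assigned to
        it.  Every observation must belong to exactly one stage.
    """

    stages: tuple[str, ...]
    parents: Mapping[str, frozenset[str]]
    members: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        parents = {s: frozenset(self.parents.get(s, frozenset())) for s in self.stages}
        for s, p in self.parents.items():
            if s not in parents:  # keep unknown keys visible to validate_order
                parents[s] = frozenset(p)
        object.__setattr__(self, "parents", parents)
        object.__setattr__(
            self, "members", {s: tuple(m) for s, m in self.members.items()}
        )

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.stages)
        g.add_edges_from(self.edges())
        return g

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs, in deterministic order."""
        return [
            (p, s)
            for s in self.stages
            for p in sorted(self.parents.get(s, frozenset()))
        ]

    def initial_stages(self) -> list[str]:
        return [s for s in self.stages if not self.parents.get(s)]

    def topological_order(self) -> list[str]:
        """Stable topological sort (lexicographic tie-break on stage id)."""
        return list(nx.lexicographical_topological_sort(self.graph()))

    def stage_of(self) -> dict[str, str]:
        """Map each observation identifier to its stage."""
        return {obs: s for s in self.stages for obs in self.members.get(s, ())}

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": list(self.stages),
            "edges": [[p, c] for p, c in self.edges()],
            "members": {s: list(self.members.get(s, ())) for s in self.stages},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PartialOrder":
        payload = json.loads(Path(path).read_text())
        stages = list(payload["stages"])
        parents: dict[str, set[str]] = {s: set() for s in stages}
        for parent, child in payload.get("edges", []):
            parents.setdefault(child, set()).add(parent)
        members = {s: tuple(payload.get("members", {}).get(s, ())) for s in stages}
        return cls(tuple(stages), {s: frozenset(p) for s, p in parents.items()}, members)


def validate_order(order: PartialOrder) -> list[str]:
    """Check the PartialOrder invariants; return one message per violation.

    An empty list means the order is valid.  Violations are returned rather
    than raised so callers can report all problems at once.
    """
    violations: list[str] = []
    stage_set = set(order.stages)
    if len(stage_set) != len(order.stages):
        violations.append("duplicate stage identifiers")

    for s, ps in order.parents.items():
        if s not in stage_set:
            violations.append(f"parent map references unknown stage {s!r}")
        for p in ps:
            if p not in stage_set:
                violations.append(f"stage {s!r} has unknown parent {p!r}")

    g = order.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        violations.append(
            "cycle among stages: " + " -> ".join(str(e[0]) for e in cycle)
        )
    elif order.stages and not order.initial_stages():
        violations.append("no initial stage (every stage has parents)")

    seen: dict[str, str] = {}
    for s in order.stages:
        for obs in order.members.get(s, ()):
            if obs in seen:
                violations.append(
                    f"observation {obs!r} assigned to both {seen[obs]!r} and {s!r}"
                )
            seen[obs] = s
    return violations


def _check_labels(
    labels: Iterable[str], ordered_labels: Sequence[str], branches: Mapping[str, str]
) -> None:
    known = set(ordered_labels) | set(branches)
    for lab in labels:
        if lab not in known:
            raise ValueError(f"unknown stage label {lab!r}; declared labels: {sorted(known)}")
    for branch, parent in branches.items():
        if parent not in ordered_labels:
            raise ValueError(
                f"branch label {branch!r} attaches to unknown label {parent!r}"
            )


def _sample_pairs(sample_table: pd.DataFrame) -> list[tuple[str, str]]:
    if not {"sample_id", "stage"}.issubset(sample_table.columns):
        raise ValueError("sample table needs columns 'sample_id' and 'stage'")
    ids = sample_table["sample_id"].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate sample ids: {dups}")
    return list(zip(ids, sample_table["stage"].astype(str)))


def build_grouped_ordered(
    sample_table: pd.DataFrame,
    ordered_labels: Sequence[str],
    branches: Mapping[str, str] | None = None,
) -> PartialOrder:
    """Grouped-ordered (G-O) design: one stage per label.

    Samples sharing a label are grouped as replicates of one stage;
    consecutive labels (among those present) are chained parent -> child,
    and each branch label is attached to its declared parent label.

    Parameters
    ----------
    sample_table
        Rows of (sample_id, stage).
    ordered_labels
        The main-chain labels in their natural order.
    branches
        Optional branch labels mapped to the main-chain label they follow
        (e.g. ``{"PCL": "IA"}``).
    """
    branches = dict(branches or {})
    pairs = _sample_pairs(sample_table)
    _check_labels((lab for _, lab in pairs), ordered_labels, branches)

    present = [lab for lab in ordered_labels if any(l == lab for _, l in pairs)]
    present += [lab for lab in branches if any(l == lab for _, l in pairs)]
    parents: dict[str, frozenset[str]] = {}
    chain = [lab for lab in ordered_labels if lab in present]
    for prev, nxt in zip(chain, chain[1:]):
        parents[nxt] = frozenset({prev})
    for branch, parent in branches.items():
        if branch in present:
            if parent not in present:
                raise ValueError(
                    f"branch {branch!r} attaches to {parent!r}, which has no samples"
                )
            parents[branch] = frozenset({parent})
    members = {
        lab: tuple(sid for sid, l in pairs if l == lab) for lab in present
    }
    return PartialOrder(tuple(present), parents, members)


def build_individual_ordered(
    sample_table: pd.DataFrame,
    ordered_labels: Sequence[str],
    branches: Mapping[str, str] | None = None,
) -> PartialOrder:
    """Individual-ordered (I-O) design: one single-member stage per sample.

    Each sample is preceded by every sample of the immediately preceding
    label, and each branch-label sample by every sample of the branch's
    declared parent label.
    """
    branches = dict(branches or {})
    pairs = _sample_pairs(sample_table)
    _check_labels((lab for _, lab in pairs), ordered_labels, branches)

    by_label: dict[str, list[str]] = {}
    for sid, lab in pairs:
        by_label.setdefault(lab, []).append(sid)

    chain = [lab for lab in ordered_labels if lab in by_label]
    prev_label: dict[str, str | None] = {}
    for i, lab in enumerate(chain):
        prev_label[lab] = chain[i - 1] if i > 0 else None
    for branch, parent in branches.items():
        if branch in by_label:
            if parent not in by_label:
                raise ValueError(
                    f"branch {branch!r} attaches to {parent!r}, which has no samples"
                )
            prev_label[branch] = parent

    stages: list[str] = []
    parents: dict[str, frozenset[str]] = {}
    members: dict[str, tuple[str, ...]] = {}
    for lab in chain + [b for b in branches if b in by_label]:
        for sid in by_label[lab]:
            stages.append(sid)
            members[sid] = (sid,)
            prev = prev_label[lab]
            parents[sid] = frozenset(by_label[prev]) if prev else frozenset()
    return PartialOrder(tuple(stages), parents, members)


def build_individual_reference(
    sample_table: pd.DataFrame, reference_label: str
) -> PartialOrder:
    """Individual-reference (I-R) design: reference samples precede all others.

    One single-member stage per sample; every non-reference stage's parents
    are exactly the reference-label stages, which themselves have no parents.
    """
    pairs = _sample_pairs(sample_table)
    refs = [sid for sid, lab in pairs if lab == reference_label]
    if not refs:
        raise ValueError(f"reference label {reference_label!r} not present in table")
    ref_set = frozenset(refs)
    stages, parents, members = [], {}, {}
    for sid, lab in pairs:
        stages.append(sid)
        members[sid] = (sid,)
        parents[sid] = frozenset() if lab == reference_label else ref_set
    return PartialOrder(tuple(stages), parents, members)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample table with header columns (sample_id, stage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "stage"}.issubset(df.columns):
        raise ValueError(f"{path}: expected header columns 'sample_id' and 'stage'")
    return df
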