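"""Cross-species annotation consolidation over orthologue groups.

For every orthologue group the ontology positions of its member genes are
gathered (a gene with no explicit annotation contributes BIN 35, the
not-assigned sink) and a small decision tree classifies the group:

1. every position lies in the BIN 35 family → **UNKNOWN_FUNCTION**; the
   genes remain not-assigned and no task is generated;
2. exactly one unique position → **NO_INCONSISTENCIES**; nothing to do;
3. otherwise the not-assigned positions are dropped ("genes are deleted
   from BIN 35").  If a single informative BIN remains — and it is not a
   miscellaneous catch-all — the group is **UPGRADED_FROM_35**: a task list
   assigns that BIN to every member lacking it and deletes the BIN 35
   family codes;
4. otherwise the surviving BINs are pushed to their finest hierarchical
   level (strict ancestors of another member BIN are removed) and
   miscellaneous BINs are stripped (never to emptiness).  A single
   surviving non-miscellaneous BIN makes the group **UPGRADED_WITHIN_BIN**
   with the analogous task list;
5. anything else — genuinely conflicting annotations, or a consensus that
   is only a catch-all — is flagged **MANUAL_CHECK** for an expert.

Classification is pure: tasks are proposals in the batch-curation format
and are only applied through :func:`apply_tasks`, each application landing
in the store's history under an automation actor label.  Consolidation
never invents a BIN absent from the group's own annotations and never
assigns a not-assigned or miscellaneous BIN as an upgrade target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .ontology import BinCode, OntologyTree
from .orthology import OrthologueGroup, OrthologueGrouping
from .store import AnnotationStore, CurationAction, GeneKey, StoreError

NO_INCONSISTENCIES = "NO_INCONSISTENCIES"
UNKNOWN_FUNCTION = "UNKNOWN_FUNCTION"
UPGRADED_FROM_35 = "UPGRADED_FROM_35"
UPGRADED_WITHIN_BIN = "UPGRADED_WITHIN_BIN"
MANUAL_CHECK = "MANUAL_CHECK"

CATEGORIES = (
    NO_INCONSISTENCIES,
    UNKNOWN_FUNCTION,
    UPGRADED_FROM_35,
    UPGRADED_WITHIN_BIN,
    MANUAL_CHECK,
)

AUTOMATION_ACTOR = "consolidation"


class EmptyGroupError(ValueError):
    """A group with zero members resolvable in the store."""


@dataclass(frozen=True)
class GroupOutcome:
    group_id: str
    category: str
    resolved_bins: frozenset[BinCode]
    tasks: tuple[CurationAction, ...] = ()


@dataclass
class ConsolidationReport:
    grouping_type: str
    outcomes: list[GroupOutcome] = field(default_factory=list)
    skipped_groups: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {category: 0 for category in CATEGORIES}
        for outcome in self.outcomes:
            out[outcome.category] += 1
        return out

    @property
    def manual_check_groups(self) -> list[str]:
        return [o.group_id for o in self.outcomes if o.category == MANUAL_CHECK]

    @property
    def tasks(self) -> list[CurationAction]:
        return [task for outcome in self.outcomes for task in outcome.tasks]

    def to_dict(self) -> dict:
        return {
            "grouping_type": self.grouping_type,
            "counts": self.counts,
            "n_groups": len(self.outcomes),
            "n_tasks": len(self.tasks),
            "skipped_groups": list(self.skipped_groups),
            "manual_check_groups": self.manual_check_groups,
            "outcomes": [
                {
                    "group_id": o.group_id,
                    "category": o.category,
                    "resolved_bins": sorted(str(b) for b in o.resolved_bins),
                    "n_tasks": len(o.tasks),
                }
                for o in self.outcomes
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    def to_text(self) -> str:
        lines = [f"Consolidation report — grouping '{self.grouping_type}'"]
        counts = self.counts
        for category in CATEGORIES:
            lines.append(f"  {category:<20} {counts[category]}")
        lines.append(f"  groups processed     {len(self.outcomes)}")
        lines.append(f"  curation tasks       {len(self.tasks)}")
        if self.skipped_groups:
            lines.append(f"  skipped (no resolvable members): {', '.join(self.skipped_groups)}")
        if self.manual_check_groups:
            lines.append("  manual check needed: " + ", ".join(self.manual_check_groups))
        return "\n".join(lines)


# -- the decision tree ---------------------------------------------------

def gather_positions(
    group: OrthologueGroup, store: AnnotationStore, tree: OntologyTree
) -> frozenset[BinCode]:
    """Union of ontology positions over the group's resolvable members.

    Unannotated members contribute the implicit BIN 35; members of species
    not loaded in the store are skipped entirely.
    """
    members = group.resolvable_members(store)
    if not members:
        raise EmptyGroupError(f"group {group.group_id} has no members in the store")
    positions: set[BinCode] = set()
    for species, gene_id in members:
        positions |= store.annotations_of(tree, species, gene_id)
    return frozenset(positions)


def resolve_hierarchy(bins: Iterable[BinCode]) -> frozenset[BinCode]:
    """Keep only the finest-grained codes: drop every code that is a strict
    ancestor of another code in the set; incomparable codes are untouched."""
    pool = set(bins)
    return frozenset(
        a for a in pool if not any(a.is_ancestor_of(b) for b in pool if b != a)
    )


def strip_misc(bins: Iterable[BinCode], tree: OntologyTree) -> frozenset[BinCode]:
    """Remove miscellaneous catch-all codes — unless that would empty the
    set, in which case the input is returned unchanged (a group whose only
    consensus is a catch-all keeps it and is left for manual review)."""
    pool = frozenset(bins)
    kept = frozenset(b for b in pool if not tree.is_misc(b))
    return kept if kept else pool


def classify_group(
    group: OrthologueGroup, store: AnnotationStore, tree: OntologyTree
) -> GroupOutcome:
    """Run the consolidation decision tree on one orthologue group."""
    positions = gather_positions(group, store, tree)

    if all(code.is_unassigned for code in positions):
        return GroupOutcome(group.group_id, UNKNOWN_FUNCTION, frozenset({BinCode((35,))}))

    if len(positions) == 1:
        return GroupOutcome(group.group_id, NO_INCONSISTENCIES, positions)

    informative = frozenset(code for code in positions if not code.is_unassigned)
    if len(informative) == 1:
        (target,) = informative
        if not tree.is_misc(target):
            tasks = _upgrade_tasks(group, store, tree, target)
            return GroupOutcome(group.group_id, UPGRADED_FROM_35, informative, tasks)
        # sole informative BIN is a catch-all: no automatic upgrade target
        return GroupOutcome(group.group_id, MANUAL_CHECK, frozenset())

    refined = strip_misc(resolve_hierarchy(informative), tree)
    if len(refined) == 1:
        (target,) = refined
        if not tree.is_misc(target):
            tasks = _upgrade_tasks(group, store, tree, target)
            return GroupOutcome(group.group_id, UPGRADED_WITHIN_BIN, refined, tasks)

    return GroupOutcome(group.group_id, MANUAL_CHECK, frozenset())


def _upgrade_tasks(
    group: OrthologueGroup,
    store: AnnotationStore,
    tree: OntologyTree,
    target: BinCode,
) -> tuple[CurationAction, ...]:
    """Task list driving every member to exactly the resolved BIN.

    Each member gains the target (copy) if it lacks it, and loses every
    superseded explicit code — not-assigned family, ancestors of the
    target, miscellaneous codes stripped during refinement.  Because the
    group resolved to a single BIN, every member position other than the
    target was superseded.
    """
    tasks: list[CurationAction] = []
    for species, gene_id in group.resolvable_members(store):
        explicit = store.explicit_assignments(species, gene_id)
        comment = f"consolidated via orthologue group {group.group_id}"
        if target not in explicit:
            tasks.append(
                CurationAction(
                    action="copy", species=species, gene_id=gene_id,
                    to_bin=target, actor=AUTOMATION_ACTOR, comment=comment,
                )
            )
        for code in sorted(explicit):
            if code != target:
                tasks.append(
                    CurationAction(
                        action="delete", species=species, gene_id=gene_id,
                        from_bin=code, actor=AUTOMATION_ACTOR, comment=comment,
                    )
                )
    return tuple(tasks)


def run_consolidation(
    store: AnnotationStore,
    tree: OntologyTree,
    grouping: OrthologueGrouping,
) -> ConsolidationReport:
    """Classify every group of one grouping; apply nothing.

    Groups are processed in group-id order and tasks within a group are
    ordered by gene then BIN, so identical inputs yield identical reports.
    Groups whose members are all external are skipped and listed.
    """
    report = ConsolidationReport(grouping_type=grouping.grouping_type)
    for group in grouping.sorted_groups():
        try:
            report.outcomes.append(classify_group(group, store, tree))
        except EmptyGroupError:
            report.skipped_groups.append(group.group_id)
    return report


def apply_tasks(
    store: AnnotationStore,
    tree: OntologyTree,
    report: ConsolidationReport,
    actor: str = AUTOMATION_ACTOR,
) -> tuple[int, list[tuple[CurationAction, str]]]:
    """Apply a report's task list through the curation path.

    Each task lands in the history under ``actor``.  A task invalidated by
    interleaved curation (e.g. the assignment already exists or was already
    removed) is skipped and returned with its reason; the remainder is
    still applied.  Returns (number applied, skipped task list).
    """
    applied = 0
    skipped: list[tuple[CurationAction, str]] = []
    for task in report.tasks:
        task = CurationAction(
            action=task.action, species=task.species, gene_id=task.gene_id,
            from_bin=task.from_bin, to_bin=task.to_bin,
            actor=actor, comment=task.comment,
        )
        try:
            store.apply_action(tree, task)
            applied += 1
        except StoreError as exc:
            skipped.append((task, str(exc)))
    return applied, skipped
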