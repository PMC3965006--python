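"""Orthologue groupings, coverage statistics, and new-species inheritance.

An orthologue group clusters genes across (and within) species that are
inferred to descend from one ancestral gene; it is the only channel used
for transferring functional annotation between species.  Several typed
groupings can coexist (e.g. an orthoMCL-style clustering over many
proteomes next to a reciprocal-smallest-distance grouping over a few),
because orthology detection methods trade sensitivity for specificity.
Groups may contain members of species that are not loaded in the store —
these *external* members are retained for display/linking but contribute
nothing to statistics or annotation transfer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .ontology import BinCode, OntologyTree
from .store import AnnotationStore, CurationAction, GeneKey, StoreError


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologueGroup:
    """A typed cluster of (species, gene_id) members."""

    group_id: str
    grouping_type: str
    members: frozenset[GeneKey]

    def __post_init__(self) -> None:
        if not self.group_id:
            raise OrthologyError("empty group id")
        if not self.members:
            raise OrthologyError(f"group {self.group_id} has no members")

    def resolvable_members(self, store: AnnotationStore) -> list[GeneKey]:
        """Members whose gene is loaded in the store, sorted."""
        return sorted(m for m in self.members if m in store.genes)

    def external_members(self, store: AnnotationStore) -> list[GeneKey]:
        """Members of species/genes not loaded (display-only links)."""
        return sorted(m for m in self.members if m not in store.genes)


@dataclass
class OrthologueGrouping:
    grouping_type: str
    groups: dict[str, OrthologueGroup] = field(default_factory=dict)

    def add_group(self, group_id: str, members: Iterable[GeneKey]) -> OrthologueGroup:
        if group_id in self.groups:
            raise OrthologyError(f"duplicate group id {group_id}")
        group = OrthologueGroup(group_id, self.grouping_type, frozenset(members))
        self.groups[group_id] = group
        return group

    def sorted_groups(self) -> list[OrthologueGroup]:
        return [self.groups[gid] for gid in sorted(self.groups)]

    def member_genes(self) -> set[GeneKey]:
        out: set[GeneKey] = set()
        for group in self.groups.values():
            out |= group.members
        return out

    def groups_of(self, gene: GeneKey) -> list[OrthologueGroup]:
        return [g for g in self.sorted_groups() if gene in g.members]


GROUPING_COLUMNS = ("GROUP_ID", "SPECIES", "GENE_ID")


def load_grouping(path, grouping_type: str) -> OrthologueGrouping:
    """Read a GROUP_ID/SPECIES/GENE_ID TSV into a grouping.

    Duplicate (group, gene) lines collapse to one membership (set
    semantics); members of unloaded species are kept as external members.
    """
    staged: dict[str, set[GeneKey]] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in GROUPING_COLUMNS if not reader.fieldnames or c not in reader.fieldnames]
        if missing:
            raise OrthologyError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            gid = (row.get("GROUP_ID") or "").strip()
            species = (row.get("SPECIES") or "").strip()
            gene_id = (row.get("GENE_ID") or "").strip()
            if not gid:
                errors.append(f"line {lineno}: empty group id")
                continue
            if not species or not gene_id:
                errors.append(f"line {lineno}: empty species or gene id")
                continue
            staged.setdefault(gid, set()).add((species, gene_id))
    if errors:
        raise OrthologyError("; ".join(errors))
    grouping = OrthologueGrouping(grouping_type)
    for gid in sorted(staged):
        grouping.add_group(gid, staged[gid])
    return grouping


def write_grouping(grouping: OrthologueGrouping, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(GROUPING_COLUMNS)
        for group in grouping.sorted_groups():
            for species, gene_id in sorted(group.members):
                writer.writerow([group.group_id, species, gene_id])


# -- coverage statistics -------------------------------------------------

@dataclass(frozen=True)
class CoverageRow:
    """One species' orthologue-coverage line: totals and a rounded percent."""

    species: str
    total_genes: int
    genes_in_any_group: int

    @property
    def percent(self) -> int:
        return _round_half_up(100 * self.genes_in_any_group / self.total_genes)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def coverage_table(
    store: AnnotationStore,
    groupings: Sequence[OrthologueGrouping],
) -> list[CoverageRow]:
    """Per species: protein-coding gene total and the count (and nearest-
    integer percentage) of genes present in at least one orthologue group of
    *any* supplied grouping.  Species with zero registered genes are
    omitted.  A gene counts once however many groups contain it."""
    grouped: set[GeneKey] = set()
    for grouping in groupings:
        grouped |= grouping.member_genes()
    rows = []
    for species in store.species_list():
        total = sum(1 for key in store.genes if key[0] == species)
        if total == 0:
            continue
        in_any = sum(1 for key in store.genes if key[0] == species and key in grouped)
        rows.append(CoverageRow(species, total, in_any))
    return rows


def write_coverage_table(rows: Sequence[CoverageRow], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(("SPECIES", "TOTAL_GENES", "GENES_IN_ANY_GROUP", "PERCENT"))
        for row in rows:
            writer.writerow([row.species, row.total_genes, row.genes_in_any_group, row.percent])


# -- species onboarding --------------------------------------------------

def onboard_species(
    store: AnnotationStore,
    tree: OntologyTree,
    grouping: OrthologueGrouping,
    new_species: str,
    actor: str = "onboarding",
) -> list[CurationAction]:
    """Propose inherited annotations for a newly added species.

    For each registered gene of ``new_species`` that sits in an orthologue
    group, propose a ``copy`` for every informative (non-BIN-35) annotation
    held by any resolvable co-member.  Proposals never duplicate an
    existing assignment and never target the not-assigned family; nothing
    is applied here — application goes through the store's curation path.
    """
    proposals: list[CurationAction] = []
    seen: set[tuple[GeneKey, BinCode]] = set()
    for group in grouping.sorted_groups():
        newcomers = sorted(
            m for m in group.members if m[0] == new_species and m in store.genes
        )
        if not newcomers:
            continue
        donor_bins: set[BinCode] = set()
        for member in group.resolvable_members(store):
            if member[0] == new_species:
                continue
            donor_bins |= store.annotations_of(tree, *member)
        informative = sorted(b for b in donor_bins if not b.is_unassigned and b in tree)
        for gene in newcomers:
            existing = store.explicit_assignments(*gene)
            for code in informative:
                if code in existing or (gene, code) in seen:
                    continue
                seen.add((gene, code))
                proposals.append(
                    CurationAction(
                        action="copy",
                        species=gene[0],
                        gene_id=gene[1],
                        to_bin=code,
                        actor=actor,
                        comment=f"inherited via orthologue group {group.group_id}",
                    )
                )
    proposals.sort(key=lambda a: (a.species, a.gene_id, a.to_bin.segments))
    return proposals
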