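"""Deterministic synthetic fixtures with planted consolidation outcomes.

Real annotation databases are built from external gene models, mapping
files and orthology runs; none of that is needed to exercise the
consolidation logic.  This module generates, purely from a seed:

* a BIN ontology tree with realistic shape (top-level processes, sub-BINs,
  a not-assigned 35 family, ``.99``/"unspecified" catch-all children);
* a multi-species annotation store with decoy genes and microarray
  feature links;
* an orthologue grouping whose groups are *constructed to force* a chosen
  classification each — the planted truth — so classifier correctness can
  be asserted exactly, for any seed;
* a miniature coverage fixture carrying the exact published per-species
  gene totals and in-group counts as lightweight stub genes, so the
  coverage table arithmetic can be checked against the printed
  percentages.

Groups plant the minimal forcing configuration (2–4 members) plus
randomized decoys: duplicate members, explicit not-assigned assignments,
and occasional external (unloaded-species) members that must not change
the outcome.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .consolidation import (
    CATEGORIES,
    MANUAL_CHECK,
    NO_INCONSISTENCIES,
    UNKNOWN_FUNCTION,
    UPGRADED_FROM_35,
    UPGRADED_WITHIN_BIN,
)
from .ontology import BinCode, BinNode, OntologyTree, UNASSIGNED_BIN
from .orthology import OrthologueGrouping, write_grouping
from .store import AnnotationStore, CurationAction, GeneKey, write_feature_map, write_gene_models
from . import ontology as _ontology
from . import store as _store

SPECIES_POOL = ("potato", "tomato", "arabidopsis", "rice", "barley", "maize")
EXTERNAL_SPECIES = "grapevine"  # in groups but never loaded in the store

DEFAULT_MIX = {
    NO_INCONSISTENCIES: 10,
    UNKNOWN_FUNCTION: 10,
    UPGRADED_FROM_35: 10,
    UPGRADED_WITHIN_BIN: 10,
    MANUAL_CHECK: 10,
}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    n_species: int = 3
    genes_per_species: int = 30  # decoy genes outside any group
    tree_depth: int = 3
    branching: int = 3
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    misc_fraction: float = 0.3

    def validate(self) -> None:
        if any(count < 0 for count in self.category_mix.values()):
            raise FixtureError("category_mix counts must be >= 0")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise FixtureError(f"unknown categories in mix: {sorted(unknown)}")
        if self.category_mix.get(UPGRADED_WITHIN_BIN, 0) > 0 and self.tree_depth < 2:
            raise FixtureError("within-BIN upgrades need tree_depth >= 2")
        if self.n_species < 1 or self.n_species > len(SPECIES_POOL):
            raise FixtureError(f"n_species must be 1..{len(SPECIES_POOL)}")


@dataclass
class PlantedTruth:
    """Expected classification per generated group."""

    categories: dict[str, str] = field(default_factory=dict)
    resolved_bins: dict[str, Optional[BinCode]] = field(default_factory=dict)


def _fixed_clock():
    # injectable deterministic clock: fixture stores must be byte-stable
    counter = [0]

    def tick() -> str:
        counter[0] += 1
        return f"t{counter[0]:06d}"

    return tick


def _build_tree(rng: random.Random, spec: FixtureSpec) -> OntologyTree:
    nodes = [
        BinNode(UNASSIGNED_BIN, "not assigned"),
        BinNode(BinCode((35, 1)), "not assigned.unknown"),
        BinNode(BinCode((35, 2)), "not assigned.no ontology"),
    ]
    n_top = max(6, spec.branching * 2)
    for top in range(1, n_top + 1):
        if top == 35:
            continue
        nodes.append(BinNode(BinCode((top,)), f"process {top}"))
        prefix = (top,)
        _grow(rng, nodes, prefix, depth=1, spec=spec)
    return OntologyTree(nodes, source_labels=[f"synthetic-seed-{spec.seed}"])


def _grow(rng: random.Random, nodes: list, prefix: tuple, depth: int, spec: FixtureSpec) -> None:
    if depth >= spec.tree_depth:
        return
    n_children = rng.randint(1, spec.branching)
    for child in range(1, n_children + 1):
        code = BinCode(prefix + (child,))
        nodes.append(BinNode(code, f"process {'.'.join(map(str, code.segments))}"))
        _grow(rng, nodes, code.segments, depth + 1, spec)
    if rng.random() < spec.misc_fraction:
        nodes.append(BinNode(BinCode(prefix + (99,)), "unspecified"))


def _informative_codes(tree: OntologyTree) -> list[BinCode]:
    return [
        node.code
        for node in tree
        if not node.is_unassigned and not node.is_misc
    ]


def _misc_codes(tree: OntologyTree) -> list[BinCode]:
    return [node.code for node in tree if node.is_misc and not node.is_unassigned]


def make_fixture(
    spec: FixtureSpec,
) -> tuple[OntologyTree, AnnotationStore, OrthologueGrouping, PlantedTruth]:
    """Generate (tree, store, grouping, truth); pure in ``spec.seed``."""
    spec.validate()
    rng = random.Random(spec.seed)
    tree = _build_tree(rng, spec)
    store = AnnotationStore(clock=_fixed_clock())
    species = list(SPECIES_POOL[: spec.n_species])

    informative = _informative_codes(tree)
    misc = _misc_codes(tree)
    deep = [c for c in informative if c.depth >= 2]
    unassigned_family = [UNASSIGNED_BIN, BinCode((35, 1)), BinCode((35, 2))]
    if not deep and spec.category_mix.get(UPGRADED_WITHIN_BIN, 0) > 0:
        raise FixtureError("tree has no informative sub-BIN for within-BIN upgrades")

    counter = [0]

    def new_gene(sp: str) -> GeneKey:
        counter[0] += 1
        gene_id = f"{sp[:2]}nib_{counter[0]:05d}"
        store.register_gene(sp, gene_id, description=f"synthetic gene {counter[0]}")
        return (sp, gene_id)

    def assign(gene: GeneKey, code: BinCode) -> None:
        store.apply_action(
            tree,
            CurationAction(
                action="assign", species=gene[0], gene_id=gene[1],
                to_bin=code, actor="fixture", comment="planted",
            ),
        )

    # decoy genes outside any group, with 0-2 random annotations
    for sp in species:
        for _ in range(spec.genes_per_species):
            gene = new_gene(sp)
            for _ in range(rng.randint(0, 2)):
                code = rng.choice(informative)
                if code not in store.explicit_assignments(*gene):
                    assign(gene, code)

    # a small feature map over early decoy genes (platform-level exports)
    gene_keys = sorted(store.genes)
    for idx, gene in enumerate(gene_keys[: min(10, len(gene_keys))]):
        store.link_feature("chip1", f"feat_{idx:03d}", *gene)
        if idx % 3 == 0 and len(gene_keys) > idx + 1:  # many-to-many links
            store.link_feature("chip1", f"feat_{idx:03d}", *gene_keys[idx + 1])

    # planted groups, category order shuffled so ids carry no signal
    planted: list[str] = []
    for category, count in spec.category_mix.items():
        planted.extend([category] * count)
    rng.shuffle(planted)

    grouping = OrthologueGrouping("synthetic-clustering")
    truth = PlantedTruth()
    for index, category in enumerate(planted, start=1):
        group_id = f"OG{index:04d}"
        members = _plant_group(rng, category, species, tree, informative, misc, deep,
                               unassigned_family, new_gene, assign, truth, group_id)
        grouping.add_group(group_id, members)
    return tree, store, grouping, truth


def _plant_group(
    rng, category, species, tree, informative, misc, deep,
    unassigned_family, new_gene, assign, truth: PlantedTruth, group_id: str,
) -> set[GeneKey]:
    members: set[GeneKey] = set()

    def member(sp=None) -> GeneKey:
        gene = new_gene(sp or rng.choice(species))
        members.add(gene)
        return gene

    resolved: Optional[BinCode] = None
    if category == NO_INCONSISTENCIES:
        target = rng.choice(informative)
        for _ in range(rng.randint(2, 4)):
            assign(member(), target)
        resolved = target
    elif category == UNKNOWN_FUNCTION:
        for _ in range(rng.randint(2, 4)):
            gene = member()
            if rng.random() < 0.5:  # explicit 35-family, else implicit
                assign(gene, rng.choice(unassigned_family))
        resolved = UNASSIGNED_BIN
    elif category == UPGRADED_FROM_35:
        target = rng.choice(informative)
        for _ in range(rng.randint(1, 2)):
            assign(member(), target)
        for _ in range(rng.randint(1, 3)):
            gene = member()
            if rng.random() < 0.5:
                assign(gene, rng.choice(unassigned_family))
        resolved = target
    elif category == UPGRADED_WITHIN_BIN:
        target = rng.choice(deep)
        if misc and rng.random() < 0.4:
            # catch-all variant: a misc sibling is stripped in refinement
            blocker = rng.choice([m for m in misc if not m.is_ancestor_of(target)])
        else:
            blocker = target.parent
        assign(member(), blocker)
        assign(member(), target)
        if rng.random() < 0.4:
            member()  # an implicitly not-assigned member; still within-BIN
        resolved = target
    elif category == MANUAL_CHECK:
        first, second = _incomparable_pair(rng, informative)
        assign(member(), first)
        assign(member(), second)
        if rng.random() < 0.3:
            member()  # extra not-assigned member does not rescue the conflict
    else:  # pragma: no cover
        raise FixtureError(f"unknown category {category}")

    if rng.random() < 0.3:  # external member: display-only, must not matter
        members.add((EXTERNAL_SPECIES, f"gv_{group_id}"))

    truth.categories[group_id] = category
    truth.resolved_bins[group_id] = resolved
    return members


def _incomparable_pair(rng: random.Random, informative) -> tuple[BinCode, BinCode]:
    while True:
        first, second = rng.sample(informative, 2)
        if not first.is_ancestor_of(second) and not second.is_ancestor_of(first):
            return first, second


def write_fixture_files(tree, store, grouping, truth, out_dir) -> None:
    """Write all fixture inputs (and the truth table) as TSVs."""
    import csv
    import os

    os.makedirs(out_dir, exist_ok=True)
    _ontology.write_ontology_tsv(tree, os.path.join(out_dir, "ontology.tsv"))
    write_gene_models(store, os.path.join(out_dir, "gene_models.tsv"))
    write_feature_map(store, os.path.join(out_dir, "feature_map.tsv"))
    write_grouping(grouping, os.path.join(out_dir, "grouping.tsv"))
    with open(os.path.join(out_dir, "assignments.tsv"), "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(("SPECIES", "GENE_ID", "BINCODE"))
        for species, gene_id, code in sorted(
            store.assignment_relation(), key=lambda t: (t[0], t[1], t[2].segments)
        ):
            writer.writerow([species, gene_id, str(code)])
    with open(os.path.join(out_dir, "planted_truth.tsv"), "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(("GROUP_ID", "CATEGORY", "RESOLVED_BIN"))
        for gid in sorted(truth.categories):
            code = truth.resolved_bins.get(gid)
            writer.writerow([gid, truth.categories[gid], str(code) if code else ""])


# -- published coverage arithmetic ---------------------------------------

# Per-species protein-coding gene totals and in-any-orthologue-group counts
# as published for the four founding species; potato gene groups partition
# by originating source (gene models and Unigene sets merged under one
# identifier namespace).
COVERAGE_COUNTS = {
    "arabidopsis": (27416, 23446),
    "tomato": (34732, 22186),
    "potato": (35609, 23882),
    "rice": (39045, 29183),
}

POTATO_SOURCE_PARTITION = {
    "TGC": 20809,   # tomato-genome-based gene groups
    "PGSC": 9509,   # potato genome sequencing consortium gene model
    "POCI": 2882,   # potato oligo chip initiative Unigene set
    "StGI": 2409,   # potato gene index Unigene set
}

_SPECIES_PREFIX = {"arabidopsis": "at", "tomato": "sl", "potato": "stnib", "rice": "os"}


def table1_fixture() -> tuple[AnnotationStore, OrthologueGrouping]:
    """Stub store + grouping reproducing the published coverage counts.

    Genes are count-only stubs (no sequences or descriptions): only the
    cardinalities matter for the coverage arithmetic.  Potato stubs carry
    their source partition so the merged-identifier total can be recounted.
    """
    store = AnnotationStore(clock=_fixed_clock())
    grouping = OrthologueGrouping("published-coverage")
    for sp, (total, in_group) in COVERAGE_COUNTS.items():
        prefix = _SPECIES_PREFIX[sp]
        sources = _potato_sources(total) if sp == "potato" else [""] * total
        genes = []
        for idx in range(total):
            gene_id = f"{prefix}_{idx:06d}"
            key = (sp, gene_id)
            # bulk path: bypass per-call validation, 137k stub inserts
            store.genes[key] = _store.GeneRecord(sp, gene_id, source=sources[idx])
            store._assignments[key] = set()
            genes.append(key)
        chunk = 1000
        for start in range(0, in_group, chunk):
            block = genes[start : min(start + chunk, in_group)]
            grouping.add_group(f"cov_{prefix}_{start // chunk:03d}", block)
    return store, grouping


def _potato_sources(total: int) -> list[str]:
    out: list[str] = []
    for source, count in POTATO_SOURCE_PARTITION.items():
        out.extend([source] * count)
    if len(out) != total:  # partition must tile the species exactly
        raise FixtureError("potato source partition does not sum to the species total")
    return out
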