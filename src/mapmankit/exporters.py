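"""Export writers for downstream high-throughput analysis tools.

Five dialects are produced, each deterministic (fixed sort orders, no
timestamps), so identical inputs give byte-identical files:

* **MapMan mapping file** — BINCODE/NAME/IDENTIFIER/DESCRIPTION/TYPE TSV,
  one row per (BIN, identifier) pair, identifiers lower-cased, TYPE ``T``
  for genes and ``M`` for microarray features; unannotated identifiers are
  emitted under the not-assigned BIN 35 so every identifier appears.
* **GMT** (gene matrix transposed, for GSEA) — one gene set per line:
  ``BINCODE_NAME``, description, then member identifiers.
* **SEGS** — the transpose of GMT: one identifier per line followed by all
  BIN codes it belongs to.
* **OBO** — one ``[Term]`` stanza per BIN under the ``GMM:`` namespace with
  a single ``is_a`` parent (the ontology is a tree, not a DAG).
* **generic** — four neutral TSVs mirroring the internal relations
  (ontology nodes, group↔gene, gene↔bin, feature↔gene); loading them back
  reconstructs those relations exactly.
"""

from __future__ import annotations

import csv
import os
from typing import Optional, Sequence

from .ontology import BinCode, BinNode, OntologyTree
from .orthology import OrthologueGrouping, load_grouping
from .store import AnnotationStore

TYPE_GENE = "T"
TYPE_FEATURE = "M"

MAPMAN_COLUMNS = ("BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION", "TYPE")


class ExportError(ValueError):
    pass


def _tsv_writer(handle):
    return csv.writer(handle, delimiter="\t", lineterminator="\n")


# -- target resolution ---------------------------------------------------

def _annotation_relation(
    store: AnnotationStore, tree: OntologyTree, target: str
) -> tuple[dict[str, frozenset[BinCode]], dict[str, str], str]:
    """identifier (lower-cased) → BIN set for a species or platform target.

    Also returns per-identifier descriptions and the identifier type flag.
    """
    if target in store.species_list():
        relation = {}
        descriptions = {}
        for rec in store.genes_of_species(target):
            ident = rec.gene_id.lower()
            relation[ident] = store.annotations_of(tree, rec.species, rec.gene_id)
            descriptions[ident] = rec.description
        return relation, descriptions, TYPE_GENE
    if target in store.platforms():
        relation = {}
        descriptions = {}
        for fid in store.features_of_platform(target):
            ident = fid.lower()
            relation[ident] = store.feature_annotations(tree, target, fid)
            parents = sorted(store.feature_genes(target, fid))
            descriptions[ident] = "; ".join(
                d for d in (store.genes[p].description for p in parents) if d
            )
        return relation, descriptions, TYPE_FEATURE
    raise ExportError(f"unknown export target {target!r} (not a species or platform)")


# -- MapMan mapping files ------------------------------------------------

def write_mapman(store: AnnotationStore, tree: OntologyTree, target: str, path) -> None:
    """Write a MapMan mapping file for one species or microarray platform.

    Rows are sorted by BIN code (numeric, segment-wise) then identifier;
    platform targets use feature→gene annotation inheritance.
    """
    relation, descriptions, type_flag = _annotation_relation(store, tree, target)
    rows = []
    for ident, bins in relation.items():
        for code in bins:
            rows.append((code.segments, str(code), ident))
    rows.sort()
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        writer.writerow(MAPMAN_COLUMNS)
        for _, code_text, ident in rows:
            node = tree.get(code_text)
            writer.writerow([code_text, node.name, ident, descriptions[ident], type_flag])


def read_mapman(path, tree: OntologyTree) -> dict[str, frozenset[BinCode]]:
    """Read a mapping file back into identifier → BIN-set form.

    ``read_mapman(write_mapman(...))`` reproduces the store's annotation
    relation for the target exactly.  Rows naming a BIN absent from the
    tree, or malformed rows, are reported together with line numbers.
    """
    relation: dict[str, set[BinCode]] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in ("BINCODE", "IDENTIFIER") if not reader.fieldnames or c not in reader.fieldnames]
        if missing:
            raise ExportError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                code = BinCode.parse(row["BINCODE"])
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if code not in tree:
                errors.append(f"line {lineno}: BIN {code} not in ontology")
                continue
            ident = (row["IDENTIFIER"] or "").strip().lower()
            if not ident:
                errors.append(f"line {lineno}: empty identifier")
                continue
            relation.setdefault(ident, set()).add(code)
    if errors:
        raise ExportError("; ".join(errors))
    return {ident: frozenset(bins) for ident, bins in relation.items()}


# -- GMT / SEGS ----------------------------------------------------------

def write_gmt(store: AnnotationStore, tree: OntologyTree, target: str, path) -> None:
    """Gene-matrix-transposed export: one BIN gene set per line
    (``BINCODE_NAME``, description, member identifiers)."""
    relation, _, _ = _annotation_relation(store, tree, target)
    by_bin: dict[BinCode, list[str]] = {}
    for ident in sorted(relation):
        for code in relation[ident]:
            by_bin.setdefault(code, []).append(ident)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        for code in sorted(by_bin):
            node = tree.get(code)
            set_name = f"{code}_{node.name}" if node.name else str(code)
            writer.writerow([set_name, node.description or node.name, *by_bin[code]])


def write_segs(store: AnnotationStore, tree: OntologyTree, target: str, path) -> None:
    """Transposed gene-set export: one identifier per line followed by every
    BIN code it is present in."""
    relation, _, _ = _annotation_relation(store, tree, target)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        for ident in sorted(relation):
            codes = sorted(relation[ident])
            writer.writerow([ident, *(str(c) for c in codes)])


def read_gmt_relation(path) -> set[tuple[str, str]]:
    """(BIN code, identifier) pairs of a GMT file (set names are CODE_NAME)."""
    pairs = set()
    with open(path, newline="", encoding="utf-8") as handle:
        for line in csv.reader(handle, delimiter="\t"):
            if not line:
                continue
            code = line[0].split("_", 1)[0]
            for ident in line[2:]:
                pairs.add((code, ident))
    return pairs


def read_segs_relation(path) -> set[tuple[str, str]]:
    """(BIN code, identifier) pairs of a SEGS file."""
    pairs = set()
    with open(path, newline="", encoding="utf-8") as handle:
        for line in csv.reader(handle, delimiter="\t"):
            if not line:
                continue
            ident = line[0]
            for code in line[1:]:
                pairs.add((code, ident))
    return pairs


# -- OBO -----------------------------------------------------------------

OBO_NAMESPACE = "GMM"


def write_obo(tree: OntologyTree, path, ontology_name: str = "mapman-bins") -> None:
    """Write the BIN tree as OBO ``[Term]`` stanzas.

    Ids are ``GMM:<bincode>``; each non-root term carries a single ``is_a``
    to its parent.  No date line is emitted so output is deterministic.
    """
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for code in tree.sorted_codes():
        node = tree.get(code)
        lines.append("[Term]")
        lines.append(f"id: {OBO_NAMESPACE}:{code}")
        lines.append(f"name: {node.name or str(code)}")
        if node.description:
            desc = node.description.replace("\\", "\\\\").replace('"', '\\"')
            lines.append(f'def: "{desc}" []')
        parent = code.parent
        if parent is not None:
            parent_node = tree.get(parent)
            lines.append(f"is_a: {OBO_NAMESPACE}:{parent} ! {parent_node.name or str(parent)}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines))


# -- generic relation export --------------------------------------------

GENERIC_FILES = {
    "ontology": "ontology.tsv",
    "groups": "orthologue_groups.tsv",
    "gene_bins": "gene_bins.tsv",
    "features": "feature_genes.tsv",
}


def write_generic(
    store: AnnotationStore,
    tree: OntologyTree,
    groupings: Sequence[OrthologueGrouping],
    out_dir,
) -> dict[str, str]:
    """Write the four neutral relation TSVs into ``out_dir``.

    Files: ontology nodes; orthologue-group membership (with grouping
    type); explicit gene↔BIN assignments (one row per assignment);
    feature↔gene links.  Returns the mapping of relation name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {key: os.path.join(out_dir, name) for key, name in GENERIC_FILES.items()}

    with open(paths["ontology"], "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        writer.writerow(("BINCODE", "NAME", "DESCRIPTION"))
        for node in tree:
            writer.writerow([str(node.code), node.name, node.description])

    with open(paths["groups"], "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        writer.writerow(("GROUPING_TYPE", "GROUP_ID", "SPECIES", "GENE_ID"))
        for grouping in sorted(groupings, key=lambda g: g.grouping_type):
            for group in grouping.sorted_groups():
                for species, gene_id in sorted(group.members):
                    writer.writerow([grouping.grouping_type, group.group_id, species, gene_id])

    with open(paths["gene_bins"], "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        writer.writerow(("SPECIES", "GENE_ID", "BINCODE"))
        for species, gene_id, code in sorted(
            store.assignment_relation(), key=lambda t: (t[0], t[1], t[2].segments)
        ):
            writer.writerow([species, gene_id, str(code)])

    with open(paths["features"], "w", newline="", encoding="utf-8") as handle:
        writer = _tsv_writer(handle)
        writer.writerow(("PLATFORM", "FEATURE_ID", "SPECIES", "GENE_ID"))
        for plat, fid, species, gene_id in sorted(store.feature_relation()):
            writer.writerow([plat, fid, species, gene_id])

    return paths


def read_generic(in_dir, clock=None) -> tuple[OntologyTree, AnnotationStore, list[OrthologueGrouping]]:
    """Reconstruct the relations written by :func:`write_generic`.

    Genes are registered on first sight from the relation files; gene
    metadata (short name, description, source) travels via the gene-model
    TSV, not the relation export.
    """
    paths = {key: os.path.join(in_dir, name) for key, name in GENERIC_FILES.items()}

    nodes = []
    with open(paths["ontology"], newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            nodes.append(BinNode(BinCode.parse(row["BINCODE"]), row["NAME"], row["DESCRIPTION"]))
    tree = OntologyTree(nodes, source_labels=["generic-export"])

    store = AnnotationStore(clock=clock)

    def ensure_gene(species: str, gene_id: str) -> None:
        if not store.has_gene(species, gene_id):
            store.register_gene(species, gene_id)

    with open(paths["gene_bins"], newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            ensure_gene(row["SPECIES"], row["GENE_ID"])
            store._assignments[(row["SPECIES"], row["GENE_ID"])].add(BinCode.parse(row["BINCODE"]))

    with open(paths["features"], newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            ensure_gene(row["SPECIES"], row["GENE_ID"])
            store.link_feature(row["PLATFORM"], row["FEATURE_ID"], row["SPECIES"], row["GENE_ID"])

    staged: dict[str, dict[str, set]] = {}
    with open(paths["groups"], newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            gtype = row["GROUPING_TYPE"]
            # group members may be external (species not loaded): no gene registration
            staged.setdefault(gtype, {}).setdefault(row["GROUP_ID"], set()).add(
                (row["SPECIES"], row["GENE_ID"])
            )
    groupings = []
    for gtype in sorted(staged):
        grouping = OrthologueGrouping(gtype)
        for gid in sorted(staged[gtype]):
            grouping.add_group(gid, staged[gtype][gid])
        groupings.append(grouping)

    return tree, store, groupings
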