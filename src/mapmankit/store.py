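"""Species, genes, gene→BIN assignments, microarray feature links, history.

The store is the system of record for functional annotation.  Its contract:

* a gene with zero explicit assignments is implicitly in BIN 35 — the
  not-assigned sink — so every gene always has at least one ontology
  position and consolidation input is total;
* every mutation is a validated curation action (assign/copy/move/delete)
  and appends exactly one record to an append-only history; a rejected
  action changes nothing and logs nothing (atomicity);
* microarray feature identifiers live apart from genes and *inherit* the
  annotations of their parental genes (many-to-many), which is how
  platform-level exports are produced;
* replaying the history against the initial state reconstructs the live
  assignment state (event sourcing), giving full traceability of who
  changed which annotation, when, and why.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

from .ontology import BinCode, CodeLike, OntologyTree, UNASSIGNED_BIN, as_code

GeneKey = tuple[str, str]  # (species, gene_id)

ACTIONS = ("assign", "copy", "move", "delete")


class StoreError(ValueError):
    """Base class for annotation-store failures."""


class UnknownGeneError(StoreError):
    pass


class DuplicateGeneError(StoreError):
    pass


class UnknownBinError(StoreError):
    pass


class DuplicateAssignmentError(StoreError):
    """Assigning an ontology annotation the gene already carries."""


class MissingAssignmentError(StoreError):
    """Deleting/moving an assignment the gene does not carry."""


class UnknownFeatureError(StoreError):
    pass


class BatchFileError(StoreError):
    def __init__(self, errors: Sequence[str]):
        super().__init__("; ".join(errors))
        self.errors = list(errors)


class ReplayError(StoreError):
    def __init__(self, sequence: int, message: str):
        super().__init__(f"history corrupt at sequence {sequence}: {message}")
        self.sequence = sequence


@dataclass(frozen=True)
class GeneRecord:
    species: str
    gene_id: str
    short_name: str = ""
    description: str = ""
    source: str = ""  # gene-model release tag, e.g. "TAIR9"

    @property
    def key(self) -> GeneKey:
        return (self.species, self.gene_id)


@dataclass(frozen=True)
class CurationAction:
    """One copy/move/delete (or bare assign) of a gene↔BIN link.

    * ``assign``/``copy`` need ``to_bin``;
    * ``move`` needs both ``from_bin`` and ``to_bin``;
    * ``delete`` needs ``from_bin``.
    """

    action: str
    species: str
    gene_id: str
    from_bin: Optional[BinCode] = None
    to_bin: Optional[BinCode] = None
    actor: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise StoreError(f"unknown curation action {self.action!r}")
        if self.action in ("assign", "copy", "move") and self.to_bin is None:
            raise StoreError(f"{self.action} requires a target BIN")
        if self.action in ("move", "delete") and self.from_bin is None:
            raise StoreError(f"{self.action} requires a source BIN")

    @property
    def gene(self) -> GeneKey:
        return (self.species, self.gene_id)


@dataclass(frozen=True)
class HistoryRecord:
    sequence: int
    timestamp: str
    actor: str
    action: str
    species: str
    gene_id: str
    from_bin: Optional[BinCode]
    to_bin: Optional[BinCode]
    comment: str = ""


def _default_clock() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


class AnnotationStore:
    """Mutable annotation database with an append-only curation history."""

    def __init__(self, clock: Optional[Callable[[], str]] = None) -> None:
        self.genes: dict[GeneKey, GeneRecord] = {}
        self._assignments: dict[GeneKey, set[BinCode]] = {}
        self._features: dict[tuple[str, str], set[GeneKey]] = {}
        self.history: list[HistoryRecord] = []
        self.clock = clock or _default_clock

    # -- genes -----------------------------------------------------------

    def register_gene(
        self,
        species: str,
        gene_id: str,
        short_name: str = "",
        description: str = "",
        source: str = "",
    ) -> "AnnotationStore":
        key = (species, gene_id)
        if key in self.genes:
            raise DuplicateGeneError(f"gene {gene_id} already registered for {species}")
        self.genes[key] = GeneRecord(species, gene_id, short_name, description, source)
        self._assignments[key] = set()
        return self

    def has_gene(self, species: str, gene_id: str) -> bool:
        return (species, gene_id) in self.genes

    def gene(self, species: str, gene_id: str) -> GeneRecord:
        try:
            return self.genes[(species, gene_id)]
        except KeyError:
            raise UnknownGeneError(f"unknown gene {gene_id} ({species})") from None

    def species_list(self) -> list[str]:
        return sorted({species for species, _ in self.genes})

    def genes_of_species(self, species: str) -> list[GeneRecord]:
        return [rec for key, rec in sorted(self.genes.items()) if key[0] == species]

    def find_genes(self, query: str, species: Optional[str] = None) -> list[GeneRecord]:
        """Case-insensitive substring search over id, short name, description."""
        needle = query.lower()
        hits = []
        for key in sorted(self.genes):
            rec = self.genes[key]
            if species is not None and rec.species != species:
                continue
            haystack = (rec.gene_id, rec.short_name, rec.description)
            if any(needle in text.lower() for text in haystack):
                hits.append(rec)
        return hits

    # -- assignments -----------------------------------------------------

    def explicit_assignments(self, species: str, gene_id: str) -> frozenset[BinCode]:
        key = (species, gene_id)
        if key not in self.genes:
            raise UnknownGeneError(f"unknown gene {gene_id} ({species})")
        return frozenset(self._assignments[key])

    def annotations_of(self, tree: OntologyTree, species: str, gene_id: str) -> frozenset[BinCode]:
        """Ontology positions of a gene; implicitly {35} when unannotated."""
        explicit = self.explicit_assignments(species, gene_id)
        if explicit:
            return explicit
        return frozenset({UNASSIGNED_BIN})

    def assignment_relation(self) -> set[tuple[str, str, BinCode]]:
        """All explicit (species, gene_id, bin) triples."""
        return {
            (species, gene_id, code)
            for (species, gene_id), bins in self._assignments.items()
            for code in bins
        }

    def apply_action(self, tree: OntologyTree, action: CurationAction) -> HistoryRecord:
        """Validate and apply one curation action; append one history record.

        A rejected action (already-annotated copy, delete of an absent
        assignment, unknown gene or BIN) raises and leaves both the
        assignment state and the history untouched.
        """
        key = action.gene
        if key not in self.genes:
            raise UnknownGeneError(f"unknown gene {action.gene_id} ({action.species})")
        for code in (action.from_bin, action.to_bin):
            if code is not None and code not in tree:
                raise UnknownBinError(f"BIN {code} not in ontology")
        bins = self._assignments[key]
        if action.action in ("assign", "copy", "move"):
            if action.to_bin in bins:
                raise DuplicateAssignmentError(
                    f"gene {action.gene_id} already annotated with BIN {action.to_bin}"
                )
        if action.action in ("move", "delete"):
            if action.from_bin not in bins:
                raise MissingAssignmentError(
                    f"gene {action.gene_id} not annotated with BIN {action.from_bin}"
                )
        # validation passed: mutate and log atomically
        if action.action in ("assign", "copy", "move"):
            bins.add(action.to_bin)
        if action.action in ("move", "delete"):
            bins.discard(action.from_bin)
        record = HistoryRecord(
            sequence=len(self.history) + 1,
            timestamp=self.clock(),
            actor=action.actor,
            action=action.action,
            species=action.species,
            gene_id=action.gene_id,
            from_bin=action.from_bin,
            to_bin=action.to_bin,
            comment=action.comment,
        )
        self.history.append(record)
        return record

    def apply_batch(self, tree: OntologyTree, actions: Iterable[CurationAction]) -> list[HistoryRecord]:
        return [self.apply_action(tree, action) for action in actions]

    # -- microarray features --------------------------------------------

    def link_feature(self, platform: str, feature_id: str, species: str, gene_id: str) -> "AnnotationStore":
        if (species, gene_id) not in self.genes:
            raise UnknownGeneError(f"unknown gene {gene_id} ({species})")
        self._features.setdefault((platform, feature_id), set()).add((species, gene_id))
        return self

    def has_feature(self, platform: str, feature_id: str) -> bool:
        return (platform, feature_id) in self._features

    def feature_genes(self, platform: str, feature_id: str) -> frozenset[GeneKey]:
        try:
            return frozenset(self._features[(platform, feature_id)])
        except KeyError:
            raise UnknownFeatureError(f"unknown feature {feature_id} ({platform})") from None

    def feature_annotations(self, tree: OntologyTree, platform: str, feature_id: str) -> frozenset[BinCode]:
        """Annotations inherited from every parental gene (set union)."""
        out: set[BinCode] = set()
        for species, gene_id in self.feature_genes(platform, feature_id):
            out |= self.annotations_of(tree, species, gene_id)
        return frozenset(out)

    def features_of_platform(self, platform: str) -> list[str]:
        return sorted(fid for plat, fid in self._features if plat == platform)

    def platforms(self) -> list[str]:
        return sorted({plat for plat, _ in self._features})

    def feature_relation(self) -> set[tuple[str, str, str, str]]:
        """All (platform, feature_id, species, gene_id) links."""
        return {
            (plat, fid, species, gene_id)
            for (plat, fid), genes in self._features.items()
            for species, gene_id in genes
        }

    # -- snapshots -------------------------------------------------------

    def clone(self, with_history: bool = True) -> "AnnotationStore":
        other = AnnotationStore(clock=self.clock)
        other.genes = dict(self.genes)
        other._assignments = {key: set(bins) for key, bins in self._assignments.items()}
        other._features = {key: set(genes) for key, genes in self._features.items()}
        if with_history:
            other.history = list(self.history)
        return other

    def same_assignment_state(self, other: "AnnotationStore") -> bool:
        return (
            set(self.genes) == set(other.genes)
            and self._assignments == other._assignments
            and self._features == other._features
        )


def replay(
    history: Sequence[HistoryRecord],
    initial: AnnotationStore,
    tree: OntologyTree,
) -> AnnotationStore:
    """Re-derive a store's assignment state from its curation history.

    ``replay(store.history, initial, tree)`` equals the live store that
    produced the history, and any prefix reproduces the corresponding
    intermediate snapshot.  A record that violates the store invariants
    raises :class:`ReplayError` naming the offending sequence number.
    """
    state = initial.clone(with_history=False)
    for record in history:
        action = CurationAction(
            action=record.action,
            species=record.species,
            gene_id=record.gene_id,
            from_bin=record.from_bin,
            to_bin=record.to_bin,
            actor=record.actor,
            comment=record.comment,
        )
        try:
            state.apply_action(tree, action)
        except StoreError as exc:
            raise ReplayError(record.sequence, str(exc)) from exc
    return state


# -- TSV interchange -----------------------------------------------------

GENE_MODEL_COLUMNS = ("SPECIES", "GENE_ID", "SHORT_NAME", "DESCRIPTION", "SOURCE")
FEATURE_MAP_COLUMNS = ("PLATFORM", "FEATURE_ID", "SPECIES", "GENE_ID")
BATCH_COLUMNS = ("ACTION", "SPECIES", "GENE_ID", "FROM_BIN", "TO_BIN", "AUTHOR", "COMMENT")
HISTORY_COLUMNS = (
    "SEQUENCE", "TIMESTAMP", "AUTHOR", "ACTION",
    "SPECIES", "GENE_ID", "FROM_BIN", "TO_BIN", "COMMENT",
)


def load_gene_models(store: AnnotationStore, path) -> AnnotationStore:
    """Register genes from a gene-model TSV (SPECIES, GENE_ID, SHORT_NAME,
    DESCRIPTION, SOURCE)."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _require(reader.fieldnames, ("SPECIES", "GENE_ID"), path)
        for row in reader:
            store.register_gene(
                row["SPECIES"],
                row["GENE_ID"],
                row.get("SHORT_NAME", "") or "",
                row.get("DESCRIPTION", "") or "",
                row.get("SOURCE", "") or "",
            )
    return store


def write_gene_models(store: AnnotationStore, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_MODEL_COLUMNS)
        for key in sorted(store.genes):
            rec = store.genes[key]
            writer.writerow([rec.species, rec.gene_id, rec.short_name, rec.description, rec.source])


def load_feature_map(store: AnnotationStore, path) -> AnnotationStore:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _require(reader.fieldnames, FEATURE_MAP_COLUMNS, path)
        for row in reader:
            store.link_feature(row["PLATFORM"], row["FEATURE_ID"], row["SPECIES"], row["GENE_ID"])
    return store


def write_feature_map(store: AnnotationStore, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_MAP_COLUMNS)
        for plat, fid, species, gene_id in sorted(store.feature_relation()):
            writer.writerow([plat, fid, species, gene_id])


def parse_batch_file(path) -> list[CurationAction]:
    """Parse a batch-curation TSV into validated actions, in file order.

    Columns: ACTION, SPECIES, GENE_ID, FROM_BIN, TO_BIN, AUTHOR, COMMENT.
    Malformed lines are collected with their line numbers and reported
    together; if any line is bad, *no* action is returned (all-or-nothing).
    """
    actions: list[CurationAction] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in ("ACTION", "SPECIES", "GENE_ID") if c not in reader.fieldnames]
        if missing:
            raise BatchFileError([f"{path}: missing column(s) {', '.join(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            verb = (row.get("ACTION") or "").strip().lower()
            try:
                if verb not in ACTIONS:
                    raise StoreError(f"unknown curation action {verb!r}")
                actions.append(
                    CurationAction(
                        action=verb,
                        species=(row.get("SPECIES") or "").strip(),
                        gene_id=(row.get("GENE_ID") or "").strip(),
                        from_bin=_opt_code(row.get("FROM_BIN")),
                        to_bin=_opt_code(row.get("TO_BIN")),
                        actor=(row.get("AUTHOR") or "").strip(),
                        comment=(row.get("COMMENT") or "").strip(),
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise BatchFileError(errors)
    return actions


def write_batch_file(actions: Sequence[CurationAction], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(BATCH_COLUMNS)
        for act in actions:
            writer.writerow([
                act.action, act.species, act.gene_id,
                str(act.from_bin) if act.from_bin else "",
                str(act.to_bin) if act.to_bin else "",
                act.actor, act.comment,
            ])


def write_history(store: AnnotationStore, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(HISTORY_COLUMNS)
        for rec in store.history:
            writer.writerow([
                rec.sequence, rec.timestamp, rec.actor, rec.action,
                rec.species, rec.gene_id,
                str(rec.from_bin) if rec.from_bin else "",
                str(rec.to_bin) if rec.to_bin else "",
                rec.comment,
            ])


def load_history(path) -> list[HistoryRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _require(reader.fieldnames, ("SEQUENCE", "ACTION", "SPECIES", "GENE_ID"), path)
        for row in reader:
            records.append(
                HistoryRecord(
                    sequence=int(row["SEQUENCE"]),
                    timestamp=row.get("TIMESTAMP", "") or "",
                    actor=row.get("AUTHOR", "") or "",
                    action=row["ACTION"],
                    species=row["SPECIES"],
                    gene_id=row["GENE_ID"],
                    from_bin=_opt_code(row.get("FROM_BIN")),
                    to_bin=_opt_code(row.get("TO_BIN")),
                    comment=row.get("COMMENT", "") or "",
                )
            )
    return records


def _opt_code(text: Optional[str]) -> Optional[BinCode]:
    text = (text or "").strip()
    return BinCode.parse(text) if text else None


def _require(fieldnames, required, path) -> None:
    missing = [c for c in required if not fieldnames or c not in fieldnames]
    if missing:
        raise StoreError(f"{path}: missing column(s) {', '.join(missing)}")
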