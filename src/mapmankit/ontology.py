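"""Hierarchical BIN ontology.

The MapMan ontology is a rooted forest of *BINs* — biological concepts
addressed by dot-separated numeric codes (``16.2.1`` is the first child of
``16.2``, itself the second child of top-level BIN ``16``).  Two families of
BINs carry special semantics throughout this package:

* the *not-assigned* family — every code whose first segment is 35.  It is
  the sink for genes whose function is unknown, not annotated, or not yet
  described, and is treated as one uniform subtree.
* *miscellaneous* BINs — catch-all children conventionally numbered ``.99``
  (or named "misc"/"unspecified"), holding assignments too vague for a
  specific sub-BIN.

Per-species mapping files historically diverged, so trees from several
sources can be merged; conflicts are resolved by input precedence and every
conflict is recorded, never silently overwritten.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Optional, Sequence, Union

UNASSIGNED_ROOT = 35
MISC_SEGMENT = 99

_MISC_NAME = re.compile(r"misc|unspecified", re.IGNORECASE)
_SEGMENT = re.compile(r"^[1-9][0-9]*$")


class OntologyError(ValueError):
    """Base class for ontology construction/curation failures."""


class BinCodeError(OntologyError):
    """Raised when a textual BIN code cannot be parsed."""


class DuplicateBinError(OntologyError):
    """Raised when a code is inserted twice into one tree."""


class OrphanBinError(OntologyError):
    """Raised when a node's parent code is absent from the tree."""


@total_ordering
@dataclass(frozen=True)
class BinCode:
    """A dot-separated numeric ontology address, e.g. ``16.2.1``.

    Codes are immutable and hashable; ordering is segment-wise numeric
    (so ``16.2`` < ``16.10`` even though ``"16.10" < "16.2"`` as text).
    """

    segments: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise BinCodeError("a BIN code needs at least one segment")
        for seg in self.segments:
            if not isinstance(seg, int) or seg < 1:
                raise BinCodeError(f"invalid BIN segment {seg!r}: must be a positive integer")

    @classmethod
    def parse(cls, text: str) -> "BinCode":
        """Parse canonical text (``"16.2.1"``) into a :class:`BinCode`.

        Rejects empty input, empty/non-numeric segments, zero or negative
        segments, and leading zeros; the error names the offending segment.
        """
        if not isinstance(text, str) or text == "":
            raise BinCodeError("empty BIN code")
        parts = text.split(".")
        segments = []
        for part in parts:
            if not _SEGMENT.match(part):
                raise BinCodeError(f"invalid BIN segment {part!r} in code {text!r}")
            segments.append(int(part))
        return cls(tuple(segments))

    def __str__(self) -> str:
        return ".".join(str(s) for s in self.segments)

    def __lt__(self, other: "BinCode") -> bool:
        return self.segments < other.segments

    @property
    def depth(self) -> int:
        return len(self.segments)

    @property
    def parent(self) -> Optional["BinCode"]:
        """The code one level up, or None at depth 1."""
        if len(self.segments) == 1:
            return None
        return BinCode(self.segments[:-1])

    def is_ancestor_of(self, other: "BinCode") -> bool:
        """True iff this code's segments are a strict prefix of ``other``'s."""
        return (
            len(self.segments) < len(other.segments)
            and other.segments[: len(self.segments)] == self.segments
        )

    @property
    def is_unassigned(self) -> bool:
        """True for the whole not-assigned subtree (35, 35.1, 35.2, ...)."""
        return self.segments[0] == UNASSIGNED_ROOT


CodeLike = Union[BinCode, str]


def as_code(code: CodeLike) -> BinCode:
    return code if isinstance(code, BinCode) else BinCode.parse(code)


def parse_bin_code(text: str) -> BinCode:
    """Module-level alias for :meth:`BinCode.parse`."""
    return BinCode.parse(text)


def is_ancestor(a: CodeLike, b: CodeLike) -> bool:
    """Strict-prefix hierarchy predicate: ``16.2`` is an ancestor of ``16.2.1``."""
    return as_code(a).is_ancestor_of(as_code(b))


def is_unassigned(code: CodeLike) -> bool:
    """Whether ``code`` lies in the not-assigned (BIN 35) subtree."""
    return as_code(code).is_unassigned


UNASSIGNED_BIN = BinCode((UNASSIGNED_ROOT,))

FLAG_UNASSIGNED = "unassigned-family"
FLAG_MISC = "miscellaneous"


@dataclass(frozen=True)
class BinNode:
    """One ontology concept: a code plus its human-readable labelling."""

    code: BinCode
    name: str = ""
    description: str = ""

    @property
    def is_unassigned(self) -> bool:
        return self.code.is_unassigned

    @property
    def is_misc(self) -> bool:
        """Catch-all nodes: last segment 99 or a 'misc'/'unspecified' name."""
        return self.code.segments[-1] == MISC_SEGMENT or bool(_MISC_NAME.search(self.name))

    @property
    def flags(self) -> frozenset:
        out = set()
        if self.is_unassigned:
            out.add(FLAG_UNASSIGNED)
        if self.is_misc:
            out.add(FLAG_MISC)
        return frozenset(out)


@dataclass(frozen=True)
class MergeConflict:
    """Record of a same-code/different-name collision during a merge."""

    code: BinCode
    kept_name: str
    discarded_name: str
    kept_source: str
    discarded_source: str


class OntologyTree:
    """A validated BIN hierarchy.

    Invariants maintained by every mutator:

    * codes are unique;
    * every node of depth > 1 has its parent present (no orphans);
    * the not-assigned sink (BIN 35) exists.
    """

    def __init__(
        self,
        nodes: Iterable[BinNode] = (),
        source_labels: Sequence[str] = (),
    ) -> None:
        self._nodes: dict[str, BinNode] = {}
        self.source_labels: list[str] = list(source_labels)
        self.merge_conflicts: list[MergeConflict] = []
        staged = list(nodes)
        seen = set()
        for node in staged:
            key = str(node.code)
            if key in seen:
                raise DuplicateBinError(f"duplicate BIN code {key}")
            seen.add(key)
        # Parents may appear after children in the input; stage then validate.
        for node in staged:
            self._nodes[str(node.code)] = node
        if str(UNASSIGNED_BIN) not in self._nodes:
            self._nodes[str(UNASSIGNED_BIN)] = BinNode(UNASSIGNED_BIN, "not assigned")
        self.validate()

    # -- queries ---------------------------------------------------------

    def __contains__(self, code: CodeLike) -> bool:
        return str(as_code(code)) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[BinNode]:
        for code in self.sorted_codes():
            yield self._nodes[str(code)]

    def get(self, code: CodeLike) -> BinNode:
        key = str(as_code(code))
        try:
            return self._nodes[key]
        except KeyError:
            raise OntologyError(f"BIN {key} not in ontology") from None

    def sorted_codes(self) -> list[BinCode]:
        """All codes in segment-wise numeric order."""
        return sorted(node.code for node in self._nodes.values())

    def children(self, code: CodeLike) -> list[BinNode]:
        parent = as_code(code)
        return [n for n in self if n.code.parent == parent]

    def is_misc(self, code: CodeLike) -> bool:
        """Miscellaneous test for a code, using its node name when present."""
        code = as_code(code)
        if str(code) in self._nodes:
            return self._nodes[str(code)].is_misc
        return code.segments[-1] == MISC_SEGMENT

    # -- mutation --------------------------------------------------------

    def add_bin(self, code: CodeLike, name: str, description: str = "") -> "OntologyTree":
        """Insert a new BIN; its parent must already exist.

        Mirrors manual ontology-tree curation: a new sub-BIN may take the
        next number in its series or any unused number.
        """
        code = as_code(code)
        key = str(code)
        if key in self._nodes:
            raise DuplicateBinError(f"BIN {key} already in use")
        parent = code.parent
        if parent is not None and str(parent) not in self._nodes:
            raise OrphanBinError(f"cannot add BIN {key}: parent {parent} absent")
        self._nodes[key] = BinNode(code, name, description)
        return self

    def validate(self) -> None:
        missing = []
        for node in self._nodes.values():
            parent = node.code.parent
            if parent is not None and str(parent) not in self._nodes:
                missing.append(str(parent))
        if missing:
            raise OrphanBinError(
                "orphaned BINs: missing parents " + ", ".join(sorted(set(missing)))
            )


def merge_ontologies(trees: Sequence[OntologyTree]) -> OntologyTree:
    """Union several trees; on name conflicts the earliest tree wins.

    Every same-code/different-name collision is recorded on the result's
    ``merge_conflicts`` — precedence resolves, but never silently.
    """
    if not trees:
        return OntologyTree()
    merged: dict[str, BinNode] = {}
    origin: dict[str, str] = {}
    conflicts: list[MergeConflict] = []
    labels: list[str] = []
    for idx, tree in enumerate(trees):
        label = "+".join(tree.source_labels) or f"input-{idx}"
        labels.extend(tree.source_labels or [label])
        for node in tree:
            key = str(node.code)
            if key not in merged:
                merged[key] = node
                origin[key] = label
            elif node.name != merged[key].name:
                conflicts.append(
                    MergeConflict(
                        code=node.code,
                        kept_name=merged[key].name,
                        discarded_name=node.name,
                        kept_source=origin[key],
                        discarded_source=label,
                    )
                )
    out = OntologyTree(merged.values(), source_labels=labels)
    out.merge_conflicts = conflicts
    return out


# -- TSV interchange -----------------------------------------------------

ONTOLOGY_COLUMNS = ("BINCODE", "NAME", "DESCRIPTION")


def read_ontology_tsv(path, source_label: Optional[str] = None) -> OntologyTree:
    """Load a tree from a BINCODE/NAME/DESCRIPTION TSV (header row required)."""
    nodes = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _require_columns(reader.fieldnames, ONTOLOGY_COLUMNS, path)
        for row in reader:
            nodes.append(
                BinNode(
                    BinCode.parse(row["BINCODE"]),
                    row.get("NAME", "") or "",
                    row.get("DESCRIPTION", "") or "",
                )
            )
    labels = [source_label] if source_label else [str(path)]
    return OntologyTree(nodes, source_labels=labels)


def write_ontology_tsv(tree: OntologyTree, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ONTOLOGY_COLUMNS)
        for node in tree:
            writer.writerow([str(node.code), node.name, node.description])


def apply_ontology_batch(tree: OntologyTree, path) -> OntologyTree:
    """Run an ontology-curation batch file (columns ACTION, BINCODE, NAME,
    DESCRIPTION; the only supported ACTION is ``add``)."""
    errors = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _require_columns(reader.fieldnames, ("ACTION", "BINCODE", "NAME"), path)
        for lineno, row in enumerate(reader, start=2):
            action = (row.get("ACTION") or "").strip().lower()
            if action != "add":
                errors.append(f"line {lineno}: unsupported ontology action {action!r}")
                continue
            try:
                tree.add_bin(row["BINCODE"], row.get("NAME", "") or "", row.get("DESCRIPTION", "") or "")
            except OntologyError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise OntologyError("; ".join(errors))
    return tree


def _require_columns(fieldnames, required, path) -> None:
    missing = [c for c in required if not fieldnames or c not in fieldnames]
    if missing:
        raise OntologyError(f"{path}: missing column(s) {', '.join(missing)}")
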