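# Methods

## Data model

**BIN codes.** A BIN code is an ordered tuple of positive integers,
rendered as dot-separated text (`16.2.1`).  Canonical text forbids leading
zeros and whitespace so codes are unambiguous dictionary keys across file
round-trips.  `depth` is the number of segments; the parent drops the last
segment; `a` is an ancestor of `b` iff `a`'s segments are a strict prefix
of `b`'s — segment-wise, so `16.2` is *not* an ancestor of `16.20.1`.
Ordering is segment-wise numeric (`16.2 < 16.10`).

**The tree.** An `OntologyTree` maps canonical code text to nodes (code,
name, description).  Invariants enforced on every mutation: unique codes,
no orphans (each node of depth > 1 has its parent present), and the
presence of the not-assigned sink BIN 35 (inserted with the default name
"not assigned" if an input lacks it).  The ontology is a tree, not a DAG:
one parent per node, no GO-style multiple inheritance.

**Special families.** The whole subtree rooted at 35 is the *not-assigned*
family: the container of unknown / not-annotated / not-yet-described
genes.  A node is *miscellaneous* when its last segment is 99 **or** its
name contains "misc" or "unspecified" (case-insensitive) — both
conventions occur in real mapping files, and the code-only rule alone
would miss named catch-alls.

**Merging.** Per-species mapping files diverge, so trees merge by input
precedence: the node set is the union; on a same-code/different-name
collision the earliest input's name is kept and a conflict record (code,
both names, both sources) is retained on the result.  Silent overwrites
are forbidden by design — a curator must be able to see what merging
discarded.

**Implicit BIN 35.** A gene with zero explicit assignments reports the
singleton {35} from `annotations_of`.  This makes consolidation input
total (every gene has at least one ontology position) and matches the
semantics of the not-assigned family.  Deleting a gene's last informative
BIN therefore files it under 35 implicitly rather than writing an explicit
35 row; the two states are indistinguishable at query and export level.

**History.** Every successful curation action (assign, copy, move,
delete) appends exactly one record — monotonically increasing sequence
number, timestamp from an injectable clock (tests and fixtures inject a
counter so stores are byte-stable), actor, gene, from/to BIN, comment.
Failed actions append nothing: the audit trail records changes to the
ontology state, not rejected requests.  `replay(history, initial, tree)`
re-applies the log through the same validated path and must reproduce the
live assignment state; any prefix reproduces the corresponding snapshot.

## The consolidation decision tree

Stages, in order, per orthologue group:

1. gather the union of member positions (external members — species not
   loaded in the store — are skipped; a group with no resolvable members
   is skipped and listed in the report);
2. if every position is in the 35 family → `UNKNOWN_FUNCTION`.  This test
   runs before the unique-count test so that a group whose only position
   is {35} is reported as unknown function rather than as trivially
   consistent — the two categories direct very different curator
   attention;
3. if exactly one unique position → `NO_INCONSISTENCIES`;
4. drop 35-family positions.  If one informative BIN remains and it is
   not miscellaneous → `UPGRADED_FROM_35`;
5. otherwise remove strict ancestors of finer member BINs, then strip
   miscellaneous BINs — in that sentence order, and never stripping to the
   empty set.  If one non-miscellaneous BIN survives →
   `UPGRADED_WITHIN_BIN`;
6. otherwise `MANUAL_CHECK`.

Design choices worth calling out:

* **Catch-alls are never upgrade targets.**  A group like {35, 16.2.99}
  resolves to a single informative BIN that is itself a catch-all;
  automatically herding genes into "unspecified" would launder vagueness
  into apparent knowledge, so such groups go to `MANUAL_CHECK`.  The same
  guard applies after stage 5 when the forced-kept survivor is
  miscellaneous.
* **Upgrade tasks target every member lacking the resolved BIN**, not
  only formerly-35 members, and delete every superseded explicit code
  (35-family, ancestors of the target, stripped catch-alls).  Since the
  group resolved to a single BIN, every member position other than the
  target was superseded, so the task list is simply: copy the target where
  missing, delete everything else.  This is what makes consolidation a
  fixed point: after application every member holds exactly the resolved
  BIN, and a re-run classifies the group `NO_INCONSISTENCIES` with zero
  tasks.
* **35-family deletion applies to all members**, including members that
  also hold informative codes — the deletion acts on the group's ontology
  positions, not on a member subset.
* **Groupings are consolidated independently.**  Different orthology
  methods trade sensitivity for specificity; conflicting conclusions
  between groupings are a reporting matter, never auto-merged.
* Tasks are emitted in (group id, gene, copy-before-delete, BIN) order and
  applied through the ordinary curation path under an automation actor
  label, so automated and manual changes share one audit trail.  A task
  invalidated by interleaved curation is skipped with its reason; the
  remainder still applies.

## Coverage statistics

Per species: total registered genes, the count present in ≥ 1 group of
*any* supplied grouping (set-union semantics — a gene counts once however
many groups contain it), and the percentage rounded half-up to the nearest
integer.  Species with zero registered genes are omitted rather than
reported as 0/0.  The bundled coverage fixture reproduces the published
per-species totals (arabidopsis 23 446/27 416 → 86%, tomato
22 186/34 732 → 64%, potato 23 882/35 609 → 67%) as count-only stub genes;
the published rice row (29 183/39 045 printed as 74%) is inconsistent with
nearest-integer rounding (74.74%) and is reproduced in counts but not
asserted as a percentage.  Potato stubs carry their source partition
(TGC 20 809, PGSC 9 509, POCI 2 882, StGI 2 409), so the merged-identifier
total of 35 609 gene groups is recounted, not restated.

## Species onboarding

A newly added species' genes inherit annotations through their orthologue
groups: for each new-species gene in a group, a `copy` is proposed for
every informative (non-35) BIN held by any resolvable co-member.
Proposals never duplicate existing assignments and never target the
not-assigned family; they are proposals only — application goes through
the curation path like everything else.

## Export formats

All writers are deterministic: fixed sort orders (BIN codes segment-wise
numeric, identifiers lexicographic), no timestamps in payloads.

* **MapMan mapping** — TSV with header BINCODE, NAME, IDENTIFIER,
  DESCRIPTION, TYPE; one row per (BIN, identifier); identifiers
  lower-cased uniformly (common mapping-file practice, and it makes
  round-trips well defined); TYPE `T` for genes, `M` for features;
  unannotated identifiers appear under BIN 35, so every identifier of the
  target is present.  The reader inverts the writer exactly at the
  annotation-relation level.
* **GMT / SEGS** — one gene set per line (`BINCODE_NAME`, description,
  members) and its exact transpose (identifier, then its BIN codes).
* **OBO** — `GMM:`-namespaced `[Term]` stanzas with single-parent `is_a`;
  no date header line, for byte determinism; output is validated in tests
  by an independent OBO parser (node count and parent relation preserved).
* **generic** — four neutral relation TSVs (ontology nodes, orthologue
  group membership with grouping type, explicit gene↔BIN assignments,
  feature↔gene links).  Reloading reconstructs those four relations
  exactly.  Gene metadata (short name, description, source) is not a
  relation and round-trips through the gene-model TSV instead; a gene
  appearing in no relation is not recoverable from the generic export
  alone.

## Synthetic fixtures

The fixture generator is pure in its seed (a single `random.Random`, no
hidden entropy) and *plants* consolidation outcomes: for each requested
category it constructs the minimal forcing configuration (2–4 members) —
e.g. one informative donor plus not-assigned members for
`UPGRADED_FROM_35`; an ancestor/descendant or catch-all/specific pair for
`UPGRADED_WITHIN_BIN`; two incomparable informative BINs for
`MANUAL_CHECK` — plus randomized decoys: duplicate members, explicit
35-family assignments, and occasional external (unloaded-species) members
that must not alter the outcome.  Defaults: 3 species, 30 decoy genes per
species, tree depth 3, branching 3, ~30% of internal nodes with a `.99`
catch-all child, 10 planted groups per category (50 groups).  Group ids
are assigned over a shuffled category sequence so the id carries no
signal.

What the generator does **not** emulate: realistic orthology inference
error (mis-clustered paralogues), sequence-level evidence, annotation
evidence codes, and the size/shape of production databases.  Passing the
planted-truth tests demonstrates that the classifier implements the rule
set exactly; it does not validate the biological accuracy of annotation
transfer on real data, which depends on the quality of the input
groupings.

## Verification sizes and numerical choices

The oracle-equivalence check compares the classifier with an independently
coded brute-force rule set (string codes, explicit loops) on 10,000
randomly generated groups; planted-truth recovery runs ten seeds × 50
groups; replay checks 20 random histories of 100 valid actions.  These
sizes give full branch coverage of the decision tree many times over while
keeping the whole verification run in seconds.  Percent rounding uses
`floor(x + 0.5)` (half-up) rather than banker's rounding.  Ties and
degenerate inputs: empty groups are skipped and reported; `strip_misc` on
an all-miscellaneous set returns its input; duplicate (group, gene) rows
in grouping files collapse to one membership; batch files are
all-or-nothing (any malformed line rejects the file with line numbers).

## Known limitations

* Single-writer store: no concurrent-curation conflict resolution.
* No BIN deletion or renumbering migrations in ontology curation (add
  only); no DAG generalisation.
* Orthology inference itself is out of scope — groupings are inputs.
* External-database link harvesting and web views are out of scope; the
  CLI provides the query surface.
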