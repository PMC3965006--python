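import random

import pytest

from mapmankit import (
    MANUAL_CHECK,
    NO_INCONSISTENCIES,
    UNKNOWN_FUNCTION,
    UPGRADED_FROM_35,
    UPGRADED_WITHIN_BIN,
    AnnotationStore,
    apply_tasks,
    classify_group,
    gather_positions,
    parse_bin_code,
    resolve_hierarchy,
    run_consolidation,
    strip_misc,
)
from mapmankit.consolidation import EmptyGroupError
from mapmankit.orthology import OrthologueGroup, OrthologueGrouping

from .conftest import assign, counting_clock
from .oracles import misc_codes_of, oracle_classify, oracle_resolve_hierarchy


def codes(*texts):
    return frozenset(parse_bin_code(t) for t in texts)


def build_group(store, tree, member_bins, group_id="OG1", species="potato"):
    """Register one gene per member annotation set and wrap them in a group."""
    members = []
    for idx, bins in enumerate(member_bins):
        gene_id = f"{group_id}_g{idx}"
        if not store.has_gene(species, gene_id):
            store.register_gene(species, gene_id)
        for code in sorted(bins):
            assign(store, tree, species, gene_id, code)
        members.append((species, gene_id))
    return OrthologueGroup(group_id, "t", frozenset(members))


@pytest.fixture
def store(clock):
    return AnnotationStore(clock=clock)


class TestGatherPositions:
    def test_union_of_equal_sets_is_singleton(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2.1"}, {"16.2.1"}])
        assert gather_positions(group, store, tiny_tree) == codes("16.2.1")

    def test_unannotated_member_contributes_implicit_35(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [set(), {"16.2"}])
        assert gather_positions(group, store, tiny_tree) == codes("35", "16.2")

    def test_all_unannotated_gathers_only_35(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [set(), set(), set()])
        assert gather_positions(group, store, tiny_tree) == codes("35")

    def test_external_members_skipped(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2.1"}])
        widened = OrthologueGroup("OG1", "t", group.members | {("grapevine", "GSVIVT1")})
        assert gather_positions(widened, store, tiny_tree) == codes("16.2.1")

    def test_all_external_raises_empty_group(self, store, tiny_tree):
        group = OrthologueGroup("OGx", "t", frozenset({("grapevine", "GSVIVT1")}))
        with pytest.raises(EmptyGroupError):
            gather_positions(group, store, tiny_tree)


class TestResolveHierarchy:
    @pytest.mark.parametrize(
        "given,expected",
        [
            ({"16.2", "16.2.1"}, {"16.2.1"}),
            ({"16.2.1", "17.1"}, {"16.2.1", "17.1"}),
            ({"1", "1.1", "1.1.1"}, {"1.1.1"}),
            ({"16.2", "16.20.1"}, {"16.2", "16.20.1"}),  # not a string prefix
        ],
    )
    def test_examples(self, given, expected):
        assert resolve_hierarchy(codes(*given)) == codes(*expected)

    def test_matches_pairwise_oracle_on_random_sets(self):
        rng = random.Random(5)
        pool = ["1", "1.1", "1.1.1", "1.2", "16", "16.2", "16.2.1", "16.2.99", "17", "17.1", "35", "35.1"]
        for _ in range(300):
            chosen = set(rng.sample(pool, rng.randint(1, 6)))
            ours = {str(c) for c in resolve_hierarchy(codes(*chosen))}
            assert ours == oracle_resolve_hierarchy(chosen)


class TestStripMisc:
    def test_misc_removed(self, tiny_tree):
        assert strip_misc(codes("16.2.1", "16.2.99"), tiny_tree) == codes("16.2.1")

    def test_never_empties_the_set(self, tiny_tree):
        assert strip_misc(codes("16.2.99"), tiny_tree) == codes("16.2.99")

    def test_nothing_misc_untouched(self, tiny_tree):
        assert strip_misc(codes("16.2.1", "17.1"), tiny_tree) == codes("16.2.1", "17.1")


class TestClassifyExamples:
    """The published decision-tree outcomes on hand-built groups."""

    def test_agreeing_members_no_inconsistencies(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2.1"}, {"16.2.1"}])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == NO_INCONSISTENCIES and outcome.tasks == ()

    def test_all_unannotated_is_unknown_function(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [set(), set()])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == UNKNOWN_FUNCTION and outcome.tasks == ()
        assert outcome.resolved_bins == codes("35")  # genes remain not-assigned

    def test_explicit_35_members_also_unknown_function(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"35"}, {"35.1"}])
        assert classify_group(group, store, tiny_tree).category == UNKNOWN_FUNCTION

    def test_upgraded_from_35_generates_copy_and_delete(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"35"}, {"16.2"}])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == UPGRADED_FROM_35
        assert outcome.resolved_bins == codes("16.2")
        moves = {(t.action, t.gene_id, str(t.from_bin or t.to_bin)) for t in outcome.tasks}
        assert moves == {("copy", "OG1_g0", "16.2"), ("delete", "OG1_g0", "35")}

    def test_upgraded_within_bin_to_finer_level(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2"}, {"16.2.1"}])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == UPGRADED_WITHIN_BIN
        assert outcome.resolved_bins == codes("16.2.1")
        moves = {(t.action, t.gene_id, str(t.from_bin or t.to_bin)) for t in outcome.tasks}
        assert moves == {("copy", "OG1_g0", "16.2.1"), ("delete", "OG1_g0", "16.2")}

    def test_misc_stripping_enables_within_bin_upgrade(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2.99"}, {"16.2.1"}])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == UPGRADED_WITHIN_BIN
        assert outcome.resolved_bins == codes("16.2.1")

    def test_conflicting_branches_need_manual_check(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"16.2.1"}, {"17.1"}])
        outcome = classify_group(group, store, tiny_tree)
        assert outcome.category == MANUAL_CHECK
        assert outcome.resolved_bins == frozenset() and outcome.tasks == ()

    def test_sole_informative_catchall_is_not_an_upgrade_target(self, store, tiny_tree):
        group = build_group(store, tiny_tree, [{"35"}, {"16.2.99"}])
        assert classify_group(group, store, tiny_tree).category == MANUAL_CHECK


def random_member_sets(rng, pool):
    members = []
    for _ in range(rng.randint(1, 5)):
        if rng.random() < 0.3:
            members.append(set())
        else:
            members.append(set(rng.sample(pool, rng.randint(1, 3))))
    return members


class TestOracleEquivalence:
    def test_classifier_agrees_with_bruteforce_on_random_groups(self, tiny_tree, clock):
        pool = [str(c) for c in tiny_tree.sorted_codes()]
        misc = misc_codes_of([(str(n.code), n.name) for n in tiny_tree])
        rng = random.Random(42)
        store = AnnotationStore(clock=clock)
        for i in range(3000):
            member_sets = random_member_sets(rng, pool)
            group = build_group(store, tiny_tree, member_sets, group_id=f"OG{i}")
            outcome = classify_group(group, store, tiny_tree)
            expected_cat, expected_bin = oracle_classify(member_sets, misc)
            assert outcome.category == expected_cat, (member_sets, outcome.category, expected_cat)
            if expected_bin is not None and expected_cat != UNKNOWN_FUNCTION:
                assert outcome.resolved_bins == codes(expected_bin)

    def test_closure_and_target_hygiene(self, tiny_tree, clock):
        # upgrades only ever target a BIN the group itself supplied, and the
        # target is never not-assigned or a catch-all
        pool = [str(c) for c in tiny_tree.sorted_codes()]
        rng = random.Random(99)
        store = AnnotationStore(clock=clock)
        for i in range(800):
            member_sets = random_member_sets(rng, pool)
            group = build_group(store, tiny_tree, member_sets, group_id=f"OG{i}")
            outcome = classify_group(group, store, tiny_tree)
            union = {c for s in member_sets for c in s} | ({"35"} if any(not s for s in member_sets) else set())
            if outcome.category in (UPGRADED_FROM_35, UPGRADED_WITHIN_BIN):
                (target,) = outcome.resolved_bins
                assert str(target) in union
                assert not target.is_unassigned and not tiny_tree.is_misc(target)
                for task in outcome.tasks:
                    if task.action == "copy":
                        assert task.to_bin == target


class TestRunAndApply:
    def test_total_partition_and_counts_sum(self, tiny_tree, clock):
        rng = random.Random(8)
        store = AnnotationStore(clock=clock)
        pool = [str(c) for c in tiny_tree.sorted_codes()]
        grouping = OrthologueGrouping("rng")
        for i in range(40):
            group = build_group(store, tiny_tree, random_member_sets(rng, pool), group_id=f"OG{i:03d}")
            grouping.add_group(group.group_id, group.members)
        report = run_consolidation(store, tiny_tree, grouping)
        assert sum(report.counts.values()) == len(report.outcomes) == 40
        for outcome in report.outcomes:
            if outcome.category in (NO_INCONSISTENCIES, UNKNOWN_FUNCTION, MANUAL_CHECK):
                assert outcome.tasks == ()

    def test_empty_grouping_all_counts_zero(self, tiny_tree, store):
        report = run_consolidation(store, tiny_tree, OrthologueGrouping("empty"))
        assert sum(report.counts.values()) == 0 and report.tasks == []

    def test_report_is_deterministic(self, tiny_tree, clock):
        def make():
            store = AnnotationStore(clock=counting_clock())
            grouping = OrthologueGrouping("t")
            rng = random.Random(4)
            pool = [str(c) for c in tiny_tree.sorted_codes()]
            for i in range(15):
                group = build_group(store, tiny_tree, random_member_sets(rng, pool), group_id=f"OG{i:02d}")
                grouping.add_group(group.group_id, group.members)
            return run_consolidation(store, tiny_tree, grouping).to_dict()

        assert make() == make()

    def test_all_external_group_skipped_and_reported(self, tiny_tree, store):
        grouping = OrthologueGrouping("t")
        grouping.add_group("OGext", {("grapevine", "GSVIVT1")})
        report = run_consolidation(store, tiny_tree, grouping)
        assert report.skipped_groups == ["OGext"] and report.outcomes == []

    def test_apply_moves_genes_out_of_35(self, tiny_tree, store):
        group = build_group(store, tiny_tree, [{"35"}, {"16.2"}])
        grouping = OrthologueGrouping("t")
        grouping.add_group(group.group_id, group.members)
        report = run_consolidation(store, tiny_tree, grouping)
        applied, skipped = apply_tasks(store, tiny_tree, report, actor="autobot")
        assert applied == 2 and skipped == []
        assert store.explicit_assignments("potato", "OG1_g0") == codes("16.2")
        assert store.history[-1].actor == "autobot"

    def test_apply_empty_task_list_is_a_no_op(self, tiny_tree, store):
        group = build_group(store, tiny_tree, [{"16.2.1"}, {"16.2.1"}])
        grouping = OrthologueGrouping("t")
        grouping.add_group(group.group_id, group.members)
        report = run_consolidation(store, tiny_tree, grouping)
        before = store.clone()
        apply_tasks(store, tiny_tree, report)
        assert store.same_assignment_state(before)

    def test_invalidated_task_skipped_remainder_applied(self, tiny_tree, store):
        group = build_group(store, tiny_tree, [{"35"}, {"16.2"}])
        grouping = OrthologueGrouping("t")
        grouping.add_group(group.group_id, group.members)
        report = run_consolidation(store, tiny_tree, grouping)
        # interleaved curation already performed the copy
        assign(store, tiny_tree, "potato", "OG1_g0", "16.2")
        applied, skipped = apply_tasks(store, tiny_tree, report)
        assert applied == 1 and len(skipped) == 1
        assert store.explicit_assignments("potato", "OG1_g0") == codes("16.2")

    def test_fixed_point_and_monotone_35_decrease(self, tiny_tree, clock):
        rng = random.Random(21)
        store = AnnotationStore(clock=clock)
        pool = [str(c) for c in tiny_tree.sorted_codes()]
        grouping = OrthologueGrouping("t")
        for i in range(60):
            group = build_group(store, tiny_tree, random_member_sets(rng, pool), group_id=f"OG{i:03d}")
            grouping.add_group(group.group_id, group.members)

        def only_35(s):
            return sum(1 for key in s.genes if s.explicit_assignments(*key) == codes("35"))

        before_35 = only_35(store)
        report = run_consolidation(store, tiny_tree, grouping)
        applied, skipped = apply_tasks(store, tiny_tree, report)
        assert skipped == []
        assert only_35(store) <= before_35
        second = run_consolidation(store, tiny_tree, grouping)
        assert second.tasks == []
        for outcome in second.outcomes:
            assert outcome.category in (NO_INCONSISTENCIES, UNKNOWN_FUNCTION, MANUAL_CHECK)
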