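import itertools

import pytest
from hypothesis import settings

from mapmankit import AnnotationStore, BinCode, CurationAction, OntologyTree
from mapmankit.ontology import BinNode

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def counting_clock():
    counter = itertools.count(1)
    return lambda: f"t{next(counter):06d}"


@pytest.fixture
def clock():
    return counting_clock()


@pytest.fixture
def tiny_tree():
    """Small ontology around the secondary-metabolism example: BIN 16.2
    (phenylpropanoids) with lignin biosynthesis and an unspecified
    catch-all, an unrelated BIN 17 branch, a deep chain under BIN 1, and
    the not-assigned 35 family."""
    nodes = [
        BinNode(BinCode.parse("1"), "PS"),
        BinNode(BinCode.parse("1.1"), "PS.lightreaction"),
        BinNode(BinCode.parse("1.1.1"), "PS.lightreaction.photosystem II"),
        BinNode(BinCode.parse("16"), "secondary metabolism"),
        BinNode(BinCode.parse("16.2"), "phenylpropanoids", "phenylpropanoid metabolism"),
        BinNode(BinCode.parse("16.2.1"), "lignin biosynthesis"),
        BinNode(BinCode.parse("16.2.99"), "unspecified assignments"),
        BinNode(BinCode.parse("17"), "hormone metabolism"),
        BinNode(BinCode.parse("17.1"), "abscisic acid"),
        BinNode(BinCode.parse("35"), "not assigned"),
        BinNode(BinCode.parse("35.1"), "not assigned.unknown"),
        BinNode(BinCode.parse("35.2"), "not assigned.no ontology"),
    ]
    return OntologyTree(nodes, source_labels=["tiny"])


@pytest.fixture
def tiny_store(clock):
    store = AnnotationStore(clock=clock)
    store.register_gene("potato", "StNIB_0001", "pal1", "phenylalanine ammonia-lyase", "PGSC")
    store.register_gene("potato", "StNIB_0002", "", "unknown protein", "PGSC")
    store.register_gene("tomato", "Solyc01g001", "", "lignin-forming peroxidase", "ITAG2.3")
    store.register_gene("arabidopsis", "AT1G00010", "nac001", "NAC domain protein", "TAIR10")
    return store


def assign(store, tree, species, gene_id, code, actor="tester"):
    store.apply_action(
        tree,
        CurationAction(
            action="assign", species=species, gene_id=gene_id,
            to_bin=BinCode.parse(code), actor=actor,
        ),
    )
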