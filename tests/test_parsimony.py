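import numpy as np
import pytest

from otulink.parsimony import (
    CharMatrix,
    bnb_search,
    bremer,
    build_annotated_tree,
    deltran_lengths,
    enumerate_topologies,
    mp_bootstrap,
    parsimony_informative_count,
    score_tree,
    tuple_to_node,
)
from otulink.seqio import Msa, SeqRecord


def _random_matrix(rng, n_taxa, n_chars=8, partitions=("ITS", "macromorphology")):
    data = rng.integers(0, 2, size=(n_taxa, n_chars))
    tags = [partitions[j % len(partitions)] for j in range(n_chars)]
    return CharMatrix([f"t{i}" for i in range(n_taxa)], data, ["unordered"] * n_chars, tags)


# ---------------------------------------------------------------------------
# informative counts
# ---------------------------------------------------------------------------


def test_informative_constant_matrix():
    m = CharMatrix(["a", "b", "c"], np.zeros((3, 4), dtype=int), ["unordered"] * 4, ["ITS"] * 4)
    assert parsimony_informative_count(m) == 0


def test_informative_autapomorphy():
    m = CharMatrix(
        [f"t{i}" for i in range(6)],
        np.array([[0], [0], [0], [0], [0], [1]]),
        ["unordered"],
        ["ITS"],
    )
    assert parsimony_informative_count(m) == 0


def test_informative_two_by_two(examples):
    assert parsimony_informative_count(examples["four_taxon_matrix"]) == 2


def test_informative_per_partition():
    m = CharMatrix(
        ["a", "b", "c", "d"],
        np.array([[0, 0], [0, 0], [1, 1], [1, 1]]),
        ["unordered", "unordered"],
        ["ITS", "macromorphology"],
    )
    assert parsimony_informative_count(m, "ITS") == 1
    assert parsimony_informative_count(m, "macromorphology") == 1


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_score_all_identical_is_zero():
    m = CharMatrix(["a", "b", "c", "d"], np.ones((4, 3), dtype=int), ["unordered"] * 3, ["ITS"] * 3)
    for topo in enumerate_topologies(4):
        total, parts = score_tree(topo, m)
        assert total == 0


def test_score_fitch_hand_example():
    # 4 taxa, 1 unordered character A,A,C,C on ((0,1),(2,3)) -> 1 change
    m = CharMatrix(["t0", "t1", "t2", "t3"], np.array([[0], [0], [1], [1]]), ["unordered"], ["ITS"])
    total, parts = score_tree((1, (2, 3)), m)
    assert total == 1
    assert parts == {"ITS": 1}
    # worst grouping costs 2
    total_bad, _ = score_tree((2, (1, 3)), m)
    assert total_bad == 2


def test_score_ordered_vs_unordered_two_taxa_on_triple():
    # state 0 vs 2: ordered costs 2, unordered costs 1 (third taxon missing)
    base = dict(taxa=["t0", "t1", "t2"], data=np.array([[0], [2], [-1]]))
    ordered = CharMatrix(base["taxa"], base["data"], ["ordered"], ["macromorphology"])
    unordered = CharMatrix(base["taxa"], base["data"], ["unordered"], ["macromorphology"])
    assert score_tree((1, 2), ordered)[0] == 2
    assert score_tree((1, 2), unordered)[0] == 1


def test_score_node_tree_equals_tuple():
    m = _random_matrix(np.random.default_rng(3), 5)
    topo = next(enumerate_topologies(5))
    node = tuple_to_node(topo, m.taxa)
    assert score_tree(node, m) == score_tree(topo, m)


def test_score_taxon_mismatch():
    m = _random_matrix(np.random.default_rng(3), 4)
    from otulink.trees import parse_newick

    with pytest.raises(ValueError):
        score_tree(parse_newick("((a,b),(c,d));"), m)


def test_score_lower_bound(rng):
    # score >= sum over characters of (observed states - 1)
    m = _random_matrix(rng, 6, n_chars=10)
    bound = sum(
        max(0, len(np.unique(m.data[m.data[:, j] >= 0, j])) - 1) for j in range(m.n_chars)
    )
    best, _ = bnb_search(m)
    assert best >= bound


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------


def test_enumerate_topology_counts():
    assert len(list(enumerate_topologies(4))) == 3
    assert len(list(enumerate_topologies(5))) == 15
    assert len(list(enumerate_topologies(6))) == 105


def test_bnb_equals_exhaustive(rng):
    for _ in range(10):
        n = int(rng.integers(5, 8))
        m = _random_matrix(rng, n)
        best, trees = bnb_search(m)
        chars_scores = [ (score_tree(t, m)[0], t) for t in enumerate_topologies(n) ]
        exhaustive_best = min(s for s, _ in chars_scores)
        assert best == exhaustive_best
        assert len(trees) >= 1


def test_bnb_recovers_clean_signal():
    # 8 taxa in 4 clean cherries
    data = np.array(
        [
            [0, 0, 0], [0, 0, 0],
            [1, 0, 0], [1, 0, 0],
            [1, 1, 0], [1, 1, 0],
            [1, 1, 1], [1, 1, 1],
        ]
    )
    m = CharMatrix([f"t{i}" for i in range(8)], data, ["unordered"] * 3, ["ITS"] * 3)
    best, trees = bnb_search(m)
    assert best == 3
    from otulink.parsimony import _tuple_splits

    # every character-supported bipartition appears in every MP tree
    for t in trees:
        splits = _tuple_splits(t, 8)
        assert frozenset({6, 7}) in splits
        assert frozenset({4, 5, 6, 7}) in splits
        assert frozenset({2, 3, 4, 5, 6, 7}) in splits


def test_bnb_bounds():
    m = _random_matrix(np.random.default_rng(0), 13)
    with pytest.raises(ValueError, match="heuristic"):
        bnb_search(m)
    m2 = _random_matrix(np.random.default_rng(0), 2)
    with pytest.raises(ValueError):
        bnb_search(m2)


# ---------------------------------------------------------------------------
# DELTRAN lengths
# ---------------------------------------------------------------------------


def test_deltran_identical_sisters_zero_length():
    msa = Msa(
        [
            SeqRecord("A", "AAAA"),
            SeqRecord("A1", "AAAA"),
            SeqRecord("B", "CCCC"),
            SeqRecord("C", "CGGG"),
        ]
    )
    m = CharMatrix.from_msa(msa, "ITS", variable_only=False)
    best, trees = bnb_search(m)
    tree = tuple_to_node(trees[0], m.taxa)
    deltran_lengths(tree, m)
    assert tree.find("A").total_changes == 0
    assert tree.find("A1").total_changes == 0


def test_deltran_single_tip_change():
    m = CharMatrix(["t0", "t1", "t2", "t3"], np.array([[0], [0], [0], [1]]), ["unordered"], ["ITS"])
    tree = tuple_to_node((1, (2, 3)), m.taxa)
    deltran_lengths(tree, m)
    for leaf in tree.leaves():
        assert leaf.total_changes == (1 if leaf.name == "t3" else 0)


def test_deltran_conservation(rng):
    for _ in range(10):
        n = int(rng.integers(4, 8))
        m = _random_matrix(rng, n)
        best, trees = bnb_search(m)
        tree = tuple_to_node(trees[0], m.taxa)
        deltran_lengths(tree, m)
        total, parts = score_tree(trees[0], m)
        branch_sum = sum(nd.total_changes for nd in tree.preorder() if nd.parent is not None)
        assert branch_sum == total
        for tag, s in parts.items():
            tag_sum = sum(nd.lengths.get(tag, 0) for nd in tree.preorder() if nd.parent is not None)
            assert tag_sum == s


# ---------------------------------------------------------------------------
# Bremer support
# ---------------------------------------------------------------------------


def test_bremer_unsupported_clade_zero():
    # no character variation -> any clade has an equal-score incompatible tree
    m = CharMatrix([f"t{i}" for i in range(5)], np.zeros((5, 2), dtype=int), ["unordered"] * 2, ["ITS"] * 2)
    _, trees = bnb_search(m)
    support = bremer(trees[0], m)
    for entry in support.values():
        assert entry["total"] == 0


def test_bremer_additivity(rng):
    for _ in range(5):
        n = int(rng.integers(5, 7))
        m = _random_matrix(rng, n)
        _, trees = bnb_search(m)
        support = bremer(trees[0], m)
        for entry in support.values():
            assert sum(v for k, v in entry.items() if k != "total") == entry["total"]


def test_bremer_negative_partition(examples):
    # partition "one" supports the (t1,t2) clade with 3 characters; "two"
    # conflicts with 1 -> Bremer one=+3, two=-1, total 2
    m = examples["six_taxon_conflict"]
    best, trees = bnb_search(m)
    support = bremer(trees[0], m)
    # the (t1,t2) clade is keyed by the split side not containing t1
    entry = support[frozenset({"t3", "t4", "t5", "t6"})]
    assert entry["total"] == 2
    assert entry["one"] == 3
    assert entry["two"] == -1


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_deterministic(examples):
    m = examples["six_taxon_conflict"]
    b1 = mp_bootstrap(m, replicates=30, seed=5)
    b2 = mp_bootstrap(m, replicates=30, seed=5)
    assert b1 == b2


def test_bootstrap_single_replicate_binary(examples):
    m = examples["six_taxon_conflict"]
    b = mp_bootstrap(m, replicates=1, seed=1)
    assert set(b.values()) <= {0.0, 100.0}


def test_bootstrap_congruent_high_support():
    data = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [1, 1, 1, 1, 1, 1],
        ]
    )
    m = CharMatrix([f"t{i}" for i in range(6)], data, ["unordered"] * 6, ["ITS"] * 6)
    b = mp_bootstrap(m, replicates=200, seed=2)
    # every clade in the strict consensus should be supported well above chance
    assert all(v >= 80.0 for v in b.values())
    with pytest.raises(ValueError):
        mp_bootstrap(m, replicates=0, seed=2)


# ---------------------------------------------------------------------------
# full annotation pipeline
# ---------------------------------------------------------------------------


def test_build_annotated_tree(examples):
    m = examples["six_taxon_conflict"]
    with pytest.warns(UserWarning):
        tree = build_annotated_tree(m, bootstrap_replicates=20, seed=1)
    assert sorted(tree.leaf_names()) == [f"t{i}" for i in range(1, 7)]
    # every non-root branch carries per-partition lengths covering both tags
    for nd in tree.preorder():
        if nd.parent is not None:
            assert set(nd.lengths) == {"one", "two"}
    # some internal branch carries Bremer annotations that sum to the total
    annotated = [nd for nd in tree.preorder() if nd.total_bremer is not None]
    assert annotated
    for nd in annotated:
        assert sum(nd.bremer.values()) == nd.total_bremer
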