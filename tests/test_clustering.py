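import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import rand_score

from otulink.clustering import (
    ClusterParams,
    OptimizationResult,
    Partition,
    ReferencePartition,
    ThresholdOptimizer,
    f_linkage_cluster,
    identify,
    optimize_params,
    rand_family,
)
from otulink.distances import DistanceMatrix
from conftest import random_distance_matrix


# ---------------------------------------------------------------------------
# Partition basics
# ---------------------------------------------------------------------------


def test_partition_blocks_and_equality():
    p = Partition({"A": "x", "B": "x", "C": "y"})
    q = Partition.from_blocks([["A", "B"], ["C"]])
    assert p == q
    assert p.n_clusters() == 2
    assert p.relabeled().assignment == {"A": "0", "B": "0", "C": "1"}


def test_partition_from_blocks_rejects_overlap():
    with pytest.raises(ValueError):
        Partition.from_blocks([["A"], ["A", "B"]])


# ---------------------------------------------------------------------------
# f-linkage clustering
# ---------------------------------------------------------------------------


def test_cluster_t_above_max_single_cluster(rng):
    D = random_distance_matrix(rng, 10)
    for F in (0.0, 0.5, 1.0):
        part = f_linkage_cluster(D, ClusterParams(t=1.0, F=F))
        assert part.n_clusters() == 1


def test_cluster_t_below_min_all_singletons(rng):
    D = random_distance_matrix(rng, 10, scale=0.5)
    tmin = D.d[~np.eye(10, dtype=bool)].min()
    part = f_linkage_cluster(D, ClusterParams(t=tmin / 2, F=0.0))
    assert part.n_clusters() == 10


def test_cluster_chain_example(examples):
    # d(A,B)=d(B,C)=0.01, d(A,C)=0.05, t=0.02: F=0 merges all, F=1 splits C
    D = examples["chain_distances"]
    assert f_linkage_cluster(D, ClusterParams(t=0.02, F=0.0)) == Partition.from_blocks([["A", "B", "C"]])
    assert f_linkage_cluster(D, ClusterParams(t=0.02, F=1.0)) == Partition.from_blocks([["A", "B"], ["C"]])


def _components_partition(D, t):
    adj = csr_matrix((D.d <= t) & ~np.eye(len(D), dtype=bool))
    _, labels = connected_components(adj, directed=False)
    return Partition({D.ids[i]: str(labels[i]) for i in range(len(D))})


def test_f0_equals_connected_components(rng):
    for _ in range(25):
        D = random_distance_matrix(rng, 15)
        t = float(rng.uniform(0, 0.1))
        assert f_linkage_cluster(D, ClusterParams(t=t, F=0.0)) == _components_partition(D, t)


def test_f1_clique_property(rng):
    for _ in range(25):
        D = random_distance_matrix(rng, 15)
        t = float(rng.uniform(0, 0.1))
        part = f_linkage_cluster(D, ClusterParams(t=t, F=1.0))
        for block in part.blocks():
            members = sorted(block)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert D.get(a, b) <= t


def test_cluster_count_monotone_in_t(rng):
    D = random_distance_matrix(rng, 12)
    for F in (0.0, 1.0):
        counts = [
            f_linkage_cluster(D, ClusterParams(t=t, F=F)).n_clusters()
            for t in np.linspace(0, 0.12, 13)
        ]
        assert counts == sorted(counts, reverse=True)


def test_cluster_deterministic(rng):
    D = random_distance_matrix(rng, 12)
    p1 = f_linkage_cluster(D, ClusterParams(t=0.05, F=0.5))
    p2 = f_linkage_cluster(D, ClusterParams(t=0.05, F=0.5))
    assert p1.assignment == p2.assignment


# ---------------------------------------------------------------------------
# agreement indices
# ---------------------------------------------------------------------------


def test_rand_self_agreement_max():
    p = Partition({"A": "0", "B": "0", "C": "1", "D": "2"})
    r = ReferencePartition(p.assignment)
    for metric in ("rand", "adjusted_rand", "modified_rand"):
        assert rand_family(p, r, metric) == pytest.approx(1.0)


def test_rand_singletons_vs_one_block():
    p = Partition({x: x for x in "ABCD"})
    r = ReferencePartition({x: "one" for x in "ABCD"})
    assert rand_family(p, r, "rand") == 0.0
    assert rand_family(p, r, "modified_rand") == -1.0


def test_rand_ignores_unlabeled():
    r = ReferencePartition({"A": "0", "B": "0", "C": "1"})
    p = Partition({"A": "x", "B": "x", "C": "y"})
    val = rand_family(p, r)
    p_extra = Partition({**p.assignment, "Z1": "q", "Z2": "x"})
    assert rand_family(p_extra, r) == val


def test_rand_symmetric_and_relabel_invariant(rng):
    labels_p = rng.integers(0, 3, size=10)
    labels_r = rng.integers(0, 4, size=10)
    ids = [f"e{i}" for i in range(10)]
    p = Partition(dict(zip(ids, map(str, labels_p))))
    r = Partition(dict(zip(ids, map(str, labels_r))))
    assert rand_family(p, ReferencePartition(r.assignment)) == pytest.approx(
        rand_family(r, ReferencePartition(p.assignment))
    )
    relab = Partition({k: f"cluster_{v}" for k, v in p.assignment.items()})
    assert rand_family(relab, ReferencePartition(r.assignment)) == pytest.approx(
        rand_family(p, ReferencePartition(r.assignment))
    )


def test_rand_matches_sklearn(rng):
    for _ in range(10):
        labels_p = rng.integers(0, 3, size=12)
        labels_r = rng.integers(0, 3, size=12)
        ids = [f"e{i}" for i in range(12)]
        p = Partition(dict(zip(ids, map(str, labels_p))))
        r = ReferencePartition(dict(zip(ids, map(str, labels_r))))
        assert rand_family(p, r, "rand") == pytest.approx(rand_score(labels_r, labels_p))


def test_rand_too_few_labeled():
    p = Partition({"A": "0", "B": "1"})
    with pytest.raises(ValueError):
        rand_family(p, ReferencePartition({"A": "0"}))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def test_optimize_reference_all_singletons(rng):
    D = random_distance_matrix(rng, 8, scale=0.4)
    offdiag = D.d[~np.eye(8, dtype=bool)]
    r = ReferencePartition({i: i for i in D.ids})
    res = optimize_params(D, r, F_grid=[0.0], t_step=0.01)
    opt = res.optimal(0.0)
    assert opt["max_agreement"] == pytest.approx(1.0)
    assert opt["t_max"] < offdiag.min()


def test_optimize_result_structure(rng):
    D = random_distance_matrix(rng, 6)
    r = ReferencePartition({i: "0" for i in D.ids})
    res = optimize_params(D, r, F_grid=[0.0, 1.0], t_step=0.02)
    summary = res.summary()
    assert list(summary["F"]) == [0.0, 1.0]
    for opt in summary.to_dict("records"):
        assert opt["t_min"] <= opt["t_median"] <= opt["t_max"]
        assert opt["n_optimal"] >= 1
    with pytest.raises(KeyError):
        res.optimal(0.25)


def test_optimizer_wrapper_matches_function(rng):
    D = random_distance_matrix(rng, 6)
    r = ReferencePartition({i: "0" for i in D.ids})
    res1 = ThresholdOptimizer(D, r).fit(F_grid=[0.5], t_step=0.02)
    res2 = optimize_params(D, r, F_grid=[0.5], t_step=0.02)
    assert res1.table.equals(res2.table)


def test_optimize_errors(rng):
    D = random_distance_matrix(rng, 4)
    r = ReferencePartition({D.ids[0]: "0"})
    with pytest.raises(ValueError):
        optimize_params(D, r)
    r2 = ReferencePartition({i: "0" for i in D.ids})
    with pytest.raises(ValueError):
        optimize_params(D, r2, F_grid=[])
    with pytest.raises(ValueError):
        optimize_params(D, r2, t_grid=[])


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------


def _identify_setup():
    ids = ["r1", "r2", "q_same", "q_novel", "q_bridge"]
    d = np.array(
        [
            # r1    r2    q_same q_novel q_bridge
            [0.00, 0.20, 0.00, 0.50, 0.01],
            [0.20, 0.00, 0.20, 0.50, 0.01],
            [0.00, 0.20, 0.00, 0.50, 0.01],
            [0.50, 0.50, 0.50, 0.00, 0.50],
            [0.01, 0.01, 0.01, 0.50, 0.00],
        ]
    )
    return DistanceMatrix(ids, d), ReferencePartition({"r1": "sp1", "r2": "sp2"})


def test_identify_exact_match():
    D, R = _identify_setup()
    table = identify(D.submatrix(["r1", "r2", "q_same", "q_novel"]), R, ClusterParams(t=0.005, F=0.5))
    row = table[table["query"] == "q_same"].iloc[0]
    assert row["status"] == "identified"
    assert row["labels"] == "sp1"


def test_identify_novel():
    D, R = _identify_setup()
    table = identify(D, R, ClusterParams(t=0.005, F=0.5))
    assert table[table["query"] == "q_novel"].iloc[0]["status"] == "novel"


def test_identify_ambiguous_bridge():
    D, R = _identify_setup()
    table = identify(D.submatrix(["r1", "r2", "q_bridge"]), R, ClusterParams(t=0.05, F=0.0))
    row = table[table["query"] == "q_bridge"].iloc[0]
    assert row["status"] == "ambiguous"
    assert row["labels"] == "sp1;sp2"
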