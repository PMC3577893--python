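"""F-linkage threshold clustering, partition agreement and parameter fitting.

Sequences are grouped into molecular operational taxonomic units (OTUs) by
agglomerative threshold clustering.  Two elements are *linked* when their
distance is at most the threshold ``t``.  The shape parameter ``F`` in [0, 1]
interpolates between single linkage (``F = 0``: one link between two clusters
suffices to merge them) and complete linkage (``F = 1``: every cross-pair
must be linked).  A pair of clusters (A, B) is mergeable when the linked
fraction ``f = |linked cross-pairs| / (|A| * |B|)`` satisfies ``f >= F`` and
``f > 0``; the pair with the largest ``f`` is merged first, ties broken by
smaller mean cross-distance and then by the lexicographically smallest member
id, so the agglomeration is deterministic.

The free parameters (t, F) are fitted against a reference partition — built,
for example, from the database sequences that carry full species names — by
maximizing a pair-counting agreement index.  The default index is the
modified Rand index (MRI), ``2 * Rand - 1``, whose theoretical maximum 1.0 is
attained exactly when the clustering restricted to the labeled elements
equals the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .distances import DistanceMatrix

__all__ = [
    "Partition",
    "ReferencePartition",
    "ClusterParams",
    "OptimizationResult",
    "f_linkage_cluster",
    "rand_family",
    "optimize_params",
    "ThresholdOptimizer",
    "identify",
]


class Partition:
    """Assignment of element ids to disjoint clusters."""

    def __init__(self, assignment: Mapping[str, object]):
        self.assignment: dict[str, str] = {str(k): str(v) for k, v in assignment.items()}

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[str]]) -> "Partition":
        assignment = {}
        for i, block in enumerate(blocks):
            for el in block:
                if el in assignment:
                    raise ValueError(f"element {el!r} in two blocks")
                assignment[el] = str(i)
        return cls(assignment)

    @property
    def elements(self) -> set[str]:
        return set(self.assignment)

    def blocks(self) -> list[frozenset]:
        by_label: dict[str, set] = {}
        for el, lab in self.assignment.items():
            by_label.setdefault(lab, set()).add(el)
        return sorted((frozenset(b) for b in by_label.values()), key=lambda b: min(b))

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def restricted(self, ids: Iterable[str]) -> "Partition":
        ids = set(ids)
        return Partition({k: v for k, v in self.assignment.items() if k in ids})

    def relabeled(self) -> "Partition":
        """Stable canonical labels: clusters numbered by their smallest member."""
        blocks = self.blocks()
        return Partition({el: str(i) for i, b in enumerate(blocks) for el in b})

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and set(self.blocks()) == set(other.blocks())

    def __len__(self) -> int:
        return len(self.assignment)

    def __repr__(self) -> str:
        return f"<Partition of {len(self)} elements into {self.n_clusters()} clusters>"


class ReferencePartition(Partition):
    """A partition defined on a (possibly strict) subset of the elements.

    Only the labeled elements take part in agreement computations; unlabeled
    elements are ignored entirely.
    """

    @property
    def labeled(self) -> set[str]:
        return set(self.assignment)


@dataclass(frozen=True)
class ClusterParams:
    """Threshold ``t`` (distance fraction) and cluster-shape factor ``F``."""

    t: float
    F: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("threshold t must be in [0, 1]")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must be in [0, 1]")


def f_linkage_cluster(D: DistanceMatrix, params: ClusterParams) -> Partition:
    """Deterministic agglomerative F-linkage clustering of a distance matrix.

    Cross-cluster link counts and distance sums are maintained incrementally
    under merges; the linked-fraction comparison uses exact integer
    cross-multiplication, so tie-breaking (largest fraction, then smallest
    mean cross-distance, then smallest member id) is reproducible.
    """
    n = len(D)
    t, F = params.t, params.F
    lcnt = (D.d <= t).astype(np.int64)
    np.fill_diagonal(lcnt, 0)
    dsum = D.d.copy()
    size = [1] * n
    minid = list(D.ids)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))

    while len(active) > 1:
        best = None  # (a, b, l, pairs, mean, minid)
        order = sorted(active)
        for ia, a in enumerate(order):
            row_l = lcnt[a]
            row_d = dsum[a]
            for b in order[ia + 1 :]:
                l = int(row_l[b])
                if l == 0:
                    continue
                pairs = size[a] * size[b]
                if l < F * pairs:
                    continue
                mid = min(minid[a], minid[b])
                if best is None:
                    best = (a, b, l, pairs, float(row_d[b]) / pairs, mid)
                    continue
                # compare fractions l/pairs exactly via cross-multiplication
                lhs = l * best[3]
                rhs = best[2] * pairs
                if lhs > rhs:
                    better = True
                elif lhs < rhs:
                    better = False
                else:
                    mean = float(row_d[b]) / pairs
                    better = (mean, mid) < (best[4], best[5])
                if better:
                    best = (a, b, l, pairs, float(row_d[b]) / pairs, mid)
        if best is None:
            break
        a, b = best[0], best[1]
        lcnt[a, :] += lcnt[b, :]
        lcnt[:, a] = lcnt[a, :]
        dsum[a, :] += dsum[b, :]
        dsum[:, a] = dsum[a, :]
        lcnt[a, a] = 0
        dsum[a, a] = 0.0
        size[a] += size[b]
        minid[a] = min(minid[a], minid[b])
        members[a] = sorted(members[a] + members[b])
        del members[b]
        active.discard(b)
    return Partition.from_blocks([[D.ids[i] for i in m] for m in members.values()]).relabeled()


def _pair_counts(p: Partition, r: Partition, elements: Sequence[str]) -> tuple[int, int, int]:
    """(agreeing pairs, disagreeing pairs, total pairs) over ``elements``."""
    a = b = 0
    total = 0
    for x, y in combinations(elements, 2):
        same_p = p.assignment[x] == p.assignment[y]
        same_r = r.assignment[x] == r.assignment[y]
        total += 1
        if same_p == same_r:
            a += 1
        else:
            b += 1
    return a, b, total


def rand_family(P: Partition, R: ReferencePartition, metric: str = "modified_rand") -> float:
    """Pair-counting agreement between a clustering and a reference.

    Computed over the reference's labeled elements only.  ``rand`` is the
    plain Rand index, ``adjusted_rand`` the Hubert–Arabie chance-corrected
    version, and ``modified_rand`` (MRI) is ``2 * rand - 1``, ranging over
    [-1, 1] with maximum 1.0 iff the restricted partitions are identical.
    """
    labeled = sorted(R.labeled & P.elements)
    if len(labeled) < 2:
        raise ValueError("agreement needs at least 2 labeled elements present in the clustering")
    if metric == "adjusted_rand":
        lp = [P.assignment[x] for x in labeled]
        lr = [R.assignment[x] for x in labeled]
        return float(adjusted_rand_score(lr, lp))
    agree, _, total = _pair_counts(P, R, labeled)
    rand = agree / total
    if metric == "rand":
        return rand
    if metric == "modified_rand":
        return 2.0 * rand - 1.0
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class OptimizationResult:
    """Agreement surface over the (F, t) grid and the per-F optima."""

    table: pd.DataFrame  # columns: F, t, agreement
    metric: str

    def optimal(self, F: float) -> dict:
        sub = self.table[self.table["F"] == F]
        if sub.empty:
            raise KeyError(f"F={F} not in the evaluated grid")
        best = sub["agreement"].max()
        ts = np.sort(sub.loc[sub["agreement"] == best, "t"].to_numpy())
        return {
            "F": F,
            "max_agreement": float(best),
            "t_min": float(ts.min()),
            "t_max": float(ts.max()),
            "t_median": float(np.median(ts)),
            "n_optimal": int(len(ts)),
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([self.optimal(F) for F in sorted(self.table["F"].unique())])

    def __repr__(self) -> str:
        return f"<OptimizationResult ({self.metric}) over {len(self.table)} (F, t) points>"


DEFAULT_T_STEP = 0.0005  # 0.05 percentage points


def optimize_params(
    D: DistanceMatrix,
    R: ReferencePartition,
    F_grid: Sequence[float] = (0.0, 0.5, 1.0),
    t_grid: Optional[Sequence[float]] = None,
    t_step: float = DEFAULT_T_STEP,
    metric: str = "modified_rand",
) -> OptimizationResult:
    """Scan the (F, t) grid, scoring each clustering against the reference.

    The default threshold grid runs from 0 to the largest observed distance
    in steps of ``t_step`` (0.05 percentage points).
    """
    if len(F_grid) == 0:
        raise ValueError("empty F grid")
    if t_grid is None:
        tmax = D.max_offdiag()
        t_grid = np.arange(0.0, tmax + t_step, t_step)
    t_grid = np.asarray(list(t_grid), dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty threshold grid")
    if len(R.labeled & set(D.ids)) < 2:
        raise ValueError("reference must label at least 2 elements of the matrix")
    rows = []
    for F in F_grid:
        for t in t_grid:
            part = f_linkage_cluster(D, ClusterParams(t=float(t), F=float(F)))
            rows.append({"F": float(F), "t": float(t), "agreement": rand_family(part, R, metric)})
    return OptimizationResult(pd.DataFrame(rows), metric)


class ThresholdOptimizer:
    """Model-style wrapper: fit clustering parameters to a reference partition.

    Examples
    --------
    >>> res = ThresholdOptimizer(D, reference).fit(F_grid=[0.0, 0.5, 1.0])
    >>> res.summary()
    """

    def __init__(self, D: DistanceMatrix, reference: ReferencePartition, metric: str = "modified_rand"):
        self.D = D
        self.reference = reference
        self.metric = metric

    def fit(
        self,
        F_grid: Sequence[float] = (0.0, 0.5, 1.0),
        t_grid: Optional[Sequence[float]] = None,
        t_step: float = DEFAULT_T_STEP,
    ) -> OptimizationResult:
        return optimize_params(self.D, self.reference, F_grid, t_grid, t_step, self.metric)


def identify(
    D: DistanceMatrix,
    R: ReferencePartition,
    params: ClusterParams,
) -> pd.DataFrame:
    """Classify query sequences by cluster co-membership with references.

    All elements of ``D`` are clustered with the given parameters; every
    element not labeled by the reference is a query.  A query inherits the
    species labels of the labeled references in its cluster (all of them when
    they conflict, flagged ambiguous) and is reported as novel when its
    cluster contains no labeled reference.

    Returns
    -------
    DataFrame with columns query, cluster, labels, status
        status is one of ``identified``, ``ambiguous``, ``novel``.
    """
    queries = [i for i in D.ids if i not in R.labeled]
    part = f_linkage_cluster(D, params)
    rows = []
    for q in sorted(queries):
        cluster = part.assignment[q]
        members = [el for el, c in part.assignment.items() if c == cluster]
        labels = sorted({R.assignment[m] for m in members if m in R.labeled})
        if not labels:
            status = "novel"
        elif len(labels) == 1:
            status = "identified"
        else:
            status = "ambiguous"
        rows.append({"query": q, "cluster": cluster, "labels": ";".join(labels), "status": status})
    return pd.DataFrame(rows, columns=["query", "cluster", "labels", "status"])
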