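"""Maximum-parsimony inference with per-partition branch statistics.

The character matrix mixes data partitions — DNA characters (unordered, gaps
recoded as missing), macromorphological characters (binary or ordered
multistate) and physiological characters (binary).  Unordered characters are
scored with the Fitch algorithm, ordered characters with Sankoff dynamic
programming under linear step costs (|i - j| changes between states i and
j).  Missing states (``?``) are free wildcards.

Tree search is exact: stepwise-addition branch and bound over all unrooted
binary topologies, returning every most-parsimonious tree.  The enumeration
bound defaults to 12 taxa; beyond that the search space (654,729,075
topologies at 13) is out of reach for an exact method and the caller is told
to use a heuristic tool instead.

On the preferred tree the module computes DELTRAN branch lengths (integer
change counts per partition, ambiguous changes delayed toward the tips),
partitioned Bremer support (per partition, possibly negative, summing to the
total Bremer value on each internal branch) and maximum-parsimony bootstrap
percentages.  These annotations feed the species-boundary rule.

Internally an unrooted topology over taxa ``0..n-1`` is a nested tuple over
``1..n-1`` with an implicit pendant edge to taxon 0; scoring roots the tree
on that edge (parsimony scores are rooting-invariant).
"""

from __future__ import annotations

import warnings
from typing import Iterator, Optional, Sequence

import numpy as np

from .trees import Node, edge_splits, midpoint_root, normalize_split

__all__ = [
    "CharMatrix",
    "parsimony_informative_count",
    "score_tree",
    "bnb_search",
    "enumerate_topologies",
    "deltran_lengths",
    "bremer",
    "mp_bootstrap",
    "build_annotated_tree",
    "tuple_to_node",
]

MISSING = -1
_INF = float("inf")

_DNA_STATES = {"A": 0, "C": 1, "G": 2, "T": 3}


class CharMatrix:
    """Taxa-by-characters matrix with per-character type and partition tag.

    ``data`` holds integer states, ``-1`` for missing.  ``ctypes`` is
    ``'unordered'`` or ``'ordered'`` per character; ``partitions`` is the
    per-character data-partition tag (e.g. ITS / macromorphology /
    physiology).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        data: np.ndarray,
        ctypes: Sequence[str],
        partitions: Sequence[str],
        names: Optional[Sequence[str]] = None,
    ):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=int)
        self.ctypes = list(ctypes)
        self.partitions = list(partitions)
        self.names = list(names) if names is not None else None
        n, k = self.data.shape
        if n != len(self.taxa):
            raise ValueError("row count does not match taxa")
        if k != len(self.ctypes) or k != len(self.partitions):
            raise ValueError("character annotation rows do not match the matrix width")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa")
        for j, ct in enumerate(self.ctypes):
            if ct not in ("unordered", "ordered"):
                raise ValueError(f"unknown character type {ct!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.data.shape[1]

    @property
    def partition_tags(self) -> list[str]:
        seen = []
        for p in self.partitions:
            if p not in seen:
                seen.append(p)
        return seen

    def subset(self, partition_tag: str) -> "CharMatrix":
        cols = [j for j, p in enumerate(self.partitions) if p == partition_tag]
        return CharMatrix(
            self.taxa,
            self.data[:, cols],
            [self.ctypes[j] for j in cols],
            [self.partitions[j] for j in cols],
            [self.names[j] for j in cols] if self.names else None,
        )

    @classmethod
    def from_msa(cls, msa, partition_tag: str = "ITS", variable_only: bool = True) -> "CharMatrix":
        """Recode an alignment as unordered characters, gaps as missing."""
        taxa = [r.id for r in msa.records]
        cols = []
        for c in range(msa.length):
            column = [r.residues[c] for r in msa.records]
            states = [_DNA_STATES.get(x, MISSING) for x in column]
            observed = {s for s in states if s != MISSING}
            if variable_only and len(observed) < 2:
                continue
            cols.append(states)
        data = np.array(cols, dtype=int).T if cols else np.empty((len(taxa), 0), dtype=int)
        k = data.shape[1]
        return cls(taxa, data, ["unordered"] * k, [partition_tag] * k)

    @classmethod
    def concat(cls, matrices: Sequence["CharMatrix"]) -> "CharMatrix":
        taxa = matrices[0].taxa
        for m in matrices[1:]:
            if m.taxa != taxa:
                raise ValueError("matrices must share the same taxa, in order")
        return cls(
            taxa,
            np.hstack([m.data for m in matrices]),
            sum((m.ctypes for m in matrices), []),
            sum((m.partitions for m in matrices), []),
        )

    def resampled(self, rng: np.random.Generator) -> "CharMatrix":
        """Bootstrap resample of the characters (columns), with replacement."""
        idx = rng.integers(0, self.n_chars, size=self.n_chars)
        return CharMatrix(
            self.taxa,
            self.data[:, idx],
            [self.ctypes[j] for j in idx],
            [self.partitions[j] for j in idx],
        )


def parsimony_informative_count(m: CharMatrix, partition_tag: Optional[str] = None) -> int:
    """Characters with >= 2 states each present in >= 2 taxa (missing excluded)."""
    count = 0
    for j in range(m.n_chars):
        if partition_tag is not None and m.partitions[j] != partition_tag:
            continue
        states, freq = np.unique(m.data[m.data[:, j] != MISSING, j], return_counts=True)
        if (freq >= 2).sum() >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# tuple topologies
# ---------------------------------------------------------------------------


def _insertions(subtree, leaf: int) -> Iterator:
    """All topologies obtained by attaching ``leaf`` to an edge of ``subtree``."""
    yield (subtree, leaf)
    if isinstance(subtree, tuple):
        a, b = subtree
        for ins in _insertions(a, leaf):
            yield (ins, b)
        for ins in _insertions(b, leaf):
            yield (a, ins)


def enumerate_topologies(n: int) -> Iterator:
    """All unrooted binary topologies over taxa 0..n-1, as rooted tuples
    over 1..n-1 (implicit edge to taxon 0)."""
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def rec(tree, k):
        if k == n:
            yield tree
            return
        for ins in _insertions(tree, k):
            yield from rec(ins, k + 1)

    yield from rec((1, 2), 3)


def _canonical(subtree):
    if isinstance(subtree, int):
        return subtree
    a, b = _canonical(subtree[0]), _canonical(subtree[1])
    return (a, b) if _min_leaf(a) < _min_leaf(b) else (b, a)


def _min_leaf(subtree) -> int:
    return subtree if isinstance(subtree, int) else min(_min_leaf(subtree[0]), _min_leaf(subtree[1]))


def _tuple_splits(tree, n: int) -> set[frozenset]:
    """Internal bipartitions of the unrooted tree (0, tree), as the side not
    containing taxon 0."""
    splits: set[frozenset] = set()

    def rec(sub) -> frozenset:
        if isinstance(sub, int):
            return frozenset([sub])
        below = rec(sub[0]) | rec(sub[1])
        if 2 <= len(below) <= n - 2:
            splits.add(below)
        return below

    rec(tree)
    return splits


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _char_arrays(m: CharMatrix):
    """Per-character scoring payloads: Fitch bitmasks or Sankoff leaf vectors."""
    chars = []
    for j in range(m.n_chars):
        col = m.data[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            continue
        nstates = int(observed.max()) + 1
        if m.ctypes[j] == "unordered":
            full = (1 << nstates) - 1 if nstates > 0 else 1
            masks = [full if s == MISSING else (1 << int(s)) for s in col]
            chars.append(("fitch", masks, m.partitions[j]))
        else:
            vecs = []
            for s in col:
                if s == MISSING:
                    vecs.append([0.0] * nstates)
                else:
                    vecs.append([_INF] * int(s) + [0.0] + [_INF] * (nstates - int(s) - 1))
            chars.append(("sankoff", vecs, m.partitions[j]))
    return chars


def _fitch_cost(tree, masks) -> tuple[int, int]:
    if isinstance(tree, int):
        return masks[tree], 0
    ma, ca = _fitch_cost(tree[0], masks)
    mb, cb = _fitch_cost(tree[1], masks)
    inter = ma & mb
    if inter:
        return inter, ca + cb
    return ma | mb, ca + cb + 1


def _sankoff_cost(tree, vecs) -> list[float]:
    if isinstance(tree, int):
        return vecs[tree]
    ca = _sankoff_cost(tree[0], vecs)
    cb = _sankoff_cost(tree[1], vecs)
    k = len(ca)
    out = []
    for s in range(k):
        best_a = min(ca[i] + abs(s - i) for i in range(k))
        best_b = min(cb[i] + abs(s - i) for i in range(k))
        out.append(best_a + best_b)
    return out


def _score_tuple(tree, chars, by_partition: bool = False):
    """Parsimony score of the unrooted tree (0, tree)."""
    total = 0.0
    parts: dict[str, float] = {}
    for kind, payload, tag in chars:
        rooted = (0, tree)
        if kind == "fitch":
            _, cost = _fitch_cost(rooted, payload)
        else:
            cost = min(_sankoff_cost(rooted, payload))
        total += cost
        if by_partition:
            parts[tag] = parts.get(tag, 0) + cost
    total = int(total) if total == int(total) else total
    if by_partition:
        parts = {k: int(v) if v == int(v) else v for k, v in parts.items()}
        return total, parts
    return total


def score_tree(tree, m: CharMatrix):
    """Parsimony score (total, per-partition dict) of a topology.

    ``tree`` may be a tuple topology (taxa as indices into ``m.taxa``) or a
    :class:`Node` tree whose leaf names are the taxa.
    """
    if isinstance(tree, Node):
        tree = _node_to_tuple(tree, m.taxa)
    chars = _char_arrays(m)
    return _score_tuple(tree, chars, by_partition=True)


def _node_to_tuple(root: Node, taxa: Sequence[str]):
    """Convert a (rooted or unrooted) Node tree to tuple form over taxa indices."""
    index = {t: i for i, t in enumerate(taxa)}
    names = set(root.leaf_names())
    if names != set(taxa):
        raise ValueError("tree leaves do not match matrix taxa")

    # unroot: collapse into a neighbor list, then root on the edge to taxon 0
    adj: dict[int, set[int]] = {}
    ids: dict[Node, int] = {}

    def nid(n: Node) -> int:
        if n not in ids:
            ids[n] = len(ids) + len(taxa)  # leaves get 0..n-1 below
        return ids[n]

    for n in root.preorder():
        if n.is_leaf:
            ids[n] = index[n.name]
    edges = []
    for n in root.preorder():
        if n.parent is not None:
            edges.append((nid(n.parent), nid(n)))
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    # suppress degree-2 vertices (e.g. the root of a rooted tree)
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if len(adj[v]) == 2 and v >= len(taxa):
                a, b = sorted(adj[v])
                adj[a].discard(v)
                adj[b].discard(v)
                adj[a].add(b)
                adj[b].add(a)
                del adj[v]
                changed = True

    def build(v: int, parent: int):
        if v < len(taxa):
            return v
        kids = [build(c, v) for c in sorted(adj[v]) if c != parent]
        node = kids[0]
        for k in kids[1:]:
            node = (node, k)
        return node

    anchor = 0
    nb = next(iter(adj[anchor]))
    return _canonical(build(nb, anchor))


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------

MAX_EXACT_TAXA = 12


def bnb_search(m: CharMatrix, max_taxa: int = MAX_EXACT_TAXA):
    """Exact search for all most-parsimonious unrooted topologies.

    Stepwise-addition branch and bound: partial-tree scores never decrease
    when a taxon is added, so subtrees scoring above the best complete score
    are pruned.  Returns ``(best_score, trees)`` with the trees in canonical
    deterministic order (tuple topologies over taxa indices).
    """
    n = m.n_taxa
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceed the exact-search bound of {max_taxa}; use a heuristic search tool for matrices this large"
        )
    if n < 3:
        raise ValueError("need at least 3 taxa")
    chars = _char_arrays(m)
    best: list[float] = [_INF]
    found: list = []

    def rec(tree, k):
        s = _score_tuple(tree, chars)
        if s > best[0]:
            return
        if k == n:
            if s < best[0]:
                best[0] = s
                found.clear()
            found.append(_canonical(tree))
            return
        for ins in _insertions(tree, k):
            rec(ins, k + 1)

    rec((1, 2), 3)
    trees = sorted(set(found), key=repr)
    return best[0], trees


def bremer(tree, m: CharMatrix, max_taxa: int = MAX_EXACT_TAXA) -> dict[frozenset, dict]:
    """Total and partitioned Bremer support for every internal branch.

    For each internal bipartition of ``tree`` the total Bremer value is the
    minimum parsimony score over all topologies *not* containing that
    bipartition, minus the global minimum score.  The per-partition values
    are the corresponding differences of partition scores on the best
    incompatible tree (the first in canonical enumeration order when several
    tie); they can be negative and sum to the total.

    Returns a mapping ``frozenset of taxon names -> {"total": ..., tag: ...}``.
    """
    n = m.n_taxa
    if n > max_taxa:
        raise ValueError(f"{n} taxa exceed the exact enumeration bound of {max_taxa}")
    if isinstance(tree, Node):
        tree = _node_to_tuple(tree, m.taxa)
    chars = _char_arrays(m)
    mp_total, mp_parts = _score_tuple(tree, chars, by_partition=True)
    target_splits = _tuple_splits(tree, n)
    best_incompat: dict[frozenset, tuple] = {}
    for topo in enumerate_topologies(n):
        s = _score_tuple(topo, chars)
        topo_splits = _tuple_splits(topo, n)
        for split in target_splits:
            if split not in topo_splits:
                cur = best_incompat.get(split)
                if cur is None or s < cur[0]:
                    best_incompat[split] = (s, topo)
    out: dict[frozenset, dict] = {}
    for split in target_splits:
        s, topo = best_incompat[split]
        _, parts = _score_tuple(topo, chars, by_partition=True)
        entry = {"total": s - mp_total}
        for tag in m.partition_tags:
            entry[tag] = parts.get(tag, 0) - mp_parts.get(tag, 0)
        out[frozenset(m.taxa[i] for i in split)] = entry
    return out


# ---------------------------------------------------------------------------
# DELTRAN branch lengths
# ---------------------------------------------------------------------------


def _step_cost(ct: str, i: int, j: int) -> float:
    if ct == "unordered":
        return 0.0 if i == j else 1.0
    return float(abs(i - j))


def deltran_lengths(root: Node, m: CharMatrix) -> Node:
    """Assign per-branch, per-partition integer change counts (DELTRAN).

    Character states at internal nodes are reconstructed by Sankoff dynamic
    programming; among co-optimal assignments the parent's state is preferred
    (then the smallest state index), which delays transformations toward the
    tips.  Traversal is preorder with children in tree order.  Sets
    ``node.lengths[tag]`` on every non-root node and ``node.length`` to the
    total change count of the edge.
    """
    index = {t: i for i, t in enumerate(m.taxa)}
    if set(root.leaf_names()) != set(m.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    nodes = list(root.preorder())
    for nd in nodes:
        nd.lengths = {tag: 0 for tag in m.partition_tags}
    for j in range(m.n_chars):
        col = m.data[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            continue
        nstates = int(observed.max()) + 1
        ct = m.ctypes[j]
        tag = m.partitions[j]
        cost: dict[Node, list[float]] = {}
        for nd in root.postorder():
            if nd.is_leaf:
                s = col[index[nd.name]]
                if s == MISSING:
                    cost[nd] = [0.0] * nstates
                else:
                    cost[nd] = [_INF] * int(s) + [0.0] + [_INF] * (nstates - int(s) - 1)
            else:
                vec = []
                for st in range(nstates):
                    tot = 0.0
                    for c in nd.children:
                        tot += min(cost[c][i] + _step_cost(ct, st, i) for i in range(nstates))
                    vec.append(tot)
                cost[nd] = vec
        assign: dict[Node, int] = {}
        for nd in root.preorder():
            if nd.parent is None:
                best = min(cost[nd])
                assign[nd] = min(s for s in range(nstates) if cost[nd][s] == best)
            else:
                p = assign[nd.parent]
                vals = [cost[nd][s] + _step_cost(ct, s, p) for s in range(nstates)]
                best = min(vals)
                optimal = [s for s in range(nstates) if vals[s] == best]
                assign[nd] = p if p in optimal else optimal[0]
                changes = _step_cost(ct, assign[nd], p)
                if changes:
                    nd.lengths[tag] = nd.lengths.get(tag, 0) + int(changes)
    for nd in nodes:
        if nd.parent is not None:
            nd.length = float(nd.total_changes)
    root.length = None
    return root


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def mp_bootstrap(
    m: CharMatrix,
    replicates: int,
    seed: int,
    reference: Optional[Node] = None,
    max_taxa: int = MAX_EXACT_TAXA,
) -> dict[frozenset, float]:
    """Maximum-parsimony bootstrap percentages for the reference tree's clades.

    Characters are resampled with replacement; each replicate contributes to
    a clade when the clade appears in the strict consensus of that
    replicate's most-parsimonious trees.  Deterministic for a fixed seed.

    Returns a mapping normalized bipartition (frozenset of taxon names on the
    side without the alphabetically first taxon) -> support percent.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    all_leaves = frozenset(m.taxa)
    if reference is None:
        _, trees = bnb_search(m, max_taxa)
        ref_splits = set.intersection(*(_tuple_splits(t, m.n_taxa) for t in trees))
        ref_named = {normalize_split(frozenset(m.taxa[i] for i in s), all_leaves) for s in ref_splits}
    else:
        ref_named = set(edge_splits(reference).keys())
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in ref_named}
    for _ in range(replicates):
        boot = m.resampled(rng)
        _, trees = bnb_search(boot, max_taxa)
        consensus = set.intersection(*(_tuple_splits(t, m.n_taxa) for t in trees))
        named = {normalize_split(frozenset(m.taxa[i] for i in s), all_leaves) for s in consensus}
        for s in ref_named:
            if s in named:
                counts[s] += 1
    return {s: 100.0 * c / replicates for s, c in counts.items()}


# ---------------------------------------------------------------------------
# pipeline: matrix -> annotated tree
# ---------------------------------------------------------------------------


def tuple_to_node(tree, taxa: Sequence[str]) -> Node:
    """Rooted Node tree for tuple topology ``tree``, rooted on taxon 0's edge."""

    def build(sub) -> Node:
        if isinstance(sub, int):
            return Node(taxa[sub])
        return Node(children=[build(sub[0]), build(sub[1])])

    return Node(children=[Node(taxa[0]), build(tree)])


def build_annotated_tree(
    m: CharMatrix,
    bootstrap_replicates: int = 0,
    seed: int = 0,
    max_taxa: int = MAX_EXACT_TAXA,
    compute_bremer: bool = True,
) -> Node:
    """Run the full parsimony stage: search, root, annotate.

    Branch-and-bound search selects the (canonically first) most-parsimonious
    topology; provisional DELTRAN change counts provide branch lengths for
    midpoint rooting; the rooted tree is re-annotated with final DELTRAN
    lengths, partitioned Bremer supports and (optionally) bootstrap
    percentages.
    """
    _, trees = bnb_search(m, max_taxa)
    mp = trees[0]
    if len(trees) > 1:
        warnings.warn(f"{len(trees)} equally parsimonious trees; annotating the canonically first")
    provisional = tuple_to_node(mp, m.taxa)
    deltran_lengths(provisional, m)
    rooted = midpoint_root(provisional)
    deltran_lengths(rooted, m)
    all_leaves = frozenset(m.taxa)
    splits = edge_splits(rooted)
    if compute_bremer:
        support = bremer(mp, m, max_taxa)
        for named, entry in support.items():
            node = splits.get(normalize_split(named, all_leaves))
            if node is None:
                continue
            node.total_bremer = entry["total"]
            node.bremer = {k: v for k, v in entry.items() if k != "total"}
    if bootstrap_replicates:
        boots = mp_bootstrap(m, bootstrap_replicates, seed, reference=rooted, max_taxa=max_taxa)
        for named, pct in boots.items():
            node = splits.get(named)
            if node is not None:
                node.bootstrap = pct
    return rooted
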