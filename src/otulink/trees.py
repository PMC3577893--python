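"""Phylogenetic tree structure with per-branch, per-partition annotations.

A tree is a rooted :class:`Node` hierarchy.  Every edge is identified with the
node below it and can carry the annotations the pipeline produces: integer
maximum-parsimony change counts per data partition (``lengths``), partitioned
Bremer support (``bremer``), a bootstrap percentage, and a within-species
mark.  Newick serialization writes these as a bracketed comment after the
branch length, e.g. ``A:3[&len_ITS=2,len_macromorphology=1,star=1]``, and
parsing restores them, so topology, lengths and annotations round-trip.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "to_newick",
    "midpoint_root",
    "leaf_path_lengths",
    "edge_splits",
    "normalize_split",
]


class Node:
    """A tree node; the edge to its parent carries this node's annotations."""

    __slots__ = ("name", "length", "children", "parent", "lengths", "bremer", "total_bremer", "bootstrap", "within_species")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None, children: Optional[list] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.lengths: dict[str, int] = {}
        self.bremer: dict[str, int] = {}
        self.total_bremer: Optional[float] = None
        self.bootstrap: Optional[float] = None
        self.within_species: bool = False
        for c in children or []:
            self.add(c)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def total_changes(self) -> int:
        """Sum of per-partition change counts on the edge above this node."""
        return sum(self.lengths.values())

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        new.lengths = dict(self.lengths)
        new.bremer = dict(self.bremer)
        new.total_bremer = self.total_bremer
        new.bootstrap = self.bootstrap
        new.within_species = self.within_species
        for c in self.children:
            new.add(c.copy())
        return new

    def find(self, name: str) -> "Node":
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def __repr__(self) -> str:
        return f"<Node {to_newick(self)}>"


# ---------------------------------------------------------------------------
# annotation comments
# ---------------------------------------------------------------------------


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x) == int(x) else f"{x:g}"


def _annotation_comment(node: Node) -> str:
    parts = []
    for k in sorted(node.lengths):
        parts.append(f"len_{k}={_fmt_num(node.lengths[k])}")
    for k in sorted(node.bremer):
        parts.append(f"brem_{k}={_fmt_num(node.bremer[k])}")
    if node.total_bremer is not None:
        parts.append(f"brem_total={_fmt_num(node.total_bremer)}")
    if node.bootstrap is not None:
        parts.append(f"boot={_fmt_num(node.bootstrap)}")
    if node.within_species:
        parts.append("star=1")
    return "[&" + ",".join(parts) + "]" if parts else ""


def _apply_annotation_comment(node: Node, comment: str) -> None:
    body = comment.strip()
    if body.startswith("&"):
        body = body[1:]
    for item in body.split(","):
        if "=" in item:
            key, val = item.split("=", 1)
            _apply_annotation(node, key, val)


def _apply_annotation(node: Node, key: str, val: str) -> None:
    if key.startswith("len_"):
        node.lengths[key[4:]] = int(float(val))
    elif key == "brem_total":
        node.total_bremer = float(val)
    elif key.startswith("brem_"):
        node.bremer[key[5:]] = int(float(val))
    elif key == "boot":
        node.bootstrap = float(val)
    elif key == "star":
        node.within_species = bool(int(val))


def to_newick(root: Node) -> str:
    """Serialize a tree to Newick with bracketed annotation comments."""

    def rec(n: Node) -> str:
        s = n.name or "" if n.is_leaf else "(" + ",".join(rec(c) for c in n.children) + ")" + (n.name or "")
        if n.length is not None:
            s += f":{_fmt_num(n.length)}"
        s += _annotation_comment(n)
        return s

    return rec(root) + ";"


def parse_newick(s: str) -> Node:
    """Parse a Newick string (with optional annotation comments) into a tree."""
    tree = dendropy.Tree.get(
        data=s,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = Node(name, dnode.edge.length)
        for ann in dnode.annotations:
            _apply_annotation(node, ann.name, str(ann.value))
        for comment in dnode.comments:
            _apply_annotation_comment(node, comment)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return convert(tree.seed_node)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def normalize_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical bipartition form: the side not containing the smallest leaf."""
    ref = min(all_leaves)
    return frozenset(all_leaves - side) if ref in side else frozenset(side)


def edge_splits(root: Node, internal_only: bool = True) -> dict[frozenset, Node]:
    """Map normalized bipartitions to the node below the corresponding edge.

    Trivial splits (single leaf or all-but-one) are excluded when
    ``internal_only`` is set.
    """
    all_leaves = frozenset(root.leaf_names())
    out: dict[frozenset, Node] = {}
    for n in root.preorder():
        if n is root:
            continue
        below = frozenset(n.leaf_names())
        if internal_only and (len(below) < 2 or len(below) > len(all_leaves) - 2):
            continue
        out[normalize_split(below, all_leaves)] = n
    return out


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------


def leaf_path_lengths(root: Node) -> dict[tuple[str, str], float]:
    """All pairwise leaf-to-leaf path lengths (edge ``length`` attributes)."""
    leaves = root.leaves()
    depth: dict[Node, float] = {}
    for n in root.preorder():
        depth[n] = (depth[n.parent] if n.parent else 0.0) + (n.length or 0.0)
    ancestors: dict[Node, list[Node]] = {}
    for lf in leaves:
        chain = []
        n = lf
        while n is not None:
            chain.append(n)
            n = n.parent
        ancestors[lf] = chain
    out = {}
    for i, a in enumerate(leaves):
        seta = set(ancestors[a])
        for b in leaves[i + 1 :]:
            lca = next(n for n in ancestors[b] if n in seta)
            key = tuple(sorted((a.name, b.name)))
            out[key] = depth[a] + depth[b] - 2 * depth[lca]
    return out


class _EdgePayload:
    __slots__ = ("length", "lengths", "bremer", "total_bremer", "bootstrap", "within_species")

    def __init__(self, node: Node):
        self.length = node.length
        self.lengths = node.lengths
        self.bremer = node.bremer
        self.total_bremer = node.total_bremer
        self.bootstrap = node.bootstrap
        self.within_species = node.within_species

    def apply(self, node: Node) -> None:
        node.length = self.length
        node.lengths = self.lengths
        node.bremer = self.bremer
        node.total_bremer = self.total_bremer
        node.bootstrap = self.bootstrap
        node.within_species = self.within_species


def _clear_edge(node: Node) -> None:
    node.length = None
    node.lengths = {}
    node.bremer = {}
    node.total_bremer = None
    node.bootstrap = None
    node.within_species = False


def _reroot_at_edge(v: Node, dist_below: float) -> Node:
    """Place a new root on the edge above ``v``, ``dist_below`` above v.

    The edge's annotations stay with v; the newly created upper half-edge
    carries only the remaining length.
    """
    u = v.parent
    if u is None:
        raise ValueError("cannot reroot above the root")
    u.children.remove(v)
    v.parent = None
    root = Node()
    root.add(v)
    upper_len = (v.length or 0.0) - dist_below
    v.length = dist_below if v.length is not None else None

    # reverse the path from u up to the old root; each reversed edge's payload
    # moves to its new child (the former parent)
    carry_len = upper_len
    carry_payload: Optional[_EdgePayload] = None
    prev = root
    node: Optional[Node] = u
    while node is not None:
        parent = node.parent
        if parent is not None:
            parent.children.remove(node)
        next_payload = _EdgePayload(node)
        _clear_edge(node)
        if carry_payload is not None:
            carry_payload.apply(node)
        node.length = carry_len
        prev.add(node)
        carry_len = next_payload.length if next_payload.length is not None else 0.0
        carry_payload = next_payload
        carry_payload.length = None
        prev = node
        node = parent
    # contract a leftover degree-1 old root
    _contract_unary(root)
    return root


def _merge_payloads(child: Node, parent_of_child: Node) -> None:
    """Fold the edge of ``parent_of_child`` into ``child`` (splice)."""
    child.length = (child.length or 0.0) + (parent_of_child.length or 0.0)
    merged = dict(parent_of_child.lengths)
    for k, val in child.lengths.items():
        merged[k] = merged.get(k, 0) + val
    child.lengths = merged
    child.bremer = child.bremer or parent_of_child.bremer
    child.total_bremer = child.total_bremer if child.total_bremer is not None else parent_of_child.total_bremer
    child.bootstrap = child.bootstrap if child.bootstrap is not None else parent_of_child.bootstrap
    child.within_species = child.within_species or parent_of_child.within_species


def _contract_unary(root: Node) -> None:
    for n in list(root.postorder()):
        if n is root or n.is_leaf or len(n.children) != 1:
            continue
        child = n.children[0]
        _merge_payloads(child, n)
        gp = n.parent
        idx = gp.children.index(n)
        gp.children[idx] = child
        child.parent = gp


def midpoint_root(tree: Node) -> Node:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Edge lengths are the ``length`` attributes.  Ties between equally long
    leaf pairs are broken by the lexicographically smallest (sorted) name
    pair, so the placement is deterministic.  A tree with all-zero lengths is
    rooted on the edge above its lexicographically first leaf, with a warning.
    """
    tree = tree.copy()
    paths = leaf_path_lengths(tree)
    if not paths:
        raise ValueError("midpoint rooting needs at least two leaves")
    dmax = max(paths.values())
    if dmax <= 0:
        warnings.warn("all path lengths are zero; rooting on the first leaf edge")
        first = min(tree.leaves(), key=lambda n: n.name)
        return _reroot_at_edge(first, 0.0)
    pair = min(k for k, val in paths.items() if val == dmax)
    a = tree.find(pair[0])
    b = tree.find(pair[1])
    # walk from a towards b, accumulating until we pass dmax / 2
    chain_a = []
    n = a
    while n is not None:
        chain_a.append(n)
        n = n.parent
    chain_b = []
    n = b
    while n is not None:
        chain_b.append(n)
        n = n.parent
    lca = next(x for x in chain_a if x in set(chain_b))
    path = chain_a[: chain_a.index(lca)] + list(reversed(chain_b[: chain_b.index(lca)]))
    # path = edges from a's side to b's side; edge i is above path[i] for the
    # a→lca stretch and above path[i] itself on the way down to b
    half = dmax / 2.0
    cum = 0.0
    up_count = chain_a.index(lca)
    for i, node in enumerate(path):
        elen = node.length or 0.0
        if cum + elen >= half or i == len(path) - 1:
            if i < up_count:
                # moving rootward from a: midpoint is (half - cum) above `node`
                return _reroot_at_edge(node, half - cum)
            # moving tipward towards b: midpoint is measured from the top of
            # the edge; distance below `node`'s child end is elen-(half-cum)
            return _reroot_at_edge(node, elen - (half - cum))
        cum += elen
    raise AssertionError("unreachable")
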