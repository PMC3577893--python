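"""Species-boundary estimation from phenotype-vs-DNA branch statistics.

The rationale: culture macromorphology and physiology evolve faster than the
ITS marker, so a branch on which the phenotype partitions contribute more
support or more changes than ITS reflects diversification *within* a
species.  Marking those branches and contracting them (together with
zero-length branches, which indicate clonal variants) partitions the leaves
into species: two leaves are conspecific exactly when the path between them
consists solely of contracted branches.  The resulting partition is the
reference against which ITS clustering thresholds are optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import Partition
from .trees import Node

__all__ = ["BoundaryConfig", "mark_within_species", "species_partition"]

DNA_PARTITION = "ITS"


@dataclass
class BoundaryConfig:
    """Configuration of the within-species branch-marking rule.

    ``use_support`` compares per-partition Bremer values (internal branches),
    ``use_lengths`` compares per-partition change counts (all branches); at
    least one must be on.  Comparisons are strict (phenotype must contribute
    *more* than the DNA partition).
    """

    phenotype_partitions: frozenset = frozenset({"macromorphology", "physiology"})
    dna_partition: str = DNA_PARTITION
    use_support: bool = True
    use_lengths: bool = True
    contract_zero_length: bool = True

    def __post_init__(self) -> None:
        if not (self.use_support or self.use_lengths):
            raise ValueError("at least one of use_support / use_lengths must be enabled")


def mark_within_species(tree: Node, cfg: BoundaryConfig = BoundaryConfig()) -> Node:
    """Set ``within_species`` on every branch the phenotype dominates.

    A branch is marked iff some phenotype partition p satisfies
    ``Bremer_p > Bremer_DNA`` (when ``use_support`` and the branch carries
    Bremer values) or ``length_p > length_DNA`` (when ``use_lengths``).
    Branches without length annotations are an error when lengths are used.
    """
    for node in tree.preorder():
        if node.parent is None:
            continue
        marked = False
        if cfg.use_lengths:
            if not node.lengths:
                raise ValueError(f"branch above {node.name or 'internal node'} lacks per-partition lengths")
            dna_len = node.lengths.get(cfg.dna_partition, 0)
            marked = any(node.lengths.get(p, 0) > dna_len for p in cfg.phenotype_partitions)
        if not marked and cfg.use_support and node.bremer:
            dna_sup = node.bremer.get(cfg.dna_partition, 0)
            marked = any(node.bremer.get(p, 0) > dna_sup for p in cfg.phenotype_partitions)
        node.within_species = marked
    return tree


def species_partition(tree: Node, cfg: BoundaryConfig = BoundaryConfig()) -> Partition:
    """Contract marked (and optionally zero-length) branches into species.

    Every marked branch, and every branch of zero total change count when
    ``contract_zero_length`` is set, is contracted; leaves connected through
    contracted branches only form one species.  Marking more branches can
    only merge species further, never split them.
    """
    parent_map: dict[Node, Node] = {}

    def find(x: Node) -> Node:
        while parent_map.get(x, x) is not x:
            parent_map[x] = parent_map.get(parent_map[x], parent_map[x])
            x = parent_map[x]
        return x

    def union(a: Node, b: Node) -> None:
        ra, rb = find(a), find(b)
        if ra is not rb:
            parent_map[ra] = rb

    for node in tree.preorder():
        parent_map.setdefault(node, node)
        if node.parent is None:
            continue
        zero = node.total_changes == 0 if node.lengths else (node.length or 0) == 0
        if node.within_species or (cfg.contract_zero_length and zero):
            union(node, node.parent)
    blocks: dict[Node, list[str]] = {}
    for leaf in tree.leaves():
        blocks.setdefault(find(leaf), []).append(leaf.name)
    return Partition.from_blocks(sorted(blocks.values(), key=min)).relabeled()
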