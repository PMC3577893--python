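"""Synthetic barcoding datasets with the structure the pipeline assumes.

The generator emulates a symbiont barcode survey: several species whose
within-species sequence divergence is well below the between-species
divergence (the barcode gap the threshold optimization relies on), partial
species labels (only some database entries carry full names), host genus and
species annotations with tunable host specificity, deposition years, and
coded phenotype characters (macromorphology, physiology) that change faster
within species than the DNA marker.

Sequences evolve by uniform substitution without indels on a star-of-stars
genealogy: a root sequence acquires disjoint diagnostic mutations per
species, and each sequence adds private mutations within its species — the
star shape mimics the clonal propagation of vertically transmitted fungal
symbionts.  Mutated positions are globally disjoint, so the configured
within/between p-distance bounds hold exactly.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import Partition, ReferencePartition
from .distances import DistanceMatrix
from .parsimony import CharMatrix
from .seqio import Msa, SeqRecord
from .trees import Node

__all__ = ["SynthConfig", "SynthTruth", "SimulatedDataset", "simulate_dataset", "simulate_worked_examples"]

_BASES = "ACGT"

HOST_GENERA = ["Macrotermes", "Odontotermes", "Microtermes", "Protermes", "Ancistrotermes", "Allodontermes", "Synacanthotermes"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the analysed system: six symbiont species with a handful
    of representatives each, an ITS-length marker, within-species p-distance
    at most 1% against between-species divergence of at least 5%, roughly
    two-thirds of entries labeled to species, three termite host genera with
    strong (but not absolute) host specificity, and 38 phenotype characters
    (30 ordered macromorphological, 8 binary physiological) that change
    faster within species than the marker does.
    """

    n_species: int = 6
    seqs_per_species: int = 5
    seq_length: int = 764
    d_within_max: float = 0.01
    d_between_min: float = 0.05
    label_fraction: float = 0.65
    n_hosts: int = 3
    host_specificity: float = 0.7
    host_annotation_rate: float = 0.7
    host_species_resolution: float = 0.5
    year_range: tuple = (1995, 2011)
    n_macro_chars: int = 30
    n_phys_chars: int = 8
    pheno_within_rate: float = 0.25
    pheno_between_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_within_max < self.d_between_min:
            raise ValueError("d_within_max must be below d_between_min")
        for name in ("n_species", "seqs_per_species", "seq_length", "n_hosts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynthTruth:
    """Generating truth: species partition, host map and the config used."""

    species: Partition
    hosts: dict[str, str]
    config: SynthConfig

    def reference(self, labeled_ids) -> ReferencePartition:
        return ReferencePartition({i: self.species.assignment[i] for i in labeled_ids})


@dataclass
class SimulatedDataset:
    msa: Msa
    meta: pd.DataFrame
    char_matrix: CharMatrix
    truth: SynthTruth

    @property
    def labeled_ids(self) -> list[str]:
        return list(self.meta.loc[self.meta["species_label"].notna(), "accession"])

    def reference(self) -> ReferencePartition:
        return ReferencePartition(
            {row.accession: row.species_label for row in self.meta.itertuples() if pd.notna(row.species_label)}
        )


def _mutate(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    current = seq[pos]
    choices = [b for b in _BASES if b != current]
    seq[pos] = choices[rng.integers(0, 3)]


def simulate_dataset(cfg: SynthConfig = SynthConfig()) -> SimulatedDataset:
    """Generate an aligned sequence family, metadata, phenotype characters
    and the generating truth, per the configured study conditions."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    n_total = cfg.n_species * cfg.seqs_per_species
    m_between = math.ceil(cfg.d_between_min * L)
    k_max = math.floor(cfg.d_within_max * L / 2)
    needed = cfg.n_species * m_between + n_total * k_max
    if needed > L:
        raise ValueError(
            f"divergence targets infeasible at length {L}: {needed} distinct mutated positions required"
        )
    positions = list(rng.permutation(L))
    root = [_BASES[i] for i in rng.integers(0, 4, size=L)]

    records = []
    species_map: dict[str, str] = {}
    pheno_rows = []
    genera = HOST_GENERA[: cfg.n_hosts] + [f"Genus{i:02d}" for i in range(max(0, cfg.n_hosts - len(HOST_GENERA)))]
    meta_rows = []

    n_chars = cfg.n_macro_chars + cfg.n_phys_chars
    pheno_root = np.zeros(n_chars, dtype=int)

    for s in range(cfg.n_species):
        label = f"species_{s + 1:02d}"
        ancestor = list(root)
        for _ in range(m_between):
            _mutate(ancestor, positions.pop(), rng)
        # phenotype species ancestor: slow between-species change
        pheno_anc = pheno_root.copy()
        _evolve_pheno(pheno_anc, cfg, cfg.pheno_between_rate, rng)
        primary = genera[int(rng.integers(0, len(genera)))]
        secondary = genera[(genera.index(primary) + 1) % len(genera)]
        for i in range(cfg.seqs_per_species):
            acc = f"SYN{s + 1:02d}{i + 1:02d}"
            seq = list(ancestor)
            for _ in range(int(rng.integers(0, k_max + 1))):
                _mutate(seq, positions.pop(), rng)
            records.append(SeqRecord(acc, "".join(seq), f"synthetic isolate {label}"))
            species_map[acc] = label
            tip = pheno_anc.copy()
            _evolve_pheno(tip, cfg, cfg.pheno_within_rate, rng)
            pheno_rows.append(tip)
            genus = primary if rng.random() < cfg.host_specificity else secondary
            annotated = rng.random() < cfg.host_annotation_rate
            resolved = annotated and rng.random() < cfg.host_species_resolution
            meta_rows.append(
                {
                    "accession": acc,
                    "organism": "Termitomyces sp." if rng.random() > cfg.label_fraction else f"Termitomyces {label}",
                    "species_label": None,  # filled below
                    "host_genus": genus if annotated else None,
                    "host_species": f"{genus} sym{s + 1}" if resolved else None,
                    "country": None,
                    "deposition_year": float(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1)),
                }
            )

    # species labels on a random subset of the requested size
    n_labeled = round(cfg.label_fraction * n_total)
    labeled_idx = set(rng.choice(n_total, size=n_labeled, replace=False).tolist())
    for i, row in enumerate(meta_rows):
        if i in labeled_idx:
            row["species_label"] = species_map[row["accession"]]
    meta = pd.DataFrame(meta_rows)

    msa = Msa(records)
    its = CharMatrix.from_msa(msa, "ITS")
    pheno_data = np.vstack(pheno_rows)
    macro = CharMatrix(
        msa.ids,
        pheno_data[:, : cfg.n_macro_chars],
        ["ordered"] * cfg.n_macro_chars,
        ["macromorphology"] * cfg.n_macro_chars,
    )
    phys = CharMatrix(
        msa.ids,
        pheno_data[:, cfg.n_macro_chars :],
        ["unordered"] * cfg.n_phys_chars,
        ["physiology"] * cfg.n_phys_chars,
    )
    combined = CharMatrix.concat([its, macro, phys])
    truth = SynthTruth(Partition(species_map), {r["accession"]: r["host_genus"] for r in meta_rows}, cfg)
    return SimulatedDataset(msa, meta, combined, truth)


def _evolve_pheno(states: np.ndarray, cfg: SynthConfig, rate: float, rng: np.random.Generator) -> None:
    """One edge of phenotype evolution: ordered macromorphology steps +-1 in
    0..2, binary physiology flips, each character changing with ``rate``."""
    for j in range(len(states)):
        if rng.random() >= rate:
            continue
        if j < cfg.n_macro_chars:  # ordered, states 0..2
            if states[j] == 0:
                states[j] = 1
            elif states[j] == 2:
                states[j] = 1
            else:
                states[j] = 0 if rng.random() < 0.5 else 2
        else:  # binary
            states[j] = 1 - states[j]


# ---------------------------------------------------------------------------
# hand-checkable worked examples
# ---------------------------------------------------------------------------


def _species_example_tree() -> Node:
    """A nine-culture annotated phylogeny whose boundary rule yields six species.

    Reconstructs the qualitative situation of the study system: three
    zero-length terminals (clonal variants), two terminals with more
    phenotype than DNA changes, a within-species internal branch and the
    root branch better supported by macromorphology than by ITS, and two
    backbone branches with negative macromorphology support.  The exact
    topology is one consistent reading of the published description, not a
    certainty; it is a synthetic reconstruction.
    """

    def leaf(name, its, macro, phys):
        n = Node(name)
        n.lengths = {"ITS": its, "macromorphology": macro, "physiology": phys}
        n.length = float(its + macro + phys)
        return n

    def internal(children, its, macro, phys, brem=None):
        n = Node(children=children)
        n.lengths = {"ITS": its, "macromorphology": macro, "physiology": phys}
        n.length = float(its + macro + phys)
        if brem:
            n.bremer = {"ITS": brem[0], "macromorphology": brem[1], "physiology": brem[2]}
            n.total_bremer = sum(brem)
        return n

    a = leaf("A", 0, 0, 0)
    a1 = leaf("A1", 0, 0, 0)
    f = leaf("F", 0, 2, 1)  # phenotype-dominated terminal
    aa1 = internal([a, a1], 1, 2, 0, brem=(1, 2, 2))  # within-species internal branch
    x = internal([aa1, f], 1, 0, 0, brem=(1, 2, 0))  # the root branch
    b2 = leaf("B2", 0, 0, 0)
    d2 = leaf("D2", 0, 1, 0)  # phenotype-dominated terminal
    b2d2 = internal([b2, d2], 4, 0, 0, brem=(3, 1, 0))
    d1 = leaf("D1", 6, 1, 0)
    inner = internal([d1, b2d2], 3, 1, 0, brem=(3, -1, 0))  # negative macromorphology support
    b1 = leaf("B1", 5, 1, 1)
    left = internal([b1, inner], 4, 0, 0, brem=(3, -1, 1))  # negative macromorphology support
    c = leaf("C", 5, 0, 1)
    e = leaf("E", 7, 1, 0)
    ce = internal([c, e], 2, 0, 0, brem=(2, 0, 0))
    y = internal([left, ce], 3, 1, 0, brem=(4, 1, 0))
    return Node(children=[x, y])


def simulate_worked_examples() -> dict:
    """Small deterministic fixtures used across the documentation and tests."""
    chain = DistanceMatrix(["A", "B", "C"], np.array([[0.0, 0.01, 0.05], [0.01, 0.0, 0.01], [0.05, 0.01, 0.0]]))
    four_taxon = CharMatrix(
        ["t1", "t2", "t3", "t4"],
        np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        ["unordered", "unordered"],
        ["ITS", "ITS"],
    )
    # partition "one" cleanly supports ((t1,t2),(t3,...)); partition "two" conflicts
    six_taxon_conflict = CharMatrix(
        ["t1", "t2", "t3", "t4", "t5", "t6"],
        np.array(
            [
                # one: t1,t2 | rest (3 chars)   two: t1,t3 | rest (1 char)
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [0, 0, 0, 1],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        ),
        ["unordered"] * 4,
        ["one", "one", "one", "two"],
    )
    coverage_meta = pd.DataFrame(
        {
            "accession": [f"X{i}" for i in range(1, 7)],
            "host_genus": ["Macrotermes", "Macrotermes", None, None, None, "Microtermes"],
            "host_species": ["Macrotermes michaelseni", None, None, None, None, None],
            "deposition_year": [2000.0, 2000.0, 2001.0, 2001.0, 2002.0, 2002.0],
        }
    )
    coverage_partition = Partition({"X1": "c1", "X2": "c1", "X3": "c2", "X4": "c2", "X5": "c3", "X6": "c3"})
    return {
        "chain_distances": chain,
        "four_taxon_matrix": four_taxon,
        "six_taxon_conflict": six_taxon_conflict,
        "species_example_tree": _species_example_tree(),
        "coverage_partition": coverage_partition,
        "coverage_meta": coverage_meta,
        "coverage_years": [2000.0, 2001.0, 2002.0],
    }
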