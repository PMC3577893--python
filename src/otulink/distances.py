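"""Pairwise sequence dissimilarities, alignment overlap filtering and
representative-sequence screening.

All distances handled here are *uncorrected* p-distances: the fraction of
mismatching sites among the alignment columns in which both members of a pair
carry a residue (pairwise deletion of gaps and missing data).  Thresholds are
expressed as fractions in [0, 1] throughout; percentages quoted at interfaces
are divided by 100 before they reach this module.

Local-alignment similarity (used to screen redundant per-host sequences
against a designated representative culture) follows the Smith–Waterman
algorithm with affine gap costs, and reports percent identity over the local
alignment length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seqio import Msa, SeqRecord

__all__ = [
    "DistanceMatrix",
    "SimilarityReport",
    "sw_similarity",
    "p_distance_matrix",
    "overlap_filter",
    "overlap_table",
    "screen_representatives",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise dissimilarities in [0, 1].

    Parameters
    ----------
    ids : list of str
        Element identifiers, in matrix row/column order.
    d : ndarray of shape (n, n)
        Symmetric dissimilarities with zero diagonal.
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {x: i for i, x in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.d[idx[a], idx[b]])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = self.index
        rows = [idx[k] for k in keep]
        return DistanceMatrix(list(keep), self.d[np.ix_(rows, rows)])

    def max_offdiag(self) -> float:
        if len(self.ids) < 2:
            return 0.0
        mask = ~np.eye(len(self.ids), dtype=bool)
        return float(self.d[mask].max())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.d, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.index], df.to_numpy(dtype=float))


@dataclass
class SimilarityReport:
    """Percent identity of a query against a subject over a local alignment."""

    query: str
    subject: str
    percent_similarity: float
    alignment_length: int = 0
    identities: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_similarity <= 100.0:
            raise ValueError("percent_similarity outside [0, 100]")


# EDNAFULL-like defaults mirroring the EMBOSS water conventions.
_DEFAULT_SCORING = {"match": 5.0, "mismatch": -4.0, "gap_open": 10.0, "gap_extend": 0.5}


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_similarity(
    a: SeqRecord,
    b: SeqRecord,
    match: float = _DEFAULT_SCORING["match"],
    mismatch: float = _DEFAULT_SCORING["mismatch"],
    gap_open: float = _DEFAULT_SCORING["gap_open"],
    gap_extend: float = _DEFAULT_SCORING["gap_extend"],
) -> SimilarityReport:
    """Optimal local (Smith–Waterman) alignment similarity of two sequences.

    Gap characters are stripped before alignment.  The reported value is
    ``100 * identities / alignment_columns`` over the optimal local alignment
    under affine gap costs (a gap of length L costs ``gap_open + L *
    gap_extend``).

    Returns
    -------
    SimilarityReport
    """
    sa = a.residues.replace("-", "").replace("?", "")
    sb = b.residues.replace("-", "").replace("?", "")
    if not sa or not sb:
        raise ValueError(f"empty sequence in pair ({a.id}, {b.id})")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    pct = 100.0 * counts.identities / length if length else 0.0
    return SimilarityReport(a.id, b.id, pct, alignment_length=length, identities=counts.identities)


_GAPCODES = (ord("-"), ord("?"))


def _encode_msa(msa: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode an alignment; returns (codes, residue mask)."""
    arr = np.frombuffer("".join(r.residues for r in msa.records).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(msa.records), msa.length)
    mask = ~np.isin(arr, _GAPCODES)
    return arr, mask


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Uncorrected pairwise distances with pairwise deletion of gaps.

    ``d(i, j)`` is the number of mismatches divided by the number of columns
    in which both sequences carry a residue.  A pair with zero shared residue
    columns is an error (no distance is defined for it).
    """
    arr, mask = _encode_msa(msa)
    n = len(msa.records)
    ids = [r.id for r in msa.records]
    d = np.zeros((n, n))
    for i in range(n):
        both = mask[i] & mask[i + 1 :]
        overlap = both.sum(axis=1)
        if np.any(overlap == 0):
            j = int(np.argmax(overlap == 0)) + i + 1
            raise ValueError(f"zero alignment overlap between {ids[i]} and {ids[j]}")
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = mism / overlap
    d = d + d.T
    return DistanceMatrix(ids, d)


def _overlap_counts(msa: Msa, target_ids: set[str], informative: str) -> dict[str, int]:
    """Per-record count of columns shared (non-gap) with at least one target."""
    arr, mask = _encode_msa(msa)
    ids = [r.id for r in msa.records]
    tset = set(target_ids)
    missing = tset - set(ids)
    if missing:
        raise ValueError(f"target ids not in alignment: {sorted(missing)}")
    tmask = np.array([i in tset for i in ids])
    target_cols = mask[tmask].any(axis=0)
    if informative == "variable":
        # restrict to columns with >= 2 distinct residues across the alignment
        var = np.zeros(msa.length, dtype=bool)
        for c in range(msa.length):
            col = arr[mask[:, c], c]
            var[c] = len(np.unique(col)) >= 2
        target_cols = target_cols & var
    elif informative != "shared":
        raise ValueError("informative must be 'shared' or 'variable'")
    return {ids[i]: int((mask[i] & target_cols).sum()) for i in range(len(ids))}


def overlap_filter(
    msa: Msa,
    target_ids: Iterable[str],
    min_overlap: int,
    informative: str = "shared",
) -> Msa:
    """Reduce an alignment to targets plus records sufficiently overlapping them.

    A non-target record is retained iff the number of columns that are
    simultaneously non-gap in it and in at least one target is at least
    ``min_overlap``.  With ``informative='variable'`` only alignment columns
    with at least two distinct residues are counted (the stricter reading of
    "informative sites"); the default counts every shared residue column.
    """
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    tset = set(target_ids)
    counts = _overlap_counts(msa, tset, informative)
    keep = [r for r in msa.records if r.id in tset or counts[r.id] >= min_overlap]
    return Msa(keep)


def overlap_table(
    msa: Msa,
    target_ids: Iterable[str],
    thresholds: Sequence[int],
    informative: str = "shared",
) -> pd.DataFrame:
    """Retained alignment size per minimum-overlap threshold.

    Reproduces the shape of a size-vs-overlap sensitivity table: one row per
    threshold, with the number of retained sequences.  Monotonically
    non-increasing in the threshold.
    """
    tset = set(target_ids)
    counts = _overlap_counts(msa, tset, informative)
    rows = []
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        n = sum(1 for r in msa.records if r.id in tset or counts[r.id] >= t)
        rows.append({"min_overlap": int(t), "retained": n})
    return pd.DataFrame(rows)


def screen_representatives(
    groups: Mapping[str, Sequence[SeqRecord]],
    representatives: Mapping[str, SeqRecord],
    categories: Mapping[str, str] | None = None,
    **scoring,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity of every member sequence to its host's representative.

    Parameters
    ----------
    groups : mapping host -> sequences
    representatives : mapping host -> designated representative sequence
    categories : optional mapping sequence id -> source category
        e.g. culture / nodule / gut-specific / gut-clone.

    Returns
    -------
    (reports, summary) : DataFrames
        Per-sequence percent similarities, and min/max summaries per host and
        per (host, category).
    """
    rows = []
    for host, members in groups.items():
        if host not in representatives:
            raise ValueError(f"host {host!r} has no designated representative")
        rep = representatives[host]
        if not members:
            warnings.warn(f"host {host!r} has no member sequences")
            continue
        for m in members:
            rep_report = sw_similarity(m, rep, **scoring)
            rows.append(
                {
                    "host": host,
                    "query": m.id,
                    "subject": rep.id,
                    "category": (categories or {}).get(m.id, "unknown"),
                    "percent_similarity": rep_report.percent_similarity,
                }
            )
    reports = pd.DataFrame(rows, columns=["host", "query", "subject", "category", "percent_similarity"])
    if reports.empty:
        return reports, pd.DataFrame(columns=["host", "category", "min", "max", "n"])
    summary = (
        reports.groupby(["host", "category"])["percent_similarity"]
        .agg(["min", "max", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return reports, summary
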