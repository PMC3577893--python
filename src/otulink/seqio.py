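"""Readers and writers for the external formats of the pipeline.

Covers plain and aligned FASTA, GenBank flat files (metadata only), coded
character matrices (CSV with documented header rows), partition TSV files and
Newick trees with bracketed annotation comments.

Conventions: the gap symbol is ``-`` and missing data is ``?`` everywhere;
residues are upper-cased on input; record ids are the first
whitespace-delimited token of a FASTA header.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "SeqRecord",
    "Msa",
    "SeqMeta",
    "read_fasta",
    "write_fasta",
    "parse_genbank_flatfiles",
    "read_char_matrix",
    "write_char_matrix",
    "read_partition_tsv",
    "write_partition_tsv",
    "read_newick",
    "write_newick",
]

# IUPAC DNA codes plus gap and missing
_VALID_RESIDUES = frozenset("ACGTURYSWKMBDHVN-?")


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence; residues may contain ``-`` (gap) and ``?``."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has no residues")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"record {self.id!r} contains illegal residue characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


class Msa:
    """A multiple sequence alignment: equal-length records, two or more."""

    def __init__(self, records: Sequence[SeqRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in alignment: {dup}")
        self.records: list[SeqRecord] = records
        self.length: int = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rec_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass
class SeqMeta:
    """Per-accession metadata extracted from a GenBank flat file."""

    accession: str
    organism: str = ""
    host_genus: Optional[str] = None
    host_species: Optional[str] = None
    country: Optional[str] = None
    deposition_year: Optional[float] = None

    def __post_init__(self) -> None:
        if self.host_species and not self.host_genus:
            raise ValueError("host_species implies host_genus")
        if self.deposition_year is not None and self.deposition_year <= 1980:
            raise ValueError(f"implausible deposition year {self.deposition_year}")


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order.

    Residues are upper-cased; duplicate ids and illegal residue characters
    raise a format error naming the offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description and r.description != r.id else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


_NOT_EPITHET = {"sp", "spp", "cf", "aff"}


def _split_host(qualifier: str) -> tuple[Optional[str], Optional[str]]:
    """Genus = first token; species only for a real binomial (not 'sp.')."""
    tokens = qualifier.strip().split()
    if not tokens:
        return None, None
    genus = tokens[0]
    if len(tokens) >= 2 and tokens[1].rstrip(".").lower() not in _NOT_EPITHET:
        return genus, f"{genus} {tokens[1]}"
    return genus, None


def _host_from_free_text(text: str) -> tuple[Optional[str], Optional[str]]:
    """Heuristic for free-text qualifiers (isolation_source): the first
    capitalized genus-like token, plus a following lowercase epithet."""
    tokens = text.strip().split()
    for i, tok in enumerate(tokens):
        if re.fullmatch(r"[A-Z][a-z]{2,}", tok):
            nxt = tokens[i + 1] if i + 1 < len(tokens) else ""
            if re.fullmatch(r"[a-z]{3,}", nxt.rstrip(".")) and nxt.rstrip(".").lower() not in _NOT_EPITHET:
                return tok, f"{tok} {nxt}"
            return tok, None
    return None, None


def parse_genbank_flatfiles(paths: Iterable, recode_incomplete_year: Optional[int] = None) -> pd.DataFrame:
    """Extract SeqMeta from GenBank flat files into a DataFrame.

    Organism comes from the ORGANISM line, host from the ``/host`` qualifier
    (falling back to ``/isolation_source``), country from ``/country``, and the
    deposition year from the LOCUS-line date.  When ``recode_incomplete_year``
    is given (e.g. 2012 for a mid-year snapshot), records deposited in that
    year are recoded as ``year - 0.5``.

    Records without a parseable LOCUS date keep an absent year (with a logged
    warning); records that fail to parse are skipped with a warning.
    """
    rows = []
    for path in [paths] if isinstance(paths, (str, Path)) else list(paths):
        for rec in SeqIO.parse(str(path), "genbank"):
            try:
                meta = _meta_from_record(rec, recode_incomplete_year)
            except Exception as exc:  # malformed record: skip, keep going
                logger.warning("skipping unparseable record in %s: %s", path, exc)
                continue
            rows.append(meta)
    return pd.DataFrame(
        [
            {
                "accession": m.accession,
                "organism": m.organism,
                "host_genus": m.host_genus,
                "host_species": m.host_species,
                "country": m.country,
                "deposition_year": m.deposition_year,
            }
            for m in rows
        ]
    )


def _meta_from_record(rec, recode_incomplete_year: Optional[int]) -> SeqMeta:
    organism = rec.annotations.get("organism", "")
    genus = species = None
    country = None
    for feat in rec.features:
        if feat.type == "source":
            q = feat.qualifiers
            country = (q.get("country") or q.get("geo_loc_name") or [None])[0]
            host_q = (q.get("host") or [None])[0]
            if host_q:
                genus, species = _split_host(host_q)
            else:
                iso = (q.get("isolation_source") or [None])[0]
                if iso:
                    genus, species = _host_from_free_text(iso)
            break
    year: Optional[float] = None
    date = rec.annotations.get("date")
    if date:
        m = re.search(r"(\d{4})", date)
        if m:
            year = float(m.group(1))
            if recode_incomplete_year is not None and year == recode_incomplete_year:
                year -= 0.5
    accession = rec.name or rec.id  # LOCUS name, without the version suffix
    if year is None:
        logger.warning("record %s has no LOCUS date; year left absent", accession)
    return SeqMeta(accession, organism, genus, species, country, year)


# ---------------------------------------------------------------------------
# coded character matrices
#
# CSV layout (documented contract):
#   taxon,<char1>,<char2>,...          header with character names
#   #type,unordered,ordered,...        per-character type row
#   #partition,ITS,macromorphology,... per-character partition tag row
#   <taxon id>,0,1,?,...               one data row per taxon
# ---------------------------------------------------------------------------


def read_char_matrix(path):
    """Read a coded character matrix (see module docstring for the layout)."""
    from .parsimony import CharMatrix  # local import to avoid a cycle

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 4:
        raise ValueError(f"character matrix {path} is too short")
    header = lines[0].split(",")
    ncols = len(header) - 1
    type_row = lines[1].split(",")
    part_row = lines[2].split(",")
    if type_row[0] != "#type" or part_row[0] != "#partition":
        raise ValueError("expected '#type' and '#partition' header rows")
    if len(type_row) - 1 != ncols or len(part_row) - 1 != ncols:
        raise ValueError("header rows do not match the number of characters")
    ctypes = type_row[1:]
    partitions = part_row[1:]
    for t in ctypes:
        if t not in ("unordered", "ordered"):
            raise ValueError(f"unknown character type {t!r}")
    taxa, data = [], []
    for ln in lines[3:]:
        cells = ln.split(",")
        if len(cells) - 1 != ncols:
            raise ValueError(f"ragged row for taxon {cells[0]!r}: {len(cells) - 1} cells, expected {ncols}")
        taxa.append(cells[0])
        row = []
        for c in cells[1:]:
            c = c.strip()
            if c == "?":
                row.append(-1)
            elif re.fullmatch(r"\d+", c):
                row.append(int(c))
            else:
                raise ValueError(f"unknown state symbol {c!r} for taxon {cells[0]!r}")
        data.append(row)
    return CharMatrix(taxa, np.array(data, dtype=int), ctypes, partitions, names=header[1:])


def write_char_matrix(matrix, path) -> None:
    with open(path, "w") as fh:
        names = matrix.names or [f"c{i + 1}" for i in range(matrix.n_chars)]
        fh.write("taxon," + ",".join(names) + "\n")
        fh.write("#type," + ",".join(matrix.ctypes) + "\n")
        fh.write("#partition," + ",".join(matrix.partitions) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            states = ["?" if s < 0 else str(int(s)) for s in matrix.data[i]]
            fh.write(taxon + "," + ",".join(states) + "\n")


# ---------------------------------------------------------------------------
# partition TSV: element <TAB> cluster
# ---------------------------------------------------------------------------


def read_partition_tsv(path):
    from .clustering import Partition

    assignment = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#") or ln == "element\tcluster":
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed partition line {ln!r}")
            if parts[0] in assignment:
                raise ValueError(f"element {parts[0]!r} assigned twice")
            assignment[parts[0]] = parts[1]
    return Partition(assignment)


def write_partition_tsv(partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("element\tcluster\n")
        for el in sorted(partition.assignment):
            fh.write(f"{el}\t{partition.assignment[el]}\n")


def read_newick(path_or_string):
    from .trees import parse_newick

    s = path_or_string
    try:
        if isinstance(s, (str, Path)) and Path(str(s)).exists():
            s = Path(str(s)).read_text()
    except OSError:  # a raw newick string, not a path
        pass
    return parse_newick(str(s))


def write_newick(tree, path=None) -> str:
    from .trees import to_newick

    s = to_newick(tree)
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
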