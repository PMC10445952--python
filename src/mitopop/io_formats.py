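"""Readers and writers for every external representation the pipeline touches.

Aligned multi-FASTA, the genome feature table (tab-separated, 1-based
inclusive coordinates on the heavy-strand numbering), the segmental-PCR
primer table, Newick trees and GraphML haplotype networks.  Coordinates are
1-based inclusive throughout the package; no half-open convention exists
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    CoordinateError,
    DuplicateNameError,
)

ALPHABET = frozenset("ACGTN-")
#: Characters treated as missing for "complete deletion" column filtering.
MISSING = frozenset("-N")


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A named, equal-length set of nucleotide rows.

    Parameters
    ----------
    names
        Ordered, unique identifiers, one per row.
    rows
        Upper-case nucleotide strings over ``{A,C,G,T,-,N}``, all of the
        same length.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise AlignmentShapeError("names and rows differ in count")
        if not self.rows:
            raise AlignmentShapeError("alignment is empty")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise DuplicateNameError(f"duplicate sequence names: {dupes}")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentShapeError("alignment has zero columns")
        for name, row in zip(self.names, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"row {name!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlphabetError(f"row {name!r} contains {sorted(bad)}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        names, rows = [], []
        for name, seq in records:
            names.append(name)
            rows.append(seq.upper())
        return cls(tuple(names), tuple(rows))

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def column(self, col: int) -> str:
        """Column ``col`` (1-based) across all rows."""
        if not 1 <= col <= self.length:
            raise CoordinateError(f"column {col} outside 1..{self.length}")
        return "".join(r[col - 1] for r in self.rows)

    def drop_rows(self, names: Sequence[str]) -> "AlignedSequenceSet":
        keep = [(n, r) for n, r in zip(self.names, self.rows) if n not in set(names)]
        return AlignedSequenceSet.from_records(keep)


@dataclass(frozen=True)
class FeatureRecord:
    """One genome feature on the circular molecule.

    ``start``/``end`` are 1-based inclusive on the heavy-strand numbering;
    no feature spans the origin in this schema.  ``printed_size`` keeps the
    size column of the source table verbatim: it is audited downstream, not
    trusted.  The stop codon may be the incomplete form ``"T--"``
    (polyadenylation-completed stop, common in mitogenomes).
    """

    name: str
    start: int
    end: int
    strand: str = "H"
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    printed_size: int | None = None
    printed_space: int | None = None

    def __post_init__(self):
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start {self.start} < 1 (1-based)")
        if self.end < self.start:
            raise CoordinateError(f"{self.name}: end {self.end} < start {self.start}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L, got {self.strand!r}")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its intended target region."""

    gene: str
    region_start: int
    region_end: int
    fwd: str
    rev: str
    expected_size: int
    tm_fwd: float | None = None
    tm_rev: float | None = None

    def __post_init__(self):
        for label, p in (("fwd", self.fwd), ("rev", self.rev)):
            if not p or set(p) - set("ACGT"):
                raise AlphabetError(f"{self.gene} {label} primer invalid: {p!r}")
        if self.expected_size < 1:
            raise ValueError(f"{self.gene}: expected_size must be >= 1")


# ---------------------------------------------------------------------------
# FASTA


def read_alignment(path) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA into an :class:`AlignedSequenceSet`.

    Input order is preserved.  Ragged alignments, duplicate names and
    non-IUPAC characters raise the corresponding errors.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return AlignedSequenceSet.from_records(records)


def write_alignment(aln: AlignedSequenceSet, path) -> None:
    recs = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature and primer tables


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def _opt_int(v) -> int | None:
    s = _opt_str(v)
    return int(float(s)) if s is not None else None


def read_feature_table(path) -> list[FeatureRecord]:
    """Read a tab-separated feature table into records, in file order.

    Required columns: ``name``, ``start``, ``end``, ``strand`` (an empty
    strand defaults to H).  Optional: ``size`` (kept as ``printed_size``,
    recomputed downstream), ``start_codon``, ``stop_codon``, ``anticodon``,
    ``space`` (printed inter-feature delta, audited downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        strand = _opt_str(row.get("strand")) or "H"
        out.append(
            FeatureRecord(
                name=str(row["name"]).strip(),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=strand,
                start_codon=_opt_str(row.get("start_codon")),
                stop_codon=_opt_str(row.get("stop_codon")),
                anticodon=_opt_str(row.get("anticodon")),
                printed_size=_opt_int(row.get("size")),
                printed_space=_opt_int(row.get("space")),
            )
        )
    return out


def write_feature_table(features: Sequence[FeatureRecord], path) -> None:
    rows = [
        {
            "name": f.name,
            "start": f.start,
            "end": f.end,
            "size": f.printed_size,
            "start_codon": f.start_codon,
            "stop_codon": f.stop_codon,
            "anticodon": f.anticodon,
            "strand": f.strand,
            "space": f.printed_space,
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_primer_table(path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        tm_f, tm_r = _opt_str(row.get("tm_fwd")), _opt_str(row.get("tm_rev"))
        out.append(
            PrimerPair(
                gene=str(row["gene"]).strip(),
                region_start=int(row["region_start"]),
                region_end=int(row["region_end"]),
                fwd=str(row["fwd"]).strip().upper(),
                rev=str(row["rev"]).strip().upper(),
                expected_size=int(row["expected_size"]),
                tm_fwd=float(tm_f) if tm_f else None,
                tm_rev=float(tm_r) if tm_r else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged reference tables (the published chicken mitogenome layout/primers)

_DATA = Path(__file__).parent / "data"


def load_chicken_features() -> list[FeatureRecord]:
    """The published 19-feature chicken mitogenome organization table."""
    return read_feature_table(_DATA / "chicken_mtdna_features.tsv")


def load_chicken_primers() -> list[PrimerPair]:
    """The published 15 segmental-amplification primer pairs."""
    return read_primer_table(_DATA / "chicken_mtdna_primers.tsv")


def load_printed_rate_matrix() -> pd.DataFrame:
    """The published 4x4 instantaneous substitution-rate table (A,T,C,G order).

    Off-diagonal entries are relative rates normalised so their sum is 100;
    the diagonal is empty (NaN).
    """
    return pd.read_csv(
        _DATA / "substitution_rates_printed.tsv", sep="\t", index_col=0
    )


# ---------------------------------------------------------------------------
# Newick / GraphML (delegating to the tree and network objects)


def write_newick(tree, path) -> None:
    """Serialize a phylogenetic tree: branch lengths to 6 decimals, integer
    support labels on internal nodes."""
    Path(path).write_text(tree.to_newick() + "\n")


def write_graphml(net, path) -> None:
    """Serialize a haplotype network; nodes carry ``kind`` and ``frequency``,
    edges carry the comma-joined list of mutated 1-based positions."""
    import networkx as nx

    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        data["positions"] = ",".join(str(p) for p in data["positions"])
    nx.write_graphml(g, str(path))
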