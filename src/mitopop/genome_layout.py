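"""Genome-organization analytics for a circular mitogenome.

Recomputes everything a feature table asserts — feature lengths,
inter-feature spacing and overlap, start/stop codons, base composition —
and audits the table's own printed values against the recomputation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import CoordinateError, EmptyInputError, OrderingError
from .io_formats import MISSING, FeatureRecord

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered feature list on a circular molecule of known length."""

    features: tuple[FeatureRecord, ...]
    genome_length: int
    circular: bool = True

    def __post_init__(self):
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise OrderingError("features must be sorted by start coordinate")
        if self.features and self.genome_length < max(f.end for f in self.features):
            raise CoordinateError("genome_length smaller than the last feature end")


@dataclass(frozen=True)
class AdjacencyReport:
    """Spacer/overlap classification of consecutive feature pairs.

    ``delta = start(next) - end(prev)``; a positive delta is a spacer of
    that many bases, a delta <= 0 is an overlap.  ``shared_bases`` is the
    other convention (``end(prev) - start(next) + 1``), reported alongside
    because published tables mix the two.
    """

    pairs: tuple[tuple[str, str, int], ...]
    n_spacers: int
    n_overlaps: int
    min_spacer: int | None
    max_spacer: int | None

    @property
    def shared_bases(self) -> tuple[tuple[str, str, int], ...]:
        return tuple((a, b, 1 - d) for a, b, d in self.pairs if d <= 0)


def feature_length(f: FeatureRecord) -> int:
    """Length in bp of a 1-based inclusive feature: ``end - start + 1``."""
    return f.end - f.start + 1


def adjacency_deltas(layout: GenomeLayout) -> AdjacencyReport:
    """Classify every consecutive feature pair as spacer or overlap."""
    feats = layout.features
    if len(feats) < 2:
        raise ValueError("need at least two features for adjacency analysis")
    pairs = []
    for prev, nxt in zip(feats, feats[1:]):
        pairs.append((prev.name, nxt.name, nxt.start - prev.end))
    spacers = [d for _, _, d in pairs if d > 0]
    overlaps = [d for _, _, d in pairs if d <= 0]
    return AdjacencyReport(
        pairs=tuple(pairs),
        n_spacers=len(spacers),
        n_overlaps=len(overlaps),
        min_spacer=min(spacers) if spacers else None,
        max_spacer=max(spacers) if spacers else None,
    )


def audit_printed_sizes(features: Iterable[FeatureRecord]) -> list[dict]:
    """Features whose printed size column disagrees with ``end - start + 1``.

    Features without a printed size are skipped (nothing to audit).
    """
    out = []
    for f in features:
        if f.printed_size is None:
            continue
        computed = feature_length(f)
        if f.printed_size != computed:
            out.append(
                {"name": f.name, "printed": f.printed_size, "computed": computed}
            )
    return out


def audit_printed_spaces(layout: GenomeLayout) -> list[dict]:
    """Printed inter-feature deltas that disagree with the recomputation."""
    report = adjacency_deltas(layout)
    out = []
    for (prev_name, name, delta), feat in zip(report.pairs, layout.features[1:]):
        if feat.printed_space is not None and feat.printed_space != delta:
            out.append(
                {
                    "prev": prev_name,
                    "name": name,
                    "printed": feat.printed_space,
                    "computed": delta,
                }
            )
    return out


def extract_codons(genome: str, f: FeatureRecord) -> tuple[str, str]:
    """Start and stop codon of a feature read off the genome sequence.

    L-strand features are reverse-complemented before reading.  When the
    feature length is not a multiple of 3 the stop is reported in the
    incomplete, dash-padded form (e.g. ``"T--"``), the convention for
    polyadenylation-completed mitochondrial stops.
    """
    if f.end > len(genome):
        raise CoordinateError(f"{f.name}: end {f.end} beyond genome ({len(genome)})")
    sub = genome[f.start - 1 : f.end].upper()
    if f.strand == "L":
        sub = reverse_complement(sub)
    start_codon = sub[:3]
    rem = len(sub) % 3
    if rem == 0:
        stop_codon = sub[-3:]
    elif rem == 1:
        stop_codon = sub[-1] + "--"
    else:
        stop_codon = sub[-2:] + "-"
    return start_codon, stop_codon


def base_composition(seqs: str | Sequence[str]) -> dict[str, float]:
    """Percent A/C/G/T composition pooled over one or more sequences.

    Gap and N characters are ignored; case-insensitive.  Also returns the
    A+T and G+C aggregates.  Raises on input with no countable bases.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = Counter()
    for s in seqs:
        counts.update(s.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise EmptyInputError("no A/C/G/T characters to count")
    pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    pct["A+T"] = pct["A"] + pct["T"]
    pct["G+C"] = pct["G"] + pct["C"]
    return pct


def layout_report(layout: GenomeLayout, genome: str | None = None) -> pd.DataFrame:
    """Per-feature recomputation table: length, delta to the previous
    feature, printed-value audits, and (when a genome is given) codons."""
    rows = []
    prev = None
    for f in layout.features:
        delta = f.start - prev.end if prev is not None else None
        row = {
            "name": f.name,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "length": feature_length(f),
            "printed_size": f.printed_size,
            "size_ok": f.printed_size is None or f.printed_size == feature_length(f),
            "delta_prev": delta,
            "printed_space": f.printed_space,
        }
        if genome is not None and f.start_codon is not None:
            start_c, stop_c = extract_codons(genome, f)
            row["start_codon"] = start_c
            row["stop_codon"] = stop_c
        rows.append(row)
        prev = f
    return pd.DataFrame(rows)


def strip_missing(seq: str) -> str:
    """Remove gap/N characters (both count as missing throughout)."""
    return "".join(c for c in seq if c not in MISSING)
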