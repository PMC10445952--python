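"""Conserved-motif scanning and in-silico PCR on a circular genome.

The control region (D-loop) of vertebrate mitogenomes carries short
conserved elements — an invariant tetradecamer, TACAT/TATAT boxes, poly-C
and poly-G tracts — that anchor comparative analyses; ``find_motif`` and
``find_homopolymer_runs`` locate them with overlap-aware 1-based positions.
``insilico_pcr`` predicts the product a primer pair would amplify,
including products that span the origin of the circular molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AmbiguousAmpliconError, NoAmpliconError
from .genome_layout import reverse_complement
from .io_formats import AlignedSequenceSet, PrimerPair, MISSING


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # 1-based start
    length: int

    @property
    def span(self) -> tuple[int, int]:
        return self.position, self.position + self.length - 1


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a circular genome (1-based inclusive).

    For origin-spanning products ``end < start`` and the length is
    ``genome_length - start + 1 + end``.
    """

    start: int
    end: int
    length: int
    fwd_site: int
    rev_site: int


def find_motif(seq: str, motif: str) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``seq``, overlapping ones included.

    Positions are 1-based and ascending.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq, motif = seq.upper(), motif.upper()
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(MotifHit(motif=motif, position=start + 1, length=len(motif)))
        start = seq.find(motif, start + 1)
    return hits


def find_homopolymer_runs(seq: str, base: str, min_len: int) -> list[MotifHit]:
    """Maximal runs of ``base`` with length >= ``min_len``."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq, base = seq.upper(), base.upper()
    hits = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                hits.append(MotifHit(motif=base * (j - i), position=i + 1, length=j - i))
            i = j
        else:
            i += 1
    return hits


def conserved_block(
    aln: AlignedSequenceSet, from_col: int, to_col: int
) -> tuple[bool, list[int]]:
    """Whether every column in [from_col, to_col] (1-based) is invariant.

    A column is conserved when its non-missing states are all identical.
    Returns the flag and the list of violating columns.
    """
    if not 1 <= from_col <= to_col <= aln.length:
        raise ValueError(
            f"range {from_col}-{to_col} outside 1..{aln.length}"
        )
    violating = []
    for col in range(from_col, to_col + 1):
        states = {c for c in aln.column(col) if c not in MISSING}
        if len(states) > 1:
            violating.append(col)
    return (not violating), violating


def _binding_sites(genome: str, probe: str, max_mismatch: int) -> list[int]:
    """1-based start positions where ``probe`` matches the circular genome.

    Mismatches, when allowed, may fall anywhere except the probe's final
    base (the 3'-terminal base of the corresponding primer must pair).
    """
    g, m = len(genome), len(probe)
    doubled = genome + genome[: m - 1]  # circular wrap
    sites = []
    for i in range(g):
        window = doubled[i : i + m]
        if window[-1] != probe[-1]:
            continue
        mism = sum(a != b for a, b in zip(window[:-1], probe[:-1]))
        if mism <= max_mismatch:
            sites.append(i + 1)
    return sites


def insilico_pcr(genome: str, p: PrimerPair, max_mismatch: int = 0) -> Amplicon:
    """Predict the product of a primer pair on a circular genome.

    The forward primer binds the sense strand; the reverse primer binds as
    its reverse complement downstream.  Product length is measured 5'-end
    to 5'-end inclusive, and products may span the origin.  No binding
    raises :class:`NoAmpliconError`; several distinct products raise
    :class:`AmbiguousAmpliconError` listing all of them.
    """
    genome = genome.upper()
    g = len(genome)
    fwd_sites = _binding_sites(genome, p.fwd, max_mismatch)
    # reverse primer anneals to the sense strand as its reverse complement;
    # its 5' end is the *last* base of the rev-comp site on the sense strand,
    # and its 3'-terminal base is the first — handled by matching the
    # rev-comp with the mismatch-free position at the start.
    rc = reverse_complement(p.rev)
    rev_starts = _rc_sites(genome, rc, max_mismatch)
    if not fwd_sites or not rev_starts:
        raise NoAmpliconError(f"{p.gene}: primer(s) do not bind")
    products = []
    for fs in fwd_sites:
        for rs in rev_starts:
            rev_5p = rs + len(rc) - 1
            if rev_5p > g:
                rev_5p -= g
            length = (rev_5p - fs) % g + 1
            if length < len(p.fwd) + len(p.rev):
                continue  # primers overlapping head-on, not a product
            products.append(
                Amplicon(start=fs, end=rev_5p, length=length, fwd_site=fs, rev_site=rs)
            )
    if not products:
        raise NoAmpliconError(f"{p.gene}: no compatible primer orientation")
    if len(products) > 1:
        raise AmbiguousAmpliconError(
            f"{p.gene}: {len(products)} products", products
        )
    return products[0]


def _rc_sites(genome: str, rc_probe: str, max_mismatch: int) -> list[int]:
    # For the reverse primer the 3'-terminal base corresponds to the FIRST
    # base of the reverse-complement written on the sense strand.
    g, m = len(genome), len(rc_probe)
    doubled = genome + genome[: m - 1]
    sites = []
    for i in range(g):
        window = doubled[i : i + m]
        if window[0] != rc_probe[0]:
            continue
        mism = sum(a != b for a, b in zip(window[1:], rc_probe[1:]))
        if mism <= max_mismatch:
            sites.append(i + 1)
    return sites
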