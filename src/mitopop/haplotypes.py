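"""Haplotype collapsing, segregating sites and substitution classification.

An aligned set of sequences is reduced to its distinct patterns
(haplotypes) after applying a gap policy; columns carrying a gap or N in
any row are removed first under the default "complete deletion" policy,
mirroring the convention of excluding alignment gaps that arise from
deletion events.  The module also renders the classic variable-site matrix
(dots for identity with a reference, letters for substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateAlignmentError
from .io_formats import MISSING, AlignedSequenceSet

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class Haplotype:
    pattern: str  # over analyzed columns
    members: tuple[str, ...]
    count: int


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequence patterns with frequencies over analyzed columns.

    ``sites`` are the 1-based positions (in the original alignment) of the
    variable columns among the retained ones; ``S = len(sites)``.
    ``analyzed_columns`` are the original positions retained by the gap
    policy; every pattern is a string over exactly these columns.
    """

    haplotypes: tuple[Haplotype, ...]
    n: int
    analyzed_columns: tuple[int, ...]
    sites: tuple[int, ...]

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    @property
    def S(self) -> int:
        return len(self.sites)

    @property
    def x(self) -> tuple[float, ...]:
        return tuple(h.count / self.n for h in self.haplotypes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(h.count for h in self.haplotypes)

    def pattern_of(self, member: str) -> str:
        for h in self.haplotypes:
            if member in h.members:
                return h.pattern
        raise KeyError(member)


def retained_columns(aln: AlignedSequenceSet, gap_policy: str = "complete") -> list[int]:
    """1-based columns kept by the gap policy.

    ``complete``: drop any column with a gap/N in any row.  ``none``: keep
    everything (pairwise handling is then the caller's concern).
    """
    if gap_policy == "none":
        return list(range(1, aln.length + 1))
    if gap_policy != "complete":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    cols = []
    for c in range(1, aln.length + 1):
        if not (set(aln.column(c)) & MISSING):
            cols.append(c)
    return cols


def collapse_haplotypes(
    aln: AlignedSequenceSet, gap_policy: str = "complete"
) -> HaplotypeTable:
    """Collapse an alignment into haplotypes over the retained columns.

    Haplotype order is first occurrence; identical retained-column rows
    merge.  Raises :class:`DegenerateAlignmentError` when no column
    survives the policy.
    """
    cols = retained_columns(aln, gap_policy)
    if not cols:
        raise DegenerateAlignmentError("no columns survive the gap policy")
    idx = [c - 1 for c in cols]
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for name, row in zip(aln.names, aln.rows):
        pattern = "".join(row[i] for i in idx)
        if pattern not in groups:
            groups[pattern] = []
            order.append(pattern)
        groups[pattern].append(name)
    sites = []
    for pos_i, c in enumerate(cols):
        states = {p[pos_i] for p in order} - MISSING
        if len(states) > 1:
            sites.append(c)
    haps = tuple(
        Haplotype(pattern=p, members=tuple(groups[p]), count=len(groups[p]))
        for p in order
    )
    return HaplotypeTable(
        haplotypes=haps, n=aln.n, analyzed_columns=tuple(cols), sites=tuple(sites)
    )


def is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts of substitution classes at the variable sites.

    Keys of ``counts`` are unordered base pairs written alphabetically
    (``"A/G"``, ``"C/T"`` transitions; the four transversion classes).
    Sites with more than one alternate base contribute once per distinct
    alternate and are listed in ``triallelic_sites``.
    """

    counts: dict[str, int]
    triallelic_sites: tuple[int, ...]

    @property
    def transitions(self) -> int:
        return self.counts.get("A/G", 0) + self.counts.get("C/T", 0)

    @property
    def transversions(self) -> int:
        return sum(v for k, v in self.counts.items() if k not in ("A/G", "C/T"))

    @property
    def total(self) -> int:
        return self.transitions + self.transversions


def substitution_spectrum(
    table: HaplotypeTable, reference: str
) -> SubstitutionSpectrum:
    """Classify each variable site against a reference pattern.

    ``reference`` must be over the same column space as the haplotype
    patterns.  Each variable site contributes the unordered (reference,
    alternate) base pair; A<->G and C<->T are transitions.
    """
    if len(reference) != len(table.analyzed_columns):
        raise ValueError("reference not over the analyzed column space")
    counts: dict[str, int] = {}
    triallelic = []
    col_index = {c: i for i, c in enumerate(table.analyzed_columns)}
    for site in table.sites:
        i = col_index[site]
        ref = reference[i]
        alts = sorted(
            {h.pattern[i] for h in table.haplotypes} - {ref} - set(MISSING)
        )
        if len(alts) > 1:
            triallelic.append(site)
        for alt in alts:
            if ref in MISSING:
                continue
            key = "/".join(sorted((ref, alt)))
            counts[key] = counts.get(key, 0) + 1
    return SubstitutionSpectrum(counts=counts, triallelic_sites=tuple(triallelic))


def variable_site_matrix(table: HaplotypeTable, reference: str) -> str:
    """Render the variable-site matrix as text.

    Column headers are the 1-based original positions printed vertically;
    the first row is the reference bases, following rows are one per
    haplotype with "." for identity and the base letter for substitution.
    """
    if len(reference) != len(table.analyzed_columns):
        raise ValueError("reference not over the analyzed column space")
    col_index = {c: i for i, c in enumerate(table.analyzed_columns)}
    sites = table.sites
    name_w = max(
        [len("reference")] + [len(f"H{i+1}") for i in range(table.H)]
    )
    lines = []
    if sites:
        digits = max(len(str(s)) for s in sites)
        padded = [str(s).rjust(digits) for s in sites]
        for d in range(digits):
            lines.append(" " * name_w + " " + "".join(p[d] for p in padded))
    ref_cells = "".join(reference[col_index[s]] for s in sites)
    lines.append("reference".ljust(name_w) + " " + ref_cells)
    for k, h in enumerate(table.haplotypes):
        cells = []
        for s in sites:
            i = col_index[s]
            cells.append("." if h.pattern[i] == reference[i] else h.pattern[i])
        lines.append(f"H{k+1}".ljust(name_w) + " " + "".join(cells))
    return "\n".join(lines) + "\n"
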