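"""Nei diversity statistics and haplotype-frequency differentiation.

Nucleotide diversity pi is the average per-site proportion of differences
between two randomly drawn sequences with the small-sample correction
n/(n-1):

    pi = n/(n-1) * sum_{i<j} 2 x_i x_j pi_ij

where x_i is the frequency of the i-th haplotype and pi_ij the per-site
difference proportion between haplotypes i and j; equivalently, pi is the
mean pairwise difference over all n(n-1)/2 sequence comparisons.

Haplotype (gene) diversity is Nei's unbiased heterozygosity

    h = 2n (1 - sum x_i^2) / (2n - 1).

Population differentiation is a Gst-style statistic on haplotype
frequencies, (Ht - Hs)/Ht, with significance from a permutation test that
reassigns individuals to populations.  This exercises haplotype-frequency
differentiation without claiming equivalence to any particular Fst
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import SampleSizeError
from .haplotypes import HaplotypeTable, collapse_haplotypes
from .io_formats import AlignedSequenceSet


@dataclass(frozen=True)
class DiversityStats:
    S: int
    H: int
    Hd: float
    pi: float
    n: int
    nc: int


@dataclass(frozen=True)
class DifferentiationResult:
    statistic: float
    p_value: float
    n_perm: int


def _pairwise_prop(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def nucleotide_diversity(data: AlignedSequenceSet | HaplotypeTable) -> float:
    """Nei's pi on an alignment (collapsed internally) or haplotype table."""
    table = data if isinstance(data, HaplotypeTable) else collapse_haplotypes(data)
    n = table.n
    if n < 2:
        raise SampleSizeError("pi requires n >= 2")
    if not table.analyzed_columns:
        raise SampleSizeError("no analyzed columns")
    x = table.x
    total = 0.0
    for i, j in combinations(range(table.H), 2):
        pij = _pairwise_prop(table.haplotypes[i].pattern, table.haplotypes[j].pattern)
        total += 2.0 * x[i] * x[j] * pij
    return n / (n - 1) * total


def nucleotide_diversity_pairwise(aln: AlignedSequenceSet) -> float:
    """pi as the mean difference proportion over all sequence pairs.

    The direct form pi = sum pi_ij / nc over the n(n-1)/2 comparisons;
    algebraically identical to :func:`nucleotide_diversity` and kept as the
    second route the definition itself offers.
    """
    table = collapse_haplotypes(aln)
    if table.n < 2:
        raise SampleSizeError("pi requires n >= 2")
    pats = [table.pattern_of(name) for name in aln.names]
    props = [_pairwise_prop(a, b) for a, b in combinations(pats, 2)]
    return float(np.mean(props))


def haplotype_diversity(table: HaplotypeTable) -> float:
    """Nei's unbiased haplotype diversity h = 2n(1 - sum x_i^2)/(2n - 1)."""
    n = table.n
    if n < 2:
        raise SampleSizeError("h requires n >= 2")
    sum_x2 = sum(xi * xi for xi in table.x)
    return 2 * n * (1 - sum_x2) / (2 * n - 1)


def diversity_stats(aln: AlignedSequenceSet) -> DiversityStats:
    """S, H, Hd and pi in one pass over an alignment."""
    table = collapse_haplotypes(aln)
    n = table.n
    return DiversityStats(
        S=table.S,
        H=table.H,
        Hd=haplotype_diversity(table),
        pi=nucleotide_diversity(table),
        n=n,
        nc=n * (n - 1) // 2,
    )


def _gst(groups: list[list[str]]) -> float:
    """(Ht - Hs)/Ht on lists of haplotype labels, one list per population."""
    labels = sorted({h for g in groups for h in g})
    freqs = []
    hs_terms = []
    for g in groups:
        n = len(g)
        f = np.array([g.count(lbl) / n for lbl in labels])
        freqs.append(f)
        hs_terms.append(1.0 - float(f @ f))
    mean_f = np.mean(freqs, axis=0)
    ht = 1.0 - float(mean_f @ mean_f)
    hs = float(np.mean(hs_terms))
    if ht <= 0.0:
        return 0.0
    return (ht - hs) / ht


def differentiation(
    tableA: HaplotypeTable,
    tableB: HaplotypeTable,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DifferentiationResult:
    """Haplotype-frequency differentiation between two populations.

    Individuals are labelled by their haplotype pattern; the permutation
    test reassigns individuals to populations at the observed sizes and
    uses the (b+1)/(m+1) p-value convention.  Two identical monomorphic
    populations give statistic 0 and p = 1.
    """
    for t in (tableA, tableB):
        if t.n < 2:
            raise SampleSizeError("each population needs n >= 2")
    a = [h.pattern for h in tableA.haplotypes for _ in range(h.count)]
    b = [h.pattern for h in tableB.haplotypes for _ in range(h.count)]
    observed = _gst([a, b])
    if n_perm <= 0:
        return DifferentiationResult(statistic=observed, p_value=1.0, n_perm=0)
    rng = np.random.default_rng(seed)
    pooled = a + b
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[:na]]
        gb = [pooled[i] for i in perm[na:]]
        if _gst([ga, gb]) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return DifferentiationResult(statistic=observed, p_value=p, n_perm=n_perm)
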