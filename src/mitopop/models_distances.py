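"""Kimura 2-parameter distances and Tamura-Nei (TN93) rate-matrix estimation.

K2P corrects separately for the proportion of transition differences P and
transversion differences Q:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

TN93 distinguishes purine transitions (rate factor k1), pyrimidine
transitions (k2) and transversions (b), each scaled by the frequency of the
target base: r(x->j) = k1*pi_j for A<->G, k2*pi_j for C<->T, b*pi_j
otherwise.  The rate factors are estimated by method of moments on pooled
pairwise difference proportions (the expected proportions at low divergence
are 2*pi_A*pi_G*k1*t, 2*pi_C*pi_T*k2*t and 2*pi_R*pi_Y*b*t), and the matrix
is rescaled so the twelve off-diagonal entries sum to 100 — the relative
normalization published rate tables use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import EstimationError, SampleSizeError, SaturationError, TreeSizeError
from .haplotypes import is_transition, PURINES
from .io_formats import MISSING, AlignedSequenceSet

#: Row/column order of published rate tables.
BASE_ORDER = ("A", "T", "C", "G")


@dataclass(frozen=True)
class PairwiseDifference:
    """Observed difference proportions between two aligned sequences.

    ``P1``: purine (A<->G) transition proportion, ``P2``: pyrimidine
    (C<->T), ``Q``: transversions; ``L`` compared sites.
    """

    P1: float
    P2: float
    Q: float
    L: int

    @property
    def P(self) -> float:
        return self.P1 + self.P2


@dataclass(frozen=True)
class RateMatrix:
    """4x4 instantaneous relative rates, off-diagonal sum normalised to 100."""

    r: np.ndarray  # indexed by BASE_ORDER, diagonal zero
    freqs: dict[str, float]
    k1: float
    k2: float
    b: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.r, index=BASE_ORDER, columns=BASE_ORDER)
        return df

    @property
    def offdiag_sum(self) -> float:
        return float(self.r.sum())


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def count_differences(
    seqA: str, seqB: str, deletion_policy: str = "pairwise"
) -> PairwiseDifference:
    """Per-class difference proportions between two equal-length sequences.

    ``pairwise`` deletion drops columns missing in either sequence; the
    caller applies complete deletion beforehand if desired.
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be equal length")
    p1 = p2 = q = L = 0
    for a, b in zip(seqA.upper(), seqB.upper()):
        if a in MISSING or b in MISSING:
            continue
        L += 1
        if a == b:
            continue
        if {a, b} <= PURINES:
            p1 += 1
        elif is_transition(a, b):
            p2 += 1
        else:
            q += 1
    if L == 0:
        raise SampleSizeError("no comparable columns")
    return PairwiseDifference(P1=p1 / L, P2=p2 / L, Q=q / L, L=L)


def k2p_distance(pd_: PairwiseDifference, pair: tuple[str, str] | None = None) -> float:
    """Kimura two-parameter distance from difference proportions."""
    P, Q = pd_.P, pd_.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        who = f" for pair {pair[0]}/{pair[1]}" if pair else ""
        raise SaturationError(f"K2P correction saturated{who} (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(
    aln: AlignedSequenceSet, model: str = "k2p", deletion_policy: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs distances under the requested model (currently K2P)."""
    if model != "k2p":
        raise ValueError(f"unknown model {model!r}")
    if aln.n < 3:
        raise TreeSizeError("need >= 3 taxa for a distance matrix")
    n = aln.n
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        diff = count_differences(aln.rows[i], aln.rows[j], deletion_policy)
        d = k2p_distance(diff, pair=(aln.names[i], aln.names[j]))
        values[i, j] = values[j, i] = d
    return DistanceMatrix(names=tuple(aln.names), values=values)


def base_frequencies(aln: AlignedSequenceSet) -> dict[str, float]:
    """Base frequencies pooled over all sequences and analyzed columns."""
    counts = {b: 0 for b in BASE_ORDER}
    for row in aln.rows:
        for c in row.upper():
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise EstimationError("no countable bases")
    return {b: counts[b] / total for b in BASE_ORDER}


def tn93_rate_matrix(aln: AlignedSequenceSet) -> RateMatrix:
    """Estimate the TN93 relative rate matrix from an alignment.

    Moment estimator on pooled pairwise proportions: k1 ~ P1/(2 pi_A pi_G),
    k2 ~ P2/(2 pi_C pi_T), b ~ Q/(2 pi_R pi_Y); the common time factor
    cancels in the final normalization to sum 100.  Degenerate inputs (no
    substitutions, or a missing base class) raise
    :class:`EstimationError`.
    """
    if aln.n < 2:
        raise SampleSizeError("need >= 2 sequences")
    freqs = base_frequencies(aln)
    pa, pt, pc, pg = (freqs[b] for b in BASE_ORDER)
    if pa * pg == 0 or pc * pt == 0:
        raise EstimationError("a base class is absent; TN93 rates undefined")
    diffs = [
        count_differences(a, b)
        for a, b in combinations(aln.rows, 2)
    ]
    P1 = float(np.mean([d.P1 for d in diffs]))
    P2 = float(np.mean([d.P2 for d in diffs]))
    Q = float(np.mean([d.Q for d in diffs]))
    if P1 + P2 + Q == 0:
        raise EstimationError("sequences are identical; no substitutions to fit")
    pr, py = pa + pg, pc + pt
    k1 = P1 / (2 * pa * pg)
    k2 = P2 / (2 * pc * pt)
    b = Q / (2 * pr * py)
    r = np.zeros((4, 4))
    idx = {base: i for i, base in enumerate(BASE_ORDER)}
    for x in BASE_ORDER:
        for j in BASE_ORDER:
            if x == j:
                continue
            if {x, j} == {"A", "G"}:
                k = k1
            elif {x, j} == {"C", "T"}:
                k = k2
            else:
                k = b
            r[idx[x], idx[j]] = k * freqs[j]
    r *= 100.0 / r.sum()
    return RateMatrix(r=r, freqs=freqs, k1=k1, k2=k2, b=b)
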