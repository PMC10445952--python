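"""Synthetic mitogenomes and haplotype populations with known ground truth.

``make_genome`` lays out a circular ~16.8 kb molecule following the
published 19-feature chicken organization: protein-coding features receive
a correct start codon (ATG, or GTG for COX1) and a stop consistent with
their length mod 3 (full stop, or the 1-2 base form completed by
polyadenylation), L-strand features reverse-complemented; intergenic fill
is drawn from the published base frequencies (A 30.26, T 23.76, C 32.48,
G 13.50 percent); the conserved control-region motifs and all 15
segmental-PCR primer sites are planted verbatim, with an agreement check
where plants overlap.  Accidental extra copies of planted motifs inside
the control region are scrubbed so motif counts there are exact ground
truth.

``make_population`` evolves haplotype sets on a star or Kingman-coalescent
genealogy with a strong transition bias (default ratio 15, the order of
magnitude implied by published mitogenome rate tables) and returns the
full per-branch mutation record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .genome_layout import GenomeLayout, reverse_complement
from .io_formats import (
    AlignedSequenceSet,
    FeatureRecord,
    PrimerPair,
    load_chicken_features,
    load_chicken_primers,
)

#: Published base frequencies (percent) used for random fill.
DEFAULT_BASE_FREQS = {"A": 30.26, "T": 23.76, "C": 32.48, "G": 13.50}

#: Control-region motifs planted by default: the invariant tetradecamer at
#: its two published positions, the interrupted thymine string, the poly-C
#: and poly-G tracts, and 4 TACAT / 9 TATAT boxes.
DEFAULT_MOTIF_PLANTS: tuple[tuple[str, int], ...] = (
    ("AACTATGAATGGTT", 264),
    ("AACTATGAATGGTT", 325),
    ("TTTTATTTTTTAA", 700),
    ("CCCCCCCTTTCCCC", 730),
    ("AGGGGGGGT", 760),
    ("TACAT", 800),
    ("TACAT", 810),
    ("TACAT", 820),
    ("TACAT", 830),
    ("TATAT", 850),
    ("TATAT", 860),
    ("TATAT", 870),
    ("TATAT", 880),
    ("TATAT", 890),
    ("TATAT", 900),
    ("TATAT", 910),
    ("TATAT", 920),
    ("TATAT", 930),
)

_PROTEIN_PREFIXES = ("ND", "COX", "ATP", "CYTB")

DLOOP_SPAN = (1, 1227)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    layout: GenomeLayout | None = None  # default: published 19-feature layout
    base_freqs: dict = field(default_factory=lambda: dict(DEFAULT_BASE_FREQS))
    motif_plants: tuple[tuple[str, int], ...] = DEFAULT_MOTIF_PLANTS
    plant_primers: bool = True
    seed: int = 0

    def resolved_layout(self) -> GenomeLayout:
        if self.layout is not None:
            return self.layout
        return GenomeLayout(
            features=tuple(load_chicken_features()), genome_length=16775
        )


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Study-scale defaults: 8 control-region sequences of 1227 bp with
    per-site mutation parameter theta giving on the order of a few dozen
    segregating sites, transition:transversion ratio 15."""

    n_sequences: int = 8
    length: int = 1227
    genealogy: str = "coalescent"  # or "star"
    theta: float = 0.009
    ts_tv_bias: float = 15.0
    base_freqs: dict = field(default_factory=lambda: dict(DEFAULT_BASE_FREQS))
    #: exact mutations per tip branch (star mode, distinct sites) — overrides
    #: the Poisson process for fully controlled fixtures
    mutations_per_branch: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 2:
            raise ValueError("need n >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.ts_tv_bias <= 0:
            raise ValueError("ts_tv_bias must be > 0")
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")


def _random_bases(rng: np.random.Generator, n: int, freqs: dict) -> np.ndarray:
    bases = np.array(list("ACGT"))
    p = np.array([freqs[b] for b in "ACGT"], dtype=float)
    p = p / p.sum()
    return rng.choice(bases, size=n, p=p)


class _Planter:
    """Writes strings into the genome array with overlap agreement checks."""

    def __init__(self, genome: np.ndarray):
        self.genome = genome
        self.protected = np.zeros(len(genome), dtype=bool)

    def plant(self, pos: int, s: str, label: str) -> None:
        """Place ``s`` at 1-based position ``pos``."""
        i = pos - 1
        if i < 0 or i + len(s) > len(self.genome):
            raise PlacementError(f"{label}: {s!r} at {pos} outside genome")
        for k, ch in enumerate(s):
            if self.protected[i + k] and self.genome[i + k] != ch:
                raise PlacementError(
                    f"{label}: conflict at position {pos + k} "
                    f"({self.genome[i + k]!r} vs {ch!r})"
                )
        self.genome[i : i + len(s)] = list(s)
        self.protected[i : i + len(s)] = True


def _stop_for_length(length: int) -> str:
    """A stop codon consistent with length mod 3 (bases actually written)."""
    rem = length % 3
    if rem == 0:
        return "TAA"
    if rem == 1:
        return "T"
    return "TA"


def _is_protein(f: FeatureRecord) -> bool:
    return any(f.name.upper().startswith(p) for p in _PROTEIN_PREFIXES)


def make_genome(spec: SyntheticGenomeSpec) -> tuple[str, GenomeLayout, dict]:
    """Generate a circular genome for the given layout.

    Returns ``(sequence, layout, truth)`` where ``truth`` records planted
    motif positions, primer sites and codon spans.  Deterministic under
    ``spec.seed``.
    """
    layout = spec.resolved_layout()
    rng = np.random.default_rng(spec.seed)
    genome = _random_bases(rng, layout.genome_length, spec.base_freqs)
    planter = _Planter(genome)
    truth: dict = {"codons": {}, "primer_sites": {}, "motifs": {}}

    for f in layout.features:
        if not _is_protein(f):
            continue
        start_codon = "GTG" if f.name.upper() == "COX1" else "ATG"
        stop = _stop_for_length(f.end - f.start + 1)
        if f.strand == "H":
            planter.plant(f.start, start_codon, f"{f.name} start codon")
            planter.plant(f.end - len(stop) + 1, stop, f"{f.name} stop codon")
        else:
            # the gene is the reverse complement of the slice: its first
            # codon sits at the slice END, its stop at the slice START
            planter.plant(
                f.end - 2, reverse_complement(start_codon), f"{f.name} start codon"
            )
            planter.plant(f.start, reverse_complement(stop), f"{f.name} stop codon")
        truth["codons"][f.name] = (start_codon, _display_stop(stop))

    if spec.plant_primers:
        for p in load_chicken_primers():
            planter.plant(p.region_start, p.fwd, f"{p.gene} fwd site")
            rc = reverse_complement(p.rev)
            rev_start = p.region_start + p.expected_size - len(rc)
            planter.plant(rev_start, rc, f"{p.gene} rev site")
            truth["primer_sites"][f"{p.gene}:{p.region_start}"] = {
                "fwd": p.region_start,
                "rev": rev_start,
                "expected_size": p.expected_size,
            }

    for motif, pos in spec.motif_plants:
        planter.plant(pos, motif, f"motif {motif}")
        truth["motifs"].setdefault(motif, []).append(pos)

    _scrub_extra_motifs(planter, truth["motifs"], rng, region=DLOOP_SPAN)
    return "".join(genome), layout, truth


def _display_stop(stop: str) -> str:
    return stop + "-" * (3 - len(stop))


def _scrub_extra_motifs(planter, motif_positions: dict, rng, region) -> None:
    """Break accidental motif copies inside ``region`` so planted counts are
    exact; only unprotected fill bases are touched."""
    lo, hi = region
    text_of = lambda: "".join(planter.genome[lo - 1 : hi])
    for _ in range(200):
        dirty = False
        text = text_of()
        for motif, planted in motif_positions.items():
            start = text.find(motif)
            while start != -1:
                pos = lo + start  # 1-based genome position of the hit
                if pos not in planted:
                    free = [
                        pos + k
                        for k in range(len(motif))
                        if not planter.protected[pos - 1 + k]
                    ]
                    if not free:
                        raise PlacementError(
                            f"accidental {motif} at {pos} is fully protected"
                        )
                    target = free[len(free) // 2] - 1
                    current = planter.genome[target]
                    choices = [b for b in "ACGT" if b != current]
                    planter.genome[target] = choices[int(rng.integers(0, 3))]
                    dirty = True
                start = text.find(motif, start + 1)
        if not dirty:
            return
    raise PlacementError("motif scrub did not converge")


# ---------------------------------------------------------------------------
# Haplotype populations


@dataclass
class Genealogy:
    """Tips 0..n-1; ``parent[c]`` and ``branch_length[c]`` per child node."""

    n: int
    parent: dict[int, int]
    branch_length: dict[int, float]
    root: int

    def children(self, node: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == node]


def _star_genealogy(n: int) -> Genealogy:
    root = n
    return Genealogy(
        n=n,
        parent={i: root for i in range(n)},
        branch_length={i: 1.0 for i in range(n)},
        root=root,
    )


def _coalescent_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Standard Kingman coalescent: Exp(k(k-1)/2) waiting times, random
    pairwise merges (time in units of 2N generations)."""
    times = {i: 0.0 for i in range(n)}
    lineages = list(range(n))
    parent: dict[int, int] = {}
    t = 0.0
    nxt = n
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    root = lineages[0]
    branch_length = {c: times[p] - times[c] for c, p in parent.items()}
    return Genealogy(n=n, parent=parent, branch_length=branch_length, root=root)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def make_population(
    spec: SyntheticPopulationSpec,
) -> tuple[AlignedSequenceSet, Genealogy, list[dict]]:
    """Evolve an aligned, gap-free haplotype population.

    The ancestral sequence is drawn from ``base_freqs``; mutations fall on
    genealogy branches as a Poisson process at rate theta/2 per site per
    unit time, each a transition with probability bias/(bias+1) and
    otherwise one of the two transversions.  Returns the alignment, the
    genealogy, and the mutation record (site, from, to, branch,
    transition flag).
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.length
    gen = (
        _star_genealogy(n)
        if spec.genealogy == "star"
        else _coalescent_genealogy(n, rng)
    )
    ancestral = _random_bases(rng, L, spec.base_freqs)
    p_ts = spec.ts_tv_bias / (spec.ts_tv_bias + 1.0)

    seqs: dict[int, np.ndarray] = {gen.root: ancestral}
    mutations: list[dict] = []

    def n_mutations(branch_len: float) -> int:
        if spec.mutations_per_branch is not None:
            return spec.mutations_per_branch
        return int(rng.poisson(spec.theta / 2.0 * L * branch_len))

    # descend from the root, mutating each branch
    order = sorted(gen.parent, key=lambda c: -c)  # parents have higher ids
    used_sites: set[int] = set()
    for child in order:
        seq = seqs[gen.parent[child]].copy()
        m = n_mutations(gen.branch_length[child])
        for _ in range(m):
            if spec.mutations_per_branch is not None:
                # controlled mode: distinct sites across the whole genealogy
                site = int(rng.integers(0, L))
                while site in used_sites:
                    site = int(rng.integers(0, L))
                used_sites.add(site)
            else:
                site = int(rng.integers(0, L))
            old = seq[site]
            if rng.random() < p_ts:
                new = _TRANSITION[old]
                is_ts = True
            else:
                pair = _TRANSVERSIONS[old]
                new = pair[int(rng.integers(0, 2))]
                is_ts = False
            seq[site] = new
            mutations.append(
                {
                    "branch": child,
                    "site": site + 1,
                    "from": str(old),
                    "to": str(new),
                    "transition": is_ts,
                }
            )
        seqs[child] = seq

    names = tuple(f"seq{i+1}" for i in range(n))
    rows = tuple("".join(seqs[i]) for i in range(n))
    return AlignedSequenceSet(names=names, rows=rows), gen, mutations


def single_hit_sites(mutations: list[dict]) -> set[int]:
    """Sites hit exactly once: these are guaranteed to segregate, since
    every branch subtends a proper subset of the tips."""
    from collections import Counter

    counts = Counter(m["site"] for m in mutations)
    return {s for s, c in counts.items() if c == 1}
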