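# Methods

This note documents the models, estimators and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout.

## Coordinates, alphabets and missing data

All coordinates are 1-based inclusive everywhere (feature tables, motif
hits, amplicons, edge labels); no half-open convention exists internally,
so printed table values can be compared without translation. Sequences are
upper-case over `{A,C,G,T,-,N}`. `-` and `N` both count as missing: the
default "complete deletion" policy removes any alignment column carrying a
missing character in any row before haplotype collapsing and diversity, a
convention chosen because deletion-derived gap columns otherwise create
spurious haplotypes. Pairwise deletion (per-pair column exclusion) is used
for distance computation, where complete deletion would discard data the
pair actually shares; both policies are exposed.

## Genome organization

Feature length is `end − start + 1`. The inter-feature delta is
`start(next) − end(prev)`; a positive delta is reported as a spacer and a
delta ≤ 0 as an overlap. This convention reproduces 17 of the 18 printed
deltas of the reference organization table exactly; the one exception is a
shared-boundary pair (delta 0, printed −1), which the ≤ 0 rule classifies
as an overlap, reconciling the published "3 overlaps" count. Because the
delta convention counts one boundary base, the true shared-base count
(`end(prev) − start(next) + 1`) is reported alongside for overlap pairs.
Printed size/space columns are parsed but never trusted: the audit lists
every disagreement with the coordinates (exactly one size and one delta in
the reference table) and corrects nothing silently.

Codon extraction reads the first three bases as the start codon after
reverse-complementing L-strand features. Stops follow length mod 3: a full
last triplet at mod 0, else the 1- or 2-base incomplete form padded with
dashes (`T--`, `TA-`) — the polyadenylation-completed stops typical of
mitogenomes. Base composition ignores missing characters and returns
percentages plus A+T / G+C aggregates.

## Motifs and in-silico PCR

Motif search is exact and overlap-aware (a self-overlapping box like TATAT
is counted at every offset). Homopolymer detection reports maximal runs
only. In-silico PCR treats the genome as circular: binding sites are found
for the forward primer and for the reverse complement of the reverse
primer, with the 3′-terminal base required to match even when mismatches
are allowed elsewhere (default `max_mismatch = 0`). Product length is
measured 5′ end to 5′ end inclusive, the convention that reproduces all
printed product sizes from the reference primer table; origin-spanning
products use modular arithmetic. One product is returned; several distinct
candidate products raise an ambiguity error listing all of them rather
than guessing.

## Haplotypes and diversity

Haplotypes are distinct retained-column patterns, ordered by first
occurrence and carrying member lists; `S` counts retained columns with
more than one non-missing state. The substitution spectrum classifies each
variable site by the unordered (reference, alternate) pair — A↔G and C↔T
transitions versus the four transversion classes — counting once per
distinct alternate at multi-allelic sites and flagging those sites.

Nucleotide diversity uses the small-sample-corrected frequency form
`π = n/(n−1) Σ_{i<j} 2 x_i x_j π_ij`; the implementation also provides the
algebraically identical mean-over-pairs form, and the tests hold them to
each other and to a brute-force pairwise oracle at 1e-12. Haplotype
diversity is `h = 2n(1 − Σx_i²)/(2n−1)`, which is bounded by
`(2n−2)/(2n−1) < 1`.

Population differentiation is a Gst-style statistic on haplotype
frequencies, `(Ht − Hs)/Ht` with `Ht` the pooled-mean-frequency gene
diversity and `Hs` the mean within-population gene diversity. It is
deliberately labelled as such: it exercises haplotype-frequency
differentiation without claiming equivalence to any particular Fst or Nst
estimator, whose definitions vary by package. Significance comes from
permuting individuals across populations at the observed sizes, with the
`(b+1)/(m+1)` p-value convention so p is never zero; two identical
monomorphic populations are defined to have statistic 0 and p = 1.
Distance-weighted (Nst-style) differentiation is out of scope.

## Substitution models

K2P: `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`. A non-positive log argument raises
a saturation error naming the sequence pair instead of returning a capped
or negative value; anomalously large "distances" sometimes seen in
published tables are therefore impossible here by construction.

TN93 rates are estimated by method of moments on pooled pairwise
difference proportions: with base frequencies `π` taken from all analyzed
columns pooled over sequences, `k1 ∝ P1/(2π_Aπ_G)`,
`k2 ∝ P2/(2π_Cπ_T)`, `b ∝ Q/(2π_Rπ_Y)`; the matrix `r(x→j) = k·π_j` is then
rescaled so its twelve off-diagonal entries sum to exactly 100, the
relative normalization published rate tables use. This is a deliberate
approximation to full tree-based ML estimation: the common time factor
cancels in the normalization, and at the low-to-moderate divergences the
package targets the moment estimator recovers the same matrix structure
(the tests verify factor recovery within 10% at 10,000 sites and the exact
transversion-proportionality structure). It will understate rate ratios on
strongly saturated data, which the distance layer rejects anyway.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration on the Q criterion, with rate-corrected
branch lengths. Ties on Q break to the earliest pair in input order —
deterministic and documented. Negative branch lengths are clamped to zero
with the deficit transferred to the sibling branch, preserving the joined
pair's distance. The final three lineages are joined by the exact
three-point equations. On additive matrices the tree reproduces the input
distances to 1e-9 and recovers the generating topology (tested against
random trees, and against scikit-bio's independent NJ implementation).

Bootstrap resamples alignment columns with replacement, rebuilds the tree
per replicate, and reports for each internal bipartition of the full-data
tree the percentage of replicates containing it. Replicates whose distance
computation saturates are skipped and counted. All resampling is driven by
one seed; identical seeds give identical supports and identical Newick
output (branch lengths to 6 decimals, integer support labels).

## Median-joining networks

The growth loop alternates (1) the minimum spanning network over current
nodes — all links whose weight is within ε of the level at which their
endpoints' components first connect (ε defaults to 0, the conventional
default) — and (2) quasi-median addition: for every node with two
neighbors, the per-site majority consensus of the triplet, generating all
combinations at three-way ties (capped at 2^10 per triplet with a loud
error beyond). Novel medians enter as "median vector" (mv) nodes and the
loop repeats to a fixpoint, which exists because candidate states per site
are finite. Finally, mv nodes lying on no minimal path between observed
haplotypes are deleted, iterating to a fixpoint. Edges carry the list of
mutated original alignment positions, so every label length equals the
Hamming distance between its endpoints.

Two structural guarantees are tested exhaustively on all ≤5-haplotype
subsets of the 3-site binary cube: on homoplasy-free data
(four-gamete-compatible, where a perfect phylogeny exists) the ε = 0
network realizes every observed-pair Hamming distance — equivalently, for
tree-like data it is the unique minimum spanning tree with multi-site
edges as single labelled links; on homoplastic data ε = 0 median joining
correctly returns the spanning-network backbone, whose geodesics may
exceed the Hamming distance, and full relaxation (ε ≥ the largest pairwise
distance) restores Hamming geodesics for every subset. Node sizes in
exports are raw frequencies; proportional-area drawing is left to
downstream visualization tools.

## Synthetic data

The genome generator lays out the published 19-feature, 16,775 bp circular
organization: intergenic fill is drawn i.i.d. from the published base
frequencies (A 30.26, T 23.76, C 32.48, G 13.50 percent); protein-coding
features get a correct start codon (ATG, GTG for COX1) and a stop
consistent with length mod 3, reverse-complemented on the L strand; all 15
primer sites and the conserved control-region motifs (invariant
tetradecamer at 264 and 325, interrupted thymine string, poly-C, poly-G,
4 TACAT and 9 TATAT boxes) are planted verbatim. Overlapping plants are
allowed only where the characters agree — the real design is internally
consistent in exactly this way (one reverse-primer site is the
reverse-complement image of the next amplicon's forward primer) — and any
disagreement raises a placement error. Accidental extra motif copies
arising in random fill inside the control region are scrubbed by mutating
unprotected fill bases, so control-region motif counts are exact ground
truth. Two primer-table rows whose printed coordinates and printed product
size disagree by one base are planted from the printed product size, the
quantity a gel would verify.

Populations evolve on a star genealogy (unit tip branches; optionally an
exact per-branch mutation count at distinct sites, for fully controlled
network fixtures) or a Kingman coalescent (Exp(k(k−1)/2) waiting times,
random merges). Mutations fall as a Poisson process at rate θ/2 per site
per unit time, so E[π] = θ per site, which the tests verify against
coalescent theory over 200 replicates. Each mutation is a transition with
probability bias/(bias+1), else a uniform transversion; the default bias
of 15 is the order of magnitude implied by the pyrimidine-transition
versus transversion entries of published mitogenome rate tables. Defaults
(n = 8 sequences, 1,227 bp, θ = 0.009 — chosen to give a few dozen
segregating sites at n = 8, the scale typical of single-breed-panel
surveys) emulate a control-region study.

What the generator does not emulate: indels (alignments are generated
gap-free; gap handling is exercised by hand-made fixtures),
recombination (none, as for mtDNA), rate heterogeneity across sites,
sequencing error, and frequency-dependent (HKY/TN93-style) mutation
targeting — mutation type depends only on the transition bias, not on the
target base frequency. Passing tests therefore demonstrate correctness of
the estimators and algorithms under clean, known-truth conditions, not
robustness to alignment error or rate variation in real data.

## Problem sizes

Defaults keep every stage interactive: population simulations of 8-10
sequences at 500-8,000 sites, 200-replicate recovery experiments, 100-1000
bootstrap replicates, and exhaustive network checks over all 210 small
binary instances. The full test suite and the acceptance script each run
in seconds on one CPU.

## Known limitations

- The TN93 moment estimator is not tree-based ML; on saturated data it is
  biased toward equal rates (and the distance layer refuses saturated
  pairs outright rather than capping them).
- The differentiation statistic is a haplotype-frequency Gst with a
  permutation test, not an Arlequin-compatible Fst/Nst.
- Median-joining with ε = 0 inherits the published algorithm's behaviour
  on homoplastic data: alternative equally-short connections can be
  absent; raise ε to recover them.
- NJ tie-breaking is order-dependent by design; topologies are invariant
  to input order only when every agglomeration step has a unique Q
  minimizer.
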