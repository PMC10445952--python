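"""Neighbor-joining tree construction with column-resampling bootstrap.

Standard Saitou-Nei agglomeration: at each step join the pair minimizing

    Q(i,j) = (r - 2) d(i,j) - R_i - R_j          (R_i = sum_k d(i,k))

with branch lengths from the rate-corrected split formula

    L_i = d(i,j)/2 + (R_i - R_j) / (2 (r - 2)),   L_j = d(i,j) - L_i.

Negative branch lengths are clamped to zero with the deficit transferred
to the sibling branch.  Ties on Q break to the lowest (i,j) index pair in
input order, so the construction is deterministic.  Bootstrap support is
the percentage of column-resampled replicates whose NJ tree contains each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import SaturationError, TreeSizeError
from .io_formats import AlignedSequenceSet
from .models_distances import DistanceMatrix, distance_matrix


@dataclass
class PhyloTree:
    """An unrooted tree as an adjacency map with branch lengths.

    Node ids are ints; leaves carry names in ``leaf_names``.  Internal
    edges may carry integer bootstrap supports (percent).
    """

    adjacency: dict[int, dict[int, float]]
    leaf_names: dict[int, str]
    supports: dict[frozenset, int] = field(default_factory=dict)

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_names)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def path_length(self, name_a: str, name_b: str) -> float:
        """Sum of branch lengths on the unique path between two leaves."""
        rev = {v: k for k, v in self.leaf_names.items()}
        start, goal = rev[name_a], rev[name_b]
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length in self.adjacency[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + length))
        raise ValueError("leaves not connected")

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf-name splits, one per internal edge.

        Each split is canonicalized as the frozenset of names on the side
        not containing the lexicographically smallest taxon.
        """
        all_names = frozenset(self.leaf_names.values())
        anchor = min(all_names)
        splits = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                if a >= b:
                    continue
                side = self._leafset_beyond(b, a)
                if len(side) < 2 or len(all_names - side) < 2:
                    continue
                if anchor in side:
                    side = all_names - side
                splits.add(frozenset(side))
        return splits

    def _leafset_beyond(self, node: int, parent: int) -> frozenset:
        names = []
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in self.leaf_names:
                names.append(self.leaf_names[cur])
            for nbr in self.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        return frozenset(names)

    def to_newick(self) -> str:
        """Newick with 6-decimal branch lengths; internal nodes are labelled
        with integer support when bootstrap values are present."""
        # root arbitrarily at the highest-degree internal node
        internal = [n for n in self.adjacency if n not in self.leaf_names]
        root = max(internal, key=lambda n: len(self.adjacency[n])) if internal else min(self.adjacency)
        all_names = frozenset(self.leaf_names.values())
        anchor = min(all_names)

        def render(node: int, parent: int) -> str:
            if node in self.leaf_names:
                return self.leaf_names[node]
            parts = [
                render(nbr, node) + f":{length:.6f}"
                for nbr, length in self.adjacency[node].items()
                if nbr != parent
            ]
            label = ""
            if parent >= 0 and self.supports:
                side = self._leafset_beyond(node, parent)
                key = frozenset(all_names - side if anchor in side else side)
                if key in self.supports:
                    label = str(self.supports[key])
            return "(" + ",".join(parts) + ")" + label

        return render(root, -1) + ";"


@dataclass(frozen=True)
class TreeConfig:
    bootstrap_reps: int = 1000
    seed: int | None = None
    negative_branch_policy: str = "clamp_transfer"

    def __post_init__(self):
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Build the neighbor-joining tree of a distance matrix."""
    n = len(dm.names)
    if n < 3:
        raise TreeSizeError("NJ needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains non-finite entries")

    # active nodes are tree-node ids; distances kept in a dict-of-dict
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = {i: name for i, name in enumerate(dm.names)}
    active = list(range(n))
    d = {
        (i, j): float(dm.values[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    next_id = n

    def dist(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    while len(active) > 3:
        r = len(active)
        row_sums = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - row_sums[i] - row_sums[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
                # ties: keep the earlier (lowest-index) pair -> no update
        i, j = best
        dij = dist(i, j)
        li = dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        u = next_id
        next_id += 1
        adjacency[u] = {}
        adjacency[u][i] = li
        adjacency[i][u] = li
        adjacency[u][j] = lj
        adjacency[j][u] = lj
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            key = (k, u) if k < u else (u, k)
            d[key] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    # final three-point join
    a, b, c = active
    u = next_id
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    adjacency[u] = {}
    for node, length in ((a, la), (b, lb), (c, lc)):
        length = max(length, 0.0)
        adjacency[u][node] = length
        adjacency[node][u] = length
    return PhyloTree(adjacency=adjacency, leaf_names=leaf_names)


def bootstrap_support(
    aln: AlignedSequenceSet,
    model: str = "k2p",
    cfg: TreeConfig = TreeConfig(),
    deletion_policy: str = "pairwise",
) -> tuple[PhyloTree, int]:
    """NJ tree with bootstrap supports; returns (tree, skipped_replicates).

    Alignment columns are resampled with replacement; each replicate's NJ
    tree votes for the full-data tree's internal bipartitions.  Replicates
    whose distance computation saturates are skipped and counted.
    """
    full_dm = distance_matrix(aln, model=model, deletion_policy=deletion_policy)
    tree = nj(full_dm)
    reps = cfg.bootstrap_reps
    if reps == 0:
        return tree, 0
    splits = tree.bipartitions()
    votes = {s: 0 for s in splits}
    rng = np.random.default_rng(cfg.seed)
    L = aln.length
    skipped = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(row[c] for c in cols) for row in aln.rows)
        sample = AlignedSequenceSet(names=aln.names, rows=rows)
        try:
            rep_tree = nj(
                distance_matrix(sample, model=model, deletion_policy=deletion_policy)
            )
        except SaturationError:
            skipped += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                votes[s] += 1
    done = reps - skipped
    tree.supports = {
        s: int(round(100.0 * v / done)) if done else 0 for s, v in votes.items()
    }
    return tree, skipped
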