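"""Neighbor-joining phylogeny of transposase domains with Poisson correction.

Distances are amino-acid p-distances under pairwise deletion (columns
ambiguous in either member of a pair are dropped for that pair only),
corrected for multiple hits with d = -ln(1 - p). Trees are built with the
Saitou-Nei neighbor-joining algorithm; uncertainty comes from bootstrap
resampling of alignment columns with a plain majority-rule consensus in which
bipartitions below the cutoff (default 50%, strict) are collapsed.

Trees are scikit-bio ``TreeNode`` objects throughout, so newick serialization
and standard tree operations come for free.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

logger = logging.getLogger("pletools")

__all__ = [
    "MsaBlock",
    "DistanceMatrix",
    "p_distance",
    "poisson_correct",
    "distance_matrix",
    "nj_tree",
    "bootstrap_consensus",
]

AMBIGUOUS = {"-", "X", "?"}


@dataclass(frozen=True)
class MsaBlock:
    """An aligned block of >= 3 amino-acid sequences (gaps '-', ambiguity 'X')."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 3:
            raise ValueError("need >= 3 taxa")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("all rows must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path) -> "MsaBlock":
        from pletools.io_core import read_fasta

        records = read_fasta(path)
        return cls(tuple(r.id for r in records), tuple(r.seq for r in records))

    def resample_columns(self, rng: np.random.Generator) -> "MsaBlock":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = tuple("".join(row[c] for c in cols) for row in self.rows)
        return MsaBlock(self.taxa, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions per site)."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match taxa count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("entries must be finite and >= 0")


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Columns where either row carries '-', 'X' or '?' are excluded for this
    pair. Raises if no comparable sites remain.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    compared = 0
    diff = 0
    for a, b in zip(row_a, row_b):
        if a in AMBIGUOUS or b in AMBIGUOUS:
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        raise ValueError("zero comparable sites between rows")
    return diff / compared


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p) for 0 <= p < 1."""
    if not (0 <= p < 1):
        raise ValueError(f"p must be in [0, 1), got {p} (saturated or invalid)")
    return -math.log1p(-p)


def distance_matrix(msa: MsaBlock) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances for an alignment block.

    Vectorized equivalent of ``poisson_correct(p_distance(...))`` per pair.
    """
    n = len(msa.taxa)
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in msa.rows])
    ok = ~((arr == b"-") | (arr == b"X") | (arr == b"?"))
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"zero comparable sites between {msa.taxa[i]} and {msa.taxa[j]}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / compared
            m[i, j] = m[j, i] = poisson_correct(p)
    return DistanceMatrix(msa.taxa, m)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties on Q break by the lexicographically smallest (sorted) taxa
    pair so the output is deterministic. Negative branch lengths are clamped
    to zero with a warning.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    # smallest leaf name under each working node, for deterministic tie-breaks
    labels: list[str] = list(dm.taxa)

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        bj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = bi
        child_j.length = bj
        new = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]

    # final trifurcation: b1 = (d12 + d13 - d23)/2, cyclically
    b = [
        clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2])),
        clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2])),
        clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1])),
    ]
    for node, length in zip(nodes, b):
        node.length = length
    return TreeNode(children=list(nodes))


def _bipartitions(tree: TreeNode, all_taxa: frozenset[str]) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest taxon is the canonical representative.
    """
    anchor = min(all_taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        if anchor in side:
            side = all_taxa - side
        splits.add(side)
    return splits


def bootstrap_consensus(
    msa: MsaBlock,
    reps: int = 1000,
    cutoff: float = 50.0,
    seed: int = 0,
) -> TreeNode:
    """Majority-rule bootstrap consensus of Poisson-corrected NJ trees.

    Alignment columns are resampled with replacement ``reps`` times (replicate
    r uses the independent stream (seed, r)); a tree is built per replicate
    and bipartition frequencies accumulated. Bipartitions occurring in less
    than ``cutoff`` percent of replicates are collapsed (strict '<'); retained
    ones are added to a star tree in frequency order, skipping any that
    conflict with an already-placed split. Internal node names carry the
    support percentage.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    all_taxa = frozenset(msa.taxa)
    counts: Counter[frozenset[str]] = Counter()
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        rep = msa.resample_columns(rng)
        tree = nj_tree(distance_matrix(rep))
        counts.update(_bipartitions(tree, all_taxa))

    supported = [
        (split, 100.0 * c / reps)
        for split, c in counts.items()
        if 100.0 * c / reps >= cutoff
    ]
    supported.sort(key=lambda sc: (-sc[1], -len(sc[0]), sorted(sc[0])))

    # build consensus: nest compatible splits into a star tree
    root = TreeNode(children=[TreeNode(name=t) for t in sorted(msa.taxa)])
    placed: list[frozenset[str]] = []
    for split, support in supported:
        if any(not _compatible(split, p) for p in placed):
            continue
        _insert_split(root, split, support)
        placed.append(split)
    return root


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return a <= b or b <= a or not (a & b)


def _insert_split(root: TreeNode, split: frozenset[str], support: float) -> None:
    """Group the children of root (or a nested node) covering ``split``."""
    # find the deepest node whose tip set contains the split
    node = root
    descended = True
    while descended:
        descended = False
        for child in node.children:
            tips = {t.name for t in child.tips()} or {child.name}
            if split < tips:
                node = child
                descended = True
                break
    inside = [c for c in node.children
              if ({t.name for t in c.tips()} or {c.name}) <= split]
    for c in inside:
        node.remove(c)
    new = TreeNode(name=f"{support:g}", children=inside)
    new.support = support
    node.append(new)
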