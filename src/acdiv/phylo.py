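"""Distance-based genealogy reconstruction: JC69/K2P distances,
neighbor-joining, and nonparametric (site-resampling) bootstrap.

Gapped or ambiguous sites are dropped pairwise (each pair of sequences is
compared over its mutually resolved sites), the tolerant convention usual
for tree building on intron-bearing alignments.  Neighbor joining is
delegated to scikit-bio; bootstrap supports are percentages of replicate
trees containing each internal bipartition of the point-estimate tree.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .alignment import AlignedLocus, MISSING_CHARS

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance correction diverges (log argument <= 0)."""


def _pair_props(seq_a: str, seq_b: str) -> tuple[float, float, int]:
    """(transition proportion, transversion proportion, comparable sites)."""
    ts = tv = n = 0
    for a, b in zip(seq_a, seq_b):
        if a in MISSING_CHARS or b in MISSING_CHARS:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites between sequences")
    return ts / n, tv / n, n


def jc69_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance: d = -(3/4) ln(1 - (4/3) p)."""
    ts, tv, _ = _pair_props(seq_a, seq_b)
    p = ts + tv
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"JC69 saturated at p={p:.4f}")
    return -0.75 * math.log(arg)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance:
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)."""
    P, Q, _ = _pair_props(seq_a, seq_b)
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(f"K2P saturated at P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


_MODELS = {"jc": jc69_distance, "k2p": k2p_distance}


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.values, ids=list(self.labels))


def distance_matrix(locus: AlignedLocus, model: str = "k2p") -> DistanceMatrix:
    """All-pairs corrected distances under 'jc' or 'k2p'."""
    dist = _MODELS[model.lower()]
    seqs = [h.sequence for h in locus.haplotypes]
    labels = tuple(h.id for h in locus.haplotypes)
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(seqs[i], seqs[j])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)


@dataclass
class PhyloTree:
    """Unrooted tree with optional bootstrap supports on internal edges."""

    tree: TreeNode
    supports: Optional[dict[frozenset[str], float]] = None

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.tips())

    def newick(self) -> str:
        t = self.tree.copy()
        if self.supports:
            all_labels = self.labels
            for node in t.non_tips():
                part = _canon(frozenset(x.name for x in node.tips()), all_labels)
                if part in self.supports:
                    node.name = f"{self.supports[part]:.0f}"
        buf = io.StringIO()
        t.write(buf)
        return buf.getvalue().strip()


def _canon(side: frozenset[str], all_labels: frozenset[str]) -> frozenset[str]:
    """Canonical representation of a bipartition (smaller side, ties by sort)."""
    other = all_labels - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _bipartitions(tree: TreeNode, all_labels: frozenset[str]) -> set[frozenset[str]]:
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_labels) - 1:
            parts.add(_canon(side, all_labels))
    return parts


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining (via scikit-bio)."""
    if len(matrix.labels) < 3:
        raise ValueError("need >= 3 taxa")
    tree = nj(matrix.to_skbio())
    return PhyloTree(tree=tree)


def bootstrap_support(
    locus: AlignedLocus,
    model: str = "k2p",
    replicates: int = 1000,
    seed: Optional[int] = None,
) -> PhyloTree:
    """NJ point-estimate tree with site-resampling bootstrap supports.

    Supports are the percentage of replicate NJ trees (sites resampled with
    replacement) containing each internal bipartition of the point tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    point = nj_tree(distance_matrix(locus, model))
    all_labels = point.labels
    parts = _bipartitions(point.tree, all_labels)
    hits = {p: 0 for p in parts}
    L = locus.length
    seqs = [h.sequence for h in locus.haplotypes]
    labels = [h.id for h in locus.haplotypes]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        re_seqs = ["".join(s[c] for c in cols) for s in seqs]
        try:
            dm = _resampled_matrix(re_seqs, labels, model)
        except (SaturationError, ValueError):
            continue
        rep_tree = nj(dm)
        rep_parts = _bipartitions(rep_tree, all_labels)
        for p in parts:
            if p in rep_parts:
                hits[p] += 1
    supports = {p: 100.0 * h / replicates for p, h in hits.items()}
    return PhyloTree(tree=point.tree, supports=supports)


def _resampled_matrix(seqs: Sequence[str], labels: Sequence[str], model: str):
    dist = _MODELS[model.lower()]
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist(seqs[i], seqs[j])
    return SkbioDM(m, ids=list(labels))


def species_split_support(tree: PhyloTree, populations: dict[str, str]) -> Optional[float]:
    """Bootstrap support for the bipartition separating the two populations,
    or None if the point tree does not contain that split."""
    pops = sorted(set(populations.values()))
    if len(pops) != 2:
        raise ValueError("need exactly two populations")
    side = frozenset(l for l, p in populations.items() if p == pops[0])
    part = _canon(side, tree.labels)
    if tree.supports is None:
        return None
    return tree.supports.get(part)


def separates_populations(tree: PhyloTree, populations: dict[str, str]) -> bool:
    """True if some edge of the tree splits the two populations exactly."""
    pops = sorted(set(populations.values()))
    side = frozenset(l for l, p in populations.items() if p == pops[0])
    part = _canon(side, tree.labels)
    return part in _bipartitions(tree.tree, tree.labels)
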