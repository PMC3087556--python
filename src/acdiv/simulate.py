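"""Synthetic multilocus data under a two-population isolation-with-migration
coalescent with infinite-sites mutation.

The generator uses the same mutation-rate scaling as the inference module:
time in units of 1/u generations (u = per-locus mutation rate), pairwise
coalescence rate ``2/theta`` within a population, per-lineage migration
rates ``m1``/``m2`` (backwards in time, out of populations 1 and 2), and a
pooling of all lineages into the ancestral population (``theta_A``) at
scaled time ``t``.  Mutations fall as a Poisson process of rate 1 per unit
branch length per locus and each strikes a previously unmutated site.

Defaults mirror the study design this pipeline reproduces: six loci with
lengths (413, 159, 218, 269, 270, 274) bp and 24 haplotypes per population
(12 diploid individuals, two haplotypes each).

Sequences are written over a binary base coding: ancestral "A", derived
"T".  An optional finite-sites corruption exists only to exercise distance
corrections in phylogenetic tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import AlignedLocus, Haplotype
from .im import IMParams

DEFAULT_LENGTHS = (413, 159, 218, 269, 270, 274)
DEFAULT_TRUTH = IMParams(theta1=5.0, theta2=5.0, thetaA=2.0, t=2.0, m1=0.0, m2=0.0)
POP_PREFIX = ("Flo", "Bah")
POP_NAMES = ("Florianopolis", "Itaparica")


@dataclass(frozen=True)
class SimulationConfig:
    truth: IMParams = DEFAULT_TRUTH
    n1: int = 24
    n2: int = 24
    loci: int = 6
    lengths: Sequence[int] = DEFAULT_LENGTHS
    recombination_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2 or self.loci < 1:
            raise ValueError("counts must be positive (>=2 haplotypes per pop)")
        if len(self.lengths) != self.loci:
            raise ValueError("lengths must have one entry per locus")
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be >= 0")


@dataclass(frozen=True)
class SimulatedDataset:
    loci: tuple[AlignedLocus, ...]
    truth: IMParams
    genealogies: Optional[tuple[str, ...]] = None  # newick, when available


class CapacityError(RuntimeError):
    """More mutations than sites; use longer loci or smaller theta."""


# ---------------------------------------------------------------------------
# single-locus structured coalescent

def _simulate_genealogy(n1: int, n2: int, p: IMParams, rng: np.random.Generator):
    """Backwards-in-time IM coalescent for one locus.

    Returns (parent, time, children, leaf count) arrays in the usual
    2n-1-node indexing, leaves 0..n-1 (first n1 in population 0).
    """
    n = n1 + n2
    total = 2 * n - 1
    parent = [-1] * total
    time = [0.0] * total
    children: list[Optional[tuple[int, int]]] = [None] * total
    # active lineages per population (2 = ancestral pool)
    active = {0: list(range(n1)), 1: list(range(n1, n))}
    next_id = n
    tau = 0.0
    t_split = p.t

    def coalesce(pool: list[int]) -> None:
        nonlocal next_id
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        v = next_id
        next_id += 1
        time[v] = tau
        children[v] = (a, b)
        parent[a] = v
        parent[b] = v
        pool.remove(a)
        pool.remove(b)
        pool.append(v)

    while tau < t_split and (len(active[0]) + len(active[1])) > 1:
        k0, k1 = len(active[0]), len(active[1])
        rates = []
        if p.theta1 > 0:
            rates.append(("c0", k0 * (k0 - 1) / p.theta1))
        if p.theta2 > 0:
            rates.append(("c1", k1 * (k1 - 1) / p.theta2))
        rates.append(("m0", k0 * p.m1))
        rates.append(("m1", k1 * p.m2))
        lam = sum(r for _, r in rates)
        if lam <= 0:
            tau = t_split
            break
        delta = rng.exponential(1.0 / lam)
        if tau + delta >= t_split:
            tau = t_split
            break
        tau += delta
        u = rng.uniform(0, lam)
        for kind, r in rates:
            if u < r:
                break
            u -= r
        if kind == "c0":
            coalesce(active[0])
        elif kind == "c1":
            coalesce(active[1])
        elif kind == "m0":
            v = active[0].pop(int(rng.integers(len(active[0]))))
            active[1].append(v)
        else:
            v = active[1].pop(int(rng.integers(len(active[1]))))
            active[0].append(v)

    pool = active[0] + active[1]
    while len(pool) > 1:
        k = len(pool)
        lam = k * (k - 1) / p.thetaA if p.thetaA > 0 else float("inf")
        tau += rng.exponential(1.0 / lam) if math.isfinite(lam) else 0.0
        coalesce(pool)
    return parent, time, children, n


def _leaf_sets(parent, children, n: int) -> list[int]:
    total = 2 * n - 1
    masks = [0] * total
    for v in range(n):
        masks[v] = 1 << v
    for v in range(n, total):
        a, b = children[v]
        masks[v] = masks[a] | masks[b]
    return masks


def _newick(children, time, n: int, labels: Sequence[str]) -> str:
    root = 2 * n - 2

    def rec(v: int) -> str:
        if v < n:
            return labels[v]
        a, b = children[v]
        la = time[v] - time[a]
        lb = time[v] - time[b]
        return f"({rec(a)}:{la:.6g},{rec(b)}:{lb:.6g})"

    return rec(root) + ";"


def _haplotype_labels(n1: int, n2: int) -> list[str]:
    labels = []
    for pop, count in ((0, n1), (1, n2)):
        for i in range(count):
            indiv = i // 2 + 1
            allele = "ab"[i % 2]
            labels.append(f"{POP_PREFIX[pop]}{indiv:02d}{allele}")
    return labels


def simulate_im_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a multilocus dataset with known IM ground truth.

    Under zero recombination every locus satisfies the four-gamete test
    (RM = 0) by construction.
    """
    rng = np.random.default_rng(config.seed)
    labels = _haplotype_labels(config.n1, config.n2)
    n = config.n1 + config.n2
    loci = []
    trees = []
    for li in range(config.loci):
        L = int(config.lengths[li])
        parent, time, children, _ = _simulate_genealogy(
            config.n1, config.n2, config.truth, rng
        )
        masks = _leaf_sets(parent, children, n)
        total = 2 * n - 1
        blens = np.array(
            [time[parent[v]] - time[v] if parent[v] >= 0 else 0.0 for v in range(total)]
        )
        B = blens.sum()
        n_mut = rng.poisson(B)
        if n_mut > L:
            raise CapacityError(
                f"locus {li}: {n_mut} mutations exceed {L} sites; "
                "increase locus length or reduce theta/t"
            )
        seqs = np.full((n, L), "A", dtype="U1")
        if n_mut > 0:
            branch = rng.choice(total, size=n_mut, p=blens / B)
            sites = rng.choice(L, size=n_mut, replace=False)
            for b, s in zip(branch, sites):
                carriers = masks[b]
                for leaf in range(n):
                    if carriers >> leaf & 1:
                        seqs[leaf, s] = "T"
        haps = tuple(
            Haplotype(
                id=labels[i],
                population=POP_NAMES[0] if i < config.n1 else POP_NAMES[1],
                sequence="".join(seqs[i]),
            )
            for i in range(n)
        )
        loci.append(AlignedLocus(name=f"locus{li + 1}", haplotypes=haps))
        trees.append(_newick(children, time, n, labels))
    return SimulatedDataset(loci=tuple(loci), truth=config.truth, genealogies=tuple(trees))


# ---------------------------------------------------------------------------
# recombination backend (ancestral recombination graph via msprime)

def simulate_with_recombination(config: SimulationConfig) -> SimulatedDataset:
    """IM simulation with intra-locus recombination.

    With ``recombination_rate == 0`` this is exactly
    :func:`simulate_im_dataset` (same seed, same output).  With rho > 0 the
    ancestral recombination graph is delegated to msprime, mapped onto the
    same mutation-rate scaling (population size theta/2 with ploidy 1, one
    mutation per locus per time unit, migration and split as above); output
    loci typically violate the four-gamete test.
    """
    if config.recombination_rate == 0:
        return simulate_im_dataset(config)
    import msprime

    p = config.truth
    rng = np.random.default_rng(config.seed)
    labels = _haplotype_labels(config.n1, config.n2)
    n = config.n1 + config.n2
    loci = []
    for li in range(config.loci):
        L = int(config.lengths[li])
        demography = msprime.Demography()
        demography.add_population(name="pop1", initial_size=max(p.theta1, 1e-9) / 2)
        demography.add_population(name="pop2", initial_size=max(p.theta2, 1e-9) / 2)
        demography.add_population(name="anc", initial_size=max(p.thetaA, 1e-9) / 2)
        if p.m1 > 0:
            demography.set_migration_rate(source="pop1", dest="pop2", rate=p.m1)
        if p.m2 > 0:
            demography.set_migration_rate(source="pop2", dest="pop1", rate=p.m2)
        demography.add_population_split(
            time=p.t, derived=["pop1", "pop2"], ancestral="anc"
        )
        ts = msprime.sim_ancestry(
            samples={"pop1": config.n1, "pop2": config.n2},
            demography=demography,
            ploidy=1,
            sequence_length=L,
            recombination_rate=config.recombination_rate / L,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=1.0 / L,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        if mts.num_sites > L:
            raise CapacityError(f"locus {li}: more mutations than sites")
        seqs = np.full((n, L), "A", dtype="U1")
        used: set[int] = set()
        for variant in mts.variants():
            col = int(variant.site.position)
            while col in used:
                col = (col + 1) % L
            used.add(col)
            geno = np.asarray(variant.genotypes)
            seqs[geno > 0, col] = "T"
        haps = tuple(
            Haplotype(
                id=labels[i],
                population=POP_NAMES[0] if i < config.n1 else POP_NAMES[1],
                sequence="".join(seqs[i]),
            )
            for i in range(n)
        )
        loci.append(AlignedLocus(name=f"locus{li + 1}", haplotypes=haps))
    return SimulatedDataset(loci=tuple(loci), truth=config.truth, genealogies=None)


# ---------------------------------------------------------------------------
# clone-sequencing simulator

def simulate_clone_sequencing(
    individuals: int,
    het_fraction: float,
    clones: int,
    seed: Optional[int] = None,
) -> tuple[list[frozenset[int]], list[bool]]:
    """Simulate the consensus-from-clones genotyping procedure.

    Each heterozygote's ``clones`` sequenced clones are drawn uniformly
    from its two alleles; the individual is observed homozygous iff all
    clones show one allele.  Returns (observed allele sets, true
    heterozygosity flags); the empirical misclassification rate is the
    fraction of true heterozygotes with a singleton observed set.
    """
    if clones < 1:
        raise ValueError("clones must be >= 1")
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    observed: list[frozenset[int]] = []
    truth: list[bool] = []
    for _ in range(individuals):
        is_het = bool(rng.uniform() < het_fraction)
        truth.append(is_het)
        if is_het:
            draws = rng.integers(0, 2, size=clones)
            observed.append(frozenset(int(d) for d in draws))
        else:
            observed.append(frozenset({0}))
    return observed, truth


def misclassification_rate(
    observed: Sequence[frozenset[int]], truth: Sequence[bool]
) -> float:
    """Fraction of true heterozygotes observed as homozygous."""
    hets = [o for o, t in zip(observed, truth) if t]
    if not hets:
        return 0.0
    return sum(1 for o in hets if len(o) == 1) / len(hets)


def jc_corrupt(
    locus: AlignedLocus, extra_rate: float, seed: Optional[int] = None
) -> AlignedLocus:
    """Sprinkle random substitutions over all four bases (for distance tests
    only; breaks the infinite-sites guarantee)."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    haps = []
    for h in locus.haplotypes:
        seq = list(h.sequence)
        hits = rng.uniform(size=len(seq)) < extra_rate
        for i in np.flatnonzero(hits):
            cur = seq[i]
            choices = [b for b in bases if b != cur]
            seq[i] = choices[int(rng.integers(3))]
        haps.append(replace(h, sequence="".join(seq)))
    return AlignedLocus(name=locus.name, haplotypes=tuple(haps))
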