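"""Per-population polymorphism/neutrality statistics and between-population
divergence statistics for two-population multilocus alignments.

Conventions
-----------
* Watterson's theta is computed from eta, the total number of mutations
  (sum over sites of distinct-bases-minus-one), divided by a1 * L; with
  purely biallelic data eta equals S.
* Fu & Li statistics are the starred, outgroup-free versions (D*, F*),
  using the count of singleton mutations.
* FST is the Hudson/Slatkin/Maddison estimator 1 - Hw/Hb with Hw the
  unweighted mean of the two within-population mean pairwise differences
  and Hb the between-population mean pairwise difference (= Dxy).
* Statistics undefined at S = 0 are reported as None, never as 0.
* Neutrality p-values come from coalescent simulation conditioned on the
  observed number of segregating sites (fixed-S null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment import AlignedLocus, SiteMask, build_site_mask

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class LocusSummaryStats:
    """One per-population summary row: S, eta, theta, pi and test statistics."""

    locus: str
    population: str
    n: int
    S: int
    eta: int
    theta_w: float
    pi: float
    D_T: Optional[float]
    D_FL: Optional[float]
    F_FL: Optional[float]
    L_effective: int


@dataclass(frozen=True)
class DivergenceStats:
    """Pairwise between-population divergence summary for one locus."""

    locus: str
    fst: float
    dxy: float
    da: float
    pi_a: float
    pi_b: float
    s_shared: int
    s_fixed: int
    s_excl1: int
    s_excl2: int
    s_multiallelic: int
    L_effective: int
    fst_pvalue: Optional[float] = None


@dataclass(frozen=True)
class NeutralityTestResult:
    statistic_name: str
    value: float
    p_value: float
    replicates: int
    adjusted_p: float
    family_size: int


# ---------------------------------------------------------------------------
# encoding helpers

def _encode(locus: AlignedLocus, haps, mask: SiteMask | None) -> np.ndarray:
    """Encode selected haplotypes over masked sites as an int matrix."""
    if mask is None:
        mask = build_site_mask(locus)
    rows = [
        [_BASE_CODE[c] for c in mask.apply(h.sequence)]
        for h in haps
    ]
    return np.asarray(rows, dtype=np.int8)


def _population_matrix(
    locus: AlignedLocus, population: str | None, mask: SiteMask | None
) -> np.ndarray:
    if population is None:
        haps = locus.haplotypes
    else:
        haps = locus.population_sample(population)
    if len(haps) < 2:
        raise ValueError(f"need >=2 haplotypes, got {len(haps)}")
    return _encode(locus, haps, mask)


def _site_allele_counts(column: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(column[column < 4], return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# within-population statistics

def segregating_sites(
    locus: AlignedLocus, population: str | None = None, mask: SiteMask | None = None
) -> tuple[int, int]:
    """Count segregating sites S and total mutations eta.

    eta counts (number of distinct bases - 1) at each site, so a
    triallelic site contributes 1 to S and 2 to eta.
    """
    m = _population_matrix(locus, population, mask)
    S = 0
    eta = 0
    for j in range(m.shape[1]):
        k = len(_site_allele_counts(m[:, j]))
        if k >= 2:
            S += 1
            eta += k - 1
    return S, eta


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(eta: int, n: int, L: int) -> float:
    """Watterson's diversity per site from the total mutation count."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L < 1:
        raise ValueError("need L >= 1")
    return eta / (harmonic(n) * L)


def _pairwise_diff_total(m: np.ndarray) -> float:
    """Mean number of pairwise differences over all unordered pairs."""
    n = m.shape[0]
    total = 0
    for i in range(n):
        diff = (m[i + 1 :] != m[i]) & (m[i + 1 :] < 4) & (m[i] < 4)
        total += int(diff.sum())
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(
    locus: AlignedLocus, population: str | None = None, mask: SiteMask | None = None
) -> float:
    """pi: mean pairwise differences per analyzed site."""
    m = _population_matrix(locus, population, mask)
    return _pairwise_diff_total(m) / m.shape[1]


def _singleton_count(m: np.ndarray) -> int:
    """Number of singleton mutations (a base seen in exactly one sequence)."""
    eta_s = 0
    for j in range(m.shape[1]):
        counts = _site_allele_counts(m[:, j])
        if len(counts) >= 2:
            eta_s += sum(1 for c in counts.values() if c == 1)
    return eta_s


# --- closed-form statistics from sufficient counts -------------------------

def tajimas_D_from_counts(n: int, S: int, khat: float) -> Optional[float]:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs.

    Undefined (None) for S = 0 and for n < 4, where the variance constants
    vanish."""
    if S == 0 or n < 4:
        return None
    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fu_li_constants(n: int):
    a = harmonic(n)
    b = sum(1.0 / i**2 for i in range(1, n))
    an1 = a + 1.0 / n
    cn = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    vD = ((n / (n - 1)) ** 2 * b + a**2 * dn - 2 * (n * a * (a + 1)) / ((n - 1) ** 2))
    vD /= a**2 + b
    uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))) / a - vF
    return a, uD, vD, uF, vF


def fu_li_D_star_from_counts(n: int, eta: int, eta_s: int) -> Optional[float]:
    if eta == 0 or n < 4:
        return None
    a, uD, vD, _, _ = _fu_li_constants(n)
    num = (n / (n - 1)) * eta - a * eta_s
    return num / math.sqrt(uD * eta + vD * eta * eta)


def fu_li_F_star_from_counts(
    n: int, eta: int, eta_s: int, khat: float
) -> Optional[float]:
    if eta == 0 or n < 4:
        return None
    _, _, _, uF, vF = _fu_li_constants(n)
    num = khat - ((n - 1) / n) * eta_s
    return num / math.sqrt(uF * eta + vF * eta * eta)


# --- alignment-facing wrappers ---------------------------------------------

def tajimas_D(
    locus: AlignedLocus, population: str | None = None, mask: SiteMask | None = None
) -> Optional[float]:
    m = _population_matrix(locus, population, mask)
    S, _ = segregating_sites(locus, population, mask)
    if S == 0:
        return None
    return tajimas_D_from_counts(m.shape[0], S, _pairwise_diff_total(m))


def fu_li_D_star(
    locus: AlignedLocus, population: str | None = None, mask: SiteMask | None = None
) -> Optional[float]:
    m = _population_matrix(locus, population, mask)
    _, eta = segregating_sites(locus, population, mask)
    return fu_li_D_star_from_counts(m.shape[0], eta, _singleton_count(m))


def fu_li_F_star(
    locus: AlignedLocus, population: str | None = None, mask: SiteMask | None = None
) -> Optional[float]:
    m = _population_matrix(locus, population, mask)
    _, eta = segregating_sites(locus, population, mask)
    if eta == 0:
        return None
    return fu_li_F_star_from_counts(
        m.shape[0], eta, _singleton_count(m), _pairwise_diff_total(m)
    )


def locus_summary(
    locus: AlignedLocus, population: str, mask: SiteMask | None = None
) -> LocusSummaryStats:
    """All per-population summary statistics for one locus (one table row)."""
    if mask is None:
        mask = build_site_mask(locus, populations=[population])
    m = _population_matrix(locus, population, mask)
    n, L = m.shape
    S, eta = segregating_sites(locus, population, mask)
    khat = _pairwise_diff_total(m)
    eta_s = _singleton_count(m)
    return LocusSummaryStats(
        locus=locus.name,
        population=population,
        n=n,
        S=S,
        eta=eta,
        theta_w=watterson_theta(eta, n, L) if L else 0.0,
        pi=khat / L if L else 0.0,
        D_T=tajimas_D_from_counts(n, S, khat),
        D_FL=fu_li_D_star_from_counts(n, eta, eta_s),
        F_FL=fu_li_F_star_from_counts(n, eta, eta_s, khat),
        L_effective=L,
    )


# ---------------------------------------------------------------------------
# fixed-S coalescent null simulation

_STATISTICS = ("tajima_d", "fu_li_d_star", "fu_li_f_star")


def simulate_null_statistics(
    statistic_name: str, n: int, S: int, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of a neutrality statistic under the standard
    coalescent conditioned on S segregating sites.

    For each replicate a Kingman genealogy is drawn and S mutations are
    placed uniformly on its branches; the statistic is recomputed from the
    resulting derived-allele counts.
    """
    if statistic_name not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic_name!r}")
    out = np.empty(replicates)
    for r in range(replicates):
        counts = _sample_fixed_s_counts(n, S, rng)
        khat = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
        eta_s = int(np.sum((counts == 1) | (counts == n - 1)))
        if statistic_name == "tajima_d":
            v = tajimas_D_from_counts(n, S, khat)
        elif statistic_name == "fu_li_d_star":
            v = fu_li_D_star_from_counts(n, S, eta_s)
        else:
            v = fu_li_F_star_from_counts(n, S, eta_s, khat)
        out[r] = v
    return out


def _sample_fixed_s_counts(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts of S mutations dropped on a Kingman genealogy."""
    sizes = np.ones(n, dtype=np.int64)
    level_weights = np.empty(n - 1)
    snapshots: list[np.ndarray] = []
    active = list(range(n))
    for k in range(n, 1, -1):
        t_k = rng.exponential(2.0 / (k * (k - 1)))
        snapshots.append(sizes[active].copy())
        level_weights[n - k] = k * t_k
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        sizes[a] += sizes[b]
        active.remove(b)
    levels = rng.choice(n - 1, size=S, p=level_weights / level_weights.sum())
    counts = np.empty(S, dtype=np.int64)
    for idx, lev in enumerate(levels):
        snap = snapshots[lev]
        counts[idx] = snap[rng.integers(len(snap))]
    # mutations subtending all n leaves are invisible; the root has no branch,
    # so snapshot sizes are always < n except possibly the last level where a
    # lineage of size n never exists before the final merge
    return counts


def neutrality_p_value(
    statistic: float,
    statistic_name: str,
    n: int,
    S: int,
    replicates: int = 10_000,
    seed: int | None = None,
    family_size: int = 12,
) -> NeutralityTestResult:
    """Two-tailed simulation p-value against the fixed-S coalescent null,
    with Bonferroni adjustment over ``family_size`` tests."""
    if replicates < 1000:
        raise ValueError("need >= 1000 replicates")
    rng = np.random.default_rng(seed)
    null = simulate_null_statistics(statistic_name, n, S, replicates, rng)
    p = float(np.mean(np.abs(null) >= abs(statistic)))
    return NeutralityTestResult(
        statistic_name=statistic_name,
        value=statistic,
        p_value=p,
        replicates=replicates,
        adjusted_p=min(1.0, p * family_size),
        family_size=family_size,
    )


# ---------------------------------------------------------------------------
# between-population statistics

def _pair_diff_matrix(m: np.ndarray) -> np.ndarray:
    """n x n matrix of pairwise difference counts (missing-aware)."""
    n = m.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = (m[i + 1 :] != m[i]) & (m[i + 1 :] < 4) & (m[i] < 4)
        d = diff.sum(axis=1)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


def _hw_hb(D: np.ndarray, is_a: np.ndarray) -> tuple[float, float]:
    a_idx = np.flatnonzero(is_a)
    b_idx = np.flatnonzero(~is_a)
    pi_a = D[np.ix_(a_idx, a_idx)].sum() / (len(a_idx) * (len(a_idx) - 1))
    pi_b = D[np.ix_(b_idx, b_idx)].sum() / (len(b_idx) * (len(b_idx) - 1))
    hb = D[np.ix_(a_idx, b_idx)].mean()
    return 0.5 * (pi_a + pi_b), hb


def between_population_stats(
    locus: AlignedLocus,
    pop_a: str,
    pop_b: str,
    mask: SiteMask | None = None,
) -> DivergenceStats:
    """Dxy, Da, FST and the shared/fixed/exclusive site partition.

    The four site categories are defined for sites biallelic in the pooled
    sample; sites with more than two alleles are tallied separately.
    """
    if mask is None:
        mask = build_site_mask(locus, populations=[pop_a, pop_b])
    haps_a = locus.population_sample(pop_a)
    haps_b = locus.population_sample(pop_b)
    if len(haps_a) < 2 or len(haps_b) < 2:
        raise ValueError("need >=2 haplotypes per population")
    ma = _encode(locus, haps_a, mask)
    mb = _encode(locus, haps_b, mask)
    L = ma.shape[1]
    na, nb = ma.shape[0], mb.shape[0]

    pi_a = _pairwise_diff_total(ma) / L
    pi_b = _pairwise_diff_total(mb) / L
    # cross-population mean pairwise differences
    cross = 0
    for i in range(na):
        cross += int((((mb != ma[i]) & (mb < 4)) & (ma[i] < 4)).sum())
    dxy = cross / (na * nb) / L
    da = dxy - 0.5 * (pi_a + pi_b)
    hw = 0.5 * (pi_a + pi_b) * L
    hb = dxy * L
    fst = 1.0 - hw / hb if hb > 0 else 0.0

    s_shared = s_fixed = s1 = s2 = s_multi = 0
    for j in range(L):
        ca = _site_allele_counts(ma[:, j])
        cb = _site_allele_counts(mb[:, j])
        pooled = set(ca) | set(cb)
        if len(pooled) < 2:
            continue
        if len(pooled) > 2:
            s_multi += 1
            continue
        poly_a = len(ca) == 2
        poly_b = len(cb) == 2
        if poly_a and poly_b:
            s_shared += 1
        elif poly_a:
            s1 += 1
        elif poly_b:
            s2 += 1
        else:
            # monomorphic in both; different alleles (pooled is biallelic)
            s_fixed += 1
    return DivergenceStats(
        locus=locus.name,
        fst=fst,
        dxy=dxy,
        da=da,
        pi_a=pi_a,
        pi_b=pi_b,
        s_shared=s_shared,
        s_fixed=s_fixed,
        s_excl1=s1,
        s_excl2=s2,
        s_multiallelic=s_multi,
        L_effective=L,
    )


def fst_permutation_p(
    locus: AlignedLocus,
    pop_a: str,
    pop_b: str,
    permutations: int = 10_000,
    seed: int | None = None,
    mask: SiteMask | None = None,
) -> float:
    """One-sided permutation p-value for FST (label shuffling)."""
    if permutations < 1000:
        raise ValueError("need >= 1000 permutations")
    if mask is None:
        mask = build_site_mask(locus, populations=[pop_a, pop_b])
    haps = list(locus.population_sample(pop_a)) + list(locus.population_sample(pop_b))
    m = _encode(locus, haps, mask)
    na = len(locus.population_sample(pop_a))
    D = _pair_diff_matrix(m)
    is_a = np.zeros(len(haps), dtype=bool)
    is_a[:na] = True
    hw, hb = _hw_hb(D, is_a)
    obs = 1.0 - hw / hb if hb > 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    labels = is_a.copy()
    for _ in range(permutations):
        rng.shuffle(labels)
        hw_p, hb_p = _hw_hb(D, labels)
        f = 1.0 - hw_p / hb_p if hb_p > 0 else 0.0
        if f >= obs - 1e-12:
            hits += 1
    return hits / permutations
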