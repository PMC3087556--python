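"""Bayesian isolation-with-migration (IM) inference by MCMC over
per-locus genealogies under the infinite-sites mutation model.

Model
-----
Two descendant populations (indexed 0 and 1) split from an ancestral
population at scaled time ``t``.  All quantities use the mutation-rate
scaling conventional for IM analyses: time is measured in units of
``1/u`` generations (``u`` = neutral mutation rate per locus per
generation), so

* a pair of lineages in population ``i`` coalesces at rate ``2/theta_i``
  (``theta_i = 4 N_i u``),
* a lineage in population ``i`` migrates (backwards in time) to the other
  population at rate ``m_i`` (``m_i = m/u``),
* mutations fall on a branch of length ``b`` as Poisson(``b``).

Older than ``t`` every lineage belongs to the ancestral population
(coalescence rate ``2/theta_A``) and migration stops.

Priors are uniform on ``[0, upper]`` for each of the six parameters.

Sampler
-------
The genealogy move detaches a random subtree and re-simulates its lineage
path (migration events and re-attachment) forward from its base under the
structured coalescent conditioned on the rest of the genealogy; both the
forward and reverse proposal densities are evaluated explicitly, so the
acceptance ratio is the exact Metropolis--Hastings ratio.  theta and
migration parameters are updated by Gibbs sampling from their
sufficient-statistic conditionals (truncated gamma); the split time uses a
reflected random walk whose step size is adapted during burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special as sp_special

from .alignment import AlignedLocus, build_site_mask
from .popgen import harmonic

PARAM_NAMES = ("theta1", "theta2", "thetaA", "t", "m1", "m2")


@dataclass(frozen=True)
class IMParams:
    """Six demographic parameters on the mutation-rate scale."""

    theta1: float
    theta2: float
    thetaA: float
    t: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, k) for k in PARAM_NAMES)


class IncompatibleDataError(ValueError):
    """Locus data admit no perfect phylogeny (recombination not removed?)."""


# ===========================================================================
# data preparation

@dataclass(frozen=True)
class LocusData:
    """Mutation patterns of one locus, ready for genealogy likelihoods."""

    name: str
    ids: tuple[str, ...]
    pops: tuple[int, ...]          # 0/1 per leaf
    carriers: dict[int, int]       # leaf bitmask of derived carriers -> #sites
    n_sites_total: int

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_mutations(self) -> int:
        return sum(self.carriers.values())


def prepare_locus(
    locus: AlignedLocus,
    pop_labels: Sequence[str] | None = None,
    ancestral: str = "A",
) -> LocusData:
    """Extract derived-carrier bitmasks per segregating site.

    ``ancestral`` is either a base ("A" by convention for simulated data) or
    "majority" (the most frequent allele is treated as ancestral).  The
    carrier-set family must be laminar (a rooted perfect phylogeny must
    exist); crossing sets whose union covers the sample are re-polarized by
    complementation, anything else raises :class:`IncompatibleDataError`.
    """
    pops_declared = list(pop_labels) if pop_labels else list(locus.populations)
    if len(pops_declared) != 2:
        raise ValueError("IM inference needs exactly two populations")
    mask = build_site_mask(locus)
    haps = locus.haplotypes
    n = len(haps)
    pop_idx = tuple(pops_declared.index(h.population) for h in haps)
    seqs = [mask.apply(h.sequence) for h in haps]
    full = (1 << n) - 1
    carriers: dict[int, int] = {}
    for j in range(len(mask)):
        col = [s[j] for s in seqs]
        alleles = sorted(set(col))
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            raise IncompatibleDataError(
                f"{locus.name}: site {mask.included[j]} has >2 alleles; "
                "infinite-sites likelihood undefined"
            )
        if ancestral == "majority":
            anc = max(alleles, key=lambda a: (col.count(a), a))
        else:
            anc = ancestral
            if anc not in alleles:
                # fixed difference from the nominal ancestral base: treat the
                # majority allele as ancestral at this site
                anc = max(alleles, key=lambda a: (col.count(a), a))
        m = 0
        for i, c in enumerate(col):
            if c != anc:
                m |= 1 << i
        if m == full or m == 0:
            continue
        carriers[m] = carriers.get(m, 0) + 1
    carriers = _laminar_fix(carriers, full, locus.name)
    return LocusData(
        name=locus.name,
        ids=tuple(h.id for h in haps),
        pops=pop_idx,
        carriers=carriers,
        n_sites_total=len(mask),
    )


def _crossing(a: int, b: int, full: int) -> bool:
    return bool(a & b) and bool(a & ~b & full) and bool(~a & b & full)


def _laminar_fix(carriers: dict[int, int], full: int, name: str) -> dict[int, int]:
    masks = sorted(carriers, key=lambda m: -bin(m).count("1"))
    for _ in range(len(masks) + 1):
        flipped = False
        masks = sorted(carriers, key=lambda m: -bin(m).count("1"))
        for i, a in enumerate(masks):
            for b in masks[i + 1 :]:
                if _crossing(a, b, full):
                    if (a | b) == full:
                        big = a if bin(a).count("1") >= bin(b).count("1") else b
                        cnt = carriers.pop(big)
                        comp = ~big & full
                        carriers[comp] = carriers.get(comp, 0) + cnt
                        flipped = True
                        break
                    raise IncompatibleDataError(
                        f"{name}: segregating sites are not compatible with a "
                        "single genealogy (was recombination filtered?)"
                    )
            if flipped:
                break
        if not flipped:
            return carriers
    raise IncompatibleDataError(f"{name}: could not re-polarize to a laminar family")


# ===========================================================================
# genealogy state

class Genealogy:
    """Rooted binary genealogy with population-labelled lineage segments.

    Nodes ``0..n-1`` are leaves (time 0); internal nodes occupy indices
    ``n..2n-2``.  ``migs[v]`` lists migration events on the branch from
    ``v`` toward its parent as ``(time, population_after)`` going backwards,
    sorted by time.
    """

    __slots__ = ("n", "leaf_pops", "time", "parent", "children", "migs", "root")

    def __init__(self, n: int, leaf_pops: Sequence[int]):
        self.n = n
        self.leaf_pops = list(leaf_pops)
        total = 2 * n - 1
        self.time = [0.0] * total
        self.parent: list[Optional[int]] = [None] * total
        self.children: list[Optional[tuple[int, int]]] = [None] * total
        self.migs: list[list[tuple[float, int]]] = [[] for _ in range(total)]
        self.root = -1

    def clone(self) -> "Genealogy":
        g = Genealogy.__new__(Genealogy)
        g.n = self.n
        g.leaf_pops = self.leaf_pops
        g.time = list(self.time)
        g.parent = list(self.parent)
        g.children = list(self.children)
        g.migs = [list(m) for m in self.migs]
        g.root = self.root
        return g

    # -- population bookkeeping --------------------------------------------

    def base_pop(self, v: int) -> int:
        """Population of lineage v at its own node time."""
        while v >= self.n:
            v = self.children[v][0]
            for _, pa in reversed(self.migs[v]):
                return pa
        return self.leaf_pops[v]

    def pop_at(self, v: int, tau: float) -> int:
        """Population of the lineage above node v at time tau."""
        p = self.base_pop(v)
        for tm, pa in self.migs[v]:
            if tm <= tau:
                p = pa
            else:
                break
        return p

    def subtree_nodes(self, x: int) -> set[int]:
        out = set()
        stack = [x]
        while stack:
            v = stack.pop()
            out.add(v)
            if v >= self.n:
                stack.extend(self.children[v])
        return out

    def clades(self) -> dict[int, int]:
        """Map node -> bitmask of descendant leaves (post-order)."""
        cl: dict[int, int] = {}
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if v >= self.n:
                stack.extend(self.children[v])
        for v in reversed(order):
            if v < self.n:
                cl[v] = 1 << v
            else:
                a, b = self.children[v]
                cl[v] = cl[a] | cl[b]
        return cl

    def total_length(self) -> float:
        return sum(
            self.time[self.parent[v]] - self.time[v]
            for v in range(2 * self.n - 1)
            if self.parent[v] is not None
        )

    def height(self) -> float:
        return self.time[self.root]


def build_initial_genealogy(
    data: LocusData, t_floor: float, dt: float
) -> Genealogy:
    """Deterministic perfect-phylogeny-compatible starting genealogy.

    All coalescences are placed above ``t_floor`` (ancestral era), so no
    migration events are needed for validity regardless of leaf labels.
    """
    n = data.n
    g = Genealogy(n, data.pops)
    full = (1 << n) - 1
    clusters = sorted(set(data.carriers) | {full}, key=lambda m: bin(m).count("1"))
    units: dict[int, int] = {1 << i: i for i in range(n)}  # mask -> node id
    next_id = n
    tau = t_floor
    for cl in clusters:
        if bin(cl).count("1") < 2:
            continue
        members = [m for m in units if m & cl == m]
        sum_mask = 0
        for m in members:
            sum_mask |= m
        if sum_mask != cl:
            raise IncompatibleDataError(f"{data.name}: non-laminar carrier family")
        members.sort()
        cur = members[0]
        for m in members[1:]:
            tau += dt
            v = next_id
            next_id += 1
            g.time[v] = tau
            g.children[v] = (units[cur], units[m])
            g.parent[units[cur]] = v
            g.parent[units[m]] = v
            del units[cur], units[m]
            cur = cur | m
            units[cur] = v
    assert list(units) == [full]
    g.root = units[full]
    return g


# ===========================================================================
# densities

def genealogy_log_prior(g: Genealogy, p: IMParams):
    """log density of the genealogy under the structured coalescent, plus
    the sufficient statistics for the parameter conditionals.

    Returns ``(logf, stats)`` where stats has coalescence counts ``C1, C2,
    CA``, waiting opportunities ``W1, W2, WA`` (integrals of k(k-1)),
    migration counts ``M1, M2`` and lineage-time integrals ``R1, R2``.
    ``logf`` is ``-inf`` for invalid states (e.g. cross-population
    coalescence below the split or migration above it).
    """
    NEG = float("-inf")
    zero_stats = dict(C1=0, C2=0, CA=0, W1=0.0, W2=0.0, WA=0.0,
                      M1=0, M2=0, R1=0.0, R2=0.0)
    events: list[tuple[float, int, int, int]] = []  # (tau, kind, node, pop_after)
    for v in range(2 * g.n - 1):
        if g.parent[v] is not None:
            for tm, pa in g.migs[v]:
                events.append((tm, 0, v, pa))
        if v >= g.n and (g.parent[v] is not None or v == g.root):
            events.append((g.time[v], 1, v, -1))
    events.sort(key=lambda e: (e[0], e[1]))

    cur_pop = {i: g.leaf_pops[i] for i in range(g.n)}
    k = [0, 0]
    for i in range(g.n):
        k[g.leaf_pops[i]] += 1
    st = dict(zero_stats)
    logf = 0.0
    tau = 0.0
    t_split = p.t
    theta = (p.theta1, p.theta2)
    mrate = (p.m1, p.m2)

    def integrate(a: float, b: float) -> None:
        nonlocal logf
        if b <= a:
            return
        lo, hi = a, min(b, t_split)
        if hi > lo:
            st["W1"] += k[0] * (k[0] - 1) * (hi - lo)
            st["W2"] += k[1] * (k[1] - 1) * (hi - lo)
            st["R1"] += k[0] * (hi - lo)
            st["R2"] += k[1] * (hi - lo)
            rate = 0.0
            if theta[0] > 0:
                rate += k[0] * (k[0] - 1) / theta[0]
            elif k[0] > 1:
                rate = float("inf")
            if theta[1] > 0:
                rate += k[1] * (k[1] - 1) / theta[1]
            elif k[1] > 1:
                rate = float("inf")
            rate += mrate[0] * k[0] + mrate[1] * k[1]
            logf -= rate * (hi - lo)
        lo2 = max(a, t_split)
        if b > lo2:
            ka = k[0] + k[1]
            st["WA"] += ka * (ka - 1) * (b - lo2)
            if p.thetaA > 0:
                logf -= ka * (ka - 1) / p.thetaA * (b - lo2)
            elif ka > 1:
                logf = float("-inf")

    for tm, kind, v, pa in events:
        integrate(tau, tm)
        tau = tm
        if kind == 0:  # migration
            if tm >= t_split:
                return NEG, zero_stats
            frm = cur_pop[v]
            if pa == frm:
                return NEG, zero_stats
            if mrate[frm] <= 0:
                return NEG, zero_stats
            logf += math.log(mrate[frm])
            st["M1" if frm == 0 else "M2"] += 1
            k[frm] -= 1
            k[pa] += 1
            cur_pop[v] = pa
        else:  # coalescence at node v
            a, b = g.children[v]
            if tm < t_split:
                if cur_pop[a] != cur_pop[b]:
                    return NEG, zero_stats
                pop = cur_pop[a]
                if theta[pop] <= 0:
                    return NEG, zero_stats
                logf += math.log(2.0 / theta[pop])
                st["C1" if pop == 0 else "C2"] += 1
                k[pop] -= 1
            else:
                if p.thetaA <= 0:
                    return NEG, zero_stats
                logf += math.log(2.0 / p.thetaA)
                st["CA"] += 1
                k[cur_pop[a]] -= 1
                k[cur_pop[b]] -= 1
                k[cur_pop[a]] += 1
            carried = cur_pop[a]
            del cur_pop[a], cur_pop[b]
            cur_pop[v] = carried
    if not math.isfinite(logf):
        return NEG, zero_stats
    return logf, st


def genealogy_log_likelihood(g: Genealogy, data: LocusData) -> float:
    """Infinite-sites log likelihood: Poisson mutations on branches, each
    observed site's derived-carrier set must match one branch's clade."""
    cl = g.clades()
    by_clade = {cl[v]: v for v in cl if v != g.root}
    logL = -g.total_length()
    for mask, count in data.carriers.items():
        v = by_clade.get(mask)
        if v is None:
            return float("-inf")
        blen = g.time[g.parent[v]] - g.time[v]
        if blen <= 0:
            return float("-inf")
        logL += count * math.log(blen)
    return logL


def is_compatible(g: Genealogy, data: LocusData):
    """Perfect-phylogeny embedding test.

    Returns the branch (node) assignment ``{carrier mask -> node}`` if every
    segregating site maps onto one branch, else ``None``.
    """
    cl = g.clades()
    by_clade = {cl[v]: v for v in cl if v != g.root}
    out = {}
    for mask in data.carriers:
        v = by_clade.get(mask)
        if v is None:
            return None
        out[mask] = v
    return out


# ===========================================================================
# focal-lineage resimulation move

@dataclass
class _Path:
    """A realized focal-lineage path: migration events, coalescence target
    (background lineage id), coalescence time, and the background-root
    lineage's migration events when attachment happens above it."""

    mig_events: list[tuple[float, int]]
    partner: int
    tau_c: float
    b_events: list[tuple[float, int]]


class _Background:
    """Piecewise-constant profile of the genealogy minus a detached subtree."""

    def __init__(self, g: Genealogy, x: int):
        self.g = g
        sub = g.subtree_nodes(x)
        p = g.parent[x]
        self.x = x
        self.detached_parent = p
        lineages: dict[int, tuple[float, float, list, int]] = {}
        sib = None
        if p is not None:
            ca, cb = g.children[p]
            sib = cb if ca == x else ca
        for v in range(2 * g.n - 1):
            if v in sub or v == p:
                continue
            if g.parent[v] is None and v != g.root:
                continue  # unused slot
            par = g.parent[v]
            base = g.base_pop(v)
            if v == g.root:
                lineages[v] = (g.time[v], math.inf, [], base)
            elif par == p:
                # v == sib; branch extends through the removed node
                if g.parent[p] is None:
                    lineages[v] = (g.time[v], math.inf, [], base)
                else:
                    evs = list(g.migs[v]) + list(g.migs[p])
                    lineages[v] = (g.time[v], g.time[g.parent[p]], evs, base)
            else:
                lineages[v] = (g.time[v], g.time[par], list(g.migs[v]), base)
        self.lineages = lineages
        self.sib = sib
        self.bg_root = max(lineages, key=lambda v: lineages[v][0])
        self.tau_root = lineages[self.bg_root][0]
        # change points: starts, ends, migration flips
        pts = set()
        for v, (a, b, evs, _) in lineages.items():
            pts.add(a)
            if math.isfinite(b):
                pts.add(b)
            for tm, _ in evs:
                pts.add(tm)
        self.change_points = sorted(pts)
        # precomputed state profile: _profile[i] is the active-lineage -> pop
        # map on [change_points[i], change_points[i+1])
        self._profile: list[dict[int, int]] = []
        for cp in self.change_points:
            out = {}
            for v, (a, b, evs, base) in lineages.items():
                if a <= cp < b:
                    pop = base
                    for tm, pa in evs:
                        if tm <= cp:
                            pop = pa
                        else:
                            break
                    out[v] = pop
            self._profile.append(out)

    def state_at(self, tau: float) -> dict[int, int]:
        """Active background lineages and their populations at time tau
        (tau treated as within the half-open interval [start, end))."""
        from bisect import bisect_right

        i = bisect_right(self.change_points, tau) - 1
        if i < 0:
            return {}
        return dict(self._profile[i])


def _focal_process(
    bg: _Background,
    tau0: float,
    pop0: int,
    p: IMParams,
    rng: Optional[np.random.Generator] = None,
    fixed: Optional[_Path] = None,
):
    """Simulate (rng) or evaluate (fixed) the focal lineage path.

    Returns ``(path, logq)``.  The process runs the focal lineage upward at
    migration rate m_c and coalescence rate 2/theta per same-population
    background lineage (2/theta_A toward everyone above the split); once
    only the background root lineage remains, that lineage migrates too.
    """
    theta = (p.theta1, p.theta2)
    mrate = (p.m1, p.m2)
    t_split = p.t
    tau = tau0
    c = pop0
    logq = 0.0
    mig_events: list[tuple[float, int]] = []
    b_events: list[tuple[float, int]] = []

    # pending scripted events in evaluation mode
    script: list[tuple[float, str, int]] = []
    if fixed is not None:
        for tm, pa in fixed.mig_events:
            script.append((tm, "mig_f", pa))
        for tm, pa in fixed.b_events:
            script.append((tm, "mig_b", pa))
        script.append((fixed.tau_c, "coal", fixed.partner))
        script.sort(key=lambda e: e[0])

    # background root lineage population trajectory (mutable in B-phase)
    b_pop_override: list[tuple[float, int]] = []

    def bg_state(tau_now: float) -> dict[int, int]:
        st = bg.state_at(tau_now)
        if bg.bg_root in st:
            pop = st[bg.bg_root]
            for tm, pa in b_events:
                if tm <= tau_now:
                    pop = pa
            st[bg.bg_root] = pop
        return st

    guard = 0
    while True:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("focal path simulation failed to terminate")
        st = bg_state(tau)
        in_b_phase = len(st) == 1 and bg.bg_root in st and tau >= bg.tau_root
        below = tau < t_split
        # rates
        coal_rates: dict[int, float] = {}
        if below:
            th = theta[c]
            for v, pop in st.items():
                if pop == c and th > 0:
                    coal_rates[v] = 2.0 / th
            lam_mig_f = mrate[c]
            lam_mig_b = mrate[st[bg.bg_root]] if in_b_phase else 0.0
        else:
            for v in st:
                coal_rates[v] = 2.0 / p.thetaA if p.thetaA > 0 else math.inf
            lam_mig_f = 0.0
            lam_mig_b = 0.0
        lam_tot = sum(coal_rates.values()) + lam_mig_f + lam_mig_b

        # next deterministic boundary
        nxt = math.inf
        for cp in bg.change_points:
            if cp > tau + 1e-15:
                nxt = cp
                break
        if below and t_split < nxt:
            nxt = t_split

        if fixed is not None:
            if not script:
                return None, float("-inf")
            tm, kind, arg = script[0]
            if tm <= nxt + 1e-15 and tm >= tau - 1e-12:
                # scripted event occurs in this interval
                logq -= lam_tot * (tm - tau)
                if kind == "coal":
                    rate = coal_rates.get(arg, 0.0)
                    if rate <= 0:
                        return None, float("-inf")
                    logq += math.log(rate)
                    return fixed, logq
                if kind == "mig_f":
                    if lam_mig_f <= 0:
                        return None, float("-inf")
                    logq += math.log(lam_mig_f)
                    c = arg
                else:
                    if lam_mig_b <= 0:
                        return None, float("-inf")
                    logq += math.log(lam_mig_b)
                    b_events.append((tm, arg))
                tau = tm
                script.pop(0)
                continue
            # no event before boundary
            if math.isinf(nxt):
                return None, float("-inf")
            logq -= lam_tot * (nxt - tau)
            tau = nxt
            continue

        # --- sampling mode ---
        delta = rng.exponential(1.0 / lam_tot) if lam_tot > 0 else math.inf
        if tau + delta < nxt:
            tau += delta
            logq -= lam_tot * delta
            u = rng.uniform(0, lam_tot)
            if u < lam_mig_f:
                logq += math.log(lam_mig_f)
                c = 1 - c
                mig_events.append((tau, c))
                continue
            u -= lam_mig_f
            if u < lam_mig_b:
                logq += math.log(lam_mig_b)
                newpop = 1 - st[bg.bg_root]
                b_events.append((tau, newpop))
                continue
            u -= lam_mig_b
            for v, rate in coal_rates.items():
                if u < rate:
                    logq += math.log(rate)
                    return _Path(mig_events, v, tau, b_events), logq
                u -= rate
            # numerical edge: attribute to the last target
            v = list(coal_rates)[-1]
            logq += math.log(coal_rates[v])
            return _Path(mig_events, v, tau, b_events), logq
        if math.isinf(nxt):
            raise RuntimeError("no boundary and zero total rate")
        logq -= lam_tot * (nxt - tau)
        tau = nxt


def _extract_old_path(g: Genealogy, x: int) -> _Path:
    p = g.parent[x]
    ca, cb = g.children[p]
    sib = cb if ca == x else ca
    p_is_root = g.parent[p] is None
    b_events = list(g.migs[sib]) if p_is_root else []
    return _Path(list(g.migs[x]), sib, g.time[p], b_events)


def _apply_path(g: Genealogy, x: int, path: _Path) -> None:
    """Detach subtree x in place and re-attach along the given path."""
    p = g.parent[x]
    ca, cb = g.children[p]
    sib = cb if ca == x else ca
    pp = g.parent[p]
    if pp is None:
        g.parent[sib] = None
        g.migs[sib] = []
        g.root = sib
    else:
        g.parent[sib] = pp
        a, b = g.children[pp]
        g.children[pp] = (sib if a == p else a, sib if b == p else b)
        g.migs[sib] = g.migs[sib] + g.migs[p]
    g.parent[p] = None
    g.children[p] = None
    g.migs[p] = []
    g.migs[x] = []

    # re-attach at path.tau_c on lineage path.partner, reusing node p
    j = path.partner
    tau_c = path.tau_c
    jp = g.parent[j]
    g.time[p] = tau_c
    g.children[p] = (x, j)
    if j == g.root:
        # partner is the background root lineage: p becomes the new root;
        # simulated events for that lineage go on j's new branch
        g.parent[j] = p
        g.parent[x] = p
        g.parent[p] = None
        g.migs[j] = sorted(path.b_events)
        g.root = p
    else:
        below = [e for e in g.migs[j] if e[0] < tau_c]
        above = [e for e in g.migs[j] if e[0] >= tau_c]
        g.parent[p] = jp
        a, b = g.children[jp]
        g.children[jp] = (p if a == j else a, p if b == j else b)
        g.parent[j] = p
        g.parent[x] = p
        g.migs[j] = below
        g.migs[p] = above
    g.migs[x] = sorted(path.mig_events)


# ===========================================================================
# posterior container and histogram summaries

@dataclass
class IMPosterior:
    """Marginal posterior histograms and summaries for the six parameters."""

    priors: IMParams
    bins: int
    counts: dict[str, np.ndarray]
    midpoints: dict[str, np.ndarray]
    summaries: dict[str, dict[str, float]]
    ess: dict[str, float]
    acceptance: dict[str, float]
    trend: dict[str, np.ndarray]
    recorded_steps: int
    seed: Optional[int] = None
    traces: Optional[dict[str, np.ndarray]] = None
    tmrca_trace: Optional[np.ndarray] = None


def summarize_histogram(
    counts: np.ndarray, midpoints: np.ndarray, smooth_window: int = 9
) -> dict[str, float]:
    """IM-style marginal-histogram summaries.

    HiPt: midpoint of the highest-count bin.  HiSmth: same after a centered
    running average of ``smooth_window`` bins (window shrinks symmetrically
    at the edges).  95Lo/95Hi: points with 2.5% of mass to the left/right.
    HPD90Lo/Hi: shortest contiguous interval holding >= 90% of the mass.
    Ties break toward the lowest bin index.
    """
    counts = np.asarray(counts, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    nb = len(counts)
    if nb == 0:
        raise ValueError("empty histogram")
    if nb < smooth_window:
        raise ValueError("need at least smooth_window bins")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    half = smooth_window // 2
    smoothed = np.empty(nb)
    for i in range(nb):
        h = min(half, i, nb - 1 - i)
        smoothed[i] = counts[i - h : i + h + 1].mean()
    hipt = midpoints[int(np.argmax(counts))]
    # ties in the smoothed maximum (e.g. the flat plateau a running average
    # makes of a spike): prefer the highest raw count, then the lowest index
    tied = np.flatnonzero(smoothed == smoothed.max())
    hismth = midpoints[int(tied[np.argmax(counts[tied])])]
    cum = np.cumsum(counts) / total
    lo95 = midpoints[int(np.searchsorted(cum, 0.025))]
    hi95 = midpoints[min(nb - 1, int(np.searchsorted(cum, 0.975)))]
    # shortest contiguous >=90% interval (two-pointer on prefix sums)
    prefix = np.concatenate([[0.0], np.cumsum(counts)])
    target = 0.9 * total
    best = (nb, 0, nb - 1)
    j = 0
    for i in range(nb):
        if j < i:
            j = i
        while j < nb and prefix[j + 1] - prefix[i] < target:
            j += 1
        if j >= nb:
            break
        width = j - i
        if width < best[0]:
            best = (width, i, j)
    _, lo_i, hi_i = best
    return {
        "Minbin": float(midpoints[0]),
        "Maxbin": float(midpoints[-1]),
        "HiPt": float(hipt),
        "HiSmth": float(hismth),
        "95Lo": float(lo95),
        "95Hi": float(hi95),
        "HPD90Lo": float(midpoints[lo_i]),
        "HPD90Hi": float(midpoints[hi_i]),
    }


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, min(n // 2, 2000)):
        if acf[k] + (acf[k + 1] if k + 1 < n else 0) < 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


# ===========================================================================
# truncated-gamma Gibbs helpers

def _sample_theta_conditional(
    C: int, W: float, upper: float, cur: float, rng: np.random.Generator
) -> float:
    """Sample theta from pi(theta) ~ theta^-C exp(-W/theta) on (0, upper]."""
    if W <= 0 and C == 0:
        return rng.uniform(0, upper)
    if C >= 2 and W > 0:
        # x = 1/theta ~ Gamma(C-1, rate W) truncated to x >= 1/upper
        a = C - 1
        s_lo = float(sp_special.gammaincc(a, W / upper))
        if s_lo <= 0:
            return upper
        x = float(sp_special.gammainccinv(a, rng.uniform(0, 1) * s_lo)) / W
        return min(upper, 1.0 / max(x, 1e-300))
    # fallback: a few MH steps on the conditional
    th = cur if 0 < cur <= upper else upper / 2
    logp = lambda v: -C * math.log(v) - W / v  # noqa: E731
    for _ in range(8):
        prop = th * math.exp(rng.normal(0, 0.5))
        if 0 < prop <= upper:
            if math.log(rng.uniform()) < logp(prop) - logp(th) + math.log(prop / th):
                th = prop
    return th


def _sample_m_conditional(
    M: int, R: float, upper: float, rng: np.random.Generator
) -> float:
    """Sample m from pi(m) ~ m^M exp(-m R) on [0, upper] (truncated gamma)."""
    if R <= 0:
        return rng.uniform(0, upper)
    a = M + 1
    c_hi = float(sp_special.gammainc(a, R * upper))
    if c_hi <= 0:
        return 0.0
    m = float(sp_special.gammaincinv(a, rng.uniform(0, 1) * c_hi)) / R
    return min(upper, m)


# ===========================================================================
# the sampler

def suggest_priors(loci_data: Sequence[LocusData]) -> IMParams:
    """Heuristic prior upper bounds from observed diversity.

    Theta uppers are a multiple of the mean per-locus Watterson estimate
    (total mutations / a1); the split-time upper is a multiple of half the
    mean between-population divergence; migration uppers default to a broad
    range scaled inversely with diversity.
    """
    th_hat = []
    cross = []
    for d in loci_data:
        n = d.n
        th_hat.append(d.n_mutations / harmonic(n))
        pop0_mask = 0
        for i, pop in enumerate(d.pops):
            if pop == 0:
                pop0_mask |= 1 << i
        n1 = bin(pop0_mask).count("1")
        n2 = n - n1
        # mean between-population pairwise divergence in mutation counts
        diffs = 0.0
        for mask, cnt in d.carriers.items():
            in1 = bin(mask & pop0_mask).count("1")
            in2 = bin(mask).count("1") - in1
            diffs += cnt * (in1 * (n2 - in2) + in2 * (n1 - in1)) / (n1 * n2)
        cross.append(diffs)
    th = max(float(np.mean(th_hat)), 0.5)
    tx = max(float(np.mean(cross)) / 2.0, 0.5)
    m_up = min(10.0, max(0.5, 10.0 / th))
    return IMParams(
        theta1=5 * th, theta2=5 * th, thetaA=5 * th, t=4 * tx, m1=m_up, m2=m_up
    )


class _LocusChain:
    """Per-locus genealogy state with cached prior/likelihood."""

    def __init__(self, data: LocusData, params: IMParams, dt: float):
        self.data = data
        self.g = build_initial_genealogy(data, params.t, dt)
        self.logf, self.stats = genealogy_log_prior(self.g, params)
        self.logL = genealogy_log_likelihood(self.g, self.data)
        if not math.isfinite(self.logf) or not math.isfinite(self.logL):
            raise RuntimeError(f"invalid initial state for locus {data.name}")

    def refresh(self, params: IMParams) -> None:
        self.logf, self.stats = genealogy_log_prior(self.g, params)

    def focal_update(self, params: IMParams, rng: np.random.Generator) -> bool:
        g = self.g
        nodes = [v for v in range(2 * g.n - 1) if g.parent[v] is not None]
        x = nodes[rng.integers(len(nodes))]
        old_path = _extract_old_path(g, x)
        bg = _Background(g, x)
        x_pop = g.base_pop(x)
        new_path, logq_fwd = _focal_process(
            bg, g.time[x], x_pop, params, rng=rng
        )
        _, logq_rev = _focal_process(
            bg, g.time[x], x_pop, params, fixed=old_path
        )
        if not math.isfinite(logq_rev):
            # the reverse path has zero density under current parameters;
            # accepting would break reversibility, so reject
            return False
        g2 = g.clone()
        _apply_path(g2, x, new_path)
        logf2, stats2 = genealogy_log_prior(g2, params)
        if not math.isfinite(logf2):
            return False
        logL2 = genealogy_log_likelihood(g2, self.data)
        if not math.isfinite(logL2):
            return False
        delta = (logf2 + logL2 + logq_rev) - (self.logf + self.logL + logq_fwd)
        if delta >= 0 or math.log(rng.uniform()) < delta:
            self.g = g2
            self.logf, self.stats, self.logL = logf2, stats2, logL2
            return True
        return False


def im_mcmc(
    loci: Sequence[AlignedLocus] | Sequence[LocusData],
    priors: IMParams,
    burn_in: int = 1000,
    steps: int = 10_000,
    seed: Optional[int] = None,
    bins: int = 1000,
    moves_per_locus: Optional[int] = None,
    pop_labels: Sequence[str] | None = None,
    ancestral: str = "A",
    update_params: bool = True,
    use_rescale_move: bool = True,
    init_params: Optional[IMParams] = None,
    track_tmrca: bool = False,
    smooth_window: int = 9,
    ess_warn: float = 50.0,
) -> IMPosterior:
    """Run the IM Markov chain and return marginal posterior histograms.

    ``burn_in`` and ``steps`` count sweeps; one sweep performs
    ``moves_per_locus`` genealogy updates per locus followed by parameter
    updates.  ``priors`` holds the uniform prior upper bounds.  The
    defaults here are desk-scale; production analyses need far longer
    chains (the kind of run lengths used for published datasets are
    configuration values, not defaults).
    """
    for name in PARAM_NAMES:
        if getattr(priors, name) <= 0:
            raise ValueError(f"prior upper bound for {name} must be > 0")
    rng = np.random.default_rng(seed)
    data = [
        d if isinstance(d, LocusData) else prepare_locus(d, pop_labels, ancestral)
        for d in loci
    ]
    if not data:
        raise ValueError("need at least one locus")

    if init_params is None:
        th0 = min(0.5 * priors.theta1, max(0.2, float(np.mean(
            [d.n_mutations / harmonic(d.n) for d in data]
        ))))
        params = IMParams(
            theta1=th0,
            theta2=min(th0, 0.5 * priors.theta2),
            thetaA=min(0.5 * th0, 0.5 * priors.thetaA),
            t=min(0.25 * priors.t, priors.t),
            m1=0.05 * priors.m1,
            m2=0.05 * priors.m2,
        )
    else:
        params = init_params
    dt = max(params.thetaA, 0.1) / (2 * max(d.n for d in data))
    chains = [_LocusChain(d, params, dt) for d in data]
    if moves_per_locus is None:
        moves_per_locus = max(4, max(d.n for d in data))

    uppers = priors.as_tuple()
    counts = {k: np.zeros(bins) for k in PARAM_NAMES}
    edges = {
        k: np.linspace(0, uppers[i], bins + 1) for i, k in enumerate(PARAM_NAMES)
    }
    mids = {k: 0.5 * (edges[k][:-1] + edges[k][1:]) for k in PARAM_NAMES}
    trace_len = min(steps, 5000)
    trace_thin = max(1, steps // trace_len)
    traces = {k: [] for k in PARAM_NAMES}
    tmrca: list[float] = []
    acc = {"genealogy": 0, "t": 0, "rescale": 0}
    att = {"genealogy": 0, "t": 0, "rescale": 0}
    sigma_t = 0.1 * priors.t
    sigma_s = 0.15
    logpost_trend: list[float] = []

    def t_update(params: IMParams, bold: bool = False) -> IMParams:
        att["t"] += 1
        span = priors.t
        if bold:
            # independence proposal from the uniform prior: jumps between
            # posterior modes the random walk cannot cross
            t_new = rng.uniform(0, span)
        else:
            t_new = abs(params.t + rng.normal(0, sigma_t))
            if t_new > span:
                t_new = 2 * span - t_new
        if not (0 <= t_new <= span):
            return params
        cand = IMParams(**{**_asdict(params), "t": t_new})
        new_logfs = []
        tot_new = 0.0
        for ch in chains:
            lf, st = genealogy_log_prior(ch.g, cand)
            if not math.isfinite(lf):
                return params
            new_logfs.append((lf, st))
            tot_new += lf
        tot_old = sum(ch.logf for ch in chains)
        if math.log(rng.uniform()) < tot_new - tot_old:
            for ch, (lf, st) in zip(chains, new_logfs):
                ch.logf, ch.stats = lf, st
            acc["t"] += 1
            return cand
        return params

    def rescale_update(params: IMParams) -> IMParams:
        """Scale the split time and every genealogy time by a common factor
        (lognormal proposal); Jacobian s^(K+1) with K scaled coordinates."""
        att["rescale"] += 1
        # occasional bold factors help cross between time-scale regimes
        s = math.exp(rng.normal(0, sigma_s if rng.uniform() < 0.8 else 4 * sigma_s))
        t_new = params.t * s
        if not (0 < t_new <= priors.t):
            return params
        cand = IMParams(**{**_asdict(params), "t": t_new})
        K = 0
        new_states = []
        tot_new = tot_old = 0.0
        for ch in chains:
            g2 = ch.g.clone()
            for v in range(2 * g2.n - 1):
                g2.time[v] *= s
                if g2.migs[v]:
                    g2.migs[v] = [(tm * s, pa) for tm, pa in g2.migs[v]]
                    K += len(g2.migs[v])
            K += g2.n - 1  # internal node times
            lf, st = genealogy_log_prior(g2, cand)
            if not math.isfinite(lf):
                return params
            lL = genealogy_log_likelihood(g2, ch.data)
            if not math.isfinite(lL):
                return params
            new_states.append((g2, lf, st, lL))
            tot_new += lf + lL
            tot_old += ch.logf + ch.logL
        delta = tot_new - tot_old + (K + 1) * math.log(s)
        if delta >= 0 or math.log(rng.uniform()) < delta:
            for ch, (g2, lf, st, lL) in zip(chains, new_states):
                ch.g, ch.logf, ch.stats, ch.logL = g2, lf, st, lL
            acc["rescale"] += 1
            return cand
        return params

    def param_update(params: IMParams) -> IMParams:
        agg = {k: 0.0 for k in ("C1", "C2", "CA", "W1", "W2", "WA",
                                 "M1", "M2", "R1", "R2")}
        for ch in chains:
            for k in agg:
                agg[k] += ch.stats[k]
        # conditional density in theta is theta^-C exp(-W/theta) with
        # W = integral of k(k-1) over population-i intervals
        th1 = _sample_theta_conditional(int(agg["C1"]), agg["W1"], uppers[0], params.theta1, rng)
        th2 = _sample_theta_conditional(int(agg["C2"]), agg["W2"], uppers[1], params.theta2, rng)
        thA = _sample_theta_conditional(int(agg["CA"]), agg["WA"], uppers[2], params.thetaA, rng)
        m1 = _sample_m_conditional(int(agg["M1"]), agg["R1"], uppers[4], rng)
        m2 = _sample_m_conditional(int(agg["M2"]), agg["R2"], uppers[5], rng)
        cand = IMParams(theta1=th1, theta2=th2, thetaA=thA, t=params.t, m1=m1, m2=m2)
        for ch in chains:
            ch.refresh(cand)
            if not math.isfinite(ch.logf):  # cannot happen: support unchanged
                raise RuntimeError("parameter Gibbs produced invalid state")
        return cand

    total_sweeps = burn_in + steps
    adapt_interval = max(50, burn_in // 10)
    recent_t_acc = [0, 0]
    for sweep in range(total_sweeps):
        for ch in chains:
            for _ in range(moves_per_locus):
                att["genealogy"] += 1
                if ch.focal_update(params, rng):
                    acc["genealogy"] += 1
        if update_params:
            params = param_update(params)
            before = att["t"], acc["t"]
            for _ in range(3):  # the split time mixes slowest; update harder
                params = t_update(params)
            params = t_update(params, bold=True)
            if use_rescale_move:
                params = rescale_update(params)
            recent_t_acc[0] += att["t"] - before[0]
            recent_t_acc[1] += acc["t"] - before[1]
            if sweep < burn_in and (sweep + 1) % adapt_interval == 0:
                rate = recent_t_acc[1] / max(1, recent_t_acc[0])
                if rate < 0.15:
                    sigma_t *= 0.7
                elif rate > 0.45:
                    sigma_t *= 1.4
                recent_t_acc = [0, 0]
        if sweep >= burn_in:
            vals = params.as_tuple()
            for i, k in enumerate(PARAM_NAMES):
                idx = min(bins - 1, int(vals[i] / uppers[i] * bins))
                counts[k][idx] += 1
                if (sweep - burn_in) % trace_thin == 0:
                    traces[k].append(vals[i])
            if track_tmrca:
                tmrca.append(chains[0].g.height())
            logpost_trend.append(
                sum(ch.logf + ch.logL for ch in chains)
            )

    summaries = {
        k: summarize_histogram(counts[k], mids[k], smooth_window)
        for k in PARAM_NAMES
    }
    ess = {k: effective_sample_size(np.asarray(traces[k])) for k in PARAM_NAMES}
    acc_rates = {
        k: acc[k] / att[k] if att[k] else float("nan") for k in acc
    }
    low = [k for k, v in ess.items() if v < ess_warn]
    if low and update_params:
        import warnings

        warnings.warn(
            f"low effective sample size for {low}; chain may not have mixed",
            RuntimeWarning,
            stacklevel=2,
        )
    trend_chunks = np.array_split(np.asarray(logpost_trend), 10) if logpost_trend else []
    return IMPosterior(
        priors=priors,
        bins=bins,
        counts=counts,
        midpoints=mids,
        summaries=summaries,
        ess=ess,
        acceptance=acc_rates,
        trend={"logposterior": np.asarray([c.mean() for c in trend_chunks if len(c)])},
        recorded_steps=steps,
        seed=seed,
        traces={k: np.asarray(v) for k, v in traces.items()},
        tmrca_trace=np.asarray(tmrca) if track_tmrca else None,
    )


def _asdict(p: IMParams) -> dict:
    return {k: getattr(p, k) for k in PARAM_NAMES}


def convergence_report(
    runs: Sequence[IMPosterior], spread_fraction: float = 0.5
) -> dict:
    """Across-run consistency report.

    For each parameter: spread (max - min) of HiSmth across runs, mean
    HPD90 width, min ESS; a parameter is flagged when the spread exceeds
    ``spread_fraction`` of the mean HPD90 width.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    report: dict[str, dict] = {"parameters": {}, "flags": []}
    for k in PARAM_NAMES:
        his = [r.summaries[k]["HiSmth"] for r in runs]
        widths = [
            r.summaries[k]["HPD90Hi"] - r.summaries[k]["HPD90Lo"] for r in runs
        ]
        spread = max(his) - min(his)
        mean_w = float(np.mean(widths))
        flagged = bool(mean_w > 0 and spread > spread_fraction * mean_w)
        disjoint = max(r.summaries[k]["HPD90Lo"] for r in runs) > min(
            r.summaries[k]["HPD90Hi"] for r in runs
        )
        if disjoint:
            flagged = True
        report["parameters"][k] = {
            "HiSmth_spread": spread,
            "mean_HPD90_width": mean_w,
            "min_ESS": min(r.ess[k] for r in runs),
            "flagged": flagged,
        }
        if flagged:
            report["flags"].append(k)
    report["acceptance"] = {
        k: [r.acceptance.get(k) for r in runs] for k in runs[0].acceptance
    }
    return report
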