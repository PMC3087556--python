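"""Intra-locus recombination detection and non-recombining (NR) block
extraction.

The four-gamete test flags a pair of biallelic sites showing all four
haplotypes, which under infinite sites implies at least one recombination
event between them.  RM is the Hudson--Kaplan lower bound on the number of
recombination events: the maximum number of non-overlapping incompatible
intervals after discarding any interval that contains another.

NR-block extraction searches contiguous blocks combined with removal of
recombinant-like haplotypes, maximizing ``retained^weight * length``
subject to the block being four-gamete clean among retained haplotypes —
the concept used by recombination-filtering preprocessors for IM analyses.
Their exact tie-breaking is not public, so this implementation fixes its
own deterministic rules (documented on :func:`extract_nr_block`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .alignment import AlignedLocus, SiteMask, build_site_mask

MISSING = frozenset("-N")


@dataclass(frozen=True)
class IncompatiblePairSet:
    """Site pairs (1-based, i < j) failing the four-gamete test."""

    pairs: tuple[tuple[int, int], ...]

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NRBlockResult:
    start: int
    end: int
    removed_ids: tuple[str, ...]
    score: float
    retained_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------

def _biallelic_columns(locus: AlignedLocus, mask: SiteMask | None, ids=None):
    """(site_position, per-haplotype allele string) for biallelic sites."""
    if mask is None:
        mask = build_site_mask(locus, policy="none")
    haps = locus.haplotypes if ids is None else tuple(
        h for h in locus.haplotypes if h.id in set(ids)
    )
    cols = []
    for pos in mask.included:
        col = "".join(h.sequence[pos - 1] for h in haps)
        alleles = set(col) - MISSING
        if len(alleles) == 2:
            cols.append((pos, col))
    return cols, tuple(h.id for h in haps)


def _four_gametes(col_i: str, col_j: str) -> bool:
    gametes = {
        (a, b)
        for a, b in zip(col_i, col_j)
        if a not in MISSING and b not in MISSING
    }
    return len(gametes) == 4


def four_gamete_pairs(
    locus: AlignedLocus,
    mask: SiteMask | None = None,
    ids: Optional[Sequence[str]] = None,
) -> IncompatiblePairSet:
    """All site pairs (1-based positions) exhibiting four gametes."""
    cols, _ = _biallelic_columns(locus, mask, ids)
    pairs = [
        (pi, pj)
        for (pi, ci), (pj, cj) in combinations(cols, 2)
        if _four_gametes(ci, cj)
    ]
    return IncompatiblePairSet(pairs=tuple(sorted(pairs)))


def rm_hudson_kaplan(pairs: IncompatiblePairSet | Sequence[tuple[int, int]]) -> int:
    """Hudson--Kaplan minimum number of recombination events.

    Interval reduction: drop any pair whose open interval contains another
    pair's interval, then greedily count non-overlapping intervals
    left-to-right (intervals may share an endpoint).
    """
    raw = list(pairs.pairs if isinstance(pairs, IncompatiblePairSet) else pairs)
    if not raw:
        return 0
    intervals = sorted(set(raw), key=lambda ij: (ij[1], -ij[0]))
    # keep only intervals not containing another interval
    kept = []
    for i, j in intervals:
        if not any(a >= i and b <= j and (a, b) != (i, j) for a, b in intervals):
            kept.append((i, j))
    kept.sort(key=lambda ij: ij[1])
    rm = 0
    last_end = -1
    for i, j in kept:
        if i >= last_end:
            rm += 1
            last_end = j
    return rm


def rm_for_locus(locus: AlignedLocus, mask: SiteMask | None = None) -> int:
    """Convenience: RM computed on the full (pooled) haplotype sample."""
    return rm_hudson_kaplan(four_gamete_pairs(locus, mask))


# ---------------------------------------------------------------------------
# NR-block extraction

def _conflicts_for(cols, hap_ids: Sequence[str], retained: set[str]):
    """Four-gamete pairs among retained haplotypes, as site-index pairs."""
    keep_idx = [k for k, hid in enumerate(hap_ids) if hid in retained]
    sub = []
    for pos, col in cols:
        c = "".join(col[k] for k in keep_idx)
        alleles = set(c) - MISSING
        if len(alleles) == 2:
            sub.append((pos, c))
    return [
        (pi, pj)
        for (pi, ci), (pj, cj) in combinations(sub, 2)
        if _four_gametes(ci, cj)
    ]


def _first_conflict(cols, hap_ids, retained):
    """First four-gamete-violating site pair among retained haplotypes,
    with its gamete-class membership, or None."""
    keep_idx = [k for k, hid in enumerate(hap_ids) if hid in retained]
    sub = []
    for pos, col in cols:
        c = [col[k] for k in keep_idx]
        alleles = set(c) - MISSING
        if len(alleles) == 2:
            sub.append((pos, c))
    kept_ids = [hap_ids[k] for k in keep_idx]
    for (pi, ci), (pj, cj) in combinations(sub, 2):
        classes: dict[tuple[str, str], list[str]] = {}
        for hid, a, b in zip(kept_ids, ci, cj):
            if a not in MISSING and b not in MISSING:
                classes.setdefault((a, b), []).append(hid)
        if len(classes) == 4:
            return classes
    return None


def _min_removal_set(cols, hap_ids, retained, cap, budget):
    """Smallest haplotype set whose removal makes the block four-gamete
    clean, found by branching on the gamete classes of the first conflict.
    Returns (best frozenset or None, remaining budget); None also when the
    node budget is exhausted (caller falls back to greedy)."""
    budget -= 1
    if budget <= 0:
        return None, 0
    classes = _first_conflict(cols, hap_ids, retained)
    if classes is None:
        return frozenset(), budget
    best = None
    # to resolve this pair some gamete class must vanish entirely
    for key in sorted(classes):
        members = classes[key]
        if len(members) > cap or len(members) >= len(retained) - 1:
            continue
        sub, budget = _min_removal_set(
            cols, hap_ids, retained - set(members), cap - len(members), budget
        )
        if budget <= 0:
            return None, 0
        if sub is not None:
            cand = frozenset(members) | sub
            if best is None or (len(cand), tuple(sorted(cand))) < (
                len(best),
                tuple(sorted(best)),
            ):
                best = cand
                cap = len(best) - 1  # only look for strictly better solutions
                if cap < 0:
                    break
    return best, budget


def _greedy_clean(cols, hap_ids, min_retain: int = 2):
    """Remove the haplotype participating in the most conflicts (carrying a
    rarest gamete), ties by conflicts resolved then smallest id, until the
    four-gamete test passes; returns (removed ids, retained count)."""
    retained = set(hap_ids)
    removed: list[str] = []
    while True:
        conflicts_classes = []
        keep_idx = [k for k, hid in enumerate(hap_ids) if hid in retained]
        kept_ids = [hap_ids[k] for k in keep_idx]
        sub = []
        for pos, col in cols:
            c = [col[k] for k in keep_idx]
            if len(set(c) - MISSING) == 2:
                sub.append((pos, c))
        for (pi, ci), (pj, cj) in combinations(sub, 2):
            classes: dict[tuple[str, str], list[str]] = {}
            for hid, a, b in zip(kept_ids, ci, cj):
                if a not in MISSING and b not in MISSING:
                    classes.setdefault((a, b), []).append(hid)
            if len(classes) == 4:
                conflicts_classes.append(classes)
        if not conflicts_classes:
            return tuple(removed), len(retained)
        if len(retained) <= min_retain:
            return tuple(removed), len(retained)
        participation: dict[str, int] = {h: 0 for h in retained}
        for classes in conflicts_classes:
            mn = min(len(v) for v in classes.values())
            for members in classes.values():
                if len(members) == mn:
                    for h in members:
                        participation[h] += 1
        top = max(participation.values())
        tied = sorted(h for h, c in participation.items() if c == top)
        if len(tied) > 1:
            resolved = {}
            for h in tied:
                trial = retained - {h}
                resolved[h] = len(conflicts_classes) - len(
                    _conflicts_for(cols, hap_ids, trial)
                )
            top_r = max(resolved.values())
            tied = sorted(h for h, r in resolved.items() if r == top_r)
        victim = tied[0]
        retained.discard(victim)
        removed.append(victim)


def _clean_block(cols, hap_ids, budget: int = 4000):
    """Best removal set for one candidate block: exact search within the
    node budget, greedy fallback otherwise."""
    retained = frozenset(hap_ids)
    greedy_removed, greedy_retained = _greedy_clean(cols, hap_ids)
    cap = max(len(greedy_removed), 0)
    exact, _ = _min_removal_set(cols, hap_ids, set(retained), cap, budget)
    if exact is not None and len(exact) <= len(greedy_removed):
        return tuple(sorted(exact)), len(hap_ids) - len(exact)
    return greedy_removed, greedy_retained


def extract_nr_block(
    locus: AlignedLocus,
    weight: float = 1.0,
    mask: SiteMask | None = None,
    exhaustive: bool = False,
) -> NRBlockResult:
    """Optimal recombination-free block with recombinant-haplotype removal.

    Maximizes ``retained_count**weight * block_length`` over contiguous
    blocks [s, e] (1-based inclusive) and haplotype subsets whose restricted
    alignment passes the four-gamete test.  Candidate block boundaries are
    expanded to the nearest flanking segregating sites (intervening
    monomorphic sites can never create a conflict).  Removal search is
    greedy (most conflicts resolved, then lexicographically smallest id);
    ``exhaustive=True`` scans every removal subset (small inputs only).
    Ties between blocks break toward longer, then leftmost blocks.
    """
    if mask is None:
        mask = build_site_mask(locus, policy="none")
    cols, hap_ids = _biallelic_columns(locus, mask, None)
    L = locus.length
    n = locus.n
    if not cols:
        return NRBlockResult(1, L, (), n**weight * L, n)
    positions = [pos for pos, _ in cols]
    k = len(positions)

    # candidate blocks: spans of consecutive segregating sites, extended to
    # the flanking monomorphic runs
    candidates = []
    for a in range(k):
        for b in range(a - 1, k):  # b == a-1 encodes "no segregating site"
            start = 1 if a == 0 else positions[a - 1] + 1
            if b < a:
                end = positions[a] - 1
                if end < start:
                    continue
                seg = []
            else:
                end = L if b == k - 1 else positions[b + 1] - 1
                seg = cols[a : b + 1]
            candidates.append((start, end, seg))
    # also the fully monomorphic tail after the last segregating site
    best: Optional[NRBlockResult] = None

    def consider(start, end, removed, retained):
        nonlocal best
        length = end - start + 1
        score = retained**weight * length
        cand = NRBlockResult(start, end, tuple(sorted(removed)), score, retained)
        if best is None:
            best = cand
            return
        key = (cand.score, cand.length, -cand.start)
        cur = (best.score, best.length, -best.start)
        if key > cur:
            best = cand

    # prune: upper bound on score is n^weight * length
    candidates.sort(key=lambda c: -(c[1] - c[0] + 1))
    for start, end, seg in candidates:
        length = end - start + 1
        if best is not None and n**weight * length <= best.score:
            # no candidate this short can beat the incumbent; candidates are
            # sorted by length so everything after is no better
            break
        if not seg:
            consider(start, end, (), n)
            continue
        if exhaustive:
            from itertools import combinations as comb

            found = False
            for r in range(0, n - 1):
                for rem in comb(sorted(hap_ids), r):
                    retained = set(hap_ids) - set(rem)
                    if not _conflicts_for(seg, hap_ids, retained):
                        consider(start, end, rem, len(retained))
                        found = True
                if found:
                    break
        else:
            removed, retained = _clean_block(seg, hap_ids)
            if retained >= 2:
                consider(start, end, removed, retained)
    if best is None:  # pathological: single-site fallback
        best = NRBlockResult(1, 1, (), float(n**weight), n)
    return best


def apply_nr_block(locus: AlignedLocus, result: NRBlockResult) -> AlignedLocus:
    """Materialize an NR block: slice the block and drop removed haplotypes."""
    from .alignment import slice_block

    out = slice_block(locus, result.start, result.end)
    if result.removed_ids:
        out = out.drop(result.removed_ids)
    return out
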