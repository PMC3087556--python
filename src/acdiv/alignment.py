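"""Reading, validating and preprocessing per-locus haplotype alignments.

Input data are pre-aligned FASTA files of phased haplotypes, two per diploid
individual, labelled by population.  Sequences from individuals observed as
homozygous are duplicated before analysis so that every individual
contributes exactly two haplotypes (the convention used by the original
survey this pipeline reproduces).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGT-N")
#: characters treated as missing for site-masking purposes
MISSING_CHARS = frozenset("-N")

#: default id-prefix -> population mapping ("Flo" = Florianópolis,
#: "Bah" = Itaparica, Bahia)
DEFAULT_POPULATION_RULE: Mapping[str, str] = {
    "Flo": "Florianopolis",
    "Bah": "Itaparica",
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, bad characters)."""


class LabelingError(ValueError):
    """Raised when a sequence id cannot be assigned to a population."""


class PloidyError(ValueError):
    """Raised when an individual contributes more than two haplotypes."""


@dataclass(frozen=True)
class Haplotype:
    """One aligned haplotype: id, population label and gapped sequence."""

    id: str
    population: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlignmentError(f"haplotype {self.id!r} has empty sequence")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"haplotype {self.id!r} contains invalid characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class AlignedLocus:
    """A gap-aware multiple alignment of population-labelled haplotypes.

    Coordinates are 1-based and inclusive throughout.
    """

    name: str
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise AlignmentError(f"locus {self.name!r} needs >=2 haplotypes")
        lengths = {len(h.sequence) for h in self.haplotypes}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.name!r}: unequal sequence lengths {sorted(lengths)}"
            )
        ids = [h.id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"locus {self.name!r}: duplicate haplotype ids")

    @property
    def length(self) -> int:
        return len(self.haplotypes[0].sequence)

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.haplotypes:
            seen.setdefault(h.population, None)
        return tuple(seen)

    def population_sample(self, population: str) -> tuple[Haplotype, ...]:
        sub = tuple(h for h in self.haplotypes if h.population == population)
        if not sub:
            raise KeyError(f"no haplotypes labelled {population!r} in {self.name!r}")
        return sub

    def subset(self, ids: Iterable[str]) -> "AlignedLocus":
        keep = set(ids)
        return replace(
            self, haplotypes=tuple(h for h in self.haplotypes if h.id in keep)
        )

    def drop(self, ids: Iterable[str]) -> "AlignedLocus":
        bad = set(ids)
        return replace(
            self, haplotypes=tuple(h for h in self.haplotypes if h.id not in bad)
        )


@dataclass(frozen=True)
class SiteMask:
    """Ordered 1-based site indices retained for analysis."""

    included: tuple[int, ...]
    policy: str = "complete-deletion"

    def __post_init__(self) -> None:
        idx = self.included
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("mask indices must be strictly increasing")
        if idx and idx[0] < 1:
            raise ValueError("mask indices are 1-based")

    def __len__(self) -> int:
        return len(self.included)

    def apply(self, sequence: str) -> str:
        return "".join(sequence[i - 1] for i in self.included)


def read_alignment(
    path,
    name: str | None = None,
    population_rule: Mapping[str, str] | None = None,
) -> AlignedLocus:
    """Read an aligned FASTA file into an :class:`AlignedLocus`.

    ``population_rule`` maps id prefixes (treated as regex anchored at the
    start of the id) to population labels; the default recognises the
    "Flo"/"Bah" convention.
    """
    rule = dict(population_rule or DEFAULT_POPULATION_RULE)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    haps = []
    for rec in records:
        seq = str(rec.seq).upper()
        pop = _assign_population(rec.id, rule)
        haps.append(Haplotype(id=rec.id, population=pop, sequence=seq))
    locus_name = name if name is not None else _stem(path)
    return AlignedLocus(name=locus_name, haplotypes=tuple(haps))


def write_alignment(locus: AlignedLocus, path) -> None:
    """Write an alignment as FASTA, wrapped at 60 columns, ids verbatim."""
    records = [
        SeqRecord(Seq(h.sequence), id=h.id, description="")
        for h in locus.haplotypes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


def _assign_population(seq_id: str, rule: Mapping[str, str]) -> str:
    for pattern, pop in rule.items():
        if re.match(pattern, seq_id):
            return pop
    raise LabelingError(
        f"id {seq_id!r} matches no population prefix in {sorted(rule)!r}"
    )


def duplicate_homozygotes(
    individual_haplotypes: Mapping[str, Sequence[Haplotype]],
) -> tuple[Haplotype, ...]:
    """Expand per-individual haplotype sets so everyone contributes two.

    Individuals observed with a single (homozygous) sequence have it
    duplicated under "a"/"b" suffixes; heterozygotes pass through unchanged.
    Idempotent on already-diploid input.
    """
    out: list[Haplotype] = []
    for indiv, haps in individual_haplotypes.items():
        if len(haps) == 1:
            h = haps[0]
            base = re.sub(r"[ab]$", "", h.id)
            out.append(replace(h, id=base + "a"))
            out.append(replace(h, id=base + "b"))
        elif len(haps) == 2:
            out.extend(haps)
        else:
            raise PloidyError(
                f"individual {indiv!r} has {len(haps)} distinct sequences (max 2)"
            )
    return tuple(out)


def het_misclassification_prob(clones: int) -> float:
    """P(all sequenced clones derive from one allele of a balanced het).

    With ``c`` clones each drawn independently from two equally likely
    alleles, the individual looks homozygous with probability
    ``2 * (1/2)**c = (1/2)**(c-1)``.  At the study's minimum of eight
    clones this is 0.78%, below the 1% bound quoted for the procedure.
    """
    if clones < 1:
        raise ValueError("clones must be >= 1")
    return 0.5 ** (clones - 1)


def build_site_mask(
    locus: AlignedLocus,
    policy: str = "complete-deletion",
    populations: Iterable[str] | None = None,
) -> SiteMask:
    """Build a gap/missing-data mask over the locus.

    ``complete-deletion`` removes every site at which any considered
    haplotype carries "-" or "N" (optionally restricted to the haplotypes of
    ``populations``); ``none`` keeps all sites.
    """
    if policy == "none":
        return SiteMask(tuple(range(1, locus.length + 1)), policy="none")
    if policy != "complete-deletion":
        raise ValueError(f"unknown gap policy {policy!r}")
    if populations is None:
        haps = locus.haplotypes
    else:
        pops = set(populations)
        haps = tuple(h for h in locus.haplotypes if h.population in pops)
    included = [
        i + 1
        for i in range(locus.length)
        if all(h.sequence[i] not in MISSING_CHARS for h in haps)
    ]
    return SiteMask(tuple(included), policy="complete-deletion")


def slice_block(locus: AlignedLocus, start: int, end: int) -> AlignedLocus:
    """Return the sub-alignment over 1-based inclusive sites [start, end]."""
    if not (1 <= start <= end <= locus.length):
        raise IndexError(
            f"block [{start}, {end}] out of range for length {locus.length}"
        )
    haps = tuple(
        replace(h, sequence=h.sequence[start - 1 : end]) for h in locus.haplotypes
    )
    name = locus.name if (start, end) == (1, locus.length) else (
        f"{locus.name}[{start}-{end}]"
    )
    return AlignedLocus(name=name, haplotypes=haps)
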