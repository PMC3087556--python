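import pytest

from acdiv.alignment import AlignedLocus, Haplotype
from acdiv.im import IMParams
from acdiv.simulate import SimulationConfig, simulate_im_dataset

POP_A = "Florianopolis"
POP_B = "Itaparica"


def make_locus(seqs_a, seqs_b=(), name="toy"):
    """Build an AlignedLocus from raw sequence strings (two populations)."""
    haps = []
    for i, s in enumerate(seqs_a):
        haps.append(Haplotype(f"Flo{i // 2 + 1:02d}{'ab'[i % 2]}", POP_A, s))
    for i, s in enumerate(seqs_b):
        haps.append(Haplotype(f"Bah{i // 2 + 1:02d}{'ab'[i % 2]}", POP_B, s))
    return AlignedLocus(name=name, haplotypes=tuple(haps))


@pytest.fixture(scope="session")
def deep_split_dataset():
    """Six loci from a deep split with no migration: the regime where the
    two populations are fully differentiated (fixed differences, high FST)."""
    return simulate_im_dataset(
        SimulationConfig(
            truth=IMParams(theta1=2, theta2=2, thetaA=2, t=10, m1=0, m2=0),
            n1=12,
            n2=12,
            loci=6,
            lengths=(413, 159, 218, 269, 270, 274),
            seed=31,
        )
    )


@pytest.fixture(scope="session")
def moderate_split_dataset():
    """Smaller dataset at the default simulated truth, for pipeline tests."""
    return simulate_im_dataset(
        SimulationConfig(
            truth=IMParams(theta1=5, theta2=5, thetaA=2, t=2, m1=0, m2=0),
            n1=8,
            n2=8,
            loci=4,
            lengths=(300, 300, 300, 300),
            seed=11,
        )
    )


def cycle_itaparica_standin(with_gap=True):
    """Synthetic stand-in for one published table row: 24 haplotypes over
    218 sites, three biallelic sites with minor-allele counts (2, 2, 5)
    inside sites 36-131, and (optionally) one gapped column at site 50.

    The allele configuration is the unique one (up to site placement) that
    reproduces the printed per-population summary statistics of that row.
    """
    L = 218
    sites = {60: 2, 80: 2, 100: 5}
    seqs = []
    for i in range(24):
        row = ["A"] * L
        for pos, c in sites.items():
            if i < c:
                row[pos - 1] = "T"
        if with_gap and i == 0:
            row[49] = "-"
        seqs.append("".join(row))
    return make_locus((), seqs, name="cycle_standin")
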