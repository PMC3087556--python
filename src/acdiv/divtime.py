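"""Conversion of genetic divergence to calendar time.

Two routes are supported:

* ``da_based_time``: per-locus net divergence Da (substitutions/site)
  divided by twice an external substitution rate (divergence accrues along
  both diverging lineages), averaged over loci.  The reported spread is the
  population standard deviation (n divisor) across loci.
* ``im_time_to_years``: a scaled IM split time t (in mutations per locus)
  divided by the per-locus mutation rate per million years, aggregated
  across loci with a geometric mean; rates are the mean of external
  synonymous and nonsynonymous substitution rates when ``mode="average"``.

The default rates are the Drosophila nuclear-gene synonymous and
nonsynonymous substitution rates, 0.0156 and 0.00191 substitutions per
site per million years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

DROSOPHILA_SYNONYMOUS_RATE = 0.0156   # subs/site/My
DROSOPHILA_NONSYNONYMOUS_RATE = 0.00191


@dataclass(frozen=True)
class RateAssumption:
    synonymous_rate: float = DROSOPHILA_SYNONYMOUS_RATE
    nonsynonymous_rate: float = DROSOPHILA_NONSYNONYMOUS_RATE
    mode: str = "synonymous"  # or "average"

    def __post_init__(self) -> None:
        if self.synonymous_rate <= 0 or self.nonsynonymous_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.mode not in ("synonymous", "average"):
            raise ValueError("mode must be 'synonymous' or 'average'")

    @property
    def per_site_rate(self) -> float:
        if self.mode == "synonymous":
            return self.synonymous_rate
        return 0.5 * (self.synonymous_rate + self.nonsynonymous_rate)


@dataclass(frozen=True)
class TimeEstimate:
    mean_Mya: float
    sd_Mya: float
    per_locus_Mya: tuple[float, ...]
    method: str
    range_Mya: Optional[tuple[float, float]] = None


def da_based_time(
    da_values: Sequence[float], rate: RateAssumption | None = None
) -> TimeEstimate:
    """Divergence time from per-locus net divergence: T_l = Da_l / (2 r).

    Mean and population SD (n divisor) are taken across loci, matching the
    "mean +/- SD" convention of multilocus Da dating.
    """
    if rate is None:
        rate = RateAssumption(mode="synonymous")
    da = np.asarray(list(da_values), dtype=float)
    if da.size == 0:
        raise ValueError("need at least one Da value")
    if np.any(da < 0):
        raise ValueError("Da values must be >= 0")
    times = da / (2.0 * rate.per_site_rate)
    return TimeEstimate(
        mean_Mya=float(times.mean()),
        sd_Mya=float(times.std(ddof=0)),
        per_locus_Mya=tuple(float(x) for x in times),
        method="da_based",
    )


def im_time_to_years(
    t_scaled: float,
    locus_lengths: Sequence[int],
    rate: RateAssumption | None = None,
    t_range: Optional[tuple[float, float]] = None,
) -> TimeEstimate:
    """Convert a scaled IM split time to million years.

    ``t_scaled`` is in units of mutations per locus (t = T * u).  Each
    locus' mutation rate per million years is ``per_site_rate * length``;
    the scalar used for conversion is their geometric mean, the aggregation
    conventional for multilocus IM scaling.  ``t_range`` (e.g. an HPD90
    interval on the same scale) converts alongside the point estimate.
    """
    if rate is None:
        rate = RateAssumption(mode="average")
    if t_scaled < 0:
        raise ValueError("t must be >= 0")
    lengths = list(locus_lengths)
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("locus lengths must be positive")
    u_per_my = [rate.per_site_rate * l for l in lengths]
    geo = math.exp(sum(math.log(u) for u in u_per_my) / len(u_per_my))
    times = tuple(t_scaled / u for u in u_per_my)
    rng = None
    if t_range is not None:
        rng = (t_range[0] / geo, t_range[1] / geo)
    mean = t_scaled / geo
    return TimeEstimate(
        mean_Mya=mean,
        sd_Mya=float(np.std(times, ddof=0)),
        per_locus_Mya=times,
        method="im_based",
        range_Mya=rng,
    )
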