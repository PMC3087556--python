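# Methods

`acdiv` re-implements, as a tested pipeline, the multilocus population-genetics
workflow used to ask whether two mosquito populations are reproductively
isolated sibling species: per-locus polymorphism and neutrality statistics,
recombination filtering, divergence statistics, Bayesian isolation-with-
migration (IM) inference, conversion of genetic divergence to calendar time,
and distance-based genealogies. This note records the models, conventions and
numerical choices; nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Input is one aligned FASTA per locus; haplotypes are labelled by population
via id prefixes ("Flo" → Florianópolis, "Bah" → Itaparica by default,
configurable regex). Diploid individuals contribute two haplotypes;
individuals observed homozygous across sequenced clones are duplicated before
analysis (`duplicate_homozygotes`). With c clones per mosquito the probability
of mistaking a balanced heterozygote for a homozygote is 2·(1/2)^c; at the
study's minimum of eight clones this is 0.78%.

Coordinates are 1-based and inclusive everywhere (block "124–381" has length
258). The alphabet is {A,C,G,T,-,N}; anything else is rejected on read. Gap
handling is complete deletion by default: a site containing "-" or "N" in any
haplotype of the analysis scope (one population for within-population
statistics, both for between-population statistics) is excluded, and the
per-site denominators use the retained site count. DNASP, the program whose
printed output we compare against, is not fully consistent here — its θ uses
net-of-gaps length while its π divides by the full fragment length — so
agreement with printed π is to ~2×10⁻⁵ rather than exact.

## Polymorphism and neutrality statistics

* S = number of segregating sites; η = Σ(site alleles − 1), so a triallelic
  site adds 1 to S and 2 to η.
* Watterson's diversity per site: θ̂ = η/(a₁L), a₁ = Σ_{i=1}^{n−1} 1/i —
  computed from η (total mutations), matching the source's caption; with
  biallelic data η = S.
* π = mean pairwise differences over all unordered pairs, per retained site.
* Tajima's D uses the 1989 constants; Fu & Li's tests are the starred
  (outgroup-free) D* and F*, with η_s the number of singleton mutations
  (an allele carried by exactly one sequence). Both families are undefined
  (returned as missing, never 0) when S = 0 or n < 4, where the variance
  constants vanish. The implementation was checked against published DNASP
  output: for the least polymorphic table row the minor-allele configuration
  (2,2,5) at n=24 reproduces the printed D_T, D* and F* simultaneously to all
  five printed decimals, which pins both the constants and the singleton
  convention.
* Significance is assessed by simulation rather than interpolated tables:
  the null is the standard coalescent conditioned on the observed S
  (a Kingman genealogy per replicate, S mutations placed uniformly on
  branches), two-tailed p = fraction of |statistic| ≥ |observed|, Bonferroni
  over a family of 12 (six loci × two populations) by default. The empirical
  type-I error of this test at nominal 5% is checked to be within ±3 points.

## Divergence statistics

Dxy is the mean between-population pairwise difference per site; Da = Dxy −
(π₁+π₂)/2. FST is the Hudson/Slatkin/Maddison estimator 1 − Hw/Hb with Hw the
*unweighted* mean of the two within-population mean pairwise differences
(sample sizes are equal here) and Hb = Dxy. Two consequences worth knowing:
the estimator is slightly negative (exactly −1/(n−1)) for identical finite
samples, because Hw excludes self-comparisons; and it is not necessarily the
estimator behind the published FST values (the source does not name one), so
comparisons to print are tolerance-based (±0.05). The permutation p-value
shuffles population labels with sample sizes fixed, reusing a precomputed
pairwise-difference matrix; "0.0000" means no permutation reached the
observed FST.

Biallelic sites in the pooled sample are partitioned into shared, fixed, and
exclusive-to-either-population categories; sites with more than two alleles
are tallied separately (`s_multiallelic`), since the four categories are
defined for biallelic sites.

## Recombination filtering

The four-gamete test flags site pairs exhibiting all four haplotypes; RM is
the Hudson–Kaplan bound: discard any pair whose open interval contains
another's, then greedily count non-overlapping intervals left to right
(intervals may share endpoints). NR-block extraction emulates the
IMgc-style preprocessing: over contiguous blocks [s,e] and haplotype-removal
sets, maximize retained^weight × length subject to the block being
four-gamete clean among retained haplotypes (weight defaults to 1.0 and is a
flag). Candidate block bounds only need to sit at segregating-site
boundaries; removal sets are found exactly by branch-and-bound over the
gamete classes of the first remaining conflict (to resolve a conflict, some
gamete class must vanish entirely) within a node budget, falling back to a
deterministic greedy rule (most conflicts participated in via rarest-gamete
carriage, then most conflicts resolved, then smallest id). Ties between
blocks break toward higher score, then longer, then leftmost. The original
filtering program's exact objective and tie-breaks are not public, so the
guaranteed contract is the invariant the IM stage relies on — the returned
block always has RM = 0 among retained haplotypes — plus exhaustive-search
equivalence on small instances.

## Isolation-with-migration inference

The model is the two-population IM coalescent: descendant populations of
scaled diversities θ₁, θ₂ split from an ancestor (θ_A) at scaled time t,
exchanging migrants at rates m₁, m₂; mutation is infinite-sites. All
parameters are on the mutation-rate scale conventional for IM analyses
(θ = 4Nu per locus, t = T·u, m = m/u; time in units of 1/u generations), so a
pair of lineages in population i coalesces at rate 2/θᵢ, a lineage in
population i migrates backwards at rate mᵢ, and a branch of length b carries
Poisson(b) mutations. Loci are assumed neutral, non-recombining (enforced:
the module refuses four-gamete-violating input) and of equal mutation rate
(inheritance scalar 1); priors are uniform on [0, upper] with mandatory
uppers (`suggest_priors` offers a multiple-of-Watterson heuristic).

The likelihood of a genealogy is the perfect-phylogeny embedding: each
segregating site's derived-carrier set must equal the leaf set under exactly
one branch; P(D|G) ∝ e^(−B) ∏ b_j^(k_j) with B the total length and k_j the
number of sites on branch j. Derived states are read against a known
ancestral base ("A") for simulated data, or majority-rule polarization with
complementation repair of crossing carrier sets for real-style input.

The sampler is Metropolis–Hastings over (per-locus genealogies with
migration events, parameters):

* **Subtree resimulation** — detach a random subtree and resimulate its
  lineage path upward under the structured coalescent conditioned on the
  remaining genealogy (migration at rate m_c, coalescence at 2/θ with each
  same-population background lineage, everyone ancestral above t); when the
  path rises above the background root, the background root lineage's own
  migrations are resimulated jointly. Forward and reverse proposal densities
  are evaluated explicitly, so the acceptance ratio is exact rather than
  relying on prior/proposal cancellation. This move performs migration
  birth/death and topology changes implicitly.
* **θ and m updates** — Gibbs from the sufficient-statistic conditionals:
  θ ∝ θ^(−C) e^(−W/θ) (inverse-gamma-like, sampled through a truncated gamma
  in 1/θ) and m ∝ m^M e^(−mR) (truncated gamma), where C/M count events and
  W/R are waiting-opportunity integrals summed over loci.
* **t updates** — reflected random walk (step adapted during burn-in toward
  ~30% acceptance) plus an occasional independence draw from the uniform
  prior; the latter lets the chain jump between time-scale regimes that the
  walk cannot cross (important when the posterior piles near t = 0).
* **Joint rescale** — scale t and every genealogy time by a common lognormal
  factor with the s^(K+1) Jacobian; this is what lets the split time mix on
  data where genealogy heights and t are strongly coupled.

One "sweep" is `moves_per_locus` resimulation moves per locus plus the
parameter updates (≈60–100 elementary updates at study-like sizes); burn-in
and recorded steps are counted in sweeps. Marginal posteriors are recorded
as histograms over the prior range (1000 bins by default), summarized the
way IM reports them: HiPt (mode), HiSmth (mode after a 9-bin centered
running average; window shrinks symmetrically at edges; ties resolved toward
the highest raw count, then the lowest bin), 95Lo/95Hi (2.5% tail points by
cumulative mass) and HPD90 (shortest contiguous interval holding ≥90% of
mass, two-pointer scan, ties toward the lowest index). Diagnostics follow
the published workflow: per-parameter ESS (initial-positive-sequence
autocorrelation estimate), per-move acceptance rates, a log-posterior trend,
and a multi-run convergence report that flags any parameter whose across-run
HiSmth spread exceeds a configurable fraction (default one half) of the mean
HPD90 width or whose HPD90s are disjoint.

Sampler validation (all in the test suite): (i) on a three-sequence,
zero-mutation locus at fixed parameters the sampled genealogy-height mean
matches the analytic posterior (exponential rates 6/θ+3 and 2/θ+2);
(ii) with migration active, the posterior mean TMRCA matches importance
sampling from the structured-coalescent prior weighted by e^(−B);
(iii) uninformative data leave the migration posteriors at their uniform
priors; (iv) panmictic data drive the split-time posterior into the lowest
decile of its prior range; (v) on synthetic data with known truth
(θ₁=θ₂=5, θ_A=2, t=2, m=0; 6 loci × 12+12 haplotypes) each parameter's truth
falls in the HPD90 in ≥80% of 10 seeded replicates and migration HiSmth sits
in the lowest histogram bin.

## Divergence-time conversion

Two routes. (1) Da-based: per-locus T = Da/(2r) with r an external
synonymous substitution rate (default 0.0156 subs/site/My, a Drosophila
nuclear-gene average); the division by 2r is because net divergence accrues
along both lineages. The reported spread is the population SD (divisor n)
across loci — this, not the sample SD, reproduces the published ±0.76/±0.65.
(2) IM-based: scaled t (mutations per locus) divided by the per-locus
mutation rate per My (rate mode "average" = mean of synonymous and
nonsynonymous rates, times locus length), aggregated across loci by
geometric mean — the aggregation conventional for multilocus IM scaling; the
source states only which rates it averaged, so the geometric mean is a
documented assumption. HPD90 bounds convert alongside the point estimate.

## Genealogies

JC69 (d = −¾ln(1−4p/3)) and K2P (d = −½ln(1−2P−Q) − ¼ln(1−2Q)) distances
with pairwise deletion of gapped sites (the tolerant convention for
intron-bearing alignments); saturation (log argument ≤ 0) raises rather than
returning infinity — note K2P is singular at transversion fraction Q ≥ 0.5,
which binary-coded synthetic data can reach. Neighbor joining is delegated
to scikit-bio; bootstrap resamples sites with replacement and reports, for
each internal bipartition of the point tree, the percentage of replicate
trees containing it. Substitution models are fixed inputs (JC for one locus,
K2P otherwise, as concluded in the source); model selection is out of scope.

## Synthetic data

`simulate_im_dataset` is a direct Gillespie implementation of the IM
coalescent above (independent of the inference code), emitting binary-coded
alignments (ancestral "A", derived "T"), with per-locus genealogies in
Newick available for oracle checks. Defaults mirror the study design: six
loci of lengths (413, 159, 218, 269, 270, 274) bp, 24 haplotypes per
population, truth (θ₁=5, θ₂=5, θ_A=2, t=2, m₁=m₂=0) — the deep-split,
no-migration regime the study inferred. Under ρ = 0 every locus passes the
four-gamete test by construction. With ρ > 0 simulation is delegated to
msprime's ancestral recombination graph under the same parameter mapping
(population size θ/2 at ploidy 1, one mutation per locus per time unit);
msprime at identical parameters is also the independent distributional
oracle for the generator (two-sample KS on S, π, FST). A clone-sequencing
simulator reproduces the heterozygote-misclassification experiment.

What the generator does *not* emulate: indels and alignment gaps, four-base
mutation (except the `jc_corrupt` helper for distance tests), locus-specific
mutation rates, population growth, selection, or more than two demes. A
green recovery test therefore establishes correctness of the inference
machinery under the model's own assumptions — not robustness to their
violation.

## Numerical choices and limitations

* Missing statistics propagate as None/NaN, never 0.
* The IM module requires a laminar (rooted-perfect-phylogeny) carrier
  family; four-gamete-clean data that are only unrooted-compatible are
  re-polarized by complementation where possible and rejected otherwise.
* The sufficient-statistic Gibbs step for θ falls back to short
  Metropolis-within-Gibbs when fewer than two coalescences inform a
  population (the truncated-gamma transform needs shape > 0).
* Chain defaults are desk-scale; published-scale analyses (tens of millions
  of elementary updates, four independent runs) are configuration values.
* `extract_nr_block`'s exact search is budgeted; beyond the budget the
  greedy rule applies, so optimality is guaranteed only on small instances
  (and verified there against exhaustion).
* Determinism: every stochastic routine takes a seed; identical
  configuration and seeds reproduce byte-identical outputs.
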