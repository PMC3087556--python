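"""End-to-end orchestration of the multilocus divergence analysis.

Stage order follows the published workflow: read and validate alignments;
per-population polymorphism/neutrality statistics on the whole fragment and
the non-recombining (NR) block; RM and NR-block extraction; simulation
neutrality p-values with a Bonferroni gate (warn, never abort); divergence
statistics; isolation-with-migration MCMC across independent seeded runs
with a convergence report; divergence-time conversions; neighbor-joining
trees with bootstrap.  All randomness flows from the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import divtime, im, phylo, popgen, recombination
from .alignment import AlignedLocus, read_alignment


@dataclass
class AnalysisConfig:
    loci: Sequence[AlignedLocus]
    populations: tuple[str, str]
    gap_policy: str = "complete-deletion"
    nr_weight: float = 1.0
    neutrality_reps: int = 2000
    bonferroni_family: Optional[int] = None  # default: loci x populations
    fst_permutations: int = 1000
    im_runs: int = 2
    im_burn_in: int = 500
    im_steps: int = 4000
    im_bins: int = 200
    im_priors: Optional[im.IMParams] = None
    ancestral: str = "A"
    rate: divtime.RateAssumption = field(
        default_factory=lambda: divtime.RateAssumption(mode="synonymous")
    )
    im_rate: divtime.RateAssumption = field(
        default_factory=lambda: divtime.RateAssumption(mode="average")
    )
    tree_models: Optional[dict[str, str]] = None  # locus name -> 'jc'/'k2p'
    bootstrap_reps: int = 200
    seed: int = 0
    run_neutrality_pvalues: bool = True
    run_im: bool = True
    run_trees: bool = True


def config_from_paths(paths: Sequence[str], **kwargs) -> AnalysisConfig:
    loci = [read_alignment(p) for p in paths]
    pops = loci[0].populations
    return AnalysisConfig(loci=list(loci), populations=(pops[0], pops[1]), **kwargs)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute every stage; returns a report bundle of DataFrames/objects."""
    rng = np.random.default_rng(config.seed)
    pop_a, pop_b = config.populations
    report: dict = {"log": [], "seed": config.seed}

    def log(msg: str) -> None:
        report["log"].append(msg)

    # --- stage 1-3: per-locus statistics, RM, NR blocks ---------------------
    summary_rows = []
    nr_results = {}
    nr_loci = {}
    for locus in config.loci:
        rm = recombination.rm_for_locus(locus)
        nr = recombination.extract_nr_block(locus, weight=config.nr_weight)
        nr_locus = recombination.apply_nr_block(locus, nr)
        nr_results[locus.name] = nr
        nr_loci[locus.name] = nr_locus
        for pop in (pop_a, pop_b):
            whole = popgen.locus_summary(locus, pop)
            try:
                block = popgen.locus_summary(nr_locus, pop)
            except KeyError:
                block = None
            summary_rows.append(
                {
                    "locus": locus.name,
                    "population": pop,
                    "RM": rm,
                    "length": locus.length,
                    "length_nr": nr_locus.length,
                    "n": whole.n,
                    "n_nr": block.n if block else 0,
                    "S": whole.S,
                    "S_nr": block.S if block else None,
                    "theta": whole.theta_w,
                    "theta_nr": block.theta_w if block else None,
                    "pi": whole.pi,
                    "pi_nr": block.pi if block else None,
                    "D_T": whole.D_T,
                    "D_T_nr": block.D_T if block else None,
                    "D_FL": whole.D_FL,
                    "D_FL_nr": block.D_FL if block else None,
                    "F_FL": whole.F_FL,
                    "F_FL_nr": block.F_FL if block else None,
                }
            )
        log(f"{locus.name}: RM={rm}, NR block {nr.start}-{nr.end}, "
            f"removed {len(nr.removed_ids)} haplotypes")
    report["polymorphism"] = pd.DataFrame(summary_rows)
    report["nr_blocks"] = pd.DataFrame(
        [
            {
                "locus": name,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "removed": ",".join(r.removed_ids),
                "retained": r.retained_count,
            }
            for name, r in nr_results.items()
        ]
    )
    report["nr_loci"] = nr_loci

    # --- stage 4: neutrality tests + Bonferroni gate -------------------------
    if config.run_neutrality_pvalues:
        family = config.bonferroni_family or (len(config.loci) * 2)
        tests = []
        for row in summary_rows:
            if row["D_T"] is None:
                continue
            res = popgen.neutrality_p_value(
                row["D_T"],
                "tajima_d",
                row["n"],
                row["S"],
                replicates=max(1000, config.neutrality_reps),
                seed=int(rng.integers(2**31 - 1)),
                family_size=family,
            )
            tests.append(
                {
                    "locus": row["locus"],
                    "population": row["population"],
                    "statistic": "tajima_d",
                    "value": res.value,
                    "p": res.p_value,
                    "p_bonferroni": res.adjusted_p,
                }
            )
            if res.adjusted_p < 0.05:
                warnings.warn(
                    f"{row['locus']}/{row['population']}: Tajima's D significant "
                    "after Bonferroni; IM neutrality assumption questionable",
                    stacklevel=2,
                )
        report["neutrality"] = pd.DataFrame(tests)

    # --- stage 5: divergence statistics --------------------------------------
    div_rows = []
    for locus in config.loci:
        for label, lc in (("whole", locus), ("nr", nr_loci[locus.name])):
            try:
                d = popgen.between_population_stats(lc, pop_a, pop_b)
            except (KeyError, ValueError):
                continue
            p = popgen.fst_permutation_p(
                lc, pop_a, pop_b,
                permutations=max(1000, config.fst_permutations),
                seed=int(rng.integers(2**31 - 1)),
            )
            div_rows.append(
                {
                    "locus": locus.name,
                    "scope": label,
                    "FST": d.fst,
                    "P_FST": p,
                    "Dxy": d.dxy,
                    "Da": d.da,
                    "Ss": d.s_shared,
                    "Sf": d.s_fixed,
                    "S1": d.s_excl1,
                    "S2": d.s_excl2,
                }
            )
    report["divergence"] = pd.DataFrame(div_rows)

    # --- stage 6: IM inference ------------------------------------------------
    if config.run_im:
        im_input = []
        for locus in config.loci:
            nr_locus = nr_loci[locus.name]
            if recombination.rm_for_locus(nr_locus) != 0:
                raise RuntimeError(
                    f"{locus.name}: NR block still fails the four-gamete test; "
                    "IM inference refuses recombining input"
                )
            im_input.append(
                im.prepare_locus(nr_locus, config.populations, config.ancestral)
            )
        priors = config.im_priors or im.suggest_priors(im_input)
        runs = []
        for r in range(config.im_runs):
            post = im.im_mcmc(
                im_input,
                priors,
                burn_in=config.im_burn_in,
                steps=config.im_steps,
                bins=config.im_bins,
                seed=int(rng.integers(2**31 - 1)),
            )
            runs.append(post)
            log(f"IM run {r}: acceptance {post.acceptance}")
        report["im_runs"] = runs
        report["im_priors"] = priors
        report["im_summary"] = pd.DataFrame(
            [
                {"run": i, "parameter": k, **post.summaries[k]}
                for i, post in enumerate(runs)
                for k in im.PARAM_NAMES
            ]
        )
        report["im_convergence"] = im.convergence_report(runs)

        # --- stage 7: time conversions ---------------------------------------
        da_whole = [r["Da"] for r in div_rows if r["scope"] == "whole"]
        da_nr = [r["Da"] for r in div_rows if r["scope"] == "nr"]
        report["time_da_whole"] = divtime.da_based_time(da_whole, config.rate)
        report["time_da_nr"] = divtime.da_based_time(da_nr, config.rate)
        lengths = [nr_loci[l.name].length for l in config.loci]
        t_hismth = float(
            np.mean([p.summaries["t"]["HiSmth"] for p in runs])
        )
        t_lo = float(np.mean([p.summaries["t"]["HPD90Lo"] for p in runs]))
        t_hi = float(np.mean([p.summaries["t"]["HPD90Hi"] for p in runs]))
        report["time_im"] = divtime.im_time_to_years(
            t_hismth, lengths, config.im_rate, t_range=(t_lo, t_hi)
        )

    # --- stage 8: genealogies --------------------------------------------------
    if config.run_trees:
        trees = {}
        models = config.tree_models or {}
        for locus in config.loci:
            model = models.get(locus.name, "k2p")
            tree = phylo.bootstrap_support(
                locus,
                model=model,
                replicates=config.bootstrap_reps,
                seed=int(rng.integers(2**31 - 1)),
            )
            trees[locus.name] = tree
        report["trees"] = trees
    return report


def write_report(report: dict, outdir: str) -> None:
    """Write the report bundle as TSV/Newick files."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    for key in ("polymorphism", "nr_blocks", "neutrality", "divergence", "im_summary"):
        if key in report and isinstance(report[key], pd.DataFrame):
            report[key].to_csv(os.path.join(outdir, f"{key}.tsv"), sep="\t", index=False)
    if "trees" in report:
        for name, tree in report["trees"].items():
            with open(os.path.join(outdir, f"{name}.nwk"), "w") as fh:
                fh.write(tree.newick() + "\n")
    manifest = {
        "seed": report.get("seed"),
        "log": report.get("log", []),
    }
    for key in ("time_da_whole", "time_da_nr", "time_im"):
        if key in report:
            te = report[key]
            manifest[key] = {
                "mean_Mya": te.mean_Mya,
                "sd_Mya": te.sd_Mya,
                "range_Mya": te.range_Mya,
            }
    if "im_convergence" in report:
        manifest["im_convergence_flags"] = report["im_convergence"]["flags"]
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
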