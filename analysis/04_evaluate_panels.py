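#!/usr/bin/env python
"""Build 48- and 96-SNP panels from each ranking and evaluate them.

Seven panels per size (five method top-k panels, the average-rank panel and
a random panel), each tested two ways: empirical assignment of holdout
individuals against a training-set baseline, and simulated assignment
(f_ORCA, 500 reps x 1000 individuals) from holdout allele frequencies.
Panel differences are tested with a one-way ANOVA and Tukey's HSD (alpha
0.01) separately for the empirical (per-population observations) and
simulated (per-rep observations) modes.
"""

from pathlib import Path

import pandas as pd

import panelrank as pr

OUT = Path(__file__).resolve().parent.parent / "results"
SPLIT_SEED = 1


def main() -> None:
    table = pr.read_genepop(OUT / "benchmark.gen")
    table = pr.filter_monomorphic_loci(pr.filter_individuals_by_missingness(table))
    training, holdout = pr.training_holdout_split(table, seed=SPLIT_SEED)
    ranks = pd.read_csv(OUT / "locus_ranks.csv")

    panels = pr.build_panels(ranks, sizes=(48, 96), random_seed=SPLIT_SEED)
    evals = pr.evaluate_panels(panels, training, holdout, orca_reps=500, orca_individuals=1000, seed=SPLIT_SEED)

    rows = []
    for ev in evals:
        rows.append(
            {
                "method": ev.panel.method,
                "size": ev.panel.size,
                "empirical_mean": ev.empirical_mean,
                "forca_mean": ev.forca_mean,
                "forca_q1": ev.forca_q1,
                "forca_q3": ev.forca_q3,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "panel_evaluations.csv", index=False)
    print(summary.round(3).to_string(index=False))
    for size in (48, 96):
        sub = summary[summary["size"] == size]
        print(
            f"mean over {size}-SNP panels: empirical "
            f"{sub['empirical_mean'].mean():.3f}, f_ORCA {sub['forca_mean'].mean():.3f}"
        )

    emp_groups = {f"{e.panel.method}{e.panel.size}": e.empirical_per_population.to_numpy() for e in evals}
    sim_groups = {f"{e.panel.method}{e.panel.size}": e.forca_reps for e in evals}
    for label, groups in (("empirical", emp_groups), ("simulated", sim_groups)):
        res = pr.compare_panel_scores(groups, alpha=0.01)
        print(f"{label} ANOVA: F={res['anova_F']:.1f}, p={res['anova_p']:.2e}")
        res["tukey"].round(4).to_csv(OUT / f"tukey_{label}.csv")


if __name__ == "__main__":
    main()
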