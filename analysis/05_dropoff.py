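#!/usr/bin/env python
"""Assignment accuracy as loci are dropped five at a time by average rank.

Starting from all polymorphic loci, repeatedly removes the five worst
average-rank loci and re-evaluates empirical holdout assignment, down to
the five best loci, reporting the mean and 1st/3rd quartiles of the
per-population probabilities of correct assignment at each panel size.
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

    curve = pr.dropoff_curve(ranks, training, holdout, step=5, floor=5)
    curve.to_csv(OUT / "dropoff_curve.csv", index=False)
    first, last = curve.iloc[0], curve.iloc[-1]
    print(curve.round(3).to_string(index=False))
    print(
        f"full set ({int(first['panel_size'])} loci): {first['mean_correct']:.3f}; "
        f"floor ({int(last['panel_size'])} loci): {last['mean_correct']:.3f}"
    )


if __name__ == "__main__":
    main()
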