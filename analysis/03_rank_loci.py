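#!/usr/bin/env python
"""Rank every locus by the five measures on the training half.

Splits each population in half (extra individual to training), ranks loci
by F_ST, I_n, LC, BELS and WHICHLOCI on the training set only, adds the
average and random ranks, and reports the concordance between methods.
"""

from pathlib import Path

from scipy import stats

import panelrank as pr
from panelrank.likelihood_rankers import RankerConfig

OUT = Path(__file__).resolve().parent.parent / "results"
SPLIT_SEED = 1


def main() -> None:
    table = pr.read_genepop(OUT / "benchmark.gen")
    table = pr.filter_monomorphic_loci(pr.filter_individuals_by_missingness(table))
    training, holdout = pr.training_holdout_split(table, seed=SPLIT_SEED)
    print(f"training {training.n_individuals} / holdout {holdout.n_individuals} individuals")

    cfg = RankerConfig(sim_pop_size=50, iterations=12, seed=SPLIT_SEED)
    ranks = pr.rank_all_methods(training, ranker_config=cfg, random_rank_seed=SPLIT_SEED)
    ranks.to_csv(OUT / "locus_ranks.csv", index=False)

    pairs = [("fst", "in"), ("in", "lc"), ("fst", "lc"), ("whichloci", "bels")]
    for a, b in pairs:
        res = pr.compare_rank_lists(ranks[f"{a}_rank"], ranks[f"{b}_rank"])
        rho = stats.spearmanr(ranks[f"{a}_rank"], ranks[f"{b}_rank"]).statistic
        wp = res["wilcoxon_p"] if res["wilcoxon_defined"] else float("nan")
        print(f"{a} vs {b}: Spearman rho={rho:.3f}, Wilcoxon p={wp:.3f}")
    print("wrote locus_ranks.csv")


if __name__ == "__main__":
    main()
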