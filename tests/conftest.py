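from __future__ import annotations

import numpy as np
import pytest

import panelrank as pr
from panelrank.likelihood_rankers import RankerConfig


@pytest.fixture(scope="session")
def benchmark():
    """The seeded 12-population / 110-polymorphic-locus benchmark dataset,
    drift-calibrated to a mean per-locus F_ST of 0.114, with its
    training/holdout split."""
    table, truth, config = pr.benchmark_dataset()
    filtered = pr.filter_monomorphic_loci(pr.filter_individuals_by_missingness(table))
    training, holdout = pr.training_holdout_split(filtered, seed=1)
    return {
        "raw": table,
        "truth": truth,
        "config": config,
        "table": filtered,
        "training": training,
        "holdout": holdout,
    }


@pytest.fixture(scope="session")
def benchmark_ranks(benchmark):
    """All-method rank table on the benchmark training set (desk-scale
    resampling settings for the likelihood rankers)."""
    cfg = RankerConfig(sim_pop_size=50, iterations=12, seed=7)
    return pr.rank_all_methods(benchmark["training"], ranker_config=cfg, random_rank_seed=5)


@pytest.fixture()
def tiny_table():
    """2 populations x 2 loci, fully called, hand-enumerable."""
    calls = np.array(
        [
            [2, 1],
            [1, 1],
            [2, 0],
            [0, 1],
            [1, 2],
            [0, 0],
        ],
        dtype=np.int8,
    )
    return pr.GenotypeTable(
        loci=[pr.Locus("locA"), pr.Locus("locB")],
        individual_ids=[f"ind{i}" for i in range(6)],
        populations=["p1", "p1", "p1", "p2", "p2", "p2"],
        regions={"p1": "r1", "p2": "r1"},
        calls=calls,
    )


def planted_freqs(n_weak: int = 49, seed: int = 0, strong: int = 1):
    """K=3 frequency matrix with ``strong`` near-fixed-difference loci
    (first columns) among weakly informative loci."""
    rng = np.random.default_rng(seed)
    weak = 0.5 + rng.uniform(-0.03, 0.03, size=(3, n_weak))
    cols = []
    for s in range(strong):
        col = np.full(3, 0.05)
        col[s % 3] = 0.95
        cols.append(col)
    return np.column_stack(cols + [weak])
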