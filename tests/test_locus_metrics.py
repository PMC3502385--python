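import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import panelrank as pr
from panelrank.data_model_io import MISSING
from panelrank.locus_metrics import hwe_chisq_from_counts, wc_components
from panelrank.synthetic_data import SimulationConfig, table_from_frequencies

from _oracles import rosenberg_in_direct, wc_theta_direct


def table_from_genotype_lists(pop_genotypes):
    calls = np.concatenate([np.asarray(g, dtype=np.int8) for g in pop_genotypes])[:, None]
    pops = [f"p{k}" for k, g in enumerate(pop_genotypes) for _ in g]
    return pr.GenotypeTable(
        loci=[pr.Locus("L")],
        individual_ids=[f"i{j}" for j in range(len(calls))],
        populations=pops,
        regions={f"p{k}": "r" for k in range(len(pop_genotypes))},
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def test_theta_matches_direct_formula_oracle_on_random_datasets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        K = int(rng.integers(2, 13))
        genos = [list(rng.integers(0, 3, size=int(rng.integers(5, 51)))) for _ in range(K)]
        # ensure overall polymorphism
        if all(x == genos[0][0] for g in genos for x in g):
            genos[0][0] = (genos[0][0] + 1) % 3
        table = table_from_genotype_lists(genos)
        comp = pr.wc_fst_per_locus(table)
        a, b, c = wc_theta_direct(genos)
        theta_oracle = a / (a + b + c)
        assert comp.theta[0] == pytest.approx(theta_oracle, abs=1e-10)
        assert comp.a[0] == pytest.approx(a, abs=1e-10)


def test_theta_is_one_for_fixed_difference():
    table = table_from_genotype_lists([[2] * 50, [0] * 50])
    assert pr.wc_fst_per_locus(table).theta[0] == pytest.approx(1.0, abs=1e-12)


def test_theta_nonpositive_for_identical_all_het_populations():
    table = table_from_genotype_lists([[1] * 50, [1] * 50])
    assert pr.wc_fst_per_locus(table).theta[0] <= 0


def test_theta_hand_case_counts_7_2_1_vs_1_2_7():
    genos = [[2] * 7 + [1] * 2 + [0] * 1, [2] * 1 + [1] * 2 + [0] * 7]
    table = table_from_genotype_lists(genos)
    a, b, c = wc_theta_direct(genos)
    assert pr.wc_fst_per_locus(table).theta[0] == pytest.approx(a / (a + b + c), abs=1e-10)


def test_theta_invariant_to_allele_relabeling_and_population_order():
    rng = np.random.default_rng(7)
    genos = [list(rng.integers(0, 3, 30)) for _ in range(4)]
    t1 = pr.wc_fst_per_locus(table_from_genotype_lists(genos)).theta[0]
    flipped = [[2 - x for x in g] for g in genos]
    t2 = pr.wc_fst_per_locus(table_from_genotype_lists(flipped)).theta[0]
    t3 = pr.wc_fst_per_locus(table_from_genotype_lists(genos[::-1])).theta[0]
    assert t1 == pytest.approx(t2, abs=1e-12)
    assert t1 == pytest.approx(t3, abs=1e-12)


def test_theta_undefined_for_overall_monomorphic_locus():
    table = table_from_genotype_lists([[2] * 10, [2] * 10])
    assert np.isnan(pr.wc_fst_per_locus(table).theta[0])


def test_theta_requires_two_populations():
    with pytest.raises(ValueError):
        pr.wc_fst_per_locus(table_from_genotype_lists([[1, 2, 0]]))


def test_multilocus_reduces_to_single_locus():
    rng = np.random.default_rng(3)
    genos = [list(rng.integers(0, 3, 20)) for _ in range(3)]
    table = table_from_genotype_lists(genos)
    assert pr.multilocus_fst(table) == pytest.approx(pr.wc_fst_per_locus(table).theta[0])


def test_multilocus_on_benchmark_near_calibrated_target(benchmark):
    assert pr.multilocus_fst(benchmark["table"]) == pytest.approx(0.114, abs=0.03)


def test_pairwise_matrix_symmetric_zero_diagonal_and_duplicate_population():
    rng = np.random.default_rng(5)
    base = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
    calls = np.vstack([base, base, rng.integers(0, 3, size=(20, 6)).astype(np.int8)])
    table = pr.GenotypeTable(
        loci=[pr.Locus(f"L{l}") for l in range(6)],
        individual_ids=[f"i{j}" for j in range(60)],
        populations=["p1"] * 20 + ["p2"] * 20 + ["p3"] * 20,
        regions={"p1": "r", "p2": "r", "p3": "r"},
        calls=calls,
    )
    M = pr.pairwise_fst_matrix(table)
    np.testing.assert_allclose(M, M.T, atol=1e-12)
    assert np.all(np.diag(M) == 0)
    assert M[0, 1] <= 0  # duplicated population


def test_within_region_pairs_less_diverged_than_between(benchmark):
    table = benchmark["table"]
    M = pr.pairwise_fst_matrix(table)
    pops = table.population_order
    within, between = [], []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            same = table.regions[pops[i]] == table.regions[pops[j]]
            (within if same else between).append(M[i, j])
    assert np.mean(within) < np.mean(between)


# ---------------------------------------------------------------------------
# Informativeness for assignment
# ---------------------------------------------------------------------------


def afm_from_freqs(freqs, n_genes=100):
    P = np.asarray(freqs, dtype=float)
    return pr.AlleleFrequencyMatrix(
        loci=[f"L{l}" for l in range(P.shape[1])],
        populations=[f"p{k}" for k in range(P.shape[0])],
        freq=P,
        n_genes=np.full(P.shape, n_genes),
    )


@pytest.mark.parametrize(
    "freqs,expected,tol",
    [
        ([[0.3], [0.3], [0.3]], 0.0, 1e-12),
        ([[1.0], [0.0]], math.log(2), 1e-9),
        ([[0.5], [1.0]], 0.215762, 1e-6),
    ],
)
def test_informativeness_analytic_cases(freqs, expected, tol):
    assert pr.informativeness_in(afm_from_freqs(freqs), 0) == pytest.approx(expected, abs=tol)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8), st.integers(0, 100))
def test_informativeness_nonnegative_and_matches_direct_formula(freqs, _seed):
    val = pr.informativeness_in(afm_from_freqs([[p] for p in freqs]), 0)
    assert val >= 0
    assert val == pytest.approx(max(rosenberg_in_direct(freqs), 0.0), abs=1e-10)


def test_informativeness_ranks_track_theta_on_benchmark(benchmark):
    theta = pr.wc_fst_per_locus(benchmark["table"]).theta
    In = pr.informativeness_in(pr.compute_allele_frequencies(benchmark["table"]))
    rho = stats.spearmanr(theta, In).statistic
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------


def test_allelic_richness_hand_case_and_bounds():
    # one population, allele counts (19, 1) in 20 gene copies, g=2 -> 1.1
    genos = [[2] * 9 + [1]]
    table = table_from_genotype_lists(genos + [[2] * 10])
    out = pr.allelic_richness_rarefied(table, "L", g=2)
    assert out["p0"] == pytest.approx(1.1, abs=1e-10)
    assert out["p1"] == pytest.approx(1.0, abs=1e-12)  # monomorphic population
    assert all(1.0 <= v <= 2.0 for v in out.values())


def test_allelic_richness_at_full_sample_gives_observed_allele_count():
    table = table_from_genotype_lists([[2, 1, 0, 1, 2], [2] * 5])
    out = pr.allelic_richness_rarefied(table, "L", g=10)
    assert out["p0"] == pytest.approx(2.0, abs=1e-10)
    assert out["p1"] == pytest.approx(1.0, abs=1e-10)


def test_allelic_richness_rejects_oversized_rarefaction():
    table = table_from_genotype_lists([[2, 1, 0], [2, 1, 0, 1, 2]])
    with pytest.raises(ValueError):
        pr.allelic_richness_rarefied(table, "L", g=8)


# ---------------------------------------------------------------------------
# Hardy-Weinberg chi-square
# ---------------------------------------------------------------------------


def test_hwe_exact_equilibrium_and_complete_deficit():
    res = hwe_chisq_from_counts(25, 50, 25)
    assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0)
    res = hwe_chisq_from_counts(50, 0, 50)
    assert res["chi2"] == pytest.approx(100.0)  # chi2 = n * Fhat^2 with Fhat = 1
    assert res["direction"] == "deficit"
    assert hwe_chisq_from_counts(10, 80, 10)["direction"] == "excess"


def test_hwe_monomorphic_sample_flagged_undefined():
    assert hwe_chisq_from_counts(20, 0, 0)["defined"] is False


def test_hwe_pvalues_uniform_under_equilibrium():
    rng = np.random.default_rng(8)
    pvals = []
    while len(pvals) < 500:
        p = rng.uniform(0.2, 0.8)
        g = rng.binomial(2, p, size=90)
        res = hwe_chisq_from_counts(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
        if res["defined"]:
            pvals.append(res["p_value"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _two_locus_table(g1, g2):
    calls = np.column_stack([g1, g2]).astype(np.int8)
    return pr.GenotypeTable(
        loci=[pr.Locus("A"), pr.Locus("B")],
        individual_ids=[f"i{j}" for j in range(len(g1))],
        populations=["p1"] * len(g1),
        regions={"p1": "r"},
        calls=calls,
    )


def test_ld_detects_perfect_association():
    rng = np.random.default_rng(17)
    g = rng.binomial(2, 0.5, size=90)
    res = pr.ld_pairwise_test(_two_locus_table(g, g), "A", "B", "p1", n_perm=1000, seed=2)
    assert res["p_value"] < 0.01


def test_ld_monomorphic_partner_undefined():
    rng = np.random.default_rng(18)
    g = rng.binomial(2, 0.5, size=30)
    res = pr.ld_pairwise_test(_two_locus_table(g, np.full(30, 2)), "A", "B", "p1")
    assert res["defined"] is False


def test_ld_pvalues_uniform_for_independent_loci():
    rng = np.random.default_rng(19)
    pvals = []
    while len(pvals) < 200:
        g1 = rng.binomial(2, 0.5, size=90)
        g2 = rng.binomial(2, 0.5, size=90)
        res = pr.ld_pairwise_test(
            _two_locus_table(g1, g2), "A", "B", "p1", n_perm=400, seed=int(rng.integers(1 << 30))
        )
        if res["defined"]:
            pvals.append(res["p_value"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Sequential Bonferroni
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pvals,alpha,expected",
    [
        ([0.01, 0.02, 0.04], 0.05, [True, True, True]),
        ([0.04], 0.05, [True]),
        ([0.03, 0.5], 0.05, [False, False]),  # 0.03 >= 0.05/2 stops the step-down
    ],
)
def test_sequential_bonferroni_step_down(pvals, alpha, expected):
    assert list(pr.sequential_bonferroni(pvals, alpha)) == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_sequential_bonferroni_rejections_form_prefix_of_sorted_pvalues(pvals):
    reject = pr.sequential_bonferroni(pvals, alpha=0.05)
    rejected = sorted(p for p, r in zip(pvals, reject) if r)
    kept = [p for p, r in zip(pvals, reject) if not r]
    if rejected and kept:
        assert max(rejected) <= min(kept)
    for p, r in zip(pvals, reject):
        if r:
            assert p < 0.05  # never rejects above the unadjusted level


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def test_estimated_theta_recovers_generator_truth():
    cfg = SimulationConfig(n_loci=110, sample_sizes=[80] * 12, seed=30)
    truth = pr.simulate_frequencies(cfg)
    table = pr.simulate_genotypes(truth, cfg)
    theta = pr.wc_fst_per_locus(table).theta
    rho = stats.spearmanr(theta, truth.true_theta).statistic
    assert rho >= 0.8
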