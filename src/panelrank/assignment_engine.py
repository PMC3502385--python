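"""Likelihood-based individual assignment and the ORCA assignment simulation.

The empirical path mirrors genetic stock identification practice: estimate a
baseline of Bayesian-smoothed allele frequencies from training individuals,
then assign holdout individuals to the population maximizing the product of
HWE genotype probabilities over panel loci.  The simulated path computes the
probability of correct assignment (f_ORCA) either exactly, by enumerating
multilocus genotypes, or by Monte Carlo with many simulated individuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import MISSING, GenotypeTable, compute_allele_frequencies

__all__ = [
    "Baseline",
    "AssignmentResult",
    "estimate_baseline",
    "posterior_frequencies",
    "genotype_loglik_table",
    "assign_individuals",
    "orca_fcorrect_exact",
    "orca_simulation",
]


@dataclass
class Baseline:
    """Reference collection for assignment: smoothed reference-allele
    frequencies per population x panel locus, guaranteed in (0, 1)."""

    populations: list[str]
    loci: list[str]
    post_freq: np.ndarray

    def __post_init__(self) -> None:
        self.post_freq = np.asarray(self.post_freq, dtype=float)
        if np.any((self.post_freq <= 0) | (self.post_freq >= 1)):
            raise ValueError("baseline frequencies must lie strictly in (0, 1)")


@dataclass
class AssignmentResult:
    per_individual: pd.DataFrame       # id, population, assigned, correct, tie, max_loglik
    per_population: pd.Series          # probability of correct assignment
    overall: float                     # unweighted mean over populations
    n_unassignable: int


def posterior_frequencies(afm_freq: np.ndarray, n_genes: np.ndarray) -> np.ndarray:
    """Dirichlet(1/2, 1/2) posterior-mean smoothing: (x + 0.5) / (n + 1)."""
    x = np.where(n_genes > 0, np.nan_to_num(afm_freq) * n_genes, 0.0)
    return (x + 0.5) / (n_genes + 1.0)


def estimate_baseline(training: GenotypeTable, panel_loci: list[str]) -> Baseline:
    """Baseline from training genotypes restricted to panel loci."""
    if training.n_individuals == 0:
        raise ValueError("empty training table")
    sub = training.subset_loci(panel_loci)
    sizes = sub.population_sizes()
    empty = [p for p, n in sizes.items() if n == 0]
    if empty:
        raise ValueError(f"empty training populations: {empty}")
    afm = compute_allele_frequencies(sub)
    post = posterior_frequencies(afm.freq, afm.n_genes)
    return Baseline(populations=afm.populations, loci=list(panel_loci), post_freq=post)


def genotype_loglik_table(freqs: np.ndarray) -> np.ndarray:
    """(K, L, 3) log HWE genotype probabilities indexed by reference dosage
    0 (hom-alt), 1 (het), 2 (hom-ref).  Zero-probability genotypes get -inf."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    out = np.empty(p.shape + (3,))
    with np.errstate(divide="ignore"):
        out[..., 0] = 2.0 * np.log(q)
        out[..., 1] = np.log(2.0) + np.log(p) + np.log(q)
        out[..., 2] = 2.0 * np.log(p)
    return out


def _credit(loglik: np.ndarray, true_idx: np.ndarray, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractional-credit correctness from an individuals x populations
    log-likelihood matrix: 1/t if the true population is among the t
    maximizers, else 0.  Also returns the order-break argmax and tie flags."""
    m = loglik.max(axis=1, keepdims=True)
    is_max = loglik >= m - atol
    t = is_max.sum(axis=1)
    credit = is_max[np.arange(len(true_idx)), true_idx] / t
    assigned = is_max.argmax(axis=1)  # first maximizer = population input order
    return credit, assigned, t > 1


def assign_individuals(holdout: GenotypeTable, baseline: Baseline) -> AssignmentResult:
    """Assign each holdout individual to the baseline population with the
    highest multilocus HWE log-likelihood.  Missing loci are skipped; exact
    ties are flagged and broken by population input order; individuals with
    no non-missing panel locus are excluded from the probabilities."""
    sub = holdout.subset_loci(baseline.loci)
    table = genotype_loglik_table(baseline.post_freq)  # (K, L, 3)
    calls = sub.calls.astype(int)                      # (N, L)
    observed = calls != MISSING
    safe = np.where(observed, calls, 0)
    # loglik[n, k] = sum over observed loci of table[k, l, g_nl]
    ll_all = table[:, np.arange(sub.n_loci)[None, :], safe]      # (K, N, L)
    ll = np.where(observed[None, :, :], ll_all, 0.0).sum(axis=2).T  # (N, K)

    pops = list(baseline.populations)
    pop_index = {p: k for k, p in enumerate(pops)}
    true_idx = np.array([pop_index[p] for p in sub.populations])
    assignable = observed.any(axis=1)

    _, assigned, tie = _credit(ll, true_idx)
    df = pd.DataFrame(
        {
            "individual": sub.individual_ids,
            "population": sub.populations,
            "assigned": [pops[k] for k in assigned],
            "tie": tie,
            "max_loglik": ll.max(axis=1),
            "assignable": assignable,
        }
    )
    df["correct"] = df["assigned"] == df["population"]
    usable = df[df["assignable"]]
    per_pop = usable.groupby("population", sort=False)["correct"].mean()
    per_pop = per_pop.reindex(pops).dropna()
    return AssignmentResult(
        per_individual=df,
        per_population=per_pop,
        overall=float(per_pop.mean()),
        n_unassignable=int((~assignable).sum()),
    )


# ---------------------------------------------------------------------------
# ORCA: probability of correct assignment from population allele frequencies
# ---------------------------------------------------------------------------


def orca_fcorrect_exact(freqs: np.ndarray, max_genotypes: int = 3**8) -> float:
    """Exact f_ORCA by enumerating all multilocus genotypes.

    ``freqs`` is populations x loci.  For each source population, sums
    P(genotype | source) times the assignment credit (1 if the source
    uniquely maximizes the likelihood, 1/t under a t-way tie); returns the
    unweighted mean over populations.  Only feasible for small panels.
    """
    P = np.asarray(freqs, dtype=float)
    K, L = P.shape
    if 3**L > max_genotypes:
        raise ValueError(
            f"3^{L} genotypes exceed the enumeration limit; use orca_simulation"
        )
    genotypes = np.array(list(itertools.product(range(3), repeat=L)), dtype=int)  # (G, L)
    table = genotype_loglik_table(P)  # (K, L, 3)
    ll = table[:, np.arange(L)[None, :], genotypes].sum(axis=2)  # (K, G)
    m = ll.max(axis=0, keepdims=True)
    is_max = ll >= m - 1e-12
    t = is_max.sum(axis=0)  # (G,)
    prob = np.exp(ll)       # P(g | k); -inf -> 0
    credit = is_max / t
    return float((prob * credit).sum(axis=1).mean())


def orca_simulation(
    freqs: np.ndarray,
    n_reps: int = 500,
    n_individuals: int = 1000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo f_ORCA: per rep, simulate individuals (split as evenly as
    possible over populations, remainder to the first populations), draw HWE
    genotypes from each population's frequencies, assign by maximum
    likelihood against the same frequencies with fractional tie credit.

    Returns the per-rep f_ORCA vector plus mean and quartiles.
    """
    P = np.asarray(freqs, dtype=float)
    K, L = P.shape
    if K < 2:
        raise ValueError("need at least two populations")
    base, rem = divmod(n_individuals, K)
    sizes = np.array([base + (k < rem) for k in range(K)])
    true_idx = np.repeat(np.arange(K), sizes)
    table = genotype_loglik_table(P)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    cols = np.arange(L)[None, :]
    for r in range(n_reps):
        genos = np.concatenate(
            [rng.binomial(2, P[k], size=(sizes[k], L)) for k in range(K)], axis=0
        )
        ll = np.stack([table[k, cols[0], genos].sum(axis=1) for k in range(K)], axis=1)
        credit, _, _ = _credit(ll, true_idx, atol=1e-12)
        reps[r] = credit.mean()
    return {
        "reps": reps,
        "mean": float(reps.mean()),
        "q1": float(np.percentile(reps, 25)),
        "q3": float(np.percentile(reps, 75)),
    }
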