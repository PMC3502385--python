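"""Study orchestration: training/holdout split, five-method locus ranking,
panel construction, empirical and simulated panel evaluation, the drop-off
curve, and the statistical comparisons between rankings and panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assignment_engine import (
    assign_individuals,
    estimate_baseline,
    orca_simulation,
    posterior_frequencies,
)
from .data_model_io import GenotypeTable, compute_allele_frequencies
from .likelihood_rankers import RankerConfig, bels_rank, whichloci_rank
from .locus_metrics import informativeness_in, wc_fst_per_locus
from .pca_ranking import locus_contribution_lc, population_pca

__all__ = [
    "Panel",
    "PanelEvaluation",
    "training_holdout_split",
    "rank_all_methods",
    "build_panels",
    "evaluate_panels",
    "dropoff_curve",
    "compare_rank_lists",
    "compare_panel_scores",
    "mantel_test",
]

RANKING_METHODS = ("fst", "in", "lc", "bels", "whichloci")
DIVERSITY_METHODS = ("fst", "in", "lc")


@dataclass
class Panel:
    """An ordered subset of locus ids with provenance."""

    method: str
    size: int
    loci: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel loci must be distinct")
        if len(self.loci) != self.size:
            raise ValueError("panel size does not match locus count")


@dataclass
class PanelEvaluation:
    panel: Panel
    empirical_per_population: pd.Series
    empirical_mean: float
    forca_reps: np.ndarray
    forca_mean: float
    forca_q1: float
    forca_q3: float


# ---------------------------------------------------------------------------
# Training / holdout split
# ---------------------------------------------------------------------------


def training_holdout_split(table: GenotypeTable, seed: int = 0) -> tuple[GenotypeTable, GenotypeTable]:
    """Per population, a seeded uniform random split into ceil(n/2) training
    and floor(n/2) holdout individuals (the extra individual of an odd-sized
    population goes to training)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    train_rows: list[int] = []
    hold_rows: list[int] = []
    for pop in table.population_order:
        rows = table.individuals_of(pop)
        if len(rows) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        perm = rng.permutation(rows)
        n_train = int(np.ceil(len(rows) / 2))
        train_rows.extend(sorted(perm[:n_train]))
        hold_rows.extend(sorted(perm[n_train:]))
    return table.subset_individuals(np.array(train_rows)), table.subset_individuals(np.array(hold_rows))


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending score -> ascending rank (1 = best); ties by input order."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def rank_all_methods(
    training: GenotypeTable,
    ranker_config: RankerConfig | None = None,
    n_components: int = 5,
    random_rank_seed: int = 0,
) -> pd.DataFrame:
    """Score and rank every locus by F_ST, I_n, LC, BELS and WHICHLOCI on
    the training data, plus the average rank over the five methods and a
    seeded random rank.  Every rank column is a permutation of 1..L."""
    if ranker_config is None:
        ranker_config = RankerConfig()
    afm = compute_allele_frequencies(training)
    L = len(afm.loci)

    theta = wc_fst_per_locus(training).theta
    theta_score = np.where(np.isnan(theta), -np.inf, theta)
    in_score = informativeness_in(afm)

    pca_freqs = afm
    if np.any(np.isnan(afm.freq)):
        warnings.warn("imputing undefined frequencies with locus means for PCA", stacklevel=2)
        filled = np.where(np.isnan(afm.freq), np.nanmean(afm.freq, axis=0), afm.freq)
        pca_freqs = type(afm)(afm.loci, afm.populations, filled, np.maximum(afm.n_genes, 2))
    lc_score = locus_contribution_lc(population_pca(pca_freqs), n_components=n_components)

    post = posterior_frequencies(afm.freq, afm.n_genes)
    wl = whichloci_rank(post, ranker_config)
    bels = bels_rank(post, ranker_config)

    df = pd.DataFrame(
        {
            "locus": afm.loci,
            "fst_score": theta,
            "fst_rank": _scores_to_ranks(theta_score),
            "in_score": in_score,
            "in_rank": _scores_to_ranks(np.asarray(in_score)),
            "lc_score": lc_score,
            "lc_rank": _scores_to_ranks(lc_score),
            "whichloci_score": wl["scores"],
            "whichloci_rank": wl["ranks"],
            "bels_rank": bels["ranks"],
        }
    )
    df["average_rank"] = df[[f"{m}_rank" for m in RANKING_METHODS]].mean(axis=1)
    rng = np.random.default_rng(np.random.SeedSequence([random_rank_seed, 11]))
    df["random_rank"] = rng.permutation(L) + 1
    return df


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


def _top_by_rank(ranks: pd.DataFrame, column: str, size: int) -> list[str]:
    order = ranks.sort_values([column], kind="stable").head(size)
    return list(order["locus"])


def build_panels(
    ranks: pd.DataFrame, sizes: tuple[int, ...] = (48, 96), random_seed: int = 0
) -> list[Panel]:
    """Seven panels per size: top-k for each of the five methods, top-k by
    average rank, and a seeded random k-subset."""
    L = len(ranks)
    panels: list[Panel] = []
    for size in sizes:
        if size > L:
            raise ValueError(f"panel size {size} exceeds {L} available loci")
        for method in RANKING_METHODS:
            panels.append(Panel(method=method, size=size, loci=_top_by_rank(ranks, f"{method}_rank", size)))
        panels.append(Panel(method="average", size=size, loci=_top_by_rank(ranks, "average_rank", size)))
        rng = np.random.default_rng(np.random.SeedSequence([random_seed, 12, size]))
        chosen = rng.choice(L, size=size, replace=False)
        panels.append(
            Panel(method="random", size=size, loci=[ranks["locus"].iloc[i] for i in chosen], seed=random_seed)
        )
    return panels


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _holdout_frequencies(holdout: GenotypeTable, loci: list[str]) -> np.ndarray:
    afm = compute_allele_frequencies(holdout.subset_loci(loci))
    return posterior_frequencies(afm.freq, afm.n_genes)


def evaluate_panels(
    panels: list[Panel],
    training: GenotypeTable,
    holdout: GenotypeTable,
    orca_reps: int = 500,
    orca_individuals: int = 1000,
    seed: int = 0,
) -> list[PanelEvaluation]:
    """Empirical holdout assignment (baseline from training) plus simulated
    f_ORCA from holdout-derived smoothed frequencies for each panel."""
    out: list[PanelEvaluation] = []
    for i, panel in enumerate(panels):
        baseline = estimate_baseline(training, panel.loci)
        empirical = assign_individuals(holdout, baseline)
        sim = orca_simulation(
            _holdout_frequencies(holdout, panel.loci),
            n_reps=orca_reps,
            n_individuals=orca_individuals,
            seed=int(np.random.SeedSequence([seed, 13, i]).generate_state(1)[0] % (2**31)),
        )
        out.append(
            PanelEvaluation(
                panel=panel,
                empirical_per_population=empirical.per_population,
                empirical_mean=empirical.overall,
                forca_reps=sim["reps"],
                forca_mean=sim["mean"],
                forca_q1=sim["q1"],
                forca_q3=sim["q3"],
            )
        )
    return out


def dropoff_curve(
    ranks: pd.DataFrame,
    training: GenotypeTable,
    holdout: GenotypeTable,
    step: int = 5,
    floor: int = 5,
) -> pd.DataFrame:
    """Empirical holdout assignment as the worst average-rank loci are
    dropped ``step`` at a time from the full polymorphic set down to
    ``floor``.  Returns one row per panel size with the mean and 1st/3rd
    quartiles of the per-population correct-assignment probabilities."""
    L = len(ranks)
    if L < floor:
        raise ValueError("fewer loci than the floor size")
    ordered = list(ranks.sort_values(["average_rank"], kind="stable")["locus"])
    sizes = list(range(L, floor - 1, -step))
    if sizes[-1] != floor:
        sizes.append(floor)
    rows = []
    for size in sizes:
        loci = ordered[:size]
        baseline = estimate_baseline(training, loci)
        res = assign_individuals(holdout, baseline)
        probs = res.per_population.to_numpy()
        rows.append(
            {
                "panel_size": size,
                "mean_correct": res.overall,
                "q1": float(np.percentile(probs, 25)),
                "q3": float(np.percentile(probs, 75)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------


def compare_rank_lists(ranks_a, ranks_b) -> dict:
    """Spearman's rho plus a two-sided Wilcoxon signed-rank test of paired
    rank lists (zero differences dropped, per convention)."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rank lists must have equal length")
    rho, rho_p = stats.spearmanr(a, b)
    diffs = a - b
    n_zero = int((diffs == 0).sum())
    if np.all(diffs == 0):
        return {
            "rho": 1.0,
            "rho_p": 0.0,
            "wilcoxon_stat": np.nan,
            "wilcoxon_p": np.nan,
            "wilcoxon_defined": False,
            "n_zero_differences": n_zero,
        }
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return {
        "rho": float(rho),
        "rho_p": float(rho_p),
        "wilcoxon_stat": float(res.statistic),
        "wilcoxon_p": float(res.pvalue),
        "wilcoxon_defined": True,
        "n_zero_differences": n_zero,
    }


def compare_panel_scores(groups: dict[str, np.ndarray], alpha: float = 0.01) -> dict:
    """One-way ANOVA across panels plus Tukey HSD pairwise significance at
    ``alpha``.  Observations are per-population correct probabilities
    (empirical mode) or per-rep f_ORCA values (simulated mode)."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 observations each")
    if all(np.var(a) == 0 for a in arrays):
        return {"anova_F": np.nan, "anova_p": np.nan, "degenerate": True, "tukey": None, "groups": names}
    F, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    n = len(names)
    pmat = pd.DataFrame(tukey.pvalue, index=names, columns=names)
    sig = pd.DataFrame(
        (tukey.pvalue < alpha) & ~np.eye(n, dtype=bool), index=names, columns=names
    )
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "degenerate": False,
        "tukey": pmat,
        "tukey_significant": sig,
        "groups": names,
    }


def mantel_test(matrix_a: np.ndarray, matrix_b: np.ndarray, n_perm: int = 9999, seed: int = 0) -> dict:
    """Mantel test: Pearson correlation of the off-diagonal upper triangles
    with a seeded row/column permutation p-value (one-sided, greater)."""
    A = np.asarray(matrix_a, dtype=float)
    B = np.asarray(matrix_b, dtype=float)
    for M in (A, B):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("matrices must be square")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("matrices must be symmetric")
        if not np.allclose(np.diag(M), 0.0, atol=1e-10):
            raise ValueError("matrices must have zero diagonals")
    if A.shape != B.shape:
        raise ValueError("matrices must have equal dimensions")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = A[iu], B[iu]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "p_value": np.nan, "defined": False}
    def _corr(u: np.ndarray, v: np.ndarray) -> float:
        uc, vc = u - u.mean(), v - v.mean()
        return float(uc @ vc / np.sqrt((uc @ uc) * (vc @ vc)))

    r_obs = _corr(x, y)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 14]))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = B[np.ix_(perm, perm)][iu]
        if _corr(x, yp) >= r_obs - 1e-12:
            count += 1
    return {"r": r_obs, "p_value": (count + 1) / (n_perm + 1), "defined": True}
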