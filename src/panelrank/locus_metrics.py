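"""Per-locus diversity statistics and QC tests.

Implements the Weir & Cockerham (1984) theta estimator of F_ST with its
a/b/c variance components, Rosenberg's informativeness for assignment (I_n),
rarefied allelic richness (FSTAT convention), a 1-df Hardy-Weinberg
chi-square test, a permutation G-test of genotypic linkage disequilibrium,
and Holm's sequential Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data_model_io import (
    HET,
    MISSING,
    AlleleFrequencyMatrix,
    GenotypeTable,
    compute_allele_frequencies,
    observed_het_matrix,
)

__all__ = [
    "WCComponents",
    "wc_components",
    "wc_fst_per_locus",
    "multilocus_fst",
    "pairwise_fst_matrix",
    "informativeness_in",
    "allelic_richness_rarefied",
    "hwe_chisq_test",
    "hwe_chisq_from_counts",
    "ld_pairwise_test",
    "sequential_bonferroni",
]


@dataclass
class WCComponents:
    """WC84 variance components per locus: a (among populations),
    b (among individuals within populations), c (within individuals)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WC84 a, b, c from per-population sample sizes ``n`` (individuals),
    allele frequencies ``p`` and observed heterozygote proportions ``h``.

    Arrays are populations x loci.  Populations with no data at a locus
    (n == 0) are excluded from that locus; loci with fewer than two sampled
    populations, or monomorphic overall, yield NaN components.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    valid = n > 0
    r = valid.sum(axis=0).astype(float)  # populations sampled per locus

    nz = np.where(valid, n, 0.0)
    pz = np.where(valid, p, 0.0)
    hz = np.where(valid, h, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nz.sum(axis=0) / r
        sum_n2 = (nz**2).sum(axis=0)
        nc = (r * nbar - sum_n2 / (r * nbar)) / (r - 1.0)
        pbar = (nz * pz).sum(axis=0) / (r * nbar)
        s2 = (nz * (pz - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (nz * hz).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    # pbar in {0,1} with s2 == 0 means monomorphic overall: theta undefined
    mono = (pbar <= 0) | (pbar >= 1)
    undefined = (r < 2) | (mono & (s2 == 0))
    for arr in (a, b, c):
        arr[undefined] = np.nan
    return a, b, c


def _nph(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    afm = compute_allele_frequencies(table)
    het = observed_het_matrix(table)
    n = afm.n_genes / 2.0
    return n, afm.freq, het


def wc_fst_per_locus(table: GenotypeTable) -> WCComponents:
    """Per-locus WC84 theta (with components) from a genotype table.

    Negative estimates are preserved; a locus monomorphic across all
    populations gets NaN.  Raises if the table has fewer than two
    populations.
    """
    if len(table.population_order) < 2:
        raise ValueError("F_ST requires at least two populations")
    n, p, h = _nph(table)
    a, b, c = wc_components(n, p, h)
    return WCComponents(a=a, b=b, c=c)


def multilocus_fst(table: GenotypeTable, loci: list[str] | None = None) -> float:
    """Ratio-of-sums WC84 estimator over a locus subset:
    sum(a) / sum(a + b + c)."""
    sub = table.subset_loci(loci) if loci is not None else table
    comp = wc_fst_per_locus(sub)
    ok = ~np.isnan(comp.a)
    if not np.any(ok):
        raise ValueError("no locus with defined WC components")
    num = comp.a[ok].sum()
    den = (comp.a + comp.b + comp.c)[ok].sum()
    return float(num / den)


def pairwise_fst_matrix(table: GenotypeTable, loci: list[str] | None = None) -> np.ndarray:
    """Symmetric population x population matrix of multilocus WC84 theta."""
    pops = table.population_order
    K = len(pops)
    if K < 2:
        raise ValueError("need at least two populations")
    M = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            pair = table.subset_populations([pops[i], pops[j]])
            M[i, j] = M[j, i] = multilocus_fst(pair, loci)
    return M


# ---------------------------------------------------------------------------
# Rosenberg's informativeness for assignment
# ---------------------------------------------------------------------------


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def informativeness_in(freqs: AlleleFrequencyMatrix, locus: str | int | None = None) -> np.ndarray | float:
    """Rosenberg's I_n per locus (natural log).

    I_n = sum over the two alleles of [ -pbar*ln(pbar) + mean_i p_i*ln(p_i) ],
    with pbar the unweighted mean frequency over populations and 0*ln 0 = 0.
    Populations with undefined frequency at a locus are excluded; fewer than
    two remaining populations raises.  Returns the full vector when ``locus``
    is None, else a scalar.
    """
    P = freqs.freq
    K, L = P.shape

    def one(l: int) -> float:
        p = P[:, l]
        p = p[~np.isnan(p)]
        if len(p) < 2:
            raise ValueError(f"locus {freqs.loci[l]!r}: <2 populations with defined frequency")
        val = 0.0
        for q in (p, 1.0 - p):
            qbar = q.mean()
            val += -float(_xlogx(np.array([qbar]))[0]) + float(_xlogx(q).mean())
        return max(val, 0.0)  # clamp tiny negative rounding

    if locus is None:
        return np.array([one(l) for l in range(L)])
    l = locus if isinstance(locus, int) else freqs.locus_index(locus)
    return one(l)


# ---------------------------------------------------------------------------
# Rarefied allelic richness (FSTAT convention)
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness_rarefied(
    table: GenotypeTable, locus: str, g: int | None = None
) -> dict[str, float]:
    """Rarefied allelic richness per population at one locus.

    A_r = sum over alleles of 1 - C(n - count_a, g) / C(n, g), with n the
    population's non-missing gene copies.  ``g`` defaults to the smallest n
    across populations at the locus (must be >= 2 and <= every n).
    """
    afm = compute_allele_frequencies(table)
    l = afm.locus_index(locus)
    n = afm.n_genes[:, l]
    if g is None:
        valid = n[n > 0]
        if len(valid) == 0:
            raise ValueError(f"locus {locus!r}: no data in any population")
        g = int(valid.min())
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    out: dict[str, float] = {}
    for k, pop in enumerate(afm.populations):
        nk = int(n[k])
        if nk == 0:
            out[pop] = float("nan")
            continue
        if g > nk:
            raise ValueError(f"g={g} exceeds n_genes={nk} in population {pop!r}")
        ref = round(afm.freq[k, l] * nk)
        richness = 0.0
        for count in (ref, nk - ref):
            if nk - count >= g:
                prob_absent = float(np.exp(_log_comb(nk - count, g) - _log_comb(nk, g)))
            else:
                prob_absent = 0.0
            richness += 1.0 - prob_absent
        out[pop] = richness
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg chi-square
# ---------------------------------------------------------------------------


def hwe_chisq_from_counts(hom_ref: int, het: int, hom_alt: int) -> dict:
    """1-df chi-square HWE test from genotype counts.

    Returns statistic, p-value and het direction ('excess', 'deficit' or
    None at exact equilibrium); monomorphic samples get an undefined flag.
    """
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no non-missing genotypes")
    p = (2 * hom_ref + het) / (2 * n)
    if p in (0.0, 1.0):
        return {"chi2": np.nan, "p_value": np.nan, "direction": None, "defined": False}
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([hom_ref, het, hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    direction = None
    if het > expected[1]:
        direction = "excess"
    elif het < expected[1]:
        direction = "deficit"
    return {
        "chi2": chi2,
        "p_value": float(stats.chi2.sf(chi2, df=1)),
        "direction": direction,
        "defined": True,
    }


def hwe_chisq_test(table: GenotypeTable, locus: str, population: str) -> dict:
    """HWE chi-square for one locus in one population sample."""
    sub = table.subset_populations([population]).subset_loci([locus])
    col = sub.calls[:, 0]
    obs = col[col != MISSING]
    if len(obs) == 0:
        raise ValueError(f"no non-missing genotypes at {locus!r} in {population!r}")
    return hwe_chisq_from_counts(int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))


# ---------------------------------------------------------------------------
# Linkage disequilibrium: genotypic permutation G-test
# ---------------------------------------------------------------------------


def _g_statistic(counts: np.ndarray) -> np.ndarray:
    """G = 2 sum O ln(O/E) for stacked 3x3 tables (leading axes arbitrary)."""
    counts = counts.astype(float)
    row = counts.sum(axis=-1, keepdims=True)
    col = counts.sum(axis=-2, keepdims=True)
    total = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = row * col / total
        ratio = np.where(counts > 0, counts / expected, 1.0)
        terms = counts * np.log(ratio)
    return 2.0 * terms.sum(axis=(-2, -1))


def ld_pairwise_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    population: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation G-test of genotypic association between two loci within
    one population.  Individuals missing at either locus are dropped; the
    3x3 genotype table's G statistic is compared with its distribution under
    seeded permutations of one locus's genotypes."""
    sub = table.subset_populations([population]).subset_loci([locus_a, locus_b])
    ga, gb = sub.calls[:, 0], sub.calls[:, 1]
    keep = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[keep].astype(int), gb[keep].astype(int)
    if len(ga) < 5:
        raise ValueError("need at least 5 individuals non-missing at both loci")
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        return {"G": np.nan, "p_value": np.nan, "defined": False, "n": int(len(ga))}

    def table33(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.bincount(3 * a + b, minlength=9).reshape(3, 3)

    g_obs = float(_g_statistic(table33(ga, gb)))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ga, (n_perm, 1)), axis=1)  # (n_perm, n)
    codes = 3 * perms + gb  # broadcasts gb over rows
    counts = (codes[:, :, None] == np.arange(9)).sum(axis=1).reshape(n_perm, 3, 3)
    g_perm = _g_statistic(counts)
    p = (1 + int((g_perm >= g_obs - 1e-12).sum())) / (n_perm + 1)
    return {"G": g_obs, "p_value": float(p), "defined": True, "n": int(len(ga))}


# ---------------------------------------------------------------------------
# Sequential Bonferroni (Holm)
# ---------------------------------------------------------------------------


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down: sort ascending, reject while p_(k) < alpha/(m-k+1),
    stop at the first non-rejection.  Returns a boolean rejection mask in the
    original order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order, start=1):
        if p[idx] < alpha / (m - k + 1):
            reject[idx] = True
        else:
            break
    return reject
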