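"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (plain-Python
loops over genotype counts) so they share no code path with the package.
"""

from __future__ import annotations

import math


def wc_theta_direct(pop_genotypes: list[list[int]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c evaluated directly from per-population
    lists of reference-allele dosages (0/1/2), plain Python arithmetic."""
    pops = [g for g in pop_genotypes if len(g) > 0]
    r = len(pops)
    if r < 2:
        raise ValueError("need two populations with data")
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def rosenberg_in_direct(freqs: list[float]) -> float:
    """Rosenberg's I_n for a biallelic locus from population frequencies."""
    K = len(freqs)
    total = 0.0
    for allele in (freqs, [1 - p for p in freqs]):
        pbar = sum(allele) / K
        term = -(pbar * math.log(pbar)) if pbar > 0 else 0.0
        for p in allele:
            if p > 0:
                term += p * math.log(p) / K
        total += term
    return total
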