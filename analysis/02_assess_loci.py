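#!/usr/bin/env python
"""Locus and population QC on the exported benchmark dataset.

Reads the Genepop export, applies the missingness (>10%) and monomorphic
filters, then computes the standard assessment battery: per-locus F_ST and
heterozygosities, HWE chi-square with sequential Bonferroni correction,
rarefied allelic richness, linkage disequilibrium for a locus subset,
pairwise F_ST between all population pairs, and a six-axis principal
coordinate analysis of that matrix.
"""

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

import panelrank as pr
from panelrank.data_model_io import observed_het_matrix
from panelrank.locus_metrics import hwe_chisq_from_counts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    regions = pr.read_region_map(OUT / "benchmark_regions.csv")
    table = pr.read_genepop(OUT / "benchmark.gen")
    # Genepop carries no population names; re-attach labels by file order
    order = table.population_order
    truth_regions = {order[i]: r for i, (p, r) in enumerate(regions.items())}
    table.regions = truth_regions
    table = pr.filter_monomorphic_loci(pr.filter_individuals_by_missingness(table))
    print(f"after filters: {table.n_individuals} individuals, {table.n_loci} loci")

    afm = pr.compute_allele_frequencies(table)
    comp = pr.wc_fst_per_locus(table)
    het = observed_het_matrix(table)
    stats_df = pd.DataFrame(
        {
            "locus": table.locus_ids,
            "Ho_pooled": np.nanmean(het, axis=0),
            "He_pooled": np.nanmean(2 * afm.freq * (1 - afm.freq), axis=0),
            "fst": comp.theta,
            "In": pr.informativeness_in(afm),
        }
    )
    stats_df.to_csv(OUT / "locus_stats.csv", index=False)
    print(f"mean per-locus F_ST: {np.nanmean(comp.theta):.4f}")

    # HWE per locus x population with Holm correction within populations
    hwe_rows = []
    for pop in table.population_order:
        sub = table.subset_populations([pop])
        for l, locus in enumerate(table.locus_ids):
            col = sub.calls[:, l]
            obs = col[col != -1]
            res = hwe_chisq_from_counts(int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
            if res["defined"]:
                hwe_rows.append({"population": pop, "locus": locus, "p": res["p_value"]})
    hwe = pd.DataFrame(hwe_rows)
    hwe["reject"] = False
    for pop, grp in hwe.groupby("population"):
        hwe.loc[grp.index, "reject"] = pr.sequential_bonferroni(grp["p"].to_numpy(), 0.05)
    hwe.to_csv(OUT / "hwe_tests.csv", index=False)
    print(f"HWE departures after sequential Bonferroni: {int(hwe['reject'].sum())}")

    # allelic richness averaged over loci per population
    rich = {p: [] for p in table.population_order}
    for locus in table.locus_ids:
        for p, v in pr.allelic_richness_rarefied(table, locus).items():
            rich[p].append(v)
    richness = pd.Series({p: np.nanmean(v) for p, v in rich.items()}, name="mean_allelic_richness")
    richness.to_csv(OUT / "allelic_richness.csv")
    print(f"mean allelic richness range: {richness.min():.3f}-{richness.max():.3f}")

    # LD for the first 10 loci in the first population (illustrative subset)
    pop0 = table.population_order[0]
    ld_rows = [
        {"locus_a": a, "locus_b": b, **pr.ld_pairwise_test(table, a, b, pop0, n_perm=500, seed=1)}
        for a, b in itertools.combinations(table.locus_ids[:10], 2)
    ]
    pd.DataFrame(ld_rows).to_csv(OUT / "ld_tests.csv", index=False)

    # pairwise F_ST and its PCoA
    M = pr.pairwise_fst_matrix(table)
    pd.DataFrame(M, index=table.population_order, columns=table.population_order).to_csv(
        OUT / "pairwise_fst.csv"
    )
    coords = pr.pcoa(np.sqrt(np.maximum(M, 0)), n_axes=6)
    pd.DataFrame(
        coords.coordinates,
        index=table.population_order,
        columns=[f"axis{i+1}" for i in range(coords.coordinates.shape[1])],
    ).to_csv(OUT / "pcoa_coordinates.csv")
    share = coords.proportion_variance[0] * 100
    print(f"PCoA axis 1 explains {share:.1f}% of positive-eigenvalue variance")


if __name__ == "__main__":
    main()
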