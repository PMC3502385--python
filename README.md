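# panelrank

Rank biallelic SNPs for individual population assignment and measure what a
fixed-size panel of the top-ranked loci actually buys you.

Fisheries and conservation labs that manage strongly philopatric species
(the motivating system is sockeye salmon sampled across the North Pacific)
must often assign an individual fish back to its population of origin from
a limited genotyping budget — 48 or 96 assays on the array platforms in
common use. Given diploid biallelic genotypes for a baseline of populations
grouped into regional pairs, `panelrank` scores every locus with five
ranking measures, assembles top-*k* panels, and evaluates each panel by
empirical holdout assignment and by assignment simulation.

## Methods at the core

* **F_ST (θ̂)** — Weir & Cockerham's (1984) variance-component estimator,
  θ̂ = a/(a+b+c), per locus and as a ratio-of-sums multilocus estimate.
* **I_n** — Rosenberg's informativeness for assignment,
  I_n = Σ_j [−p̄_j ln p̄_j + Σ_i p_ij ln p_ij / K], natural log.
* **LC** — a locus's average share of the inertia of the first five
  principal components of the populations × loci allele-frequency matrix
  (Moazami-Goudarzi & Laloë's locus-contribution measure).
* **WHICHLOCI-style jackknife ranking** — a locus's score is the mean
  assignment accuracy lost when it is dropped from the panel.
* **BELS-style backward elimination** — iteratively discard the locus whose
  removal leaves the highest assignment accuracy; rank is reverse removal
  order.
* **Assignment** — maximum-likelihood genetic stock identification: an
  individual goes to the population maximizing Σ log P(genotype | HWE, p̂),
  with baseline frequencies smoothed as (x + ½)/(n + 1).
* **f_ORCA** — the probability of correct assignment of simulated
  individuals, computed exactly by genotype enumeration for small panels or
  by Monte Carlo (500 reps × 1000 individuals) for real ones.

A hierarchical Balding–Nichols generator (`panelrank.synthetic_data`)
produces surveys with known per-locus differentiation — by default 12
populations in 6 regional pairs, 61–93 individuals each, 110 polymorphic
loci, drift calibrated so the mean per-locus F_ST is 0.114 — so the whole
pipeline runs end to end with ground truth and no external data.

## Worked example

```python
import panelrank as pr

table, truth, config = pr.benchmark_dataset()          # seeded benchmark survey
table = pr.filter_monomorphic_loci(pr.filter_individuals_by_missingness(table))
training, holdout = pr.training_holdout_split(table, seed=1)

ranks = pr.rank_all_methods(training, pr.RankerConfig(sim_pop_size=50, iterations=12, seed=1))
panels = pr.build_panels(ranks, sizes=(48, 96), random_seed=1)
evals = pr.evaluate_panels(panels, training, holdout, seed=1)
for ev in evals[:2]:
    print(ev.panel.method, ev.panel.size, round(ev.empirical_mean, 3), round(ev.forca_mean, 3))
```

On the benchmark this prints, for the F_ST-ranked 48-SNP panel and its
neighbours (numbers from `analysis/04_evaluate_panels.py`):

```
fst 48 0.901 0.933
in  48 0.885 0.932
```

i.e. 90% of holdout individuals assign back to their true population with
the 48 top-F_ST loci, and simulated (noise-free) individuals assign
correctly 93% of the time. The 96-SNP panels reach 0.96/0.99, the random
48-SNP panel only 0.84/0.90 — larger panels help, and ranked panels beat
random ones.

The numbered scripts under `analysis/` run the full study in order:
simulate and export the survey (`01`), locus QC — HWE, allelic richness,
linkage disequilibrium, pairwise F_ST, PCoA (`02`), five-method ranking on
the training half (`03`), panel building and two-mode evaluation with
ANOVA/Tukey comparisons (`04`), and the locus drop-off curve (`05`). Each
writes its tables under `results/`.

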