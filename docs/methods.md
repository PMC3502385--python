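# Methods

## The problem and the pipeline

`panelrank` evaluates how well subsets ("panels") of biallelic SNPs resolve
the population of origin of individual diploids. The pipeline is: filter
the genotype table (individuals missing >10% of calls; loci monomorphic
everywhere), split each population at random into a training half (the
extra individual of an odd-sized population goes to training) and a holdout
half, rank loci on the training half only, build top-*k* panels, and score
each panel twice — by assigning real holdout individuals against a
training-set baseline, and by simulating individuals from holdout allele
frequencies and assigning them back (f_ORCA). The split is the bias
control: no ranking decision ever sees holdout data, so panel scores are
not inflated by selecting loci on the same individuals used to test them.

## Ranking measures

Three diversity measures are computed from per-population reference-allele
frequencies:

* **θ̂ (Weir & Cockerham 1984)** with the full a/b/c variance components
  from sample sizes, allele frequencies and *observed* heterozygote
  frequencies. Negative estimates are retained (clamping would create mass
  ties among low-information loci); loci monomorphic overall are flagged
  undefined and sort last. The multilocus and pairwise-population versions
  use the ratio-of-sums estimator Σa / Σ(a+b+c).
* **I_n (Rosenberg)** with natural logs and 0·log 0 ≡ 0; the unweighted
  mean frequency across populations plays the role of the "average
  population". Tiny negative rounding is clamped to 0.
* **LC**: PCA of the populations × loci frequency matrix, column-centered
  and unscaled (frequencies share a scale; a correlation-matrix switch
  exists). One column per locus — the alternate-allele column of a
  biallelic locus is perfectly anticorrelated and would double-count. A
  locus's contribution to an axis is its squared unit loading, so per-axis
  contributions sum to 1; LC is the unweighted mean over the first five
  axes (all available axes, with a warning, when fewer exist; zero-eigenvalue
  axes are excluded).

Two performance-based rankers are **re-derivations from the operational
description** of the WHICHLOCI and BELS programs, not ports; their exact
internal objectives (e.g. WHICHLOCI's false-assignment penalty) are not
recoverable here, and the jackknife accuracy loss is used as the operative
score for both.

* The jackknife ranker simulates `sim_pop_size` individuals per population
  (default 200) from Dirichlet-smoothed frequencies for `iterations` reps
  (default 250), assigns them by maximum likelihood with fractional tie
  credit, and scores each locus as full-panel accuracy minus
  leave-that-locus-out accuracy. **Common random numbers** — the same
  simulated individuals across the full panel and every leave-one-out
  variant, implemented by subtracting per-locus log-likelihood
  contributions — make the score of a locus with identical frequencies in
  all populations *exactly* zero and keep mid-rank differences meaningful
  at moderate iteration counts. WHICHLOCI mode additionally reports the
  smallest rank-prefix panel whose accuracy reaches `min_correct`
  (default 95%), evaluated with an independent seed.
* The backward-elimination ranker repeats, per round with fresh common
  random numbers: evaluate accuracy after each candidate removal, discard
  the locus whose removal leaves the highest accuracy (ties broken by locus
  input order, which is recorded). Rank is reverse removal order; the full
  removal trace is returned so the known failure mode — arbitrary mid-ranks
  once accuracy saturates near a 100% target — is inspectable. Input-order
  sensitivity is confined to loci whose jackknife scores are within
  Monte-Carlo noise of each other.

## Assignment model

The baseline frequency is the Dirichlet(½, ½) posterior mean
(x + ½)/(n + 1) per population × locus — strictly inside (0, 1), so every
log-likelihood is finite. An individual's log-likelihood for population k
sums log HWE genotype probabilities (p², 2pq, q²) over its non-missing
panel loci; it is assigned to the argmax. Exact ties are flagged and broken
by population input order in the empirical path (a fish must be assigned
somewhere) and split as fractional credit (1/t across t maximizers) in the
exact and simulated paths. Simulated individuals are allocated as evenly as
possible across populations, the remainder going to the first populations
in order, matching f_ORCA's definition as an unweighted mean over
populations. The original assignment software delegates its smoothing
constant to an unpublished internal choice; the (x+½)/(n+1) posterior mean
is this package's documented stand-in and the main tool-fidelity gap.

## Synthetic data generator

The generator is a two-level Balding–Nichols hierarchy chosen for analytic
control of per-locus differentiation at desk scale (no genealogies are
needed, only differentiated frequencies): ancestral p₀ ~ Uniform(0.05,
0.95); regional p_r ~ Beta(p₀(1−F_R)/F_R, (1−p₀)(1−F_R)/F_R); population
p_k likewise with F_P. Defaults emulate the benchmark survey design: 6
regions × 2 populations, 110 loci (114 with 4 planted monomorphic in the
benchmark scenario), 61–93 individuals per population drawn uniformly, 1%
missing calls at random, and (F_R, F_P) scaled by bisection — ratio fixed
at 2:1 so between-region divergence exceeds within-pair divergence — until
the implied mean per-locus θ hits the 0.114 target within ±0.02.
Genotypes are HWE binomial draws; optional outlier loci multiply F_P
(default ×4, capped below 1) to mimic directionally selected markers. The
`TruthRecord` carries `true_theta`, the large-sample θ implied by the
realized population frequencies — the meaningful per-locus ground truth for
parameter-recovery checks, since the drift *parameter* is constant across
non-outlier loci. The benchmark seed is 20121120.

What the generator does **not** emulate: linkage between loci, ascertainment
bias, genotyping-error structure, or DNA-quality variation among
individuals (missingness is i.i.d.). Passing tests therefore demonstrate
correctness of the statistics and the pipeline's contracts on idealized
HWE data, not field performance on degraded tissue samples; empirical
accuracies on the benchmark run higher than one should expect of real
surveys.

## Numerical and design choices

* Missingness threshold is strict: an individual missing *exactly* 10% of
  loci is retained.
* Reference allele = numerically smaller Genepop code; θ, I_n and LC are
  orientation-invariant, so this is cosmetic. Genepop round-trips are
  lossless for calls, locus order and population order (2- and 3-digit
  dialects); regions travel in a `population,region` sidecar CSV because
  Genepop has no region concept.
* Score-to-rank conversion: descending score, ties by locus input order
  (recorded), so every rank column is a permutation of 1..L. The random
  panel uses its own named seed; random panels of different sizes are
  independent draws.
* Holm's sequential Bonferroni uses the strict `p < α/(m−k+1)` step-down.
* The genotypic LD test replaces the Markov-chain exact test of the
  standard software with a seeded permutation G-test on the 3×3 genotype
  table — same null, reproducible.
* PCoA is classical MDS (double-centering + eigendecomposition); negative
  eigenvalues are reported and their axes dropped. The Mantel test permutes
  rows/columns with a seeded generator (one-sided, greater).
* ANOVA observational units: per-population correct probabilities in
  empirical mode (12 per panel) versus per-rep f_ORCA in simulated mode
  (500 per panel). This asymmetry structurally reproduces the
  empirical-mode pattern of greater variance and fewer significant Tukey
  contrasts.
* f_ORCA computed from *estimated* (holdout) frequencies is upward-biased
  for weakly informative panels: sampling noise in the frequency estimates
  acts as apparent signal. The exact-enumeration path with known
  frequencies is the unbiased reference and the simulation converges to it.
* Ranker resampling sizes are configurable; the analysis scripts and the
  acceptance script run the likelihood rankers at 50 simulated individuals
  per population and 8–16 iterations, problem sizes chosen so a full
  110-locus backward elimination completes in seconds while common random
  numbers keep the planted-signal ordering stable. Panel evaluation keeps
  the full 500 × 1000 simulation.

## Known limitations

* WHICHLOCI's separate false-assignment penalty and BELS's mixture-
  proportion objective are not implemented (the latter is out of scope by
  design, as is coalescent-based outlier detection; outlier effects are
  supported generically by recomputing F_ST on locus subsets).
* The exact f_ORCA enumerator is limited to panels of ~8 loci (3^L
  genotypes); larger panels must use the Monte-Carlo path.
* Rarefied allelic richness reconstructs allele counts from frequencies and
  gene-copy numbers; it assumes the table's calls are integral dosages
  (always true for data read or simulated by this package).
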