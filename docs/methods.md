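# Methods

This note documents the models, estimators and design choices behind
`introgress-panel`, and what the synthetic experiments do and do not show
about real data.

## Data model

Genotypes are haploid biallelic calls: 0 (reference), 1 (alternate) or
missing. VCF input accepts haploid GT ("0", "1", ".") and
homozygous-diploid GT ("0/0", "1|1"), which variant callers often emit for
haploid males; the two alleles are collapsed to one. Heterozygous diploid
GT is rejected — a true haploid cannot be heterozygous, so such a call
indicates a sample or caller problem. Missing is a distinct sentinel and is
never treated as reference. VCF coordinates are 1-based inclusive;
everything internal (recombination-map windows, ancestry tracts, BED
output) is 0-based half-open, with conversions confined to `core_io`.

## Weir–Cockerham θ for haploid samples

Each haploid individual contributes one allele, so the two-population
(r = 2) variance-components estimator is applied directly to allele
indicators rather than to diploid genotypes:

    p̄   = (n1 p1 + n2 p2) / (n1 + n2)
    MSP = n1 (p1 − p̄)² + n2 (p2 − p̄)²                      [/(r−1), r=2]
    MSG = [n1 p1 (1−p1) + n2 p2 (1−p2)] / (n1 + n2 − 2)
    n_c = (n1 + n2) − (n1² + n2²)/(n1 + n2)
    θ   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

The haploid form matters for the fixed-SNP criterion: when the two
populations are fixed for opposite alleles, MSG = 0 and θ = 1 exactly, so
fixed SNPs are detected on integer allele counts with no floating-point
tolerance. Loci where both populations are fixed for the *same* allele
have a zero denominator and are reported as undefined (NaN) and excluded
from genomewide summaries — they are not counted as θ = 0. The estimator
is validated against a brute-force ANOVA on raw allele indicators
(agreement to 1e−12 over random configurations) and cross-checked against
Hudson's 1 − H<sub>w</sub>/H<sub>b</sub> on strongly diverged loci.

The genomewide summary is the ratio of sums Σ(MSP − MSG)/Σ(MSP +
(n_c − 1)MSG) over defined loci (the "weighted" average standard tooling
prints); the unweighted mean of per-locus θ is also reported and is
typically lower, since low-information loci contribute small or negative
ratios.

## Synthetic data

The generator emulates the population structure the workflow targets, not
any particular genome:

* **Divergence.** Per locus, an ancestral frequency p ~ Uniform(0.05,
  0.95) (avoiding loci monomorphic in the ancestor); each lineage draws
  its frequency from the Balding–Nichols law Beta(p(1−F)/F, (1−p)(1−F)/F)
  with drift parameter F = `divergence_F_MC`. The default F = 0.531 was
  fixed once by bisecting the realized genomewide ratio-of-sums θ of probe
  simulations (`calibrate_divergence`) against a target of 0.532, the
  observed M-vs-C lineage divergence; realized values at the default
  configuration land near 0.53–0.55.
* **Internal cline.** Within the focal population, two subcluster
  frequency vectors are drawn around the lineage frequency with a smaller
  drift parameter `cline_F` (default 0.08; the real within-population
  differentiation level is not published, so this is a free parameter).
  Each focal individual sits at a coordinate x ∈ [0, 1] and draws alleles
  from the mixture weighted by a logistic profile in x (steepness 10),
  mimicking a sharp geographic cline. Region tags are rectangular zones of
  x (PT < 0.25 ≤ CT < 0.5 ≤ MT < 0.75 ≤ AT), with "IP" denoting the whole
  range; PT thereby plays the role of a country-restricted sample at one
  cline end.
* **Annotations.** Effect classes are categorical draws (default intron
  0.42, intergenic 0.23, remainder spread over synonymous/UTR/missense/
  splice/other, approximating the observed composition of M–C fixed-SNP
  sets); flank variable-nucleotide counts and N-run lengths are Poisson
  (means 1.5 and 0.8), multimap/repeat flags Bernoulli (0.05 each) —
  rates chosen so that the flank filters remove a visible but minor
  fraction, as in real assay design.
* **Missingness** is uniform at rate 0.014, matching a genotyping rate of
  0.986.

Default sample sizes are 50 focal + 30 reference (20,000 loci) for
experiments, and 117 + 59 in the end-to-end pipeline so the 25% holdout
split yields the 29 + 15 individuals the hybrid design consumes.

What the generator does **not** model: linkage disequilibrium between loci
(frequencies are independent per locus), selection, mutation, and real
chromosome-scale heterogeneity in marker density or recombination rate.
Consequently, passing tests show that the estimators and the design
cascade behave correctly under the intended population structure; they do
not certify performance on LD-structured real genomes, where 5 kb thinning
interacts with true LD decay.

## Sampling-bias experiments

Subsets are drawn without replacement; each (size, replicate) or region
cell has its own named seed substream, so enlarging the experiment never
changes earlier draws. False positives are computed set-wise
(subset-fixed minus full-fixed) rather than by subtracting totals: with
missing data a locus can be scannable in the subset but undefined in the
full scan, and plain subtraction would miscount. On complete-case data the
subtraction identity holds and is asserted in tests. Per-size confidence
intervals are t-based across replicates. Whether replicates should share
individuals across sizes is not specified anywhere; independent draws are
used.

## Panel design

* **Split.** Training/holdout is stratified by population label with
  per-stratum arithmetic rounding of the holdout fraction, which
  reproduces the canonical 117 + (28 + 31) → 29 + (7 + 8) split at 25%.
* **Thinning.** The < 5,000 bp filter is implemented as a deterministic
  left-to-right sweep per chromosome with a retained-locus stack: on a
  conflict the higher-priority locus wins (priority 1 = 3′UTR, 5′UTR,
  missense, splice donor, splice region; synonymous is deliberately not
  counted functional), ties keep the lower position, and a displaced stack
  top triggers re-checking against the remaining stack. The output
  provably contains no pair closer than 5 kb and is maximal (every dropped
  locus conflicts with a retained one). A distance threshold and a
  retention preference do not by themselves pin down an algorithm; the
  greedy sweep was chosen for determinism and auditability.
* **Flank filters.** A locus is removed iff variable-left > 5 OR
  variable-right > 5 OR N-run > 5 OR multimap OR repeat, with removal
  counts attributed to the first failing rule in that order. Boundary
  semantics are strict ("> 5"): a count of exactly 5 is retained.
* **Multiplex assembly.** Greedy and seeded: one compatible SNP per
  chromosome first (skipping chromosomes with an empty pool — a warning,
  not an error, since real assays sometimes lack a chromosome), then
  functional SNPs up to the quota of 4, then random fill to 40. Chosen
  SNPs leave the pool before the next panel, so panels are disjoint by
  construction. Instrument chemistry (hairpin/dimer interactions) enters
  only through a pluggable `compat(locus, selected)` predicate defaulting
  to accept-all; panel sizes therefore default to the 40-SNP maximum
  rather than instrument-driven sizes like 37/38/40/38.
* **Random assays** draw uniformly from the *full* SNP set (not the fixed
  set), mutually disjoint, size-matched to the designed panels.

## Hybrid simulation

Crossovers per chromosome are Poisson with mean equal to the genetic length
in Morgans (Σ rate·window/100/10⁶); positions are placed by inverse-CDF
sampling on the cumulative genetic map, so breakpoints concentrate in
high-rate windows. No crossover interference and no obligate chiasma are
modelled — the upstream tool this emulates does not state a model, and
plain Poisson is the neutral choice. F1 haplotypes recombine one pure M
with one pure C genome; BC1 haplotypes recombine an F1 *realized mosaic*
(not an idealized 50/50 parent) with a fresh pure M genome, consuming F1s
in creation order; every parental genome is used exactly once so hybrids
are unrelated. True ancestry is emitted both as per-locus and per-bp
C-fractions (expected 0.5 for F1, 0.25 for BC1) and as BED tracts, so
validation can use either simulated truth or whole-genome estimates.

## Admixture EM

The haploid likelihood treats each observed allele as Bernoulli with
success probability π<sub>ij</sub> = Σ<sub>k</sub> q<sub>ik</sub>
f<sub>kj</sub>. This differs from the diploid binomial of standard
admixture software, but for K = 2 and complete data the maximizers
coincide; haploid inputs coded diploid simply double every term. EM
updates are the classic responsibility averages, implemented as matrix
products (no n×L×K intermediates), monotone in the log-likelihood
(asserted to 1e−8 in tests). Numerical guards: cluster frequencies are
clamped to [1e−6, 1 − 1e−6]; all-missing loci are dropped; an all-missing
sample keeps a uniform Q row. Stopping: Δℓ < 1e−4 (the conventional
default); initialization is Q ~ Dirichlet(1), F = observed frequencies
with ±0.1 jitter, best of 5 restarts — the exact initialization of the
reference software is not public, so restarts stand in for it.

The supervised mode fixes the two cluster frequency vectors from labelled
pure training samples and maximizes the same likelihood over the single
ancestry parameter by bounded 1-D optimization (tolerance 1e−8); it serves
as the whole-genome "truth" in the pipeline and as an independent
cross-check of the unsupervised fit (they agree at r > 0.999 on fixed-
marker data).

Bootstrap SEs resample loci with replacement, refit from the point
estimate (fast, few iterations), and align cluster labels per replicate by
L1 distance between bootstrap and point-estimate frequency vectors before
accumulating — without alignment, label switching would inflate the SEs.
Label switching in reporting is resolved once, by naming the cluster with
the higher mean Q among labelled C-lineage references "C"; purity calls
use strict thresholds (pure-M: C-ancestry < 0.05; pure-C: > 0.95).

## Validation metrics

Accuracy is the mean over individuals of 100·(1 − |error|), computed in
the algebraically equal form 100·(1 − mean error) so the identity
accuracy = 100 − 100·mean-error holds exactly in floating point. Pearson r
carries a Fisher-z 95% CI and is NA (with a warning) for constant vectors.
Misclassification counts apply the same 0.05/0.95 thresholds to the truth
and the estimate, both directions (true-pure called hybrid, true-hybrid
called pure), over both holdout individuals and simulated hybrids.

## Pipeline and problem sizes

The end-to-end pipeline runs, in order: simulation → purity screen →
split → training F_ST scan and fixed-SNP selection → thinning and flank
filters → multiplex and random-assay assembly → hybrid simulation →
whole-genome reference Q → per-panel validation → bias scans. A single
master seed spawns named per-stage substreams, every stage writes its
artifacts (VCF/TSV/BED/JSON), and the run log records per-stage counts, so
any reported number is recomputable from the intermediates.

The purity screen runs the unsupervised EM on a random subsample of 3,000
loci: ancestry signal at that density is already overwhelming for
structure screening, and the package's reference Q for validation comes
from the supervised estimate on *all* loci. Desk-scale defaults (20,000
loci, 176 + 29 samples, 200 bootstrap replicates) complete in about three
minutes on one CPU; the test suite uses smaller configurations (2,000 to
12,000 loci) chosen to keep each property detectable with wide margins.

## Known limitations

* No LD in the generator (see above); distance thinning is exercised
  mostly on sparse synthetic maps where conflicts are rare.
* The multiplex compatibility predicate defaults to accept-all; real
  assay-design chemistry can only be reproduced by plugging in an external
  predicate.
* K > 2 fits run, but orientation, supervised mode and purity
  classification are defined for K = 2.
* The recombination map in the pipeline is uniform by default; windowed
  empirical maps are supported through `read_recomb_map` but none ships
  with the package.
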