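# Methods

## Scope and model

`panselect` analyses phased haplotype panels: for each gene and population
an alignment of n chromosomes plus one outgroup sequence. All inference is
frequency-spectrum based under the infinite-sites idealisation — every
retained biallelic column is treated as one mutation (η = S). Columns are
filtered before anything else: a gap anywhere makes a column an indel,
more than two nucleotide alleles makes it triallelic-plus, and any missing
call excludes the column wholesale (complete-case per site). The
complete-case rule keeps one fixed n per gene, so the variance constants
of the tests (all functions of n) are well defined; the per-column
effective sample size is still recorded for audit. Triallelic columns are
never re-split into biallelic pairs.

Polarization uses the outgroup allele: where it matches one of the two
segregating alleles the other is derived; a gap, missing base or third
allele leaves the column unpolarized — kept for folded statistics, dropped
from derived-allele statistics. Singleton bookkeeping follows the tests'
definitions: the starred Fu & Li tests use folded singletons (minor count
1), the unstarred tests use derived singletons (external mutations).

## Statistics

* π is reported per analyzed site (monomorphic + biallelic columns after
  filtering); the locus-level π used inside the test statistics is the
  mean pairwise difference count, computed from the minor-allele counts as
  Σ k(n−k)/C(n,2). An exact identity test asserts this equals direct
  pairwise comparison.
* Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).
* Fu & Li's D, F, D*, F* use the corrected variance constants (the
  published errata forms). Correctness is established against a
  hand-worked n = 4 example (derived counts {1,1,2,3}) and against
  neutral-simulation means, not against any particular program's output.
* The normalized Fay & Wu's H follows the Zeng-style normalization:
  θ_π − θ_L over its estimated standard deviation, with θ̂ = S/a₁ and
  θ̂² = S(S−1)/(a₁² + a₂). The original H reference does not define a
  normalization, so the later formulation is adopted and documented here.
* dN/dS is Nei–Gojobori (1986): pathway-averaged codon differences,
  mutation-to-stop counted nonsynonymous, stop-crossing pathways excluded
  when avoidable, Jukes–Cantor correction. It exists so synthetic studies
  are self-contained; real analyses may supply dN/dS in the annotation.

Genes with fewer than five segregating sites are reported (π, θ_W) but
flagged untested and excluded from every test and from the scan's
percentile pools. Undefined values are NaN throughout.

## Coalescent simulator

The null engine is a backward-in-time ancestral-recombination-graph
simulator. Lineages carry lists of ancestral segments, each segment
holding the bitmask of sample chromosomes descending from it; coalescence
merges segment lists (segments reaching the full sample mask have found
their local MRCA and are dropped), recombination splits a lineage at a
uniform point within its ancestral span. Time is in units of 4N₀
generations; with k lineages the coalescence rate is k(k−1)·N₀/N(t) and
the total crossover rate R·Σspan with R = 4N₀ρ(L−1). These scalings give
the textbook expectations E[S] = θ·a_{n−1}, E[π] = θ and E[ξ_i] = θ/i,
which the tests verify at 2,000 replicates, and the marginal distribution
of Tajima's D matches an independent coalescent implementation (msprime)
by KS test, with and without recombination.

Mutations are dropped on branches proportionally to branch length ×
ancestral width: Poisson with locus θ (`fixed_theta`) or exactly S
mutations (`fixed_S`). Null distributions for observed genes default to
`fixed_S` on the observed S — a conditional test that removes the unknown
θ from the null; `fixed_theta` is available as a mode. Every simulated
column is polymorphic by construction, and null replicates run through the
same statistics code path as observed alignments.

Demography is piecewise-constant. Three presets ship: constant
(N = 10,000), an African-like expansion (7,300 → 14,000 at 5,000
generations ago) and a European-like bottleneck (10,000 recent, 1,500
between 1,000 and 3,500 generations, 7,300 ancestral), with μ = 1.5×10⁻⁸
per site per generation. These are deliberately coarse, documented
configuration values — approximations of calibrated human models, not a
fitted demography, and nothing downstream depends on their exact values.
Per-epoch exponential growth is not implemented; step changes stand in
for growth phases.

Empirical p-values use the (1 + k)/(B + 1) convention, so no p is ever
exactly zero.

## Selection scan

Percentile ranks are computed per test across all tested genes of a
population (mean rank for ties, divided by the count of defined values).
A gene is called positive with ≥2 supporting tests at percentile ≤ 0.05
(any of the six tests), balancing with ≥2 tests at ≥ 0.95 (H excluded:
its upper tail has no balancing interpretation). A gene qualifying in
both directions takes the majority direction; ties are reported ambiguous
with no direction — double counting is never allowed, and every emitted
call is checked to have ≥2 same-tail supporting tests. Corroboration
attaches one-sided coalescent p-values per supporting test; a call is
corroborated when ≥2 tests reach p < 0.05.

The joint-tail rule is conservative relative to per-test 5%: the exact
neutral call rate depends on the correlation between the six statistics,
so only an upper bound (≈10% of neutral genes across synthetic panels) is
asserted, not a point value.

## Class tests and enrichment

The class t-test is unpaired, class vs all remaining genes, pooled
variance by default (Welch available) — the directional hypothesis being
that core classes (adaptors, modulators) are more constrained. The
permutation test draws classes of the same size without replacement
(10,000 by default) and reports the lower-tail p with the +1 convention;
when C(m, k) ≤ 10⁵ it enumerates all classes and returns the exact tail
fraction. Enrichment of selection calls is the one-sided hypergeometric
upper tail on (in-class called, in-class not, out-class called, out-class
not). The gene universe is the full panel including unclassified and
untested genes, which count as "no evidence": with the bundled panel's
counts this convention reproduces all four published P-values (0.008,
0.03, 0.01, 0.04). No multiple-testing correction is applied across
classes; results are reported as-is, which the output documents as a
caveat.

## Synthetic data: what it emulates and what it does not

The generator mirrors the emulated study's design: 132 genes by default in
unequal classes (19/10/6/69/23 + 5 unclassified), two populations of 48
and 46 chromosomes, loci of 1–25 kb with locus-specific crossover rates
drawn from 0.5–2.5×10⁻⁸, class-scaled mutation rates (adaptors 0.65×,
modulators 0.8×) standing in for stronger purifying selection in the
network core, and synthetic human–chimp coding pairs (300 codons, 1.2%
divergence, class-scaled acceptance of nonsynonymous changes) feeding the
dN/dS column.

Selection is planted by frequency-spectrum distortion, not forward
simulation: with probability s each variant of a sweep-like gene is
resampled to derived count 1 (half the time) or n−1/n−2, and each variant
of a balancing-like gene to the count nearest n/2. This plants exactly the
signal the statistics read, at a controllable strength, but destroys
haplotype structure: linkage disequilibrium, haplotype-based signals, and
the spatial footprint of real sweeps are not emulated, so passing tests
demonstrate the scan's behaviour on SFS signals only. Background
selection, gene conversion, migration and admixed sampling are likewise
out of scope.

The synthetic interactome grows by preferential attachment
(degree^exponent, 8 edges per node, ~1,560 nodes by default); the focal
genes are the seed nodes, which makes them hub-like, as in a
query-centred database snapshot. The `coupling` parameter is the
magnitude of the planted negative Kendall correlation between focal
degree and diversity, implemented by Gaussian-copula rank matching
(ρ = sin(π·coupling/2)): coupling 1 pairs highest degree with lowest
diversity exactly; coupling 0.2 reproduces the τ ≈ −0.2 regime typical of
centrality-diversity analyses.

Studies are fully reproducible: one study seed spawns per-gene substreams
(`numpy.random.SeedSequence`), so reruns are byte-identical and any gene
can be regenerated in isolation.

## Problem sizes and numerical choices

Default analysis settings are the standard ones: 1,000 coalescent
replicates per gene, 10,000 label permutations, 5% tails, ≥2 supporting
tests, S ≥ 5. Verification runs use sizes chosen for tight Monte-Carlo
error at desk scale: 2,000 replicates for closed-form moments, 20
synthetic studies for recovery rates, 100 interactome replicates for
coupling detection, 400 null studies for permutation calibration. The
SFS goodness-of-fit uses the Monte-Carlo covariance of the replicate mean
spectrum (within a replicate all frequency classes share one genealogy, so
a naive multinomial chi-square would be badly miscalibrated). Exact-value
comparisons are at 10⁻⁶ (hand-worked statistics), 10⁻⁹ (betweenness vs
enumeration), 10⁻¹⁰ (hypergeometric tails) and 10⁻¹² (π identity, τ_b).

## Known limitations

* No effective-size correction for X-linked genes; the `chrom_system`
  flag is carried for reporting only.
* The unstarred Fu & Li tests use η = S with η_e counted over polarized
  sites; for genes with partially missing outgroup coverage this slightly
  deflates η_e relative to a fully polarized gene (the polarized fraction
  is reported so such genes can be filtered).
* The percentile scan is relative by construction: with many true
  positives in one tail the 5% cut saturates, so recovery is bounded by
  panel size × tail width per population.
* Demographic presets are approximations; for publication-grade
  corroboration users should supply their own calibrated epochs.
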