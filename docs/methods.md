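# Methods

This note documents the models, estimators and numerical choices behind
`ssrpopgen`, and what its synthetic-data tests do and do not demonstrate.

## SSR mining

A perfect microsatellite is a maximal run of whole copies of a primitive
2–5 bp motif. Detection compares the sequence with itself shifted by each
period p (`s[i] == s[i+p]`), run-length encodes the match track, and keeps
runs whose whole-copy count meets the period's threshold. Consequences of
this definition:

* A tract that matches at several periods (e.g. (AT)₆ also matching
  (ATAT)₃) is reported once, at the motif's primitive period.
* Reported coordinates cover whole copies only; a trailing partial copy is
  not included, and no reported locus can be extended by one further motif
  copy on either side (tested property).
* Any non-ACGT base terminates a run; soft-masked lowercase is uppercased
  before scanning.

Default thresholds are ≥5/≥4/≥3/≥2 copies for periods 2/3/4/5. Survey
criteria of this kind are sometimes phrased as "more than five dinucleotide
repeats", which is ambiguous between > and ≥; the inclusive reading is the
default here and the thresholds are fully configurable. Because marker
panels are built from long tracts (≥10 copies), downstream analyses are
insensitive to this choice. Mononucleotide and hexanucleotide repeats are
not searched by default, and compound/interrupted repeats are out of scope.

Canonical motif classes are the lexicographic minimum over all cyclic
rotations of the motif and of its reverse complement. This partitions
dinucleotides into exactly {AC, AG, AT, CG} and tetranucleotides into 33
classes at most.

## Primer screening

Primer design itself (the Primer3 objective) is not re-implemented; the
module screens given candidates against the standard windows — product
50–500 bp, primer 18–30 nt, Tm 52–65 °C, all configurable. Every constraint
is evaluated (no short-circuit) so reports enumerate all violations, and
widening any window can never turn a pass into a fail (tested monotonicity).

Melting temperature uses the SantaLucia (1998) unified nearest-neighbor
parameters with the entropic salt correction ΔS += 0.368(N−1)ln[Na⁺],
defaults 50 mM monovalent salt and 0.25 µM oligo with the oligo/4
effective-duplex concentration (oligo/1 plus the symmetry entropy term for
self-complementary sequences). No salt/oligo conditions are implied to be
those any particular study used — they are stated defaults, echoed in
output and configurable. The test suite cross-checks the implementation
against Biopython's independent NN implementation and a hand-summed
parameter table to 0.1 °C.

## Genotypes and allele frequencies

`GenotypeMatrix` stores unordered pairs of positive integer allele codes
(conventionally fragment sizes in bp) with an explicit missing state; a
genotype is missing as a whole, never one allele. GenePop read/write uses
3-digit encoding with codes ≤999 stored verbatim (rank-code fallback above
that). All statistics are complete-case per locus: each locus uses its own
n of called individuals, matching standard population-genetics software.
Pooled frequencies equal the sample-size-weighted mean of per-population
frequencies (tested invariant).

## Diversity statistics

For allele frequencies p₁…p_k at a locus with n called diploid individuals:

* Na = number of observed alleles; Ne = 1/Σpᵢ² (the allele count of an
  equifrequent locus with the same homozygosity).
* Ho = fraction of called genotypes with two distinct alleles.
* He = (2n/(2n−1))(1 − Σpᵢ²), Nei's unbiased estimator. The unbiased form
  is the default because published marker tables satisfy the identity
  He = (2n/(2n−1))(1 − 1/Ne) to printed precision; the biased 1 − Σp² form
  is available by flag.
* PIC = 1 − Σpᵢ² − Σ_{i<j}2pᵢ²pⱼ², computed via the algebraic reduction
  1 − s₂ − (s₂² − s₄). Bands: ≥0.5 high, [0.25, 0.5) moderate, else low.

The Hardy–Weinberg test is a Monte-Carlo exact test: the observed allele
pool is randomly re-paired; a table counts toward p when its Levene
conditional probability (∝ 2^het / Π n_ab!) is ≤ the observed table's, and
the observed table is included in numerator and denominator, giving
p = (b+1)/(m+1). A chi-square test is deliberately avoided because
multiallelic microsatellite loci make expected cell counts sparse. Against
full enumeration on small biallelic tables the Monte-Carlo p agrees within
0.02 at 20,000 resamples. Monomorphic loci return p = 1 by convention.
Departure counts at level α default to per-locus uncorrected tests;
sequential Bonferroni (Holm) is available.

Nei's standard distance averages the identity sums across loci first and
takes one logarithm: D = −ln(J_xy/√(J_x J_y)) with J the arithmetic means
over loci of Σpᵢ²-type identities. Populations sharing no alleles at any
locus get an explicit infinite distance.

Reported tables round half-up to 3 decimals, as such tables conventionally
print; internal computation is double precision throughout.

## AMOVA and Fst

The two-level AMOVA treats each diploid individual as two gene copies
(2N units). The squared distance between two copies is the number of loci
at which their alleles differ, skipping loci missing in either individual.
Sums of squares are computed from per-locus allele counts — algebraically
identical to partitioning the explicit pairwise distance matrix (verified
against a brute-force distance-matrix oracle) but linear in data size, which
keeps 1000-permutation tests cheap. Degrees of freedom are P−1 among and
2N−P within; the among component uses the unequal-sample-size coefficient
n′ = (m − Σm_k²/m)/(P−1) on copy counts; Fst = σ²ₐ/(σ²ₐ+σ²_w).

Permutations move whole individuals (both copies) among populations with
sizes preserved; the p-value is (b+1)/(m+1). Negative among-population
variance components are reported as-is with a warning, as is common AMOVA
practice; Fst is floored at zero only for band classification. The distance
is allele identity (0/1 per copy pair), not a stepwise-mutation size
difference, because Fst — not Rst — is the target quantity.

## UPGMA

True size-weighted UPGMA (not WPGMA): the closest pair merges at height
d/2 and distances to the merged cluster are size-weighted means. Ties are
broken by the lexicographic order of each cluster's smallest member label,
making output deterministic. On ultrametric inputs the tree's cophenetic
matrix reproduces the input exactly (tested to 1e-9). Newick branch lengths
are parent height minus child height.

## Admixture model ("structure-lite")

The model is the standard admixture mixture: allele copy c of individual i
comes from cluster z_c ~ Categorical(q_i), and an allele from cluster k at
locus l is drawn from that cluster's frequency vector p_kl. Gibbs sweeps
alternate z | (P, Q), P | z (Dirichlet with uniform prior) and Q | z
(Dirichlet with admixture parameter α). Missing genotypes simply contribute
no copies. The per-sweep log-likelihood log Pr(X | P, Q) — with copy
origins summed out — is averaged over sampled sweeps; Evanno model
selection uses ΔK = |L″(K)|/SD(K) over run replicates, requiring ≥3
consecutive K and ≥2 runs per K, with ΔK flagged undefined at zero SD.

α is sampled by a Metropolis step (uniform prior on (0, 10], normal
proposal, σ = 0.1) by default. A fixed α is supported, but fixing α = 1
bounds the posterior-mean self-membership of an unadmixed individual near
(c+1)/(c+K) for c allele copies — visibly blurring assignments at
marker-panel scale — so sampling α, as the original admixture software
does, is the default. Simplifications retained relative to that software:
cluster allele frequencies are independent (no correlated-frequencies
model) and there is no linkage model.

Default run lengths are 500 burn-in plus 2,000 sampling sweeps. On
datasets of this package's intended scale (tens to hundreds of individuals,
tens of loci, clear structure) the chain reaches its stationary regime
within ~100 sweeps, and posterior summaries are stable across seeds at
these defaults; longer chains (e.g. 50,000/100,000) remain available
through the `burnin`/`n_iter` arguments and CLI flags for weakly structured
data. Every assertion about cluster memberships is made only after optimal
cluster-permutation alignment to truth, since cluster labels are not
identifiable.

## Synthetic data

`simulate_genome` plants exact SSR tracts and PCR amplicons into i.i.d.
background sequence at a requested GC fraction (default 0.41, a typical
teleost value). The neighbourhood of every planted feature (two motif
periods on each side) is rejection-checked against accidental
threshold-meeting repeats, so planted truth tables are exact; background
repeats far from features are allowed and excluded from precision checks.
Packing that cannot succeed raises an error rather than truncating.

`simulate_genotypes` uses the Balding–Nichols island model: per locus an
ancestral frequency vector is drawn Dirichlet-uniform, each population's
vector is drawn Dirichlet(p·(1−F)/F) — giving expected differentiation F —
and individuals are two independent copies per locus, i.e. Hardy–Weinberg
within populations. F = 0 short-circuits to the ancestral frequencies
exactly. Defaults emulate the four-population survey design the package
ships reference tables for: sizes 34/77/68/89, 29 loci, 12 ancestral
alleles per locus, F = 0.074, 2% missing genotypes (a typical panel-quality
rate; the reference survey does not report one), allele codes on +4 bp
fragment-size ladders within 86–265 bp.

What the simulations do not emulate: stepwise mutation (allele sizes carry
no mutational ordering), linkage between loci, inbreeding or null alleles,
migration history, and genotyping artifacts beyond missingness. Passing
tests therefore demonstrate estimator correctness and calibration under the
stated model, not robustness to those real-data complications.

## Problem sizes in the checks

The acceptance script and test suite run the simulation-backed checks at
survey scale: 100 replicates for Fst recovery at F = 0.10, 200 null
replicates × 99 permutations for p-value uniformity, 200 loci × 1,000
resamples for HWE type-I error, and admixture experiments of 3 × 50
individuals × 20 loci across K = 1–5 with 2 runs per K. These sizes give
the comparisons their stated resolution (e.g. a binomial SD of ~3
percentage points on a 90% recovery criterion) while keeping a full run in
the minutes range on one CPU.
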