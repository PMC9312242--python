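# ssrpopgen

Microsatellite (SSR) marker development and population-genetic analysis for
codominant diploid genotype data, in one tested Python package. It covers
the full workflow a marker-development study runs:

1. **SSR mining** — detect perfect 2–5 bp tandem repeats genome-wide from
   FASTA, group motifs into canonical classes (rotation + reverse-complement
   equivalence, e.g. GT/TG/CA/AC → AC), and summarise counts and proportions
   per class.
2. **Marker screening** — extract repeat flanks and screen candidate primer
   pairs against design windows (product 50–500 bp, primer 18–30 nt, Tm
   52–65 °C, SantaLucia 1998 nearest-neighbor model), with exact-match
   in-silico PCR for validation.
3. **Diversity statistics** — per locus: allele number Na, effective allele
   number Ne = 1/Σpᵢ², observed heterozygosity Ho, Nei's unbiased expected
   heterozygosity He = (2n/(2n−1))(1 − Σpᵢ²), Botstein polymorphic
   information content PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ², and a Monte-Carlo
   exact Hardy–Weinberg test conditioning on allele counts.
4. **Differentiation** — two-level AMOVA on gene-copy mismatch distances
   with variance components, global and pairwise Fst = σ²ₐ/(σ²ₐ+σ²_w),
   permutation p-values, and Wright's bands (<0.05 low, 0.05–0.15 moderate,
   0.15–0.25 high).
5. **Clustering** — Nei's (1972) standard distance
   D = −ln(J_xy/√(J_x·J_y)) and a size-weighted UPGMA dendrogram with
   Newick export.
6. **Admixture ("structure-lite")** — a Pritchard-style Gibbs sampler for K
   clusters with sampled admixture parameter α, plus Evanno ΔK model
   selection across K.
7. **Synthetic data** — planted-SSR genomes with exact truth tables and
   Balding–Nichols island-model genotypes with controlled differentiation
   F, so every stage is testable without external downloads.

The built-in defaults of the genotype simulator mirror a four-population
wild Eurasian perch (*Perca fluviatilis*) survey: sample sizes 34/77/68/89,
29 multiallelic tetranucleotide loci with fragment sizes in the 86–265 bp
range, and moderate differentiation (F = 0.074). The published per-locus
tables from that survey are bundled in `ssrpopgen.reference` as re-analysis
inputs and cross-checks.

## Worked example

```python
import ssrpopgen as sp

# --- mine a genome with two planted repeat tracts
from ssrpopgen.simulate import PlantedGenomeSpec, PlantedSSR, simulate_genome
records, truth = simulate_genome(PlantedGenomeSpec(
    lengths=[20_000], ssrs=[PlantedSSR("AGAT", 17), PlantedSSR("ACAG", 12)], seed=4))
loci = sp.find_ssrs(records["chr1"], "chr1")
print([(l.start, l.canonical, l.n_repeats) for l in loci if l.n_repeats >= 6])
# [(10561, 'ACAG', 12), (10978, 'AGAT', 17)]   <- exactly the planted tracts

# --- survey-sized genotypes: diversity, AMOVA, tree
g, _ = sp.simulate_genotypes(sp.IslandModelSpec(seed=1))
agg = sp.aggregate_population_stats(sp.population_locus_stats(g))
print(f"{agg.n_loci} loci, {agg.total_alleles} alleles, mean Na {agg.mean_na:.3f}")
# 29 loci, 326 alleles, mean Na 11.241

res = sp.Amova(g).fit(n_permutations=999, seed=2)
print(res.summary())
# Source of variation       df          SS  Var comp   % var
# Among populations          3     400.705     0.945     8.0
# Within populations       532    5780.762    10.866    92.0
# Total                    535    6181.466    11.811
# Fst = 0.08 (moderate differentiation)
# Permutation p = 0.001 (999 permutations)

print(sp.to_newick(sp.upgma(sp.nei_distance_matrix(g))))
# (WR:0.20709,(WL:0.199265,(KR:0.15861,JL:0.15861):0.0406553):0.00782501);
```

The AMOVA table reads as a standard molecular-variance decomposition: 8% of
allelic variation lies among the four simulated populations (they were
simulated at F = 0.074, so the estimate is on target), the permutation test
rejects panmixia, and Fst = 0.08 falls in Wright's moderate band.

A command-line interface exposes the same pipeline
(`ssrpopgen mine | screen | stats | amova | pairwise-fst | tree |
structure | simulate-genome | simulate-genotypes`); every output TSV starts
with a provenance header recording version, seed and a config hash.

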