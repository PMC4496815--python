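# apisweep

Genome-wide selection scans for small diploid population samples.

`apisweep` is a library and command-line tool for detecting signatures of
natural selection from a table of biallelic SNP genotypes — the kind of
data produced by whole-genome resequencing of a handful of individuals
from wild populations (the motivating use case is ~11 diploid genomes
split into two geographic populations). It implements six classical
tests in one consistent pipeline:

**Protein-coding tests** (per annotated gene, from VCF + GFF3 + FASTA):

1. **pN/pS** — the ratio of nonsynonymous to synonymous polymorphism,
   normalized by Nei–Gojobori effective site counts:
   `pN/pS = (P_N / N) / (P_S / S)`, where `N` and `S` are the effective
   nonsynonymous and synonymous sites of the gene's CDS (per codon,
   `s` = the fraction of the 9 single-base mutants that are synonymous,
   `n = 3 − s`). Values > 1 suggest diversifying selection.
2. **Fixed-difference ratio** — `E_N / (P_N + 1)`, ranking genes whose
   fixed amino-acid differences from the reference genome (`E_N`) exceed
   their amino-acid polymorphism within the sample (`P_N`).
3. **McDonald–Kreitman Fixation Index** — from the 2×2 table of
   polymorphism vs outgroup divergence counts,
   `FI = (D_N / D_S) / (P_N / P_S)`; FI ≫ 1 indicates an excess of fixed
   amino-acid change relative to standing variation.

**Allele-frequency tests** (genome-wide):

4. **Runs of homozygosity** — each SNP scores `(p_alt − p_ref)²` within a
   population (1.0 iff monomorphic); dense stretches of high scores mark
   candidate sweeps.
5. **Reich–Patterson F_ST** — the small-sample unbiased estimator, per
   SNP and overall (ratio of summed numerators to summed denominators),
   with a group-label randomization test.
6. **Windowed Tajima's D and normalized Fay–Wu's H** — computed in
   non-overlapping windows (default 5 kb), with H polarized by an
   outgroup allele column and standardized by the Zeng variance.

Tests 4–5 feed a **remarkable-interval scanner**: after subtracting a
cutoff (e.g. the top-decile score), it finds all Ruzzo–Tompa maximal
scoring segments — intervals whose summed transformed score cannot be
increased by moving either endpoint — and assigns each a family-wise
empirical p-value from within-chromosome score permutations. Test 6 gets
its significance cutoffs from a built-in neutral coalescent simulator
(θ estimated from the mean segregating sites per window).

## Worked example

Simulate a cohort of 11 diploids in which the first population carries a
50-SNP monomorphic tract (a hard selective sweep) on a polymorphic
background, then scan for runs of homozygosity:

```sh
$ apisweep simulate sweep --n-samples 11 --length-snps 400 \
      --tract-len 50 --seed 7 --out-dir .
$ apisweep roh --vcf sweep.vcf --pops sweep.pops.tsv --group A \
      --cutoff 0.9 --reps 1000 --seed 1 --out roh.bed
$ cat roh.bed
sim1	8691	11985	5	0.000999001
```

The scanner recovers a single interval (BED columns: chromosome, start,
end, score, empirical p). The score 5 is the summed excess over the 0.9
cutoff of the 50 member SNPs (50 × 0.1); its empirical p of
1/1001 ≈ 0.000999 means the interval outscored the best segment of every
one of the 1000 permuted genomes — the strongest claim 1000
randomizations can support, and below the conventional p < 0.001
reporting threshold.

The same fixture shows the two groups are differentiated:

```sh
$ apisweep fst-overall --vcf sweep.vcf --pops sweep.pops.tsv \
      --groups A,B --reps 999 --seed 1
overall_fst	0.0805932
empirical_p	0.002
```

Overall F_ST ≈ 0.081 (driven by the tract fixed in population A), larger
than 998 of 999 random regroupings of the same individuals.

For the protein-coding tests, `apisweep pnps`, `apisweep fixed-diff` and
`apisweep mk --outgroup alleles.tsv` write one TSV row per gene with
`N, S, P_N, P_S, E_N, E_S, D_N, D_S` and the derived `pnps`, `e_ratio`
and `fi` columns (undefined ratios are NaN with an explanatory flag
rather than silently pseudocounted).

## Layout

```
src/apisweep/io_formats.py     VCF/GFF3/FASTA/TSV/BED readers & writers
src/apisweep/codon_model.py    genetic code, SNP effects, pN/pS, E-ratio, MK
src/apisweep/popgen_stats.py   frequencies, FST, Tajima's D, Fay-Wu H
src/apisweep/interval_scan.py  maximal segments, cutoffs, permutation p
src/apisweep/neutral_sim.py    coalescent nulls + synthetic fixtures
src/apisweep/cli.py            `apisweep` subcommands
docs/methods.md                models, assumptions, parameter choices
```
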