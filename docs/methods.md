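# Methods

This note documents the statistical models behind `apisweep`, the
conventions and numerical choices the implementation commits to, and
what the synthetic-data generators do and do not emulate.

## Data model and conventions

All coordinates are 0-based half-open internally; conversion happens
only at format boundaries (VCF and the outgroup TSV are 1-based, BED is
0-based half-open). Genotypes are unphased alt-allele counts
{0, 1, 2}; phase separators in the VCF are ignored, and a genotype with
any uncalled allele is treated as missing. Only biallelic SNPs passing
the variant-quality filter (default `--min-qual 100`, inclusive) are
retained; coverage and mapping-quality filters are the variant caller's
job and are not re-applied here.

Gene models are chains of CDS intervals grouped by their GFF3 `Parent`
attribute, ordered in transcription direction. A spliced CDS whose
length is not divisible by 3 has its trailing partial codon dropped
(with a warning); reading frame is taken from the cumulative spliced
position, i.e. the chain is assumed to start in frame 0, which holds
for complete annotated CDS chains. Gene symbols mapping to multiple
loci are reported separately with a warning, never merged.

## Protein-coding tests

**Effective sites (Nei–Gojobori counting).** For each codon, the
synonymous site count is the sum over its three positions of the
fraction of the three single-base mutants that preserve the amino acid;
`n = 3 − s`. Stop codons and codons containing non-ACGT letters
(assembly gaps) are skipped and tallied. Effective sites are computed
from the *reference* CDS, matching a reference-annotation-driven
pipeline, not from a sample consensus. No multiple-hit correction is
applied anywhere: all three tests use raw counts.

**SNP classification.** The reference codon is rebuilt from the genome
in transcription orientation (reverse-complemented for minus-strand
genes) and the alt allele substituted at the in-codon position.
Mutations that create or destroy a stop codon are flagged
`STOP_AFFECTED` and counted as nonsynonymous in all tallies — the
conservative, common practice. When a codon carries more than one SNP,
each is classified independently with the other positions held at the
reference base, avoiding any dependence on haplotype phase.

**Site categories.** Among the selected samples' called genotypes, a
site with ≥ 2 observed alleles is a *polymorphism* (P); a site where
every called genotype is hom-alt (and at least one is called) is a
*fixed difference* from the reference (E); a site fixed for either
allele whose allele differs from the outgroup allele is a *divergence*
(D). A site that is both polymorphic and different from the outgroup
counts as P only — polymorphism wins, which is the standard MK
bookkeeping; sites whose outgroup allele matches neither ref nor alt
are excluded and counted per gene.

**Ratios.** `pnps = (P_N/N)/(P_S/S)` is undefined (NaN, flagged) when
`P_S = 0`; `e_ratio = E_N/(P_N + 1)` uses the +1 so genes without
amino-acid polymorphism are rankable; `fi = (D_N/D_S)/(P_N/P_S)` is
undefined when `D_S`, `P_S` or `P_N` is zero, with the offending cell
named in the flag. A pseudocount variant (`fi_pseudocount`, +1 to all
four cells) exists for exploratory ranking only, and a two-sided Fisher
exact p on the 2×2 table is available as an optional column; neither
replaces the headline statistic. The `e_ratio` denominator uses
amino-acid (nonsynonymous) polymorphisms only.

## Allele-frequency statistics

**Homozygosity.** Per site and population, score `(p_alt − p_ref)²`;
exactly 1.0 iff the population is monomorphic there. Scanning these
scores with a cutoff of 0.9 finds runs of homozygosity; a cutoff of 1.0
would make every transformed score non-positive and no interval could
extend beyond a single site.

**Reich–Patterson F_ST.** With alt counts `a_k` of `n_k` chromosomes
and `h_k = a_k(n_k−a_k)/(n_k(n_k−1))`,

    num = (a1/n1 − a2/n2)² − h1/n1 − h2/n2,   den = num + h1 + h2.

Per-SNP F_ST is `num/den` (undefined when `den = 0`, i.e. both groups
monomorphic for the same allele; such sites are dropped from scans).
The overall estimate is the ratio of sums Σnum/Σden — the standard
small-sample form, yielding a single genome-wide scalar rather than an
average of noisy per-site ratios. Sites need ≥ 2 called chromosomes per
group. The randomization test redraws disjoint groups of the observed
sizes from all samples and uses the +1 empirical p-value rule, so p is
never zero; note that when the two groups exhaust the sample, random
regroupings can rediscover the true split, so the smallest achievable p
grows with 1/(number of distinct partitions).

**Tajima's D.** Per window or site mask, `π` is the sum of the unbiased
per-site estimator `2a(n−a)/(n(n−1))`, `θ_W = S/a1`, and `D` is
standardized with the original variance coefficients
(`e1 S + e2 S(S−1)`); undefined when `S = 0`. The haplotype count `n`
is fixed per run at 2 × group size. By default only sites with complete
genotypes in the group enter; `allow_missing` keeps per-site counts but
retains the run-level `n` for the variance constants (the motivating
pipeline genotyped every individual at every SNP, so complete matrices
are the expected case).

**Normalized Fay–Wu H.** Sites are polarized by the outgroup allele:
outgroup = ref gives derived count `a`, outgroup = alt gives `n − a`,
anything else excludes the site. With `S_i` the unfolded spectrum,
`θ_L = Σ i·S_i/(n−1)` and `H = (π − θ_L)/√Var`, with the Zeng variance

    Var = θ_W (n−2)/(6(n−1))
        + θ² [18n²(3n+2) b_{n+1} − (88n³ + 9n² − 13n + 6)] / (9n(n−1)²),

where `b_{n+1} = Σ_{i=1}^{n} 1/i²` and `θ²` is estimated by
`S(S−1)/(a1² + a2)`. Under `allow_missing`, a site's derived count is
mapped to the nearest run-level spectrum bin.

## Interval scanner

Scores sit on SNP ordinal positions; after subtracting the cutoff
(either user-supplied or the genome-wide nearest-rank top-fraction
quantile), the scanner returns all Ruzzo–Tompa maximal scoring
subsequences in linear time. Tie handling is strict: zero-sum
extensions are not absorbed, so every reported segment has strictly
positive proper prefixes and suffixes. Reported intervals span first to
last member SNP in bp; SNP-free gaps inside an interval carry no
penalty (no gap-penalized variant is provided). The linear scanner is
verified against quadratic enumeration in the test suite.

Empirical p-values permute the score-to-position assignment *within
each chromosome* (preserving per-chromosome score distributions and
site density; genome-wide shuffling would mix chromosome-specific score
scales). The null summary is the per-replicate maximum segment score
over the whole permuted genome, so p-values are family-wise for the
scan. With the +1 rule and `reps = 1000`, the smallest achievable p is
1/1001, which is what the default reporting threshold `p < 0.001`
demands: an interval must outscore every permuted genome.

## Neutral coalescent calibration

The simulator is a single-locus Kingman coalescent without
recombination or demography: exponential coalescence waits with rate
k(k−1)/2 (time in 2N units), Poisson(θ·L/2) mutations placed uniformly
on branches, infinite sites. This matches the classical single-window
null for windowed D/H scans; within-window recombination would make the
null conservative for D, which is the usual trade-off accepted by this
approach. Closed forms E[S] = θ·a1(n) and E[π] = θ are verified in the
tests, along with an independent cross-check against msprime.

Calibration estimates θ̂ from the data as (mean segregating sites per
window)/a1, simulates `reps` neutral windows, and returns the empirical
lower-tail α-quantile of D (and of normalized H, whose ancestral states
the simulator knows exactly) as the significance cutoff. Default mode
is per-window; `experiment_wide=True` simulates whole scans of
`n_windows` windows and takes the α-quantile of per-replicate minima,
controlling the chance that *any* window of a neutral genome is
flagged. The default haplotype count is n = 22 (11 diploids),
overridable. Monomorphic simulated windows carry no information and are
excluded from the null; if all windows are monomorphic the calibrator
refuses to produce a cutoff.

## Synthetic fixtures

The generators produce the study conditions the tests run under:

* `island_fixture` — Balding–Nichols two-deme structure: per SNP an
  ancestral frequency p ~ U(0.05, 0.95), deme frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) so E[(p_k−p)²] = F·p(1−p), binomial
  diploid genotypes. Defaults (3 + 5 diploids) mirror a small two-deme
  resequencing cohort. The Reich–Patterson ratio-of-sums estimator is
  unbiased for F under this model, which the recovery tests exploit
  (F = 0.05 recovered ±0.01 at 5×10⁴ SNPs).
* `sweep_fixture` — shared background frequencies U(0.25, 0.75) for 11
  diploids in two groups, with a contiguous tract forced hom-alt in
  group A only; exercises the ROH → scan path end to end.
* `coding_gene_fixture` — writes a miniature FASTA/GFF3/VCF (plus
  optional outgroup TSV) realizing an explicit per-codon SNP plan on
  either strand, validating each planned effect against the generated
  sequence.

What these fixtures do **not** emulate: linkage disequilibrium and
recombination along chromosomes, genotyping error, reference bias,
indels and structural variation, and realistic gene structure beyond a
two-exon toy gene. Passing tests therefore demonstrate correctness of
the estimators and scan machinery under their own model assumptions,
not robustness to the artifacts of real short-read data.

All generators and every randomized procedure (permutations, group
randomization, coalescent simulation) take explicit seeds and are
bit-reproducible.

## Problem sizes used in the checks

The bundled verification suite uses sizes chosen to make Monte-Carlo
error small relative to the tolerances while keeping a laptop run
comfortable: 10⁴ coalescent replicates for closed-form checks, 2000
neutral windows (n = 22, θ = 5) for the neutrality calibration of the
D/H stack, 5×10⁴ SNPs for F_ST parameter recovery, 1000 random tracks
(length ≤ 50) for the scanner-vs-enumeration oracle, and 1000
permutations for the end-to-end sweep detection.

## Known limitations

* The per-SNP F_ST and D/H machinery assumes biallelic SNPs throughout;
  multiallelic records are dropped at VCF read time.
* Divergence counting consumes a per-site outgroup allele column;
  producing that column (read mapping of the outgroup species) is
  upstream of this package.
* No haplotype-based statistics (iHS/XP-EHH), no Weir–Cockerham F_ST,
  no ML codon models (dN/dS), and no gap-aware or HMM segmentation —
  the scanner is deliberately the cutoff-sum formulation.
* Windows are tiled from position 0 with a fixed width; a trailing
  short window is kept, and its statistics use the same variance
  constants (window width never enters the formulas, only the site
  content).
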