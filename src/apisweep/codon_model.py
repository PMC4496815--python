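"""Genetic-code machinery and the three protein-coding selection tests.

Effective synonymous/nonsynonymous site counts follow the Nei-Gojobori
counting approach: at each codon position the synonymous fraction is the
share of the three possible single-base mutants that preserve the encoded
amino acid, so a codon contributes between 0 and 3 synonymous sites and
``n + s = 3`` always holds for a counted codon.  Stop codons and codons
containing non-ACGT letters (assembly gaps) are skipped and tallied.

On top of the per-SNP classification this module computes, per gene:

* pN/pS -- (P_N / N) / (P_S / S), the site-normalized ratio of
  nonsynonymous to synonymous polymorphism (undefined when P_S = 0);
* the fixed-difference ratio E_N / (P_N + 1), ranking genes whose fixed
  amino-acid differences from the reference outnumber their
  amino-acid polymorphisms;
* the McDonald-Kreitman Fixation Index FI = (D_N / D_S) / (P_N / P_S)
  from a 2x2 table of polymorphism vs outgroup divergence counts.

No multiple-hit (Jukes-Cantor) correction is applied anywhere: the tests
operate on raw counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .io_formats import (
    MISSING,
    GeneModel,
    OutgroupAlleles,
    ReferenceGenome,
    VariantTable,
)

logger = logging.getLogger("apisweep")

_STD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the standard genetic code; stops map to '*'.
GENETIC_CODE: dict[str, str] = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    GENETIC_CODE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NUCS = "ACGT"

SYNONYMOUS = "SYNONYMOUS"
NONSYNONYMOUS = "NONSYNONYMOUS"
STOP_AFFECTED = "STOP_AFFECTED"
SKIPPED = "SKIPPED"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# effective site counting
# ---------------------------------------------------------------------------

@dataclass
class SiteCountsPerGene:
    """Effective nonsynonymous (N) and synonymous (S) site counts."""

    gene_id: str
    N: float
    S: float
    codons_counted: int
    codons_skipped: int


def _synonymous_fraction(codon: str) -> float:
    """Per-codon synonymous sites: sum over the 3 positions of the
    fraction of single-base mutants encoding the same amino acid."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _NUCS:
            if b == codon[pos]:
                continue
            if GENETIC_CODE[codon[:pos] + b + codon[pos + 1:]] == aa:
                syn += 1
        s += syn / 3.0
    return s


def effective_sites(cds_sequence: str, gene_id: str = "") -> SiteCountsPerGene:
    """Nei-Gojobori effective site counts for a spliced CDS sequence.

    Stop codons and codons containing non-ACGT letters are skipped (and
    tallied); for counted codons N + S = 3 * codons_counted exactly.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3:
        raise ValueError(
            f"CDS length {len(seq)} not divisible by 3 (caller must pre-trim)"
        )
    S = 0.0
    counted = skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in _NUCS for b in codon) or GENETIC_CODE[codon] == "*":
            skipped += 1
            continue
        S += _synonymous_fraction(codon)
        counted += 1
    return SiteCountsPerGene(
        gene_id=gene_id, N=3.0 * counted - S, S=S,
        codons_counted=counted, codons_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# SNP effect classification
# ---------------------------------------------------------------------------

@dataclass
class SnpEffect:
    """Effect of substituting the alt allele at one CDS site."""

    chrom: str
    pos: int
    gene_id: str
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    effect: str


def classify_snp(
    gene: GeneModel,
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    ref_genome: ReferenceGenome,
) -> SnpEffect:
    """Classify a biallelic SNP inside a CDS of ``gene``.

    The reference codon is built from the reference genome in
    transcription orientation (reverse-complemented for minus-strand
    genes); the alt allele is substituted at the in-codon position and
    both codons are translated.  Changes that create or destroy a stop
    codon are ``STOP_AFFECTED``; codons containing N are ``SKIPPED``.
    """
    if chrom != gene.chrom:
        raise ValueError(f"site {chrom}:{pos + 1} not on gene chromosome {gene.chrom}")
    cds_idx = gene.genomic_to_cds(pos)
    if cds_idx is None:
        raise ValueError(f"site {chrom}:{pos + 1} outside CDS of gene {gene.gene_id}")
    genome_base = ref_genome.base(chrom, pos)
    if genome_base != ref_allele:
        raise ValueError(
            f"ref allele {ref_allele!r} at {chrom}:{pos + 1} disagrees with "
            f"reference genome base {genome_base!r}"
        )
    codon_index, codon_pos = divmod(cds_idx, 3)
    positions = gene.spliced_genomic_positions()
    start = codon_index * 3
    bases = []
    for gpos in positions[start:start + 3]:
        b = ref_genome.base(chrom, int(gpos))
        bases.append(b if gene.strand == "+" else complement(b))
    ref_codon = "".join(bases)
    alt_base = alt_allele if gene.strand == "+" else complement(alt_allele)
    alt_codon = ref_codon[:codon_pos] + alt_base + ref_codon[codon_pos + 1:]
    if any(b not in _NUCS for b in ref_codon + alt_codon):
        effect = SKIPPED
    else:
        aa_ref, aa_alt = GENETIC_CODE[ref_codon], GENETIC_CODE[alt_codon]
        if "*" in (aa_ref, aa_alt):
            effect = STOP_AFFECTED
        elif aa_ref == aa_alt:
            effect = SYNONYMOUS
        else:
            effect = NONSYNONYMOUS
    return SnpEffect(
        chrom=chrom, pos=pos, gene_id=gene.gene_id,
        codon_index=codon_index, codon_pos=codon_pos,
        ref_codon=ref_codon, alt_codon=alt_codon, effect=effect,
    )


# ---------------------------------------------------------------------------
# per-gene counting of polymorphisms, fixed differences and divergences
# ---------------------------------------------------------------------------

@dataclass
class GeneCounts:
    """Per-gene SNP counts and the derived test statistics.

    Undefined ratios are returned as NaN, with a reason appended to
    ``flags`` (e.g. ``pnps_undefined:P_S=0``).
    """

    gene_id: str
    chrom: str
    N: float
    S: float
    codons_counted: int
    codons_skipped: int
    P_N: int = 0
    P_S: int = 0
    E_N: int = 0
    E_S: int = 0
    D_N: int = 0
    D_S: int = 0
    stop_affected: int = 0
    snps_skipped: int = 0
    outgroup_skipped: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def pnps(self) -> float:
        """(P_N / N) / (P_S / S); undefined (NaN) when P_S = 0."""
        if self.P_S == 0:
            self._flag("pnps_undefined:P_S=0")
            return math.nan
        if self.N == 0:
            self._flag("pnps_undefined:N=0")
            return math.nan
        return (self.P_N / self.N) / (self.P_S / self.S)

    @property
    def e_ratio(self) -> float:
        """E_N / (P_N + 1): fixed amino-acid differences from the
        reference, tempered by amino-acid polymorphism."""
        return self.E_N / (self.P_N + 1)

    @property
    def fi(self) -> float:
        """McDonald-Kreitman Fixation Index (D_N/D_S) / (P_N/P_S)."""
        for cell, label in ((self.D_S, "D_S"), (self.P_S, "P_S"), (self.P_N, "P_N")):
            if cell == 0:
                self._flag(f"fi_undefined:{label}=0")
                return math.nan
        return (self.D_N / self.D_S) / (self.P_N / self.P_S)

    def fi_pseudocount(self, pseudocount: float = 1.0) -> float:
        """FI with a pseudocount added to all four cells (for exploratory
        ranking only; the headline statistic reports NaN instead)."""
        c = pseudocount
        return ((self.D_N + c) / (self.D_S + c)) / ((self.P_N + c) / (self.P_S + c))

    def mk_fisher_p(self) -> float:
        """Two-sided Fisher exact p for the 2x2 MK table (optional column)."""
        from scipy.stats import fisher_exact

        return float(fisher_exact([[self.D_N, self.D_S], [self.P_N, self.P_S]])[1])

    def _flag(self, msg: str) -> None:
        if msg not in self.flags:
            self.flags.append(msg)


def _site_category(codes: np.ndarray) -> str:
    """'polymorphic' | 'fixed_ref' | 'fixed_alt' | 'uncalled' for one site."""
    called = codes[codes != MISSING]
    if called.size == 0:
        return "uncalled"
    if np.any(called == 1) or (np.any(called == 0) and np.any(called == 2)):
        return "polymorphic"
    return "fixed_alt" if called[0] == 2 else "fixed_ref"


def gene_counts(
    variants: VariantTable,
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
    samples: Sequence[str] | None = None,
    outgroup: OutgroupAlleles | None = None,
) -> list[GeneCounts]:
    """One-pass tally of P/E/D counts for every gene.

    Per CDS SNP among the selected samples: a site with >=2 distinct
    observed alleles is a polymorphism (P); a site where every called
    genotype is hom-alt is a fixed difference from the reference (E);
    with outgroup data, a site fixed for either allele that differs from
    the outgroup allele is a divergence (D).  ``STOP_AFFECTED`` SNPs
    count as nonsynonymous; ``SKIPPED`` SNPs are excluded but tallied.
    Sites both polymorphic and outgroup-divergent count as P only.
    """
    if outgroup is not None and len(outgroup) != variants.n_sites:
        raise ValueError("outgroup alleles not aligned with variant table")
    cols = (variants.sample_indices(samples) if samples is not None
            else np.arange(variants.n_samples))
    _warn_duplicate_symbols(genes)
    out: list[GeneCounts] = []
    for gene in genes:
        seq = "".join(
            ref_genome.base(gene.chrom, int(p))
            for p in gene.spliced_genomic_positions()
        )
        sites = effective_sites(seq, gene.gene_id)
        if sites.codons_counted == 0:
            logger.warning("gene %s: zero countable codons; omitted", gene.gene_id)
            continue
        gc = GeneCounts(
            gene_id=gene.gene_id, chrom=gene.chrom,
            N=sites.N, S=sites.S,
            codons_counted=sites.codons_counted,
            codons_skipped=sites.codons_skipped,
        )
        lo, hi = gene.span
        on_chrom = variants.chrom == gene.chrom
        in_span = on_chrom & (variants.pos >= lo) & (variants.pos < hi)
        for i in np.flatnonzero(in_span):
            pos = int(variants.pos[i])
            if gene.genomic_to_cds(pos) is None:
                continue  # intronic within the gene span
            eff = classify_snp(
                gene, gene.chrom, pos,
                str(variants.ref[i]), str(variants.alt[i]), ref_genome,
            )
            if eff.effect == SKIPPED:
                gc.snps_skipped += 1
                continue
            nonsyn = eff.effect in (NONSYNONYMOUS, STOP_AFFECTED)
            if eff.effect == STOP_AFFECTED:
                gc.stop_affected += 1
            cat = _site_category(variants.genotypes[i, cols])
            if cat == "polymorphic":
                if nonsyn:
                    gc.P_N += 1
                else:
                    gc.P_S += 1
            elif cat == "fixed_alt":
                if nonsyn:
                    gc.E_N += 1
                else:
                    gc.E_S += 1
            if outgroup is not None and cat in ("fixed_ref", "fixed_alt"):
                og = str(outgroup.alleles[i])
                ingroup = str(variants.alt[i] if cat == "fixed_alt" else variants.ref[i])
                if og not in _NUCS:
                    pass  # no outgroup data at this site
                elif og not in (str(variants.ref[i]), str(variants.alt[i])):
                    gc.outgroup_skipped += 1
                elif og != ingroup:
                    if nonsyn:
                        gc.D_N += 1
                    else:
                        gc.D_S += 1
        out.append(gc)
    return out


def _warn_duplicate_symbols(genes: Sequence[GeneModel]) -> None:
    seen: dict[str, str] = {}
    for g in genes:
        if g.gene_id in seen and seen[g.gene_id] != g.chrom:
            logger.warning(
                "gene symbol %s maps to multiple loci (%s, %s); loci reported "
                "separately", g.gene_id, seen[g.gene_id], g.chrom,
            )
        seen.setdefault(g.gene_id, g.chrom)


def pnps_table(
    variants: VariantTable,
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
    samples: Sequence[str] | None = None,
) -> list[GeneCounts]:
    """Per-gene polymorphism counts and pN/pS (NaN where P_S = 0)."""
    return gene_counts(variants, genes, ref_genome, samples)


def fixed_diff_table(
    variants: VariantTable,
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
    samples: Sequence[str] | None = None,
) -> list[GeneCounts]:
    """Per-gene fixed differences from the reference, sorted by
    E_N / (P_N + 1) descending."""
    counts = gene_counts(variants, genes, ref_genome, samples)
    return sorted(counts, key=lambda c: c.e_ratio, reverse=True)


def mk_table(
    variants: VariantTable,
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
    outgroup: OutgroupAlleles,
    samples: Sequence[str] | None = None,
) -> list[GeneCounts]:
    """Per-gene McDonald-Kreitman 2x2 tables and Fixation Index."""
    return gene_counts(variants, genes, ref_genome, samples, outgroup=outgroup)
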