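"""Neutral coalescent window simulator, significance calibrator, and the
synthetic fixture generators that make the whole suite testable without
any sequencing data.

The simulator is a standard single-locus Kingman coalescent without
recombination: with k active lineages the waiting time to the next
coalescence is exponential with rate k(k-1)/2 (time in units of 2N
generations), mutations are Poisson with mean theta * L / 2 over the
total branch length L and are placed uniformly on branches under the
infinite-sites model, so every site's derived allele marks the leaves
below one branch.  Closed forms E[S] = theta * a1(n) and E[pi] = theta
hold and are exercised by the tests.

Cutoff calibration mirrors the experiment-wide simulation approach for
windowed scans: theta is estimated from the data as the mean number of
segregating sites per window divided by a1(n), neutral windows are
simulated, and the lower-tail alpha quantile of the null Tajima's D
(and normalized Fay-Wu H) distribution becomes the significance cutoff.
The experiment-wide variant takes the alpha quantile of per-replicate
minima over a whole scan's worth of windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import MISSING, GeneModel, PopulationSpec, VariantTable
from .popgen_stats import (
    faywu_h_norm_from_spectrum,
    tajima_d_from_counts,
    variance_constants,
)

__all__ = [
    "HaplotypeSample", "coalescent_window",
    "CalibrationResult", "calibrate_cutoffs",
    "island_fixture", "sweep_fixture",
    "PlannedSnp", "coding_gene_fixture",
]


# ---------------------------------------------------------------------------
# coalescent simulator
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSample:
    """An n x S 0/1 haplotype matrix from one neutral coalescent window."""

    haplotypes: np.ndarray  # (n, S), 0 = ancestral, 1 = derived
    theta: float
    seed: int | None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def S(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def sfs(self) -> np.ndarray:
        """Unfolded site-frequency spectrum (counts of sites with derived
        allele count i, i = 1..n-1)."""
        return np.bincount(self.derived_counts, minlength=self.n)[1:self.n]

    def pi(self) -> float:
        d = self.derived_counts.astype(float)
        n = self.n
        return float(np.sum(2.0 * d * (n - d) / (n * (n - 1))))

    def tajima_d(self) -> float:
        return tajima_d_from_counts(self.n, self.S, self.pi())

    def faywu_h_norm(self) -> float:
        return faywu_h_norm_from_spectrum(self.n, self.sfs())


def coalescent_window(
    n: int,
    theta: float,
    seed: int | np.random.Generator | None = None,
) -> HaplotypeSample:
    """Simulate one neutral, non-recombining window for n haplotypes."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # active lineages as leaf-membership masks with their birth times
    masks = [np.zeros(n, dtype=bool) for _ in range(n)]
    for i in range(n):
        masks[i][i] = True
    births = [0.0] * n
    t = 0.0
    branch_masks: list[np.ndarray] = []
    branch_lengths: list[float] = []
    while len(masks) > 1:
        k = len(masks)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (i, j):
            branch_masks.append(masks[idx])
            branch_lengths.append(t - births[idx])
        merged = masks[i] | masks[j]
        del masks[j], births[j]
        masks[i] = merged
        births[i] = t
    lengths = np.array(branch_lengths)
    total = lengths.sum()
    n_mut = rng.poisson(theta * total / 2.0)
    hap = np.zeros((n, n_mut), dtype=np.int8)
    if n_mut:
        which = rng.choice(len(lengths), size=n_mut, p=lengths / total)
        for col, b in enumerate(which):
            hap[branch_masks[b], col] = 1
    return HaplotypeSample(
        haplotypes=hap, theta=theta,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# significance-cutoff calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Neutral-null calibration of lower-tail D and H cutoffs."""

    n: int
    theta_hat: float
    alpha: float
    reps: int
    experiment_wide: bool
    cutoff_d: float
    cutoff_h: float
    null_d: np.ndarray
    null_h: np.ndarray


def theta_from_mean_segregating(mean_S: float, n: int) -> float:
    """Watterson-style theta-hat: mean segregating sites per window
    divided by a1(n)."""
    return mean_S / variance_constants(n).a1


def calibrate_cutoffs(
    n: int,
    theta_hat: float,
    alpha: float = 0.05,
    reps: int = 1000,
    n_windows: int = 1,
    seed: int | None = None,
    experiment_wide: bool = False,
) -> CalibrationResult:
    """Simulate neutral windows and return empirical lower-tail cutoffs.

    Per-window mode (default): the alpha quantile of the null D (and H)
    over ``reps`` simulated windows.  Experiment-wide mode: ``reps``
    replicates of ``n_windows`` windows each; the alpha quantile of the
    per-replicate minima, controlling the chance that any window of a
    neutral scan falls below the cutoff.
    """
    if theta_hat <= 0:
        raise ValueError("theta_hat must be positive")
    if reps < 100:
        raise ValueError("need reps >= 100 for a stable quantile")
    rng = np.random.default_rng(seed)
    per_window = n_windows if experiment_wide else 1
    null_d = np.full(reps, np.nan)
    null_h = np.full(reps, np.nan)
    for r in range(reps):
        ds, hs = [], []
        for _ in range(per_window):
            sample = coalescent_window(n, theta_hat, rng)
            if sample.S == 0:
                continue
            ds.append(sample.tajima_d())
            hs.append(sample.faywu_h_norm())
        if ds:
            null_d[r] = min(ds)
            null_h[r] = min(hs)
    ok = ~np.isnan(null_d)
    if not ok.any():
        raise ValueError(
            "all simulated windows were monomorphic; increase theta_hat or reps"
        )
    cutoff_d = float(np.quantile(null_d[ok], alpha))
    cutoff_h = float(np.quantile(null_h[ok], alpha))
    return CalibrationResult(
        n=n, theta_hat=theta_hat, alpha=alpha, reps=reps,
        experiment_wide=experiment_wide,
        cutoff_d=cutoff_d, cutoff_h=cutoff_h,
        null_d=null_d[ok], null_h=null_h[ok],
    )


# ---------------------------------------------------------------------------
# synthetic genotype fixtures
# ---------------------------------------------------------------------------

def _variant_table(chrom, pos, geno, sample_ids, ref="A", alt="G", qual=200.0):
    n_sites = len(pos)
    return VariantTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, ref, dtype="<U1"),
        alt=np.full(n_sites, alt, dtype="<U1"),
        qual=np.full(n_sites, qual, dtype=float),
        genotypes=np.asarray(geno, dtype=np.int8),
        sample_ids=list(sample_ids),
    )


def island_fixture(
    n_per_deme: tuple[int, int] = (3, 5),
    n_snps: int = 10_000,
    target_fst: float = 0.05,
    seed: int | None = None,
    chrom: str = "sim1",
) -> tuple[VariantTable, PopulationSpec]:
    """Two-deme Balding-Nichols genotype table with a target FST.

    Per SNP an ancestral frequency p ~ U(0.05, 0.95) is drawn; each
    deme's frequency is Beta(p (1-F)/F, (1-p)(1-F)/F) so that
    E[(p_k - p)^2] = F p (1-p), and diploid genotypes are binomial in
    the deme frequency.  ``target_fst=0`` collapses both demes to one
    panmictic pool.
    """
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    nA, nB = n_per_deme
    p = rng.uniform(0.05, 0.95, size=n_snps)
    if target_fst == 0.0:
        pA = pB = p
    else:
        F = target_fst
        shape = (1.0 - F) / F
        pA = rng.beta(p * shape, (1.0 - p) * shape)
        pB = rng.beta(p * shape, (1.0 - p) * shape)
    genoA = rng.binomial(2, pA[:, None], size=(n_snps, nA))
    genoB = rng.binomial(2, pB[:, None], size=(n_snps, nB))
    geno = np.hstack([genoA, genoB]).astype(np.int8)
    pos = np.sort(rng.choice(n_snps * 100, size=n_snps, replace=False))
    samplesA = [f"A{i + 1}" for i in range(nA)]
    samplesB = [f"B{i + 1}" for i in range(nB)]
    table = _variant_table(chrom, pos, geno, samplesA + samplesB)
    return table, PopulationSpec({"A": samplesA, "B": samplesB})


def sweep_fixture(
    n_samples: int = 11,
    length_snps: int = 400,
    tract_len: int = 50,
    seed: int | None = None,
    chrom: str = "sim1",
) -> tuple[VariantTable, PopulationSpec]:
    """Genotype table with a monomorphic sweep tract in group A only.

    Background sites are polymorphic in both groups (shared frequencies
    ~ U(0.25, 0.75)); a contiguous tract of ``tract_len`` sites in the
    middle of the chromosome is hom-alt in every group-A sample, giving
    a homozygosity score of exactly 1.0 there, while group B stays
    polymorphic.  ``tract_len=0`` produces a signal-free background.
    """
    if tract_len >= length_snps:
        raise ValueError("tract_len must be smaller than length_snps")
    rng = np.random.default_rng(seed)
    nA = n_samples // 2
    nB = n_samples - nA
    p = rng.uniform(0.25, 0.75, size=length_snps)
    geno = rng.binomial(2, p[:, None], size=(length_snps, n_samples)).astype(np.int8)
    if tract_len:
        start = (length_snps - tract_len) // 2
        geno[start:start + tract_len, :nA] = 2
    pos = np.sort(rng.choice(length_snps * 50, size=length_snps, replace=False))
    samplesA = [f"A{i + 1}" for i in range(nA)]
    samplesB = [f"B{i + 1}" for i in range(nB)]
    table = _variant_table(chrom, pos, geno, samplesA + samplesB)
    return table, PopulationSpec({"A": samplesA, "B": samplesB})


# ---------------------------------------------------------------------------
# toy coding-gene fixture (FASTA + GFF3 + VCF [+ outgroup TSV])
# ---------------------------------------------------------------------------

@dataclass
class PlannedSnp:
    """One planned CDS SNP for :func:`coding_gene_fixture`.

    ``codon``/``pos`` index the codon and in-codon position (0-2) in
    transcript orientation; ``alt`` is the transcript-orientation alt
    base.  ``pattern`` sets the genotype column: 'poly' (one het, rest
    hom-ref), 'fixed_alt' (all hom-alt) or 'fixed_ref' (all hom-ref).
    ``outgroup`` optionally writes the outgroup allele as 'ref' or 'alt'.
    """

    codon: int
    pos: int
    alt: str
    expected: str | None = None  # SYNONYMOUS / NONSYNONYMOUS / ...
    pattern: str = "poly"
    outgroup: str | None = None


_PATTERNS = {"poly", "fixed_alt", "fixed_ref"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_SENSE_CODONS = [c for c in (
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
) if c not in ("TAA", "TAG", "TGA")]


def coding_gene_fixture(
    n_codons: int,
    snp_plan: Sequence[PlannedSnp],
    seed: int | None = None,
    out_dir: str | Path = ".",
    strand: str = "+",
    codon_seq: str | None = None,
    n_samples: int = 11,
    chrom: str = "toy1",
    flank: int = 30,
) -> dict[str, Path]:
    """Write a mini reference, single-gene GFF3 and VCF realizing a plan.

    The CDS (``codon_seq`` or random sense codons) is split into two
    exons separated by a short intron when long enough, placed on the
    requested strand with ``flank`` bp of padding, and every planned SNP
    is emitted as a VCF record with the requested genotype pattern.
    Planned effects are validated downstream by SNP classification; a
    plan whose alt equals the reference base is rejected here.

    Returns paths: ``fasta``, ``gff``, ``vcf`` and (when any plan entry
    sets an outgroup allele) ``outgroup``.
    """
    from .codon_model import classify_snp

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if codon_seq is None:
        codon_seq = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    if len(codon_seq) != 3 * n_codons:
        raise ValueError("codon_seq length must be 3 * n_codons")
    cds = codon_seq.upper()

    # exon layout (genomic): [flank, flank+len1) intron [.., ..+len2)
    total = len(cds)
    if total >= 12:
        len1 = (total // 2) // 3 * 3  # keep the split codon-aligned for clarity
        intron = 20
    else:
        len1, intron = total, 0
    len2 = total - len1
    exon1 = (flank, flank + len1)
    exon2 = (exon1[1] + intron, exon1[1] + intron + len2) if len2 else None
    genome_len = (exon2[1] if exon2 else exon1[1]) + flank

    # lay the CDS onto the genome in transcription order
    genomic = list(rng.choice(list("ACGT"), size=genome_len))
    exons = [exon1] + ([exon2] if exon2 else [])
    tx_exons = exons if strand == "+" else exons[::-1]
    spliced_positions: list[int] = []
    for a, b in tx_exons:
        rng_pos = range(a, b) if strand == "+" else range(b - 1, a - 1, -1)
        spliced_positions.extend(rng_pos)
    for idx, gpos in enumerate(spliced_positions):
        base = cds[idx]
        genomic[gpos] = base if strand == "+" else base.translate(_COMPLEMENT)
    genome = "".join(genomic)

    fasta_path = out_dir / "ref.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, genome_len, 60):
            fh.write(genome[i:i + 60] + "\n")

    gff_path = out_dir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        # the exon split is codon-aligned, so every CDS piece starts in frame
        for k, (a, b) in enumerate(exons):
            fh.write(
                f"{chrom}\ttoy\tCDS\t{a + 1}\t{b}\t.\t{strand}\t0\t"
                f"ID=cds{k};Parent=gene1\n"
            )

    # realize the SNP plan
    records = []
    for snp in snp_plan:
        if snp.pattern not in _PATTERNS:
            raise ValueError(f"unknown genotype pattern {snp.pattern!r}")
        sidx = snp.codon * 3 + snp.pos
        if not 0 <= sidx < total:
            raise ValueError(f"planned SNP outside CDS: codon {snp.codon}")
        gpos = spliced_positions[sidx]
        ref_base = genome[gpos]
        alt_base = snp.alt if strand == "+" else snp.alt.translate(_COMPLEMENT)
        if alt_base == ref_base:
            raise ValueError(
                f"plan conflict at codon {snp.codon} pos {snp.pos}: alt equals "
                f"the generated reference base {ref_base!r}"
            )
        if snp.pattern == "poly":
            codes = [1] + [0] * (n_samples - 1)
        elif snp.pattern == "fixed_alt":
            codes = [2] * n_samples
        else:
            codes = [0] * n_samples
        records.append((gpos, ref_base, alt_base, codes, snp))
    records.sort(key=lambda r: r[0])
    if len({r[0] for r in records}) != len(records):
        raise ValueError("plan places two SNPs at the same genomic position")

    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    vcf_path = out_dir / "variants.vcf"
    gt_string = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom},length={genome_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for gpos, ref_base, alt_base, codes, _ in records:
            gts = "\t".join(gt_string[c] for c in codes)
            fh.write(f"{chrom}\t{gpos + 1}\t.\t{ref_base}\t{alt_base}\t200\t.\t.\tGT\t{gts}\n")

    paths = {"fasta": fasta_path, "gff": gff_path, "vcf": vcf_path}
    if any(r[4].outgroup for r in records):
        og_path = out_dir / "outgroup.tsv"
        with open(og_path, "w") as fh:
            for gpos, ref_base, alt_base, _, snp in records:
                if snp.outgroup is None:
                    continue
                allele = ref_base if snp.outgroup == "ref" else alt_base
                fh.write(f"{chrom}\t{gpos + 1}\t{allele}\n")
        paths["outgroup"] = og_path

    # validate planned effects against the generated sequence
    gene = GeneModel(gene_id="gene1", chrom=chrom, strand=strand,
                     exons=exons, phases=[0] * len(exons))

    class _MiniRef:
        def base(self, c, p):
            return genome[p]

        def fetch(self, c, a, b):
            return genome[a:b]

    for gpos, ref_base, alt_base, _, snp in records:
        if snp.expected is None:
            continue
        eff = classify_snp(gene, chrom, gpos, ref_base, alt_base, _MiniRef())
        if eff.effect != snp.expected:
            raise ValueError(
                f"plan conflict at codon {snp.codon}: expected {snp.expected}, "
                f"generated sequence yields {eff.effect}"
            )
    return paths
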