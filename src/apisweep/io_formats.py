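"""Readers and writers for the standard formats the scan suite touches.

Everything is normalized into a small internal data model:

* :class:`VariantTable` -- an ordered table of biallelic SNPs with
  per-sample diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt,
  ``MISSING`` = no call).
* :class:`PopulationSpec` -- named, disjoint groups of sample ids.
* :class:`GeneModel` -- a stranded chain of CDS intervals per gene.
* :class:`OutgroupAlleles` -- one outgroup nucleotide (or missing) per SNP.

All internal coordinates are 0-based, half-open.  Conversion to and from
1-based coordinates happens only at the VCF / outgroup-TSV boundary; BED
output is already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("apisweep")

#: genotype code for a sample with no (or a half-missing) call.
MISSING = -1

#: sentinel for an absent outgroup allele.
OUTGROUP_MISSING = "."

_NUCS = frozenset("ACGT")

DEFAULT_MIN_QUAL = 100.0


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# core table types
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Ordered biallelic SNP sites with per-sample diploid genotype codes.

    ``genotypes`` is an ``(n_sites, n_samples)`` int8 matrix of alt-allele
    counts per diploid genotype; phasing is ignored (``0|1`` == ``0/1``).
    Sites are strictly increasing by (chrom, pos) within each chromosome
    block and chromosome blocks are contiguous.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length != n_sites")
        if self.genotypes.shape != (n, len(self.sample_ids)):
            raise ValueError("genotype matrix shape != n_sites x n_samples")
        self._validate_order()
        if np.any(self.ref == self.alt):
            raise ValueError("ref allele equals alt allele at some site")

    def _validate_order(self) -> None:
        seen: set[str] = set()
        prev_chrom = None
        for i in range(len(self.pos)):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome block {c!r} is not contiguous")
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"sites not strictly increasing at {c}:{int(self.pos[i]) + 1}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        """Column indices for the given sample ids (error on unknown ids)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in variant table") from None

    def take(self, mask: np.ndarray) -> "VariantTable":
        """Row-subset of the table (mask or index array)."""
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            genotypes=self.genotypes[mask],
            sample_ids=list(self.sample_ids),
        )

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(str(c))
        return out


@dataclass
class PopulationSpec:
    """Mapping from group label to an ordered list of sample ids."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, samples in self.groups.items():
            for s in samples:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {label!r}"
                    )
                seen[s] = label

    def __getitem__(self, label: str) -> list[str]:
        return self.groups[label]

    def validate_against(self, table: VariantTable) -> None:
        known = set(table.sample_ids)
        for label, samples in self.groups.items():
            for s in samples:
                if s not in known:
                    raise FormatError(
                        f"sample {s!r} in group {label!r} is absent from the VCF"
                    )


@dataclass
class GeneModel:
    """A stranded CDS interval chain for one gene.

    ``exons`` are 0-based half-open genomic intervals listed in
    transcription order (genomic-descending for minus-strand genes).  If
    the spliced CDS length is not divisible by 3 the trailing partial
    codon is dropped at construction time and recorded in ``trimmed``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    trimmed: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        genomic = sorted(self.exons)
        for (a0, b0), (a1, b1) in zip(genomic, genomic[1:]):
            if b0 > a1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        # transcription order
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        total = sum(b - a for a, b in self.exons)
        extra = total % 3
        if extra:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; dropping trailing %d bp",
                self.gene_id, total, extra,
            )
            self.trimmed = extra
            # trim from the 3' end of the transcription-last exon
            a, b = self.exons[-1]
            if b - a <= extra:
                raise ValueError(f"gene {self.gene_id}: last CDS exon shorter than trim")
            self.exons[-1] = (a, b - extra) if self.strand == "+" else (a + extra, b)
        self._positions: np.ndarray | None = None

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all CDS exons, half-open."""
        return min(a for a, _ in self.exons), max(b for _, b in self.exons)

    def spliced_genomic_positions(self) -> np.ndarray:
        """Genomic position of every spliced CDS base, in transcription order."""
        if self._positions is None:
            parts = []
            for a, b in self.exons:
                p = np.arange(a, b)
                parts.append(p if self.strand == "+" else p[::-1])
            self._positions = np.concatenate(parts) if parts else np.empty(0, int)
        return self._positions

    def genomic_to_cds(self, pos: int) -> int | None:
        """Spliced CDS index of a genomic position, or None if outside."""
        idx = 0
        for a, b in self.exons:
            if a <= pos < b:
                return idx + (pos - a if self.strand == "+" else b - 1 - pos)
            idx += b - a
        return None


@dataclass
class OutgroupAlleles:
    """Outgroup allele per SNP site, aligned 1:1 with a VariantTable."""

    alleles: np.ndarray  # '<U1'; OUTGROUP_MISSING where absent

    def __len__(self) -> int:
        return len(self.alleles)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isin(self.alleles, list(_NUCS))


class ReferenceGenome:
    """Thin uppercase-returning wrapper around an indexed FASTA."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), 0-based half-open."""
        return str(self._fasta[chrom][start:end])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, min_qual: float = DEFAULT_MIN_QUAL) -> VariantTable:
    """Read biallelic SNPs with quality >= ``min_qual`` from a VCF.

    Multiallelic or non-SNP records are tolerated on input and dropped.
    Diploid GT fields are mapped to alt-allele counts {0, 1, 2}; genotypes
    with any uncalled allele become :data:`MISSING`.  Duplicate
    (chrom, pos) records among the retained SNPs raise an error.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own diagnostics
        raise FormatError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    rows: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue
            ref, alt = rec.REF, rec.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
                continue
            qual = rec.QUAL if rec.QUAL is not None else 0.0
            if qual < min_qual:
                continue
            key = (rec.CHROM, rec.POS - 1)
            if key in seen:
                raise FormatError(
                    f"duplicate SNP record at {rec.CHROM}:{rec.POS} in {path!r}"
                )
            seen.add(key)
            codes = np.full(len(samples), MISSING, dtype=np.int8)
            for j, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                if a >= 0 and b >= 0:
                    codes[j] = a + b
            chroms.append(rec.CHROM)
            poss.append(rec.POS - 1)
            refs.append(ref)
            alts.append(alt)
            quals.append(float(qual))
            rows.append(codes)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"malformed record in VCF {path!r}: {exc}") from exc
    geno = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype="<U1"),
        alt=np.array(alts, dtype="<U1"),
        qual=np.array(quals, dtype=float),
        genotypes=geno,
        sample_ids=samples,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the retained fields of a VariantTable as a minimal VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in table.chromosomes():
            length = int(table.pos[table.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for i in range(table.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{table.chrom[i]}\t{int(table.pos[i]) + 1}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t{table.qual[i]:g}\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff_cds(path: str | Path) -> list[GeneModel]:
    """Collect one GeneModel per gene id from the CDS features of a GFF3.

    CDS features are grouped by their ``Parent`` attribute (falling back
    to ``gene_id``/``ID``).  Features without a strand or a resolvable
    parent are skipped with a warning.  Zero resulting genes is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("gene_id") \
            or feat.attributes.get("ID")
        if not parents or feat.strand not in "+-":
            logger.warning("skipping CDS at %s:%d-%d: no strand or parent",
                           feat.seqid, feat.start, feat.end)
            continue
        gid = parents[0]
        entry = grouped.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand,
                                         "exons": [], "phases": []})
        entry["exons"].append((feat.start - 1, feat.end))
        try:
            entry["phases"].append(int(feat.frame))
        except (TypeError, ValueError):
            entry["phases"].append(0)
    genes = []
    for gid, entry in grouped.items():
        genes.append(GeneModel(gene_id=gid, chrom=entry["chrom"],
                               strand=entry["strand"], exons=entry["exons"],
                               phases=entry["phases"]))
    if not genes:
        raise FormatError(f"no CDS-bearing genes found in {path!r}")
    return genes


# ---------------------------------------------------------------------------
# TSV dialects: populations, outgroup alleles, intervals, gene tables
# ---------------------------------------------------------------------------

def read_populations(path: str | Path, table: VariantTable | None = None) -> PopulationSpec:
    """Read a ``sample<TAB>group`` TSV ('#' comments allowed)."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            sample, group = parts
            groups.setdefault(group, []).append(sample)
    spec = PopulationSpec(groups)
    if table is not None:
        spec.validate_against(table)
    return spec


def read_outgroup(path: str | Path, table: VariantTable) -> OutgroupAlleles:
    """Read ``chrom<TAB>pos(1-based)<TAB>allele`` and align it to the table.

    Sites absent from the file (or listed with a non-ACGT allele) are
    preserved and flagged missing.
    """
    lookup: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>pos<TAB>allele'")
            chrom, pos_s, allele = parts
            lookup[(chrom, int(pos_s) - 1)] = allele.upper()
    alleles = np.full(table.n_sites, OUTGROUP_MISSING, dtype="<U1")
    for i in range(table.n_sites):
        a = lookup.get((str(table.chrom[i]), int(table.pos[i])))
        if a in _NUCS:
            alleles[i] = a
    return OutgroupAlleles(alleles=alleles)


def write_intervals(intervals: Iterable, path: str | Path) -> None:
    """Write ScoredIntervals as BED3+2 (score, empirical_p columns)."""
    with open(path, "w") as fh:
        for iv in intervals:
            p = "NA" if iv.empirical_p is None else f"{iv.empirical_p:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:.6g}\t{p}\n")


def read_intervals(path: str | Path) -> list:
    """Read BED3+2 intervals written by :func:`write_intervals`."""
    from .interval_scan import ScoredInterval

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected BED3+2")
            chrom, start, end, score, p = parts[:5]
            out.append(ScoredInterval(
                chrom=chrom, start=int(start), end=int(end),
                n_sites=0, score=float(score),
                empirical_p=None if p == "NA" else float(p),
            ))
    return out


def write_gene_table(counts: Iterable, path: str | Path) -> None:
    """Write per-gene count records as a TSV keyed by gene id."""
    import pandas as pd

    rows = []
    for c in counts:
        rows.append({
            "gene": c.gene_id, "chrom": c.chrom,
            "N": c.N, "S": c.S,
            "P_N": c.P_N, "P_S": c.P_S,
            "E_N": c.E_N, "E_S": c.E_S,
            "D_N": c.D_N, "D_S": c.D_S,
            "pnps": c.pnps, "e_ratio": c.e_ratio, "fi": c.fi,
            "flags": ";".join(c.flags),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
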