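"""Shared fixtures: tiny in-memory variant tables and on-disk toy files."""

from __future__ import annotations

import numpy as np
import pytest

from apisweep.io_formats import VariantTable


def make_table(
    genotypes,
    pos=None,
    chrom="chr1",
    ref="A",
    alt="G",
    qual=200.0,
    sample_prefix="s",
):
    """Build a single-chromosome VariantTable from a genotype matrix."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = geno.shape
    if pos is None:
        pos = np.arange(n_sites) * 10
    refs = np.full(n_sites, ref, "<U1") if isinstance(ref, str) else np.asarray(ref, "<U1")
    alts = np.full(n_sites, alt, "<U1") if isinstance(alt, str) else np.asarray(alt, "<U1")
    return VariantTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=refs,
        alt=alts,
        qual=np.full(n_sites, qual, float),
        genotypes=geno,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
    )


@pytest.fixture
def toy_vcf(tmp_path):
    """Write a small VCF (with edge cases) and return its path."""

    def _write(body: str, samples=("s1", "s2", "s3")):
        path = tmp_path / "toy.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "##contig=<ID=chr2,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)
        return path

    return _write
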