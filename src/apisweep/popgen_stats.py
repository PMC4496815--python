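"""Per-site and windowed population-genetic statistics.

Covers the allele-frequency side of the scan suite:

* per-site allele frequencies and the (p_alt - p_ref)^2 homozygosity
  score used for runs-of-homozygosity scans;
* the Reich-Patterson FST estimator, per SNP and genome-wide
  (ratio of summed numerators to summed denominators), with a
  group-label randomization test;
* Tajima's D in non-overlapping windows or over arbitrary site masks,
  using the original variance constants;
* the normalized Fay-Wu H statistic with outgroup polarization and the
  Zeng variance (theta and theta^2 estimated from S).

Sample size conventions: for D and H the haplotype count n is fixed per
run at 2 x (group size).  By default only sites with complete genotypes
in the group are used; ``allow_missing=True`` keeps per-site allele
counts but retains the run-level n for the variance constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .interval_scan import ScoreTrack
from .io_formats import MISSING, OutgroupAlleles, VariantTable

__all__ = [
    "FreqTable", "allele_freqs", "homozygosity_scores",
    "reich_fst", "fst_per_snp", "fst_overall", "fst_group_randomization",
    "VarianceConstants", "variance_constants",
    "tajima_d_from_counts", "faywu_h_norm_from_spectrum",
    "WindowStat", "window_stats", "tajima_d_for_sites", "fay_wu_h_norm",
]


# ---------------------------------------------------------------------------
# allele frequencies and homozygosity
# ---------------------------------------------------------------------------

@dataclass
class FreqTable:
    """Per-site alt-allele counts for one group, aligned with a table.

    ``n`` is the called chromosome count (2 x called genotypes) and ``a``
    the alt allele count; sites with n = 0 are flagged by ``defined``.
    """

    a: np.ndarray
    n: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n > 0

    @property
    def p_alt(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.a / np.maximum(self.n, 1), np.nan)


def allele_freqs(table: VariantTable, samples: Sequence[str]) -> FreqTable:
    """Alt-allele counts per site over the called genotypes of a group."""
    if len(samples) == 0:
        raise ValueError("empty group")
    geno = table.genotypes[:, table.sample_indices(samples)]
    called = geno != MISSING
    a = np.where(called, geno, 0).sum(axis=1)
    n = 2 * called.sum(axis=1)
    return FreqTable(a=a.astype(np.int64), n=n.astype(np.int64))


def homozygosity_scores(table: VariantTable, freqs: FreqTable) -> ScoreTrack:
    """Score each defined site by (p_alt - p_ref)^2 in [0, 1].

    A site monomorphic within the group scores exactly 1.0; a balanced
    site scores 0.  Sites with no called genotypes are dropped.
    """
    keep = freqs.defined
    p = freqs.a[keep] / freqs.n[keep]
    return ScoreTrack(
        chrom=table.chrom[keep], pos=table.pos[keep],
        scores=(2.0 * p - 1.0) ** 2, provenance="homozygosity",
    )


# ---------------------------------------------------------------------------
# Reich-Patterson FST
# ---------------------------------------------------------------------------

def reich_fst(a1, n1, a2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Reich-Patterson per-SNP numerator and denominator (vectorized).

    With alt counts a_k out of n_k chromosomes and
    h_k = a_k (n_k - a_k) / (n_k (n_k - 1)):

        num = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2
        den = num + h1 + h2

    Requires n_k >= 2.  FST = num/den; negative values are possible and
    mean more variation within groups than between.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1.0))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1.0))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    return num, den


def _group_counts(table: VariantTable, samples: Sequence[str]):
    f = allele_freqs(table, samples)
    return f.a, f.n


def fst_per_snp(
    table: VariantTable,
    samplesA: Sequence[str],
    samplesB: Sequence[str],
) -> ScoreTrack:
    """Per-SNP Reich-Patterson FST as a score track.

    Sites where either group has fewer than 2 called chromosomes, or
    where the denominator is zero (both groups monomorphic for the same
    allele), are undefined and dropped.
    """
    a1, n1 = _group_counts(table, samplesA)
    a2, n2 = _group_counts(table, samplesB)
    usable = (n1 >= 2) & (n2 >= 2)
    num = np.full(table.n_sites, np.nan)
    den = np.full(table.n_sites, np.nan)
    num[usable], den[usable] = reich_fst(a1[usable], n1[usable], a2[usable], n2[usable])
    keep = usable & (den != 0.0)
    return ScoreTrack(
        chrom=table.chrom[keep], pos=table.pos[keep],
        scores=num[keep] / den[keep], provenance="fst",
    )


def fst_overall(
    table: VariantTable,
    samplesA: Sequence[str],
    samplesB: Sequence[str],
) -> float:
    """Genome-wide Reich-Patterson FST: sum of numerators over sum of
    denominators across all usable sites (not a mean of per-site ratios)."""
    a1, n1 = _group_counts(table, samplesA)
    a2, n2 = _group_counts(table, samplesB)
    usable = (n1 >= 2) & (n2 >= 2)
    num, den = reich_fst(a1[usable], n1[usable], a2[usable], n2[usable])
    total_den = float(den.sum())
    if total_den == 0.0:
        raise ValueError("no usable sites: all denominators are zero")
    return float(num.sum()) / total_den


def fst_group_randomization(
    table: VariantTable,
    samplesA: Sequence[str],
    samplesB: Sequence[str],
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Observed overall FST against random disjoint regroupings.

    Each replicate draws disjoint random groups of the observed sizes
    from all samples and recomputes the overall FST; the empirical p is
    ``(1 + #{replicates >= observed}) / (1 + reps)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    observed = fst_overall(table, samplesA, samplesB)
    rng = np.random.default_rng(seed)
    all_samples = np.array(table.sample_ids)
    kA, kB = len(samplesA), len(samplesB)
    if kA + kB > len(all_samples):
        raise ValueError("group sizes exceed sample count")
    null = np.empty(reps)
    for r in range(reps):
        picked = rng.choice(len(all_samples), size=kA + kB, replace=False)
        null[r] = fst_overall(
            table, list(all_samples[picked[:kA]]), list(all_samples[picked[kA:]])
        )
    p = (1 + int(np.sum(null >= observed))) / (1 + reps)
    return observed, p, null


# ---------------------------------------------------------------------------
# Tajima / Zeng variance machinery
# ---------------------------------------------------------------------------

@dataclass
class VarianceConstants:
    """Deterministic n-indexed constants for Tajima's D and normalized H.

    a1, a2 are the harmonic sums; b1..e2 are the Tajima (1989) variance
    coefficients; ``b_next`` is sum_{i=1}^{n} 1/i^2, used by the Zeng
    et al. (2006) variance of pi - theta_L.
    """

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    b_next: float


def variance_constants(n: int) -> VarianceConstants:
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return VarianceConstants(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        b_next=a2 + 1.0 / (n * n),
    )


def tajima_d_from_counts(n: int, S: int, pi: float) -> float:
    """Tajima's D from segregating-site count and summed pairwise
    diversity; NaN when S = 0."""
    if S == 0:
        return math.nan
    k = variance_constants(n)
    theta_w = S / k.a1
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi - theta_w) / math.sqrt(var)


def faywu_h_norm_from_spectrum(n: int, sfs: np.ndarray) -> float:
    """Normalized Fay-Wu H from an unfolded site-frequency spectrum.

    ``sfs[i-1]`` is the number of sites with derived-allele count i
    (i = 1..n-1).  H = pi - theta_L is standardized with the Zeng
    variance, estimating theta by Watterson's theta and theta^2 by
    S(S-1)/(a1^2 + a2).  NaN when there are no segregating sites.
    """
    sfs = np.asarray(sfs, dtype=float)
    if len(sfs) != n - 1:
        raise ValueError("spectrum must have n-1 entries")
    S = float(sfs.sum())
    if S == 0:
        return math.nan
    k = variance_constants(n)
    i = np.arange(1, n)
    pi = float(np.sum(2.0 * i * (n - i) * sfs) / (n * (n - 1)))
    theta_l = float(np.sum(i * sfs) / (n - 1))
    theta_w = S / k.a1
    theta_sq = S * (S - 1) / (k.a1 ** 2 + k.a2)
    var = (
        theta_w * (n - 2) / (6.0 * (n - 1))
        + theta_sq
        * (18.0 * n * n * (3 * n + 2) * k.b_next - (88.0 * n ** 3 + 9 * n * n - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
    )
    return (pi - theta_l) / math.sqrt(var)


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    """Summary statistics for one non-overlapping window."""

    chrom: str
    start: int
    end: int
    n: int
    S: int
    pi: float
    theta_w: float
    theta_l: float | None = None
    tajima_d: float = math.nan
    faywu_h_norm: float = math.nan
    sfs: np.ndarray | None = field(default=None, repr=False)


def _site_arrays(
    table: VariantTable,
    samples: Sequence[str],
    allow_missing: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-site (keep, a, n_site) under the missing-data policy, plus the
    run-level haplotype count."""
    freqs = allele_freqs(table, samples)
    n_run = 2 * len(samples)
    if allow_missing:
        keep = freqs.n >= 2
    else:
        keep = freqs.n == n_run
    return keep, freqs.a, freqs.n, n_run


def _pi_terms(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2a(n-a) / (n(n-1))."""
    a = a.astype(float)
    n = n.astype(float)
    return 2.0 * a * (n - a) / (n * (n - 1.0))


def window_stats(
    table: VariantTable,
    samples: Sequence[str],
    window_bp: int,
    chrom_lengths: dict[str, int],
    allow_missing: bool = False,
) -> list[WindowStat]:
    """Tajima's D (with S, pi, theta_W) in non-overlapping windows.

    Windows tile [0, chrom_length) half-open.  D is NaN for windows with
    no segregating sites.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    keep, a, n_site, n_run = _site_arrays(table, samples, allow_missing)
    k = variance_constants(n_run)
    out: list[WindowStat] = []
    for chrom, length in chrom_lengths.items():
        on = (table.chrom == chrom) & keep
        pos = table.pos[on]
        seg = (a[on] > 0) & (a[on] < n_site[on])
        pi_site = _pi_terms(a[on], n_site[on])
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            inw = (pos >= start) & (pos < end)
            S = int(np.sum(seg & inw))
            pi = float(np.sum(pi_site[inw & seg]))
            out.append(WindowStat(
                chrom=chrom, start=start, end=end, n=n_run, S=S,
                pi=pi, theta_w=S / k.a1,
                tajima_d=tajima_d_from_counts(n_run, S, pi),
            ))
    return out


def tajima_d_for_sites(
    table: VariantTable,
    samples: Sequence[str],
    site_mask: np.ndarray,
    allow_missing: bool = False,
) -> float:
    """Tajima's D pooled over an arbitrary site mask (e.g. the
    nonsynonymous, synonymous or noncoding site class)."""
    site_mask = np.asarray(site_mask, dtype=bool)
    if site_mask.shape != (table.n_sites,):
        raise ValueError("site_mask must have one entry per site")
    if not site_mask.any():
        raise ValueError("empty site mask")
    keep, a, n_site, n_run = _site_arrays(table, samples, allow_missing)
    sel = site_mask & keep
    seg = sel & (a > 0) & (a < n_site)
    S = int(seg.sum())
    pi = float(np.sum(_pi_terms(a[seg], n_site[seg])))
    return tajima_d_from_counts(n_run, S, pi)


def fay_wu_h_norm(
    table: VariantTable,
    samples: Sequence[str],
    outgroup: OutgroupAlleles,
    window_bp: int,
    chrom_lengths: dict[str, int],
    allow_missing: bool = False,
) -> list[WindowStat]:
    """Normalized Fay-Wu H (and Tajima's D) over polarizable sites in
    non-overlapping windows.

    The outgroup allele defines the ancestral state: where it matches the
    ref allele the derived count is the alt count, where it matches the
    alt allele the site is polarized the other way (derived = n - a);
    sites with a missing or third-allele outgroup are excluded.  Windows
    with no polarizable segregating site are NaN.
    """
    if len(outgroup) != table.n_sites:
        raise ValueError("outgroup alleles not aligned with variant table")
    keep, a, n_site, n_run = _site_arrays(table, samples, allow_missing)
    og = outgroup.alleles
    match_ref = og == table.ref
    match_alt = og == table.alt
    polarizable = keep & (match_ref | match_alt)
    derived = np.where(match_alt, n_site - a, a)
    k = variance_constants(n_run)
    out: list[WindowStat] = []
    for chrom, length in chrom_lengths.items():
        on = (table.chrom == chrom) & polarizable
        pos = table.pos[on]
        d = derived[on]
        ns = n_site[on]
        seg = (d > 0) & (d < ns)
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            inw = (pos >= start) & (pos < end) & seg
            S = int(inw.sum())
            # derived counts rescaled to the run-level n for the spectrum
            sfs = np.zeros(n_run - 1)
            pi = 0.0
            for dc, nc in zip(d[inw], ns[inw]):
                # with complete data nc == n_run; under allow_missing the
                # site's derived count is mapped to the nearest run-level bin
                bin_i = int(round(dc * n_run / nc))
                bin_i = min(max(bin_i, 1), n_run - 1)
                sfs[bin_i - 1] += 1
                pi += 2.0 * dc * (nc - dc) / (nc * (nc - 1.0))
            theta_l = float(np.sum(np.arange(1, n_run) * sfs) / (n_run - 1))
            out.append(WindowStat(
                chrom=chrom, start=start, end=end, n=n_run, S=S,
                pi=pi, theta_w=S / k.a1, theta_l=theta_l,
                tajima_d=tajima_d_from_counts(n_run, S, pi),
                faywu_h_norm=faywu_h_norm_from_spectrum(n_run, sfs),
                sfs=sfs,
            ))
    return out
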