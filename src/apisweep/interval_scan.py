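"""Locally optimal "remarkable interval" detection over per-SNP score tracks.

A score track assigns a real value to each SNP (homozygosity, per-SNP
FST, ...).  After subtracting a cutoff from every value, the scanner
reports all maximal-scoring segments in the Ruzzo-Tompa sense: disjoint
runs of consecutive SNPs with strictly positive total transformed score
whose total cannot be increased by moving either endpoint.  Zero-sum
extensions are not absorbed -- a segment stops at its last strictly
positive prefix/suffix -- so with a cutoff equal to the track maximum no
segment can ever grow beyond a single site.

Significance is assessed by permutation: scores are shuffled across
positions within each chromosome, the maximum segment score of each
permuted genome is recorded, and each observed segment gets
``p = (1 + #{replicate maxima >= score}) / (1 + reps)`` -- a family-wise
empirical p-value (never exactly zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GeneModel


@dataclass
class ScoreTrack:
    """Ordered (position, score) series, possibly spanning chromosomes.

    Positions are 0-based and strictly increasing within each chromosome
    block; scores must be finite (drop undefined sites before building).
    """

    chrom: np.ndarray
    pos: np.ndarray
    scores: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.chrom) == len(self.pos) == len(self.scores)):
            raise ValueError("chrom/pos/scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score track contains non-finite scores")
        prev = None
        for i in range(len(self.pos)):
            c = self.chrom[i]
            if c == prev and self.pos[i] <= self.pos[i - 1]:
                raise ValueError(f"positions not strictly increasing on {c}")
            prev = c

    def __len__(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks in track order."""
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(self.pos) + 1):
            if i == len(self.pos) or self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        return out


@dataclass
class ScoredInterval:
    """A maximal-scoring segment: genomic span of its member SNPs,
    member count, total cutoff-subtracted score and (optionally) the
    permutation p-value."""

    chrom: str
    start: int
    end: int
    n_sites: int
    score: float
    empirical_p: float | None = None


# ---------------------------------------------------------------------------
# Ruzzo-Tompa maximal scoring subsequences
# ---------------------------------------------------------------------------

def ruzzo_tompa(x: Sequence[float]) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences of ``x`` in one linear pass.

    Returns ``(first, last, total)`` index triples (inclusive indices),
    disjoint and in left-to-right order.  Only strictly positive totals
    are reported and tied (zero-sum) extensions are not merged.
    """
    segs: list[list] = []  # [start, end, Lcum, Rcum]
    cum = 0.0
    for k, v in enumerate(x):
        v = float(v)
        if v <= 0.0:
            cum += v
            continue
        cur = [k, k, cum, cum + v]
        cum += v
        while True:
            # rightmost stored segment whose left cumulative is below ours
            j = None
            for idx in range(len(segs) - 1, -1, -1):
                if segs[idx][2] < cur[2]:
                    j = idx
                    break
            if j is None or segs[j][3] >= cur[3]:
                segs.append(cur)
                break
            cur = [segs[j][0], cur[1], segs[j][2], cur[3]]
            del segs[j:]
    return [(s[0], s[1], s[3] - s[2]) for s in segs]


def maximal_segments(track: ScoreTrack, cutoff: float) -> list[ScoredInterval]:
    """Scan a track for maximal segments of cutoff-subtracted scores.

    Each reported interval spans its first to last member SNP (half-open,
    last position + 1); intervening SNP-free gaps carry no penalty.
    """
    out: list[ScoredInterval] = []
    for chrom, sl in track.chrom_slices():
        x = track.scores[sl] - cutoff
        pos = track.pos[sl]
        for first, last, total in ruzzo_tompa(x):
            out.append(ScoredInterval(
                chrom=chrom,
                start=int(pos[first]),
                end=int(pos[last]) + 1,
                n_sites=last - first + 1,
                score=float(total),
            ))
    return out


def percentile_cutoff(track: ScoreTrack, top_fraction: float) -> float:
    """Nearest-rank (1 - top_fraction) quantile of the scores, genome-wide."""
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    scores = np.sort(track.scores)
    if scores.size == 0:
        raise ValueError("empty score track")
    rank = math.ceil((1.0 - top_fraction) * scores.size)
    return float(scores[max(rank, 1) - 1])


def empirical_pvalues(
    track: ScoreTrack,
    cutoff: float,
    reps: int = 1000,
    seed: int | None = None,
    p_max: float | None = 0.001,
) -> list[ScoredInterval]:
    """Permutation p-values for the maximal segments of a track.

    The null shuffles score-to-position assignment within each chromosome
    and records, per replicate, the maximum segment score over the whole
    (permuted) track; p-values therefore control the family-wise rate of
    the scan.  Only segments with ``empirical_p < p_max`` are returned
    (``p_max=None`` reports everything).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    observed = maximal_segments(track, cutoff)
    if not observed:
        return []
    rng = np.random.default_rng(seed)
    blocks = [track.scores[sl] - cutoff for _, sl in track.chrom_slices()]
    null_max = np.empty(reps)
    for r in range(reps):
        best = 0.0
        for x in blocks:
            for _, _, total in ruzzo_tompa(rng.permutation(x)):
                if total > best:
                    best = total
        null_max[r] = best
    out = []
    for seg in observed:
        p = (1 + int(np.sum(null_max >= seg.score))) / (1 + reps)
        seg.empirical_p = p
        if p_max is None or p < p_max:
            out.append(seg)
    return out


def intersect_genes(
    intervals: Sequence[ScoredInterval],
    genes: Sequence[GeneModel],
):
    """(gene, interval) pairs for every >=1 bp overlap of gene span and
    interval, as a DataFrame; half-open coordinates on both sides."""
    import pandas as pd

    rows = []
    for iv in intervals:
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            lo, hi = g.span
            if lo < iv.end and iv.start < hi:
                rows.append({
                    "gene": g.gene_id, "chrom": g.chrom,
                    "gene_start": lo, "gene_end": hi,
                    "interval_start": iv.start, "interval_end": iv.end,
                    "score": iv.score, "empirical_p": iv.empirical_p,
                })
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "gene_start", "gene_end",
                 "interval_start", "interval_end", "score", "empirical_p"],
    )
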