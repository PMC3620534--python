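"""Gene-resolution quantification of histone marks and bin-gene association.

Promoter marks (H3K4me3, H3K9ac, H3K27me3) are quantified as the sum of
aligned reads within 2 kb on both sides of the TSS; H3K36me3, which
tracks transcriptional elongation through gene bodies, as the read count
over the gene's longest transcript; and the enhancer marks (H3K4me1,
H3K27ac) as the highest per-bin state ratio within 50 kb of the TSS.
Dynamic bins are associated to genes by two rules: promoter bins go to
the transcript with the closest 5' end within 2 kb, enhancer bins to the
most differentially expressed gene with a TSS within 50 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bin_signal import BinGrid

__all__ = [
    "Transcript",
    "GeneModel",
    "gene_models_from_transcripts",
    "count_reads_in_intervals",
    "promoter_score",
    "gene_body_score",
    "enhancer_profile",
    "associate_promoter_bins",
    "associate_enhancer_bins",
    "mark_change_ratio",
]

PROMOTER_HALF_WINDOW = 2000
ENHANCER_WINDOW = 50_000


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    start: int  # 0-based, half-open
    end: int

    @property
    def tss(self) -> int:
        """Genomic coordinate of the 5' base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[Transcript, ...]
    longest_transcript_id: str

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        longest = max(self.transcripts, key=lambda t: (t.length, t.transcript_id))
        by_id = {t.transcript_id: t for t in self.transcripts}
        if by_id[self.longest_transcript_id].length < longest.length:
            raise ValueError(
                f"{self.longest_transcript_id} is not the longest transcript of {self.gene_id}"
            )

    @property
    def longest(self) -> Transcript:
        return next(t for t in self.transcripts if t.transcript_id == self.longest_transcript_id)

    @property
    def tss(self) -> int:
        """Canonical TSS: the longest transcript's 5' end."""
        return self.longest.tss


def gene_models_from_transcripts(transcripts: pd.DataFrame) -> list[GeneModel]:
    """Build GeneModels from a transcript table (gene, transcript, chrom,
    strand, start, end); the longest transcript is designated per gene."""
    models = []
    for gene, sub in transcripts.groupby("gene", sort=True):
        txs = tuple(
            Transcript(r.transcript, r.chrom, r.strand, int(r.start), int(r.end))
            for r in sub.itertuples(index=False)
        )
        longest = max(txs, key=lambda t: (t.length, t.transcript_id))
        models.append(GeneModel(gene, txs, longest.transcript_id))
    return models


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_reads_in_intervals(
    reads: pd.DataFrame, chrom: str, intervals: list[tuple[int, int]]
) -> int:
    """Reads overlapping the union of half-open intervals on one chromosome.

    A read overlapping two windows of the union is counted once.
    """
    merged = _merge_intervals([(s, e) for s, e in intervals if e > s])
    if not merged:
        return 0
    sub = reads[reads["chrom"] == chrom]
    if sub.empty:
        return 0
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    hit = np.zeros(len(sub), dtype=bool)
    for s, e in merged:
        hit |= (starts < e) & (ends > s)
    return int(hit.sum())


def promoter_score(
    gene: GeneModel,
    reads: pd.DataFrame,
    chrom_size: int | None = None,
    half_window: int = PROMOTER_HALF_WINDOW,
    transcripts: str = "longest",
) -> int:
    """Sum of aligned reads within ``half_window`` bp on both sides of the TSS.

    ``transcripts='longest'`` uses the canonical (longest-transcript)
    TSS; ``'union'`` sums reads over the union of every transcript's
    window, de-duplicating overlap.  Windows are clipped at chromosome
    ends; a window entirely off-chromosome scores 0 with a warning.
    """
    if transcripts not in ("longest", "union"):
        raise ValueError(f"transcripts must be 'longest' or 'union', got {transcripts!r}")
    txs = [gene.longest] if transcripts == "longest" else list(gene.transcripts)
    chrom = txs[0].chrom
    windows = []
    for t in txs:
        s, e = t.tss - half_window, t.tss + half_window
        if chrom_size is not None:
            s, e = max(0, s), min(chrom_size, e)
        else:
            s = max(0, s)
        if e > s:
            windows.append((s, e))
    if not windows:
        warnings.warn(f"promoter window of {gene.gene_id} lies entirely off-chromosome")
        return 0
    return count_reads_in_intervals(reads, chrom, windows)


def gene_body_score(gene: GeneModel, reads: pd.DataFrame) -> int:
    """Reads overlapping the gene's longest transcript [5', 3')."""
    t = gene.longest
    if t.length <= 0:
        raise ValueError(f"zero-length transcript {t.transcript_id}")
    return count_reads_in_intervals(reads, t.chrom, [(t.start, t.end)])


def enhancer_profile(
    gene: GeneModel,
    bin_ratios: np.ndarray,
    grid: BinGrid,
    window: int = ENHANCER_WINDOW,
) -> float | None:
    """Highest per-bin state ratio among bins within ``window`` of the TSS.

    ``bin_ratios`` is a per-bin (global grid index) ratio track from
    quantile-normalized, pseudocounted counts.  Returns None (flagged by
    a warning) when no bin overlaps the window.
    """
    t = gene.longest
    size = grid.chrom_sizes[t.chrom]
    lo = max(0, t.tss - window)
    hi = min(size - 1, t.tss + window)
    if hi < lo:
        warnings.warn(f"enhancer window of {gene.gene_id} off-chromosome")
        return None
    first = int(grid.bin_index(t.chrom, lo))
    last = int(grid.bin_index(t.chrom, hi))
    return float(np.max(bin_ratios[first : last + 1]))


def associate_promoter_bins(
    bins: pd.DataFrame,
    transcripts: pd.DataFrame,
    max_dist: int = PROMOTER_HALF_WINDOW,
) -> pd.Series:
    """Map each bin to the transcript with the closest 5' end within 2 kb.

    ``bins`` needs chrom/start/end; ``transcripts`` needs chrom,
    transcript, strand and either a precomputed ``tss`` column or
    start/end to derive it.  Distance is measured from the bin midpoint.
    Equidistant 5' ends break ties by lexicographically smallest
    transcript id; bins with no 5' end within ``max_dist`` map to None.
    Returns a Series indexed like ``bins``.
    """
    tx = transcripts.copy()
    if "tss" not in tx.columns:
        tx["tss"] = np.where(tx["strand"] == "+", tx["start"], tx["end"] - 1)
    out = pd.Series([None] * len(bins), index=bins.index, dtype=object)
    for chrom, sub in bins.groupby("chrom", sort=False):
        cand = tx[tx["chrom"] == chrom].sort_values(["tss", "transcript"], kind="mergesort")
        if cand.empty:
            continue
        tss = cand["tss"].to_numpy()
        ids = cand["transcript"].to_numpy()
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        for i, mid in zip(sub.index, mids):
            d = np.abs(tss - mid)
            dmin = d.min()
            if dmin <= max_dist:
                # ties: smallest transcript id among equidistant 5' ends
                out.at[i] = min(ids[d == dmin])
    return out


def associate_enhancer_bins(
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = ENHANCER_WINDOW,
) -> pd.Series:
    """Map each bin to the most differentially expressed gene within 50 kb.

    ``genes`` needs chrom, gene, tss and log2fc (expression).  The gene
    with maximal |log2FC| whose TSS lies within ``window`` of the bin
    midpoint wins; ties go to the nearest TSS, then the
    lexicographically smallest gene id.  Unassigned bins map to None.
    """
    out = pd.Series([None] * len(bins), index=bins.index, dtype=object)
    for chrom, sub in bins.groupby("chrom", sort=False):
        cand = genes[genes["chrom"] == chrom]
        if cand.empty:
            continue
        tss = cand["tss"].to_numpy()
        ids = cand["gene"].to_numpy()
        fc = np.abs(cand["log2fc"].to_numpy(dtype=float))
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        for i, mid in zip(sub.index, mids):
            d = np.abs(tss - mid)
            near = d <= window
            if not near.any():
                continue
            best = None  # (-|fc|, dist, gene_id)
            for j in np.flatnonzero(near):
                key = (-fc[j], d[j], ids[j])
                if best is None or key < best:
                    best = key
            out.at[i] = best[2]
    return out


def mark_change_ratio(score_day7, score_day0, pseudocount: float = 1.0):
    """log2 histone enrichment ratio between states on depth-normalized scores."""
    a = np.asarray(score_day7, dtype=float)
    b = np.asarray(score_day0, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative scores")
    return np.log2((a + pseudocount) / (b + pseudocount))
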