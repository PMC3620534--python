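"""Fixed-bin ChIP-seq signal statistics for a two-state, multi-donor design.

The pipeline quantifies each histone mark on a fixed 500 bp partition of
the genome: aligned reads are extended to 200 bp from their 5' end,
counted per bin, depth-normalized by enforcing equal read counts,
enrichment over the sequencing control is tested with a Poisson
upper-tail p-value (Benjamini-Hochberg corrected), counts are quantile
normalized across experiments, and a bin is called dynamic when its
log2 fold change between states exceeds +/-0.2 in the same direction in
at least three of the four donors.

Coordinates are 0-based, half-open; bins are anchored at position 0 and
the last bin of a chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinGrid",
    "BinCounts",
    "extend_and_count",
    "normalize_equal_counts",
    "poisson_enrichment",
    "fdr_correct",
    "quantile_normalize",
    "log2_ratio",
    "call_dynamic_bins",
    "call_dynamic_bins_matrix",
    "filter_covered_bins",
    "dedup_reads",
]

DEFAULT_BIN_WIDTH = 500
DEFAULT_EXTENSION = 200
DEFAULT_FC_THRESHOLD = 0.2
DEFAULT_MIN_DONORS = 3
DEFAULT_MIN_READS = 200


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width partition of a genome, anchored at 0 on every chromosome."""

    chrom_sizes: dict[str, int]
    width: int = DEFAULT_BIN_WIDTH
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"bin width must be positive, got {self.width}")
        offsets, total = {}, 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size {size}")
            offsets[chrom] = total
            total += -(-size // self.width)
        object.__setattr__(self, "_offsets", offsets)

    def n_bins(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return -(-self.chrom_sizes[chrom] // self.width)
        return sum(-(-s // self.width) for s in self.chrom_sizes.values())

    def bin_index(self, chrom: str, pos) -> np.ndarray:
        """Global bin index of genomic position(s) on a chromosome."""
        return self._offsets[chrom] + np.asarray(pos) // self.width

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom, size in self.chrom_sizes.items():
            starts = np.arange(0, size, self.width)
            ends = np.minimum(starts + self.width, size)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class BinCounts:
    """Read counts on a :class:`BinGrid` for one (donor, state, mark) sample."""

    sample_id: tuple
    counts: np.ndarray
    total: int = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        if self.total is None:
            self.total = int(self.counts.sum())
        elif self.total != int(self.counts.sum()):
            raise ValueError("total disagrees with count vector sum")


def five_prime_ends(reads: pd.DataFrame) -> np.ndarray:
    """5' end coordinate of each read: start for '+', end for '-' (half-open)."""
    return np.where(reads["strand"].to_numpy() == "+", reads["start"], reads["end"])


def dedup_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (chrom, start, strand) records to one read."""
    return reads.drop_duplicates(subset=["chrom", "start", "strand"]).reset_index(drop=True)


def extend_and_count(
    reads: pd.DataFrame,
    grid: BinGrid,
    extension: int = DEFAULT_EXTENSION,
    sample_id: tuple = ("sample",),
    on_unknown_chrom: str = "error",
) -> BinCounts:
    """Extend each read to ``extension`` bp from its 5' end and count per bin.

    A read increments every bin its extended interval overlaps (coverage
    counting).  Intervals are clipped at chromosome ends.  Reads on a
    chromosome absent from the grid either raise or are skipped
    (``on_unknown_chrom`` in {'error', 'skip'}).
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError(f"on_unknown_chrom must be 'error' or 'skip', got {on_unknown_chrom!r}")
    counts = np.zeros(grid.n_bins(), dtype=np.int64)
    if len(reads) == 0:
        return BinCounts(sample_id, counts)
    known = reads["chrom"].isin(grid.chrom_sizes.keys())
    if not known.all():
        bad = sorted(reads.loc[~known, "chrom"].unique())
        if on_unknown_chrom == "error":
            raise ValueError(f"reads on chromosomes absent from the grid: {bad}")
        reads = reads[known]
    for chrom, sub in reads.groupby("chrom", sort=False, observed=True):
        size = grid.chrom_sizes[chrom]
        fives = np.where(sub["strand"].to_numpy() == "+", sub["start"], sub["end"])
        plus = sub["strand"].to_numpy() == "+"
        starts = np.where(plus, fives, fives - extension)
        ends = np.where(plus, fives + extension, fives)
        starts = np.clip(starts, 0, size)
        ends = np.clip(ends, 0, size)
        ok = ends > starts
        starts, ends = starts[ok], ends[ok]
        first = grid.bin_index(chrom, starts)
        last = grid.bin_index(chrom, ends - 1)
        span = last - first  # number of extra bins beyond the first
        for k in range(int(span.max()) + 1 if len(span) else 0):
            np.add.at(counts, first[span >= k] + k, 1)
    return BinCounts(sample_id, counts)


def normalize_equal_counts(samples: list[BinCounts]) -> np.ndarray:
    """Depth scale factors enforcing equal read counts across samples.

    factor_i = min(totals) / total_i, so every scaled total equals the
    smallest library.  A zero-total sample is an error (named).
    """
    totals = np.array([s.total for s in samples], dtype=float)
    for s in samples:
        if s.total == 0:
            raise ValueError(f"sample {s.sample_id} has zero total reads")
    return totals.min() / totals


def poisson_enrichment(
    chip_count,
    control_count,
    depth_ratio: float,
    lambda_floor: float,
    pseudocount: float = 1.0,
):
    """Per-bin enrichment of chip over control under a Poisson model.

    lambda = max(control * depth_ratio, lambda_floor), where depth_ratio
    scales the control to chip depth; p = P(X >= chip) for X ~
    Poisson(lambda) (upper tail, inclusive); fold change =
    (chip + c) / (lambda + c).  Accepts scalars or arrays.
    """
    chip = np.asarray(chip_count)
    control = np.asarray(control_count)
    if (chip < 0).any() or (control < 0).any():
        raise ValueError("negative counts")
    if depth_ratio <= 0 or lambda_floor <= 0:
        raise ValueError("depth_ratio and lambda_floor must be positive")
    lam = np.maximum(control * depth_ratio, lambda_floor)
    p = stats.poisson.sf(chip - 1, lam)  # sf(k-1) = P(X >= k)
    fc = (chip + pseudocount) / (lam + pseudocount)
    if np.isscalar(chip_count) and np.isscalar(control_count):
        return float(fc), float(p)
    return fc, p


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def quantile_normalize(matrix) -> np.ndarray:
    """Quantile-normalize a bins x samples count matrix.

    Every column is mapped onto the per-rank cross-sample means, so the
    sorted values of every output column are identical; within-column
    rank order is preserved, and values tied within a column receive the
    mean of the means at their tied ranks.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D bins x samples matrix")
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = rank_means.copy()
        # average the rank means within runs of tied values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n]))
        for a, b in zip(starts, stops):
            if b - a > 1:
                assigned[a:b] = rank_means[a:b].mean()
        out[order, j] = assigned
    return out


def log2_ratio(numerator, denominator, pseudocount: float = 1.0):
    """log2((a + c) / (b + c)) on depth-normalized counts."""
    a = np.asarray(numerator, dtype=float)
    b = np.asarray(denominator, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative values in ratio")
    return np.log2((a + pseudocount) / (b + pseudocount))


def call_dynamic_bins(
    log2fc_per_donor,
    threshold: float = DEFAULT_FC_THRESHOLD,
    min_donors: int = DEFAULT_MIN_DONORS,
) -> tuple[str, int]:
    """Direction call for one bin from per-donor log2 fold changes.

    'increased' iff log2FC > +threshold in >= min_donors donors,
    'decreased' iff < -threshold in >= min_donors donors, else
    'unchanged'; a tie where both directions qualify is 'unchanged'.
    Returns (direction, n_supporting).
    """
    fc = np.asarray(log2fc_per_donor, dtype=float)
    if fc.size < min_donors:
        raise ValueError(f"{fc.size} donors < min_donors={min_donors}")
    n_up = int((fc > threshold).sum())
    n_down = int((fc < -threshold).sum())
    up, down = n_up >= min_donors, n_down >= min_donors
    if up and not down:
        return "increased", n_up
    if down and not up:
        return "decreased", n_down
    return "unchanged", max(n_up, n_down)


def call_dynamic_bins_matrix(
    log2fc,
    threshold: float = DEFAULT_FC_THRESHOLD,
    min_donors: int = DEFAULT_MIN_DONORS,
) -> pd.DataFrame:
    """Vectorized :func:`call_dynamic_bins` over a bins x donors matrix."""
    fc = np.asarray(log2fc, dtype=float)
    if fc.ndim != 2:
        raise ValueError("expected bins x donors matrix")
    if fc.shape[1] < min_donors:
        raise ValueError(f"{fc.shape[1]} donors < min_donors={min_donors}")
    n_up = (fc > threshold).sum(axis=1)
    n_down = (fc < -threshold).sum(axis=1)
    up = (n_up >= min_donors) & ~(n_down >= min_donors)
    down = (n_down >= min_donors) & ~(n_up >= min_donors)
    direction = np.where(up, "increased", np.where(down, "decreased", "unchanged"))
    n_supporting = np.where(up, n_up, np.where(down, n_down, np.maximum(n_up, n_down)))
    return pd.DataFrame(
        {"direction": direction, "n_supporting": n_supporting.astype(int)}
    )


def filter_covered_bins(counts_matrix, min_reads: int = DEFAULT_MIN_READS) -> np.ndarray:
    """Boolean mask of bins where at least one sample has >= min_reads reads."""
    X = np.asarray(counts_matrix)
    if X.ndim == 1:
        X = X[:, None]
    return (X >= min_reads).any(axis=1)
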