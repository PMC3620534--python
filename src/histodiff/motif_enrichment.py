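"""Motif enrichment in regions of gained versus lost histone acetylation.

For each mark the top 5000 increasing and top 5000 decreasing bins are
selected, adjacent grid bins merged into regions, and region sequences
scanned with position weight matrices at a relative log-odds score
threshold of 80% of the (min, max) range.  A motif is called enriched
when BOTH a Fisher exact test on presence/absence of hits and a Wilcoxon
rank-sum test on per-region total hit counts give p < 0.05 between the
increasing and decreasing sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "MotifRegionSet",
    "MotifEnrichmentResult",
    "select_top_regions",
    "merge_adjacent_bins",
    "scan_pwm",
    "motif_tests",
]

DEFAULT_REL_THRESHOLD = 0.80
DEFAULT_TOP_N = 5000
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_COMP = str.maketrans("ACGTN", "TGCAN")


class PWM:
    """Position weight matrix with log-odds scoring.

    ``matrix`` is a (4, L) array of per-position base counts or
    probabilities in A, C, G, T row order.  A pseudocount (default 0.01
    per cell) is added before normalization; log-odds are taken against
    the background base frequencies (uniform 0.25 by default).
    """

    def __init__(
        self,
        motif_id: str,
        matrix: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ):
        mat = np.asarray(matrix, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 1:
            raise ValueError(f"PWM matrix must be 4 x L, got {mat.shape}")
        if (mat < 0).any():
            raise ValueError("negative PWM entries")
        self.motif_id = motif_id
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        probs = mat + pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.background = bg
        self.probs = probs
        self.logodds = np.log2(probs / bg[:, None])
        self.min_score = float(self.logodds.min(axis=0).sum())
        self.max_score = float(self.logodds.max(axis=0).sum())
        if not self.max_score > self.min_score:
            raise ValueError("degenerate PWM: max score not above min score")

    def __len__(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))

    def threshold(self, rel: float) -> float:
        """Absolute log-odds cutoff at a relative score (capped at 1)."""
        rel = min(rel, 1.0)
        return self.min_score + rel * (self.max_score - self.min_score)


def _window_scores(encoded: np.ndarray, logodds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds score of every window; second array flags windows with N."""
    m = logodds.shape[1]
    n_win = len(encoded) - m + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, m)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = logodds[safe, np.arange(m)].sum(axis=1)
    return scores, valid


def scan_pwm(
    sequence: str, pwm: PWM, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> pd.DataFrame:
    """All PWM hits on both strands of a sequence.

    A hit is any window whose log-odds score reaches
    min + rel_threshold * (max - min); overlapping hits are all
    reported.  Windows containing N are skipped.  Positions are 0-based
    forward-strand coordinates of the window start; a sequence shorter
    than the motif yields an empty hit list.
    """
    cutoff = pwm.threshold(rel_threshold)
    m = len(pwm)
    rows = []
    enc_fwd = _ENCODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    scores, valid = _window_scores(enc_fwd, pwm.logodds)
    for pos in np.flatnonzero(valid & (scores >= cutoff)):
        rows.append((int(pos), "+", float(scores[pos])))
    rc = sequence.translate(_COMP)[::-1]
    enc_rc = _ENCODE[np.frombuffer(rc.encode(), dtype=np.uint8)]
    scores, valid = _window_scores(enc_rc, pwm.logodds)
    L = len(sequence)
    for pos in np.flatnonzero(valid & (scores >= cutoff)):
        rows.append((int(L - m - pos), "-", float(scores[pos])))
    hits = pd.DataFrame(rows, columns=["position", "strand", "score"])
    return hits.sort_values(["position", "strand"], kind="mergesort").reset_index(drop=True)


@dataclass
class MotifRegionSet:
    """Merged top-bin regions of one direction, with sequences attached."""

    label: str  # 'increasing' or 'decreasing'
    regions: pd.DataFrame  # chrom, start, end
    sequences: list[str] | None = None

    def hit_counts(self, pwm: PWM, rel_threshold: float = DEFAULT_REL_THRESHOLD) -> np.ndarray:
        if self.sequences is None:
            raise ValueError(f"region set {self.label!r} has no sequences attached")
        return np.array(
            [len(scan_pwm(s, pwm, rel_threshold)) for s in self.sequences], dtype=int
        )


def merge_adjacent_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Merge bins that touch on the grid (end == next start, same chrom)."""
    if bins.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    b = bins.sort_values(["chrom", "start"], kind="mergesort")
    merged = []
    cur = None
    for r in b.itertuples(index=False):
        if cur is not None and r.chrom == cur[0] and r.start <= cur[2]:
            cur[2] = max(cur[2], r.end)
        else:
            if cur is not None:
                merged.append(tuple(cur))
            cur = [r.chrom, r.start, r.end]
    merged.append(tuple(cur))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def select_top_regions(
    bin_changes: pd.DataFrame, n: int = DEFAULT_TOP_N
) -> tuple[MotifRegionSet, MotifRegionSet]:
    """Top-n increasing and decreasing bins, merged into regions.

    ``bin_changes`` needs chrom/start/end and a ``stat`` column (the
    cross-donor mean log2FC).  Bins are ranked by |stat| within each
    sign; fewer than n available bins takes all of them with a warning.
    """
    pos = bin_changes[bin_changes["stat"] > 0]
    neg = bin_changes[bin_changes["stat"] < 0]
    sets = []
    for label, sub, ascending in (("increasing", pos, False), ("decreasing", neg, True)):
        if len(sub) < n:
            warnings.warn(f"only {len(sub)} {label} bins available (requested {n})")
        top = sub.sort_values("stat", ascending=ascending, kind="mergesort").head(n)
        sets.append(MotifRegionSet(label, merge_adjacent_bins(top[["chrom", "start", "end"]])))
    return sets[0], sets[1]


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    fisher_p: float
    wilcoxon_p: float
    significant: bool
    defined: bool = True


def motif_tests(
    up_hits: np.ndarray,
    down_hits: np.ndarray,
    motif_id: str = "",
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> MotifEnrichmentResult:
    """Joint Fisher presence test and Wilcoxon hit-count test.

    ``up_hits``/``down_hits`` are per-region total hit counts for the
    increasing and decreasing region sets.  The Fisher exact test
    compares the number of regions with >= 1 hit versus 0 hits between
    the sets; the Wilcoxon rank-sum (Mann-Whitney) test compares the
    per-region hit counts.  The motif is significant iff both p-values
    are below ``alpha``.  An empty set yields an undefined, flagged
    result.
    """
    up = np.asarray(up_hits, dtype=int)
    down = np.asarray(down_hits, dtype=int)
    if up.size == 0 or down.size == 0:
        warnings.warn(f"motif {motif_id!r}: empty region set, result undefined")
        return MotifEnrichmentResult(motif_id, np.nan, np.nan, False, defined=False)
    table = [
        [int((up > 0).sum()), int((up == 0).sum())],
        [int((down > 0).sum()), int((down == 0).sum())],
    ]
    fisher_p = float(stats.fisher_exact(table, alternative=alternative).pvalue)
    if np.all(up == up[0]) and np.all(down == down[0]) and up[0] == down[0]:
        wilcoxon_p = 1.0  # identical constant distributions carry no rank signal
    else:
        # exact null distribution for small tie-free samples, normal
        # approximation with tie correction otherwise
        wilcoxon_p = float(
            stats.mannwhitneyu(up, down, alternative=alternative, method="auto").pvalue
        )
    significant = bool(fisher_p < alpha and wilcoxon_p < alpha)
    return MotifEnrichmentResult(motif_id, fisher_p, wilcoxon_p, significant)
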