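"""Expression classification and mark/expression integration.

Genes are called up- or downregulated when the fold change between
states exceeds 2-fold AND a paired test across donors gives p < 0.05;
everything else is unchanged.  The module also builds the
mark-combination x expression-class percentage tables, donor-concordance
matrices (Spearman's rho on covered bins), and the deterministic
heat-map ordering (hierarchical clustering of columns, PCA-angle sort of
rows).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .bin_signal import DEFAULT_MIN_READS, filter_covered_bins

__all__ = [
    "classify_expression",
    "crosstab_marks_expression",
    "donor_concordance",
    "heatmap_order",
]


def classify_expression(
    day0: np.ndarray,
    day7: np.ndarray,
    fold: float = 2.0,
    alpha: float = 0.05,
    test: str = "ttest",
) -> pd.DataFrame:
    """Classify genes as up/down/unchanged from per-donor log2 values.

    ``day0``/``day7`` are genes x donors arrays of log2 expression.  The
    per-gene log2FC is the cross-donor mean of (day7 - day0); the
    p-value comes from a two-sided paired test on those differences
    (t-test by default, Wilcoxon signed-rank with ``test='wilcoxon'``).
    up: log2FC > log2(fold) and p < alpha; down: log2FC < -log2(fold)
    and p < alpha; otherwise unchanged.  Constant differences make the
    p-value undefined -> unchanged, flagged.
    """
    d0 = np.atleast_2d(np.asarray(day0, dtype=float))
    d7 = np.atleast_2d(np.asarray(day7, dtype=float))
    if d0.shape != d7.shape:
        raise ValueError("day0 and day7 must have the same shape")
    if d0.shape[1] < 2:
        raise ValueError("paired test needs >= 2 donors")
    diffs = d7 - d0
    log2fc = diffs.mean(axis=1)
    pvals = np.full(len(diffs), np.nan)
    flagged = np.zeros(len(diffs), dtype=bool)
    for i, d in enumerate(diffs):
        if np.allclose(d, d[0]):
            flagged[i] = True
            continue
        if test == "ttest":
            pvals[i] = stats.ttest_1samp(d, 0.0).pvalue
        elif test == "wilcoxon":
            pvals[i] = stats.wilcoxon(d).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    thr = np.log2(fold)
    sig = pvals < alpha
    cls = np.where(
        sig & (log2fc > thr), "up", np.where(sig & (log2fc < -thr), "down", "unchanged")
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "expr_class": cls, "p_undefined": flagged}
    )


def crosstab_marks_expression(
    gene_classes: pd.Series,
    groups: dict[str, set],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of genes per expression class within mark-combination groups.

    ``gene_classes`` maps gene -> class ('up'/'down'/'unchanged');
    ``groups`` maps a group label (e.g. 'H3K4me3+H3K36me3 up') to its
    member gene set.  Returns (percentages, counts); rows are groups,
    columns the expression classes, row percentages sum to 100.  Empty
    groups are dropped from the percentage table (undefined).
    """
    classes = ["up", "down", "unchanged"]
    count_rows, pct_rows, labels = [], [], []
    for label, members in groups.items():
        known = [g for g in members if g in gene_classes.index]
        counts = [sum(1 for g in known if gene_classes[g] == c) for c in classes]
        total = sum(counts)
        labels.append(label)
        count_rows.append(counts)
        pct_rows.append([100.0 * c / total for c in counts] if total else [np.nan] * 3)
    counts = pd.DataFrame(count_rows, index=labels, columns=classes)
    pct = pd.DataFrame(pct_rows, index=labels, columns=classes).dropna(how="all")
    return pct, counts


def spearman_rho(x, y) -> float:
    return float(stats.spearmanr(x, y).statistic)


def donor_concordance(
    counts: np.ndarray,
    min_reads: int = DEFAULT_MIN_READS,
    min_bins: int = 10,
) -> np.ndarray:
    """Donor x donor Spearman rho on log-scaled counts over covered bins.

    ``counts`` is bins x donors for one mark and state.  For each donor
    pair, bins where at least one of the two donors has >= min_reads
    reads are kept (the covered-bin filter applied pairwise), counts are
    log2(c+1)-scaled (rank-invariant; kept for plotting parity) and
    Spearman's rho computed.  Pairs with fewer than ``min_bins``
    qualifying bins get NaN with a warning.
    """
    X = np.asarray(counts, dtype=float)
    n = X.shape[1]
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = filter_covered_bins(X[:, [i, j]], min_reads)
            if mask.sum() < min_bins:
                warnings.warn(f"donor pair ({i},{j}): only {mask.sum()} covered bins")
                rho[i, j] = rho[j, i] = np.nan
                continue
            a = np.log2(X[mask, i] + 1)
            b = np.log2(X[mask, j] + 1)
            rho[i, j] = rho[j, i] = spearman_rho(a, b)
    return rho


def heatmap_order(matrix: np.ndarray):
    """Deterministic row and column ordering for change heat maps.

    Columns (tracks) are ordered by average-linkage hierarchical
    clustering on (1 - Pearson correlation) distance; rows (regions) by
    the angle of each row's projection onto the first two principal
    components of the column-centered matrix — a deterministic
    realization of ordering "by the first two principal components".
    Returns (row_order, col_order, linkage); an all-constant matrix gets
    identity orders with linkage None and a warning.
    """
    X = np.asarray(matrix, dtype=float)
    n_rows, n_cols = X.shape
    if np.allclose(X, X.flat[0]):
        warnings.warn("constant matrix: identity ordering")
        return np.arange(n_rows), np.arange(n_cols), None

    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    col_order = hierarchy.leaves_list(Z)

    centered = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic PC signs: largest-|loading| coordinate made positive,
    # so the ordering is invariant to input row permutation
    for k in range(min(2, Vt.shape[0])):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    pc1 = scores[:, 0]
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(n_rows)
    angle = np.arctan2(pc2, pc1)
    # start the circular ordering at the largest angular gap so that
    # clusters are never split by the branch cut at +/-pi
    sorted_angles = np.sort(angle)
    gaps = np.diff(sorted_angles)
    wrap_gap = 2 * np.pi - (sorted_angles[-1] - sorted_angles[0])
    if n_rows > 1 and gaps.size and gaps.max() > wrap_gap:
        origin = sorted_angles[int(np.argmax(gaps)) + 1]
    else:
        origin = sorted_angles[0]
    shifted = np.mod(angle - origin, 2 * np.pi)
    row_order = np.lexsort((np.arange(n_rows), shifted))
    return row_order, col_order, Z
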