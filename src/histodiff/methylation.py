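"""Promoter DNA-methylation summaries from RRBS-style CpG calls.

A promoter gets a methylation value per donor and state when at least 5
distinct CpGs with at least 5X coverage each fall in the oriented window
-1,000..+1,500 bp relative to the TSS; the value is the median
methylated fraction of those CpGs.  Per-state means require defined
values in at least 3 of the 4 donors.  Promoters are flagged when the
differentiated-minus-MSC delta reaches +50% (inclusive) or exceeds +25%
(strict), and CpGs are profiled by local CpG density (+/-50 bp), where
CpG-rich regions are expected hypomethylated (<10% median) and CpG-poor
regions hypermethylated (>50%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "promoter_methylation",
    "promoter_methylation_table",
    "state_methylation",
    "flag_methylation_gains",
    "format_percent",
    "cpg_density_profile",
    "methylation_expression_correlation",
]

UPSTREAM = 1000
DOWNSTREAM = 1500
MIN_CPGS = 5
MIN_COV = 5
GAIN_INCLUSIVE = 0.50
GAIN_STRICT = 0.25


def _relative_positions(pos0: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Signed distance from the TSS in transcript orientation."""
    return pos0 - tss if strand == "+" else tss - pos0


def promoter_methylation(
    tss: int,
    strand: str,
    calls: pd.DataFrame,
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
    min_cpgs: int = MIN_CPGS,
    min_cov: int = MIN_COV,
) -> tuple[float | None, int]:
    """Median methylation over qualifying CpGs in the oriented TSS window.

    ``calls`` are CpG calls on the TSS's chromosome (pos0, fraction,
    coverage).  Qualifying CpGs lie at relative positions in
    [-upstream, +downstream] (endpoints inclusive, strand-aware) with
    coverage >= min_cov.  Returns (median or None, n_qualifying);
    undefined (None) when fewer than ``min_cpgs`` qualify.
    """
    rel = _relative_positions(calls["pos0"].to_numpy(), tss, strand)
    keep = (rel >= -upstream) & (rel <= downstream) & (calls["coverage"].to_numpy() >= min_cov)
    fracs = calls.loc[keep, "fraction"].to_numpy()
    if len(fracs) < min_cpgs:
        return None, int(len(fracs))
    return float(np.median(fracs)), int(len(fracs))


def promoter_methylation_table(
    tss_table: pd.DataFrame,
    calls_by_sample: dict[tuple, pd.DataFrame],
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
    min_cpgs: int = MIN_CPGS,
    min_cov: int = MIN_COV,
) -> pd.DataFrame:
    """Vectorized per-TSS, per-(donor, state) promoter methylation.

    ``tss_table`` needs tss_id, chrom, tss, strand; ``calls_by_sample``
    maps (donor, state) -> CpG call DataFrame.  Returns long-format rows
    (tss_id, donor, state, median, n_cpgs) with NaN medians where
    undefined.
    """
    rows = []
    for (donor, state), calls in calls_by_sample.items():
        by_chrom = {}
        for chrom, sub in calls.groupby("chrom", sort=False):
            order = np.argsort(sub["pos0"].to_numpy(), kind="mergesort")
            by_chrom[chrom] = (
                sub["pos0"].to_numpy()[order],
                sub["fraction"].to_numpy()[order],
                sub["coverage"].to_numpy()[order],
            )
        for t in tss_table.itertuples(index=False):
            if t.chrom not in by_chrom:
                rows.append((t.tss_id, donor, state, np.nan, 0))
                continue
            pos, frac, cov = by_chrom[t.chrom]
            tss = int(t.tss)
            if t.strand == "+":
                lo, hi = tss - upstream, tss + downstream
            else:
                lo, hi = tss - downstream, tss + upstream
            a = np.searchsorted(pos, lo, side="left")
            b = np.searchsorted(pos, hi, side="right")
            qual = frac[a:b][cov[a:b] >= min_cov]
            if len(qual) < min_cpgs:
                rows.append((t.tss_id, donor, state, np.nan, int(len(qual))))
            else:
                rows.append((t.tss_id, donor, state, float(np.median(qual)), int(len(qual))))
    return pd.DataFrame(rows, columns=["tss_id", "donor", "state", "median", "n_cpgs"])


def state_methylation(per_donor: pd.DataFrame, min_donors: int = 3) -> pd.DataFrame:
    """Cross-donor mean promoter methylation per state.

    ``per_donor`` is the long table from
    :func:`promoter_methylation_table`.  The mean uses donors with
    defined medians only and is reported when at least ``min_donors``
    donors are defined in that state; otherwise NaN.  Returns
    (tss_id, state, mean, n_donors).
    """
    grouped = per_donor.groupby(["tss_id", "state"], sort=True)["median"]
    out = grouped.agg(mean="mean", n_donors="count").reset_index()
    out.loc[out["n_donors"] < min_donors, "mean"] = np.nan
    out["n_donors"] = out["n_donors"].astype(int)
    return out


def format_percent(value: float) -> str:
    """Percentages printed to 2 decimals below 1%, 1 decimal at or above."""
    return f"{value:.2f}%" if value < 1.0 else f"{value:.1f}%"


def flag_methylation_gains(
    state_means: pd.DataFrame,
    gain_inclusive: float = GAIN_INCLUSIVE,
    gain_strict: float = GAIN_STRICT,
) -> tuple[pd.DataFrame, dict]:
    """Flag promoters by cross-state methylation gain, with summary.

    ``state_means`` is the output of :func:`state_methylation` for
    states 0 (MSC) and 1 (differentiated).  Only TSSs with both state
    means defined enter; delta = state1 - state0.  The 50% threshold is
    inclusive (delta >= 0.50) and the 25% threshold strict
    (delta > 0.25).  The summary reports counts and percentages against
    two denominators: all TSSs in ``state_means`` (annotated) and the
    TSSs with both states defined (examined-with-data).
    """
    wide = state_means.pivot_table(index="tss_id", columns="state", values="mean", dropna=False)
    n_annotated = wide.shape[0]
    both = wide.dropna(subset=[0, 1])
    delta = both[1] - both[0]
    flags = pd.DataFrame(
        {
            "delta": delta,
            "gain50": delta >= gain_inclusive,
            "gain25": delta > gain_strict,
        }
    )
    n_examined = len(flags)
    summary = {"n_annotated": n_annotated, "n_examined": n_examined}
    for key, count in (("gain50", int(flags["gain50"].sum())), ("gain25", int(flags["gain25"].sum()))):
        summary[f"n_{key}"] = count
        for denom_name, denom in (("annotated", n_annotated), ("examined", n_examined)):
            pct = 100.0 * count / denom if denom else np.nan
            summary[f"pct_{key}_{denom_name}"] = pct
            summary[f"pct_{key}_{denom_name}_printed"] = (
                format_percent(pct) if denom else "n/a"
            )
    return flags.reset_index(), summary


def cpg_density_profile(
    calls: pd.DataFrame,
    sequences: dict[str, str],
    halfwidth: int = 50,
    min_cov: int = 10,
    density_edges: tuple = (1, 2, 4, 7, 11, 16, np.inf),
) -> pd.DataFrame:
    """Median methylation as a function of local CpG density (+/-halfwidth).

    Each call position must sit on a CG dinucleotide of the genome
    (consistency error otherwise).  Density is the count of CG starts
    within ``halfwidth`` bp on both sides of the CpG (the CpG itself
    included, so halfwidth=0 gives density 1).  Calls below ``min_cov``
    coverage are dropped first.  Returns one row per occupied density
    bin with its median methylation and CpG count.
    """
    kept = calls[calls["coverage"] >= min_cov]
    densities = np.empty(len(kept), dtype=int)
    for k, (chrom, sub) in enumerate(kept.groupby("chrom", sort=False)):
        seq = sequences[chrom]
        cg_starts = _cg_start_positions(seq)
        pos = sub["pos0"].to_numpy()
        onsite = np.isin(pos, cg_starts)
        if not onsite.all():
            bad = pos[~onsite][0]
            raise ValueError(f"CpG call at {chrom}:{bad + 1} does not match a CG in the genome")
        lo = np.searchsorted(cg_starts, pos - halfwidth, side="left")
        hi = np.searchsorted(cg_starts, pos + halfwidth, side="right")
        densities[kept["chrom"].to_numpy() == chrom] = hi - lo
    kept = kept.assign(density=densities)
    bins = pd.cut(kept["density"], bins=[e - 0.5 for e in density_edges[:-1]] + [np.inf])
    out = (
        kept.groupby(bins, observed=True)["fraction"]
        .agg(median_methylation="median", n_cpgs="count")
        .reset_index()
        .rename(columns={"density": "density_bin"})
    )
    return out


def _cg_start_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def methylation_expression_correlation(
    state_means: pd.DataFrame,
    expression_fc: pd.Series | None = None,
    min_tss: int = 10,
) -> dict:
    """Cross-state promoter-methylation r^2 and delta-vs-expression r.

    Primary statistic: squared Pearson correlation between the MSC
    (state 0) and differentiated (state 1) promoter methylation vectors
    over TSSs with both defined.  Secondary: Pearson r between the
    methylation delta and expression log2FC for TSS ids present in
    ``expression_fc``.  Zero variance in a vector makes the statistic
    NaN, flagged in the result.
    """
    wide = state_means.pivot_table(index="tss_id", columns="state", values="mean").dropna()
    result: dict = {"n_tss": len(wide)}
    if len(wide) < min_tss:
        raise ValueError(f"only {len(wide)} TSSs with both states defined (< {min_tss})")
    x, y = wide[0].to_numpy(), wide[1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        result.update(r2=np.nan, zero_variance=True)
    else:
        r = float(stats.pearsonr(x, y).statistic)
        result.update(r2=r * r, zero_variance=False)
    if expression_fc is not None:
        shared = wide.index.intersection(expression_fc.index)
        result["n_matched_genes"] = len(shared)
        if len(shared) >= min_tss:
            delta = (wide.loc[shared, 1] - wide.loc[shared, 0]).to_numpy()
            fc = expression_fc.loc[shared].to_numpy(dtype=float)
            if np.std(delta) == 0 or np.std(fc) == 0:
                result["delta_expression_r"] = np.nan
            else:
                result["delta_expression_r"] = float(stats.pearsonr(delta, fc).statistic)
        else:
            result["delta_expression_r"] = np.nan
    return result
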