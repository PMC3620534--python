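"""Seeded synthetic data emulating a two-state, multi-donor epigenome study.

The generator reproduces the shape of the study design this pipeline
analyses: mesenchymal stem cells from four donors assayed before (state
0) and after (state 1) seven days of chondrogenic differentiation, with
six histone marks plus a sequencing control per sample, per-gene
expression values per donor and state, and RRBS-style CpG methylation
calls.  Every planted signal (differential bins, regulated genes,
methylation shifts, motif instances) is recorded in a truth ledger so
downstream callers can be scored against known ground truth.

Randomness flows from one master seed through named substreams (one per
sample or concern), so adding samples does not perturb existing ones and
identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bin_signal import BinGrid

__all__ = [
    "MARKS",
    "CONTROL",
    "PROMOTER_MARKS",
    "BODY_MARKS",
    "ENHANCER_MARKS",
    "SyntheticConfig",
    "GenomeAnnotation",
    "PlantedTruth",
    "substream",
    "make_genome",
    "plant_truth",
    "simulate_bin_counts",
    "simulate_chip_reads",
    "simulate_expression",
    "simulate_methylation",
    "simulate_regulatory_sequences",
    "sample_motif_instance",
]

logger = logging.getLogger(__name__)

PROMOTER_MARKS = ("H3K4me3", "H3K9ac", "H3K27me3")
BODY_MARKS = ("H3K36me3",)
ENHANCER_MARKS = ("H3K4me1", "H3K27ac")
MARKS = PROMOTER_MARKS + BODY_MARKS + ENHANCER_MARKS
CONTROL = "control"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design constants and generator knobs for one synthetic study.

    Defaults mirror the emulated design: 4 donors, 2 states, 6 marks
    plus control, 500 bp bins.  Sequencing depth per sample is not a
    design constant of the emulated study; the default of 100,000 reads
    over 2 Mb gives roughly 35 extended-read increments per 500 bp bin,
    enough for the +/-0.2 log2FC donor rule to be exercised at realistic
    counting noise.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    bin_width: int = 500
    n_genes: int = 40
    n_donors: int = 4
    n_states: int = 2
    marks: tuple[str, ...] = MARKS
    reads_per_sample: int = 100_000
    frac_differential_bins: float = 0.05
    planted_log2fc: float = 1.0
    frac_regulated_genes: float = 0.3
    expression_log2fc: float = 3.0
    expression_noise_sd: float = 0.2
    expression_donor_sd: float = 0.1
    donor_effect_sd: float = 0.1
    read_length: int = 36
    tss_spacing: int = 10_000
    # methylation
    frac_meth_shift: float = 0.1
    meth_shift_delta: float = 0.6
    cpg_cov_mean: float = 30.0
    cpg_cov_dispersion: float = 5.0
    cpg_cov_fixed: int | None = None
    meth_donor_sd: float = 0.02
    # motifs
    motif_plant_rate: float = 0.4
    region_length: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_donors < 2:
            raise ValueError(f"n_donors must be >= 2, got {self.n_donors}")
        if self.chrom_length % self.bin_width != 0:
            raise ValueError(
                f"chrom_length {self.chrom_length} not divisible by bin width {self.bin_width}"
            )
        if not 0 <= self.frac_differential_bins < 0.5:
            raise ValueError(
                f"frac_differential_bins must be in [0, 0.5), got {self.frac_differential_bins}"
            )
        if self.n_chroms < 1 or self.n_genes < 0 or self.reads_per_sample < 0:
            raise ValueError("n_chroms >= 1, n_genes >= 0, reads_per_sample >= 0 required")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent generator for a named substream of a master seed."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, random sequence, and gene models with transcripts."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str]
    transcripts: pd.DataFrame  # gene, transcript, chrom, strand, start, end, tss, is_longest
    genes: pd.DataFrame  # gene, chrom, strand, tss, longest_transcript, cpg_island

    def grid(self, width: int = 500) -> BinGrid:
        return BinGrid(self.chrom_sizes, width)


@dataclass
class PlantedTruth:
    """Ledger of every planted signal, keyed to the bin grid and genes."""

    differential_bins: pd.DataFrame  # bin, mark, direction
    regulated_genes: pd.DataFrame  # gene, expr_class, log2fc
    methylation_shifts: dict[str, float] = field(default_factory=dict)  # gene -> delta
    planted_motif_regions: set = field(default_factory=set)

    def bins_for(self, mark: str, direction: str | None = None) -> np.ndarray:
        df = self.differential_bins
        sel = df["mark"] == mark
        if direction is not None:
            sel &= df["direction"] == direction
        return df.loc[sel, "bin"].to_numpy()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(config: SyntheticConfig) -> GenomeAnnotation:
    """Random genome with well-spaced gene models (1-3 transcripts each).

    TSSs are placed >= ``tss_spacing`` (default 10 kb) apart so that
    +/-2 kb promoter windows rarely collide.  Roughly half the genes get
    a planted CpG-rich stretch around the TSS (a CpG-island stand-in for
    the methylation analyses).  Raises if the requested genes do not fit
    at the stated spacing.
    """
    margin = 20_000
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    per_chrom = _split_genes(config.n_genes, config.n_chroms)
    for chrom, n in zip(chrom_sizes, per_chrom):
        needed = 2 * margin + n * config.tss_spacing
        if n and needed > config.chrom_length:
            raise ValueError(
                f"{n} genes at {config.tss_spacing} bp spacing do not fit on "
                f"{chrom} of length {config.chrom_length}"
            )

    sequences: dict[str, str] = {}
    tx_rows, gene_rows = [], []
    gene_idx = 0
    for chrom, n in zip(chrom_sizes, per_chrom):
        rng_seq = substream(config.seed, "genome", chrom)
        seq = rng_seq.choice(_BASES, size=config.chrom_length).copy()
        rng_gene = substream(config.seed, "genes", chrom)
        pos = margin
        for _ in range(n):
            tss = int(pos + rng_gene.integers(0, min(2000, config.tss_spacing // 5)))
            pos += config.tss_spacing
            gene = f"G{gene_idx:04d}"
            strand = "+" if rng_gene.random() < 0.5 else "-"
            island = bool(rng_gene.random() < 0.5)
            n_tx = int(rng_gene.integers(1, 4))
            lengths = np.sort(rng_gene.integers(2000, 8001, size=n_tx))[::-1]
            longest = f"{gene}.t0"
            for t, length in enumerate(lengths):
                # alternative transcripts may start slightly off the main TSS
                shift = 0 if t == 0 else int(rng_gene.integers(-400, 401))
                t5 = tss + shift
                if strand == "+":
                    start, end = t5, min(t5 + int(length), config.chrom_length)
                else:
                    start, end = max(0, t5 - int(length) + 1), t5 + 1
                tx_rows.append(
                    (gene, f"{gene}.t{t}", chrom, strand, start, end, t5, t == 0)
                )
            if island:
                _plant_cpg_island(seq, tss, halfwidth=250)
            gene_rows.append((gene, chrom, strand, tss, longest, island))
            gene_idx += 1
        sequences[chrom] = seq.tobytes().decode()

    transcripts = pd.DataFrame(
        tx_rows,
        columns=["gene", "transcript", "chrom", "strand", "start", "end", "tss", "is_longest"],
    )
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "strand", "tss", "longest_transcript", "cpg_island"]
    )
    return GenomeAnnotation(chrom_sizes, sequences, transcripts, genes)


def _split_genes(n_genes: int, n_chroms: int) -> list[int]:
    base, extra = divmod(n_genes, n_chroms)
    return [base + (1 if i < extra else 0) for i in range(n_chroms)]


def _plant_cpg_island(seq: np.ndarray, tss: int, halfwidth: int, step: int = 8) -> None:
    lo = max(0, tss - halfwidth)
    hi = min(len(seq) - 1, tss + halfwidth)
    for p in range(lo, hi, step):
        seq[p] = b"C"
        seq[p + 1] = b"G"


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def plant_truth(annotation: GenomeAnnotation, config: SyntheticConfig) -> PlantedTruth:
    """Choose regulated genes, co-regulated mark bins, background
    differential bins, and methylation-shift promoters.

    Upregulated genes gain H3K4me3/H3K9ac at the promoter bin, H3K36me3
    in the gene body, an enhancer bin (H3K4me1 + H3K27ac) within 50 kb,
    and lose H3K27me3; downregulated genes mirror this.  Additional
    background bins are planted per mark up to ``frac_differential_bins``
    of the grid, split evenly between directions.
    """
    grid = annotation.grid(config.bin_width)
    rng = substream(config.seed, "truth")
    genes = annotation.genes

    n_reg = int(round(config.frac_regulated_genes * len(genes)))
    reg_idx = rng.choice(len(genes), size=n_reg, replace=False) if n_reg else np.array([], int)
    half = n_reg // 2
    reg_rows = []
    diff_rows = []
    for i, gi in enumerate(sorted(reg_idx)):
        g = genes.iloc[gi]
        up = i < n_reg - half  # first part up, rest down
        expr_class = "up" if up else "down"
        sign = 1.0 if up else -1.0
        reg_rows.append((g["gene"], expr_class, sign * config.expression_log2fc))
        direction = "increased" if up else "decreased"
        anti = "decreased" if up else "increased"
        tss_bin = int(grid.bin_index(g["chrom"], g["tss"]))
        for mark in ("H3K4me3", "H3K9ac"):
            diff_rows.append((tss_bin, mark, direction))
        diff_rows.append((tss_bin, "H3K27me3", anti))
        tx = annotation.transcripts
        lt = tx[(tx["gene"] == g["gene"]) & tx["is_longest"]].iloc[0]
        body_mid = (int(lt["start"]) + int(lt["end"])) // 2
        diff_rows.append((int(grid.bin_index(g["chrom"], body_mid)), "H3K36me3", direction))
        offset = int(rng.integers(10_000, 45_000)) * (1 if rng.random() < 0.5 else -1)
        enh_pos = int(np.clip(g["tss"] + offset, 0, annotation.chrom_sizes[g["chrom"]] - 1))
        enh_bin = int(grid.bin_index(g["chrom"], enh_pos))
        for mark in ENHANCER_MARKS:
            diff_rows.append((enh_bin, mark, direction))

    n_bins = grid.n_bins()
    taken = {(b, m) for b, m, _ in diff_rows}
    for mark in config.marks:
        target = int(round(config.frac_differential_bins * n_bins))
        have = sum(1 for b, m, _ in diff_rows if m == mark)
        extra = max(0, target - have)
        if extra:
            pool = rng.permutation(n_bins)
            added = 0
            for b in pool:
                if added >= extra:
                    break
                if (int(b), mark) in taken:
                    continue
                direction = "increased" if added % 2 == 0 else "decreased"
                diff_rows.append((int(b), mark, direction))
                taken.add((int(b), mark))
                added += 1

    # zero effect size or a zero differential-bin budget means a null ChIP
    # landscape: the ledger carries no directional bins at all
    if config.planted_log2fc == 0 or config.frac_differential_bins == 0:
        diff_rows = []

    # methylation gains are planted on hypomethylated (CpG-island) promoters
    # first: a +delta on an already-hypermethylated promoter would clip
    unreg = genes.loc[~genes.index.isin(reg_idx)]
    n_shift = int(round(config.frac_meth_shift * len(genes)))
    if len(unreg) and n_shift:
        island_mask = unreg["cpg_island"].astype(bool)
        ordered = pd.concat([unreg[island_mask], unreg[~island_mask]])
        shifts = {g: config.meth_shift_delta for g in ordered["gene"].head(n_shift)}
    else:
        shifts = {}

    differential = pd.DataFrame(diff_rows, columns=["bin", "mark", "direction"])
    regulated = pd.DataFrame(reg_rows, columns=["gene", "expr_class", "log2fc"])
    return PlantedTruth(differential, regulated, methylation_shifts=shifts)


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

def _sample_ids(config: SyntheticConfig):
    for donor in range(config.n_donors):
        for state in range(config.n_states):
            for mark in tuple(config.marks) + (CONTROL,):
                yield (donor, state, mark)


def simulate_bin_counts(
    annotation: GenomeAnnotation,
    truth: PlantedTruth,
    config: SyntheticConfig,
    grid: BinGrid | None = None,
) -> dict[tuple, np.ndarray]:
    """Generative per-bin read counts for every (donor, state, mark) sample.

    Background reads are uniform per base; planted bins receive a
    multiplicative Poisson bump of 2**(planted_log2fc * donor multiplier)
    in the state carrying the signal ('increased' -> state 1,
    'decreased' -> state 0).  The control track carries no planted
    signal.  Totals are exactly ``reads_per_sample`` (multinomial).
    """
    grid = grid or annotation.grid(config.bin_width)
    bins = grid.to_dataframe()
    base_w = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    n_bins = len(base_w)
    out: dict[tuple, np.ndarray] = {}
    for donor, state, mark in _sample_ids(config):
        rng = substream(config.seed, "chip", donor, state, mark)
        w = base_w.copy()
        if mark != CONTROL and len(truth.differential_bins):
            donor_mult = float(
                substream(config.seed, "donor_effect", donor, mark).lognormal(
                    0.0, config.donor_effect_sd
                )
            )
            sub = truth.differential_bins[truth.differential_bins["mark"] == mark]
            for direction, signal_state in (("increased", 1), ("decreased", 0)):
                if state == signal_state:
                    b = sub.loc[sub["direction"] == direction, "bin"].to_numpy()
                    w[b] *= 2.0 ** (config.planted_log2fc * donor_mult)
        if config.reads_per_sample == 0:
            logger.warning("sample %s has reads_per_sample=0; emitting empty sample",
                           (donor, state, mark))
            out[(donor, state, mark)] = np.zeros(n_bins, dtype=np.int64)
            continue
        out[(donor, state, mark)] = rng.multinomial(config.reads_per_sample, w / w.sum())
    return out


def simulate_chip_reads(
    annotation: GenomeAnnotation,
    truth: PlantedTruth,
    config: SyntheticConfig,
    grid: BinGrid | None = None,
) -> dict[tuple, pd.DataFrame]:
    """Materialize :func:`simulate_bin_counts` as stranded read records.

    Each counted read gets a uniform 5' position inside its bin and a
    random strand; records are BED-like (chrom, start, end, name, score,
    strand), 0-based half-open, clipped at chromosome ends.
    """
    grid = grid or annotation.grid(config.bin_width)
    bins = grid.to_dataframe()
    bin_chrom = bins["chrom"].to_numpy()
    bin_start = bins["start"].to_numpy()
    bin_len = (bins["end"] - bins["start"]).to_numpy()
    counts_by_sample = simulate_bin_counts(annotation, truth, config, grid)
    out: dict[tuple, pd.DataFrame] = {}
    for sid, counts in counts_by_sample.items():
        rng = substream(config.seed, "reads", *sid)
        total = int(counts.sum())
        idx = np.repeat(np.arange(len(counts)), counts)
        offs = (rng.random(total) * bin_len[idx]).astype(np.int64)
        five = bin_start[idx] + offs
        plus = rng.random(total) < 0.5
        sizes = np.array([annotation.chrom_sizes[c] for c in bin_chrom[idx]]) if total else np.array([], int)
        start = np.where(plus, five, np.maximum(0, five + 1 - config.read_length))
        end = np.where(plus, np.minimum(sizes, five + config.read_length), five + 1)
        df = pd.DataFrame(
            {
                "chrom": bin_chrom[idx],
                "start": start.astype(np.int64),
                "end": end.astype(np.int64),
                "name": [f"r{i}" for i in range(total)],
                "score": 0,
                "strand": np.where(plus, "+", "-"),
            }
        )
        out[sid] = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    annotation: GenomeAnnotation, truth: PlantedTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Per-gene, per-donor, per-state log2 expression values.

    value = gene baseline + donor effect + state effect (the planted
    log2FC, applied in state 1) + Gaussian noise.  Unregulated genes
    have zero state effect.
    """
    genes = annotation.genes["gene"].tolist()
    missing = set(truth.regulated_genes["gene"]) - set(genes)
    if missing:
        raise ValueError(f"regulated genes absent from annotation: {sorted(missing)}")
    fc = dict(zip(truth.regulated_genes["gene"], truth.regulated_genes["log2fc"]))
    rng_base = substream(config.seed, "expr_baseline")
    baselines = {g: 8.0 + 2.0 * rng_base.standard_normal() for g in genes}
    rows = []
    for donor in range(config.n_donors):
        rng = substream(config.seed, "expr", donor)
        donor_eff = config.expression_donor_sd * rng.standard_normal()
        for state in range(config.n_states):
            noise = config.expression_noise_sd * rng.standard_normal(len(genes))
            for g, eps in zip(genes, noise):
                value = baselines[g] + donor_eff + (fc.get(g, 0.0) if state == 1 else 0.0) + eps
                rows.append((g, donor, state, value))
    return pd.DataFrame(rows, columns=["gene", "donor", "state", "log2_value"])


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def simulate_methylation(
    annotation: GenomeAnnotation, truth: PlantedTruth, config: SyntheticConfig
) -> dict[tuple, pd.DataFrame]:
    """RRBS-style CpG calls per (donor, state).

    CpG positions are the genome's actual CG dinucleotides inside
    oriented promoter windows (-1,000..+1,500 around each TSS) plus a
    thinned genome-wide background.  CpG-island promoters are drawn
    hypomethylated, CpG-poor ones hypermethylated; promoters in the
    truth's methylation-shift set gain the planted delta in state 1
    (clipped into [0,1] with a log message).  Coverage is negative
    binomial (floored at 1) unless ``cpg_cov_fixed`` pins it.
    """
    for g in truth.methylation_shifts:
        if g not in set(annotation.genes["gene"]):
            raise ValueError(f"methylation-shift promoter {g} absent from annotation")
    rng_truth = substream(config.seed, "meth_truth")
    sites = []  # chrom, pos0, base fraction, delta
    for _, g in annotation.genes.iterrows():
        seq = annotation.sequences[g["chrom"]]
        tss, strand = int(g["tss"]), g["strand"]
        lo, hi = (tss - 1000, tss + 1500) if strand == "+" else (tss - 1500, tss + 1000)
        lo, hi = max(0, lo), min(len(seq) - 1, hi)
        pos = _cpg_positions(seq[lo : hi + 2]) + lo
        if g["cpg_island"]:
            base = float(rng_truth.uniform(0.02, 0.15))
        else:
            base = float(rng_truth.uniform(0.50, 0.95))
        delta = truth.methylation_shifts.get(g["gene"], 0.0)
        for p in pos:
            sites.append((g["chrom"], int(p), base, delta))
    # background CpGs outside promoters, thinned
    rng_bg = substream(config.seed, "meth_background")
    promoter_pos = {(c, p) for c, p, _, _ in sites}
    for chrom, seq in annotation.sequences.items():
        pos = _cpg_positions(seq)
        keep = pos[rng_bg.random(len(pos)) < 0.02]
        for p in keep:
            if (chrom, int(p)) not in promoter_pos:
                sites.append((chrom, int(p), float(rng_bg.uniform(0.5, 0.95)), 0.0))
    site_df = pd.DataFrame(sites, columns=["chrom", "pos0", "base", "delta"]).sort_values(
        ["chrom", "pos0"], kind="mergesort"
    ).drop_duplicates(["chrom", "pos0"]).reset_index(drop=True)

    out: dict[tuple, pd.DataFrame] = {}
    n = len(site_df)
    n_clipped = 0
    for donor in range(config.n_donors):
        for state in range(config.n_states):
            rng = substream(config.seed, "meth", donor, state)
            true_frac = site_df["base"].to_numpy().copy()
            if state == 1:
                shifted = true_frac + site_df["delta"].to_numpy()
                n_clipped += int(((shifted < 0) | (shifted > 1)).sum())
                true_frac = shifted
            true_frac = np.clip(
                true_frac + config.meth_donor_sd * rng.standard_normal(n), 0.0, 1.0
            )
            if config.cpg_cov_fixed is not None:
                cov = np.full(n, config.cpg_cov_fixed, dtype=np.int64)
            else:
                k = config.cpg_cov_dispersion
                p = k / (k + config.cpg_cov_mean)
                cov = np.maximum(1, rng.negative_binomial(k, p, size=n))
            meth = rng.binomial(cov, true_frac)
            out[(donor, state)] = pd.DataFrame(
                {
                    "chrom": site_df["chrom"],
                    "pos0": site_df["pos0"],
                    "fraction": meth / cov,
                    "coverage": cov,
                }
            )
    if n_clipped:
        logger.info("clipped %d shifted CpG fractions into [0, 1]", n_clipped)
    return out


# ---------------------------------------------------------------------------
# motif-bearing sequences
# ---------------------------------------------------------------------------

def sample_motif_instance(pwm_probs: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one motif instance from per-position base probabilities (4 x L)."""
    probs = np.asarray(pwm_probs, dtype=float)
    probs = probs / probs.sum(axis=0, keepdims=True)
    return "".join("ACGT"[rng.choice(4, p=probs[:, j])] for j in range(probs.shape[1]))


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_regulatory_sequences(
    regions: pd.DataFrame,
    pwm_probs: np.ndarray,
    plant_rate: float,
    config: SyntheticConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random region sequences with motif instances planted in 'up' regions.

    ``regions`` needs columns ``region`` and ``label`` ('up'/'down') and
    optionally ``length``.  A fraction ``plant_rate`` of up regions gets
    one PWM-sampled instance at a random position and strand; down
    regions are never planted.  Returns (sequences, ledger of planted
    positions).  Regions shorter than the motif are skipped with a
    warning.
    """
    probs = np.asarray(pwm_probs, dtype=float)
    colsums = probs.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        probs = probs / colsums
    m = probs.shape[1]
    seqs: dict[str, str] = {}
    ledger_rows = []
    for i, row in enumerate(regions.itertuples(index=False)):
        length = int(getattr(row, "length", config.region_length) or config.region_length)
        rng = substream(config.seed, "regseq", row.region)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if row.label == "up" and rng.random() < plant_rate:
            if length < m:
                warnings.warn(
                    f"region {row.region} shorter than motif ({length} < {m}); skipped"
                )
                seqs[row.region] = seq
                continue
            inst = sample_motif_instance(probs, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = inst.translate(_COMP)[::-1]
            pos = int(rng.integers(0, length - m + 1))
            seq = seq[:pos] + inst + seq[pos + m :]
            ledger_rows.append((row.region, pos, strand))
        seqs[row.region] = seq
    ledger = pd.DataFrame(ledger_rows, columns=["region", "position", "strand"])
    return seqs, ledger
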