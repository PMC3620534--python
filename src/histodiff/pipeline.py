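"""Structured configuration and the end-to-end pipeline driver.

``run_pipeline`` executes simulate -> bins -> enrich -> dynamic ->
genescore -> associate -> classify -> crosstab -> concordance ->
heatmap -> motifs -> methylation on one config, writing every stage's
outputs under a run directory and returning a :class:`RunManifest`
(config hash, input checksums, per-stage row counts) that is
reproducible bit-for-bit given the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bin_signal, expression_integration, gene_marks, io as hio, methylation, motif_enrichment, synthetic_data
from .bin_signal import BinGrid
from .motif_enrichment import PWM
from .synthetic_data import CONTROL, SyntheticConfig, substream

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo_config", "DEMO_PWM_COUNTS"]

logger = logging.getLogger(__name__)

# SOX-family-like matrix around the AACAAT core, extended to 9 positions so
# an 80%-of-range threshold stays selective on random sequence; counts are a
# synthetic stand-in, not a database entry
DEMO_PWM_COUNTS = np.array(
    [
        [91, 91, 3, 91, 91, 3, 91, 3, 3],  # A
        [3, 3, 91, 3, 3, 3, 3, 3, 3],      # C
        [3, 3, 3, 3, 3, 3, 3, 91, 91],     # G
        [3, 3, 3, 3, 3, 91, 3, 3, 3],      # T
    ],
    dtype=float,
)


@dataclass
class PipelineConfig:
    """All stage parameters, with the analysis defaults used throughout."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extension: int = 200
    fc_threshold: float = 0.2
    min_donors: int = 3
    min_reads: int = 200
    promoter_half_window: int = 2000
    enhancer_window: int = 50_000
    expression_fold: float = 2.0
    alpha: float = 0.05
    expression_test: str = "ttest"
    top_n: int = 5000
    rel_threshold: float = 0.80
    motif_mark: str = "H3K27ac"
    meth_upstream: int = 1000
    meth_downstream: int = 1500
    min_cpgs: int = 5
    min_cov: int = 5
    # whether the Poisson lambda scales the control to chip depth (True) or
    # the chip to control depth; the published procedure does not say
    control_scaled_to_chip: bool = True
    # optional additional q-value cut on enrichment when filtering covered
    # bins; None applies the read-count filter only
    enrichment_q_cutoff: float | None = None

    def __post_init__(self):
        if self.min_donors > self.synthetic.n_donors:
            raise ValueError(
                f"min_donors={self.min_donors} exceeds n_donors={self.synthetic.n_donors}"
            )
        if not 0 < self.rel_threshold:
            raise ValueError("rel_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("extension", "min_reads", "promoter_half_window", "enhancer_window",
                     "top_n", "meth_upstream", "meth_downstream", "min_cpgs", "min_cov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expression_fold < 1:
            raise ValueError("expression_fold must be >= 1")

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["marks"] = list(d["synthetic"]["marks"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "marks" in syn:
            syn["marks"] = tuple(syn["marks"])
        return cls(synthetic=SyntheticConfig(**syn), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small, fast configuration exercising every stage end-to-end."""
    syn = SyntheticConfig(
        n_chroms=2,
        chrom_length=200_000,
        n_genes=10,
        reads_per_sample=20_000,
        frac_differential_bins=0.05,
        seed=seed,
    )
    # min_reads scales with the demo's shallow depth (~35 extended-read
    # increments per bin); the parameter default elsewhere stays 200
    return PipelineConfig(synthetic=syn, top_n=50, min_reads=30)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    input_checksums: dict
    row_counts: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sample_name(sid: tuple) -> str:
    donor, state, mark = sid
    return f"d{donor}_s{state}_{mark}"


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    rows: dict[str, int] = {}
    checksums: dict[str, str] = {}

    # ----- simulate -------------------------------------------------------
    annotation = synthetic_data.make_genome(syn)
    truth = synthetic_data.plant_truth(annotation, syn)
    grid = annotation.grid(syn.bin_width)
    pwm = PWM("DEMO_SOX", DEMO_PWM_COUNTS)
    _plant_motifs_in_genome(annotation, truth, grid, pwm, syn)

    simdir = outdir / "simulate"
    simdir.mkdir(exist_ok=True)
    hio.write_chrom_sizes(annotation.chrom_sizes, simdir / "chrom.sizes")
    hio.write_bed12(annotation.transcripts, simdir / "genes.bed12")
    hio.write_fasta(annotation.sequences, simdir / "genome.fa")
    reads_by_sample = synthetic_data.simulate_chip_reads(annotation, truth, syn, grid)
    for sid, reads in reads_by_sample.items():
        hio.write_bed(reads, simdir / f"reads_{_sample_name(sid)}.bed")
    expression = synthetic_data.simulate_expression(annotation, truth, syn)
    hio.write_tsv(expression, simdir / "expression.tsv")
    calls_by_sample = synthetic_data.simulate_methylation(annotation, truth, syn)
    for (donor, state), calls in calls_by_sample.items():
        hio.write_cpg_calls(calls, simdir / f"cpg_d{donor}_s{state}.tsv")
    hio.write_tsv(truth.differential_bins, simdir / "truth_differential_bins.tsv")
    hio.write_tsv(truth.regulated_genes, simdir / "truth_regulated_genes.tsv")
    for name in ("chrom.sizes", "genes.bed12", "genome.fa", "expression.tsv"):
        checksums[name] = _sha256(simdir / name)
    rows["simulate.reads"] = sum(len(r) for r in reads_by_sample.values())
    rows["simulate.expression"] = len(expression)
    rows["simulate.cpg_calls"] = sum(len(c) for c in calls_by_sample.values())
    logger.info("stage=simulate samples=%d reads=%d cpgs=%d",
                len(reads_by_sample), rows["simulate.reads"], rows["simulate.cpg_calls"])

    # ----- bins -----------------------------------------------------------
    bindir = outdir / "bins"
    bindir.mkdir(exist_ok=True)
    counts_by_sample = {
        sid: bin_signal.extend_and_count(reads, grid, config.extension, sample_id=sid)
        for sid, reads in reads_by_sample.items()
    }
    count_matrix = pd.DataFrame(
        {_sample_name(sid): bc.counts for sid, bc in counts_by_sample.items()}
    )
    hio.write_tsv(count_matrix, bindir / "bin_counts.tsv")
    for sid, bc in counts_by_sample.items():
        hio.write_bedgraph(grid, bc.counts, bindir / f"{_sample_name(sid)}.bedGraph")
    rows["bins.bins"] = grid.n_bins()
    logger.info("stage=bins bins=%d samples=%d", grid.n_bins(), len(counts_by_sample))

    # ----- enrich ---------------------------------------------------------
    enrich_rows = []
    for donor in range(syn.n_donors):
        for state in range(syn.n_states):
            control = counts_by_sample[(donor, state, CONTROL)]
            if control.total == 0:
                raise ValueError(f"control sample (donor {donor}, state {state}) has no reads")
            for mark in syn.marks:
                chip = counts_by_sample[(donor, state, mark)]
                depth_ratio = (
                    chip.total / control.total if config.control_scaled_to_chip
                    else control.total / chip.total
                )
                lam_floor = max(chip.total / grid.n_bins(), 1e-9)
                fc, p = bin_signal.poisson_enrichment(
                    chip.counts, control.counts, depth_ratio, lam_floor
                )
                q = bin_signal.fdr_correct(p)
                enrich_rows.append(
                    pd.DataFrame(
                        {
                            "bin": np.arange(grid.n_bins()),
                            "donor": donor,
                            "state": state,
                            "mark": mark,
                            "fold_change": fc,
                            "p_value": p,
                            "q_value": q,
                        }
                    )
                )
    enrichment = pd.concat(enrich_rows, ignore_index=True)
    hio.write_tsv(enrichment, outdir / "enrichment.tsv")
    rows["enrich.tests"] = len(enrichment)
    logger.info("stage=enrich tests=%d", len(enrichment))

    # ----- dynamic --------------------------------------------------------
    dynamic_tables = {}
    qn_by_mark = {}
    for mark in syn.marks:
        cols = [
            (donor, state)
            for donor in range(syn.n_donors)
            for state in range(syn.n_states)
        ]
        mat = np.column_stack(
            [counts_by_sample[(d, s, mark)].counts for d, s in cols]
        )
        qn = bin_signal.quantile_normalize(mat)
        qn_by_mark[mark] = {ds: qn[:, k] for k, ds in enumerate(cols)}
        log2fc = np.column_stack(
            [
                bin_signal.log2_ratio(qn_by_mark[mark][(d, 1)], qn_by_mark[mark][(d, 0)])
                for d in range(syn.n_donors)
            ]
        )
        calls = bin_signal.call_dynamic_bins_matrix(
            log2fc, config.fc_threshold, config.min_donors
        )
        calls.insert(0, "bin", np.arange(grid.n_bins()))
        calls["mark"] = mark
        calls["mean_log2fc"] = log2fc.mean(axis=1)
        for d in range(syn.n_donors):
            calls[f"log2fc_d{d}"] = log2fc[:, d]
        dynamic_tables[mark] = calls
    dynamic = pd.concat(dynamic_tables.values(), ignore_index=True)
    hio.write_tsv(dynamic, outdir / "dynamic_bins.tsv")
    rows["dynamic.calls"] = int((dynamic["direction"] != "unchanged").sum())
    logger.info("stage=dynamic bins=%d called=%d", len(dynamic), rows["dynamic.calls"])

    # ----- genescore ------------------------------------------------------
    models = gene_marks.gene_models_from_transcripts(annotation.transcripts)
    chip_samples = [
        counts_by_sample[sid] for sid in counts_by_sample if sid[2] != CONTROL
    ]
    factors = bin_signal.normalize_equal_counts(chip_samples)
    scale = {bc.sample_id: f for bc, f in zip(chip_samples, factors)}
    score_rows = []
    for gene in models:
        chrom_size = annotation.chrom_sizes[gene.longest.chrom]
        for donor in range(syn.n_donors):
            for mark in synthetic_data.PROMOTER_MARKS:
                for state in range(syn.n_states):
                    sid = (donor, state, mark)
                    raw = gene_marks.promoter_score(
                        gene, reads_by_sample[sid], chrom_size, config.promoter_half_window
                    )
                    score_rows.append(
                        (gene.gene_id, mark, donor, state, raw * scale[sid], "promoter_sum")
                    )
            for mark in synthetic_data.BODY_MARKS:
                for state in range(syn.n_states):
                    sid = (donor, state, mark)
                    raw = gene_marks.gene_body_score(gene, reads_by_sample[sid])
                    score_rows.append(
                        (gene.gene_id, mark, donor, state, raw * scale[sid], "gene_body_sum")
                    )
            for mark in synthetic_data.ENHANCER_MARKS:
                ratios = (qn_by_mark[mark][(donor, 1)] + 1) / (qn_by_mark[mark][(donor, 0)] + 1)
                score = gene_marks.enhancer_profile(gene, ratios, grid, config.enhancer_window)
                score_rows.append(
                    (gene.gene_id, mark, donor, -1, np.nan if score is None else score,
                     "enhancer_max_ratio")
                )
    gene_scores = pd.DataFrame(
        score_rows, columns=["gene", "mark", "donor", "state", "score", "score_kind"]
    )
    hio.write_tsv(gene_scores, outdir / "gene_scores.tsv")
    rows["genescore.scores"] = len(gene_scores)
    logger.info("stage=genescore scores=%d", len(gene_scores))

    # ----- classify -------------------------------------------------------
    expr_wide = expression.pivot_table(
        index="gene", columns=["state", "donor"], values="log2_value"
    )
    day0 = expr_wide[0].to_numpy()
    day7 = expr_wide[1].to_numpy()
    classes = expression_integration.classify_expression(
        day0, day7, config.expression_fold, config.alpha, config.expression_test
    )
    classes.insert(0, "gene", expr_wide.index)
    hio.write_tsv(classes, outdir / "expression_classes.tsv")
    rows["classify.genes"] = len(classes)
    logger.info("stage=classify genes=%d up=%d down=%d", len(classes),
                int((classes["expr_class"] == "up").sum()),
                int((classes["expr_class"] == "down").sum()))

    # ----- associate ------------------------------------------------------
    bins_df = grid.to_dataframe()
    gene_fc = classes.set_index("gene")["log2fc"]
    genes_for_assoc = annotation.genes[["gene", "chrom", "tss"]].copy()
    genes_for_assoc["log2fc"] = genes_for_assoc["gene"].map(gene_fc).fillna(0.0)
    assoc_frames = []
    for mark in syn.marks:
        calls = dynamic_tables[mark]
        moved = calls[calls["direction"] != "unchanged"]
        if moved.empty:
            continue
        sub_bins = bins_df.iloc[moved["bin"].to_numpy()]
        if mark in synthetic_data.ENHANCER_MARKS:
            target = gene_marks.associate_enhancer_bins(
                sub_bins, genes_for_assoc, config.enhancer_window
            )
            kind = "enhancer"
        else:
            target = gene_marks.associate_promoter_bins(
                sub_bins, annotation.transcripts, config.promoter_half_window
            )
            kind = "promoter"
        assoc_frames.append(
            pd.DataFrame(
                {
                    "bin": moved["bin"].to_numpy(),
                    "mark": mark,
                    "direction": moved["direction"].to_numpy(),
                    "target": target.to_numpy(),
                    "rule": kind,
                }
            )
        )
    associations = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame(columns=["bin", "mark", "direction", "target", "rule"])
    )
    hio.write_tsv(associations, outdir / "associations.tsv")
    rows["associate.assigned"] = int(associations["target"].notna().sum())
    logger.info("stage=associate bins=%d assigned=%d", len(associations),
                rows["associate.assigned"])

    # ----- crosstab -------------------------------------------------------
    tx_to_gene = dict(zip(annotation.transcripts["transcript"], annotation.transcripts["gene"]))
    groups: dict[str, set] = {}
    for mark in syn.marks:
        for direction, arrow in (("increased", "up"), ("decreased", "down")):
            sub = associations[
                (associations["mark"] == mark)
                & (associations["direction"] == direction)
                & associations["target"].notna()
            ]
            members = {
                tx_to_gene.get(t, t) for t in sub["target"]
            }
            if members:
                groups[f"{mark}_{arrow}"] = members
    combo = (
        groups.get("H3K4me3_up", set())
        & groups.get("H3K9ac_up", set())
        & groups.get("H3K36me3_up", set())
    )
    if combo:
        groups["H3K4me3_up&H3K9ac_up&H3K36me3_up"] = combo
    pct, cnt = expression_integration.crosstab_marks_expression(
        classes.set_index("gene")["expr_class"], groups
    )
    hio.write_tsv(pct.reset_index(names="group"), outdir / "crosstab_percent.tsv")
    hio.write_tsv(cnt.reset_index(names="group"), outdir / "crosstab_counts.tsv")
    rows["crosstab.groups"] = len(pct)
    logger.info("stage=crosstab groups=%d", len(pct))

    # ----- concordance ----------------------------------------------------
    conc_frames = []
    for mark in syn.marks:
        mat = np.column_stack(
            [counts_by_sample[(d, 1, mark)].counts for d in range(syn.n_donors)]
        )
        rho = expression_integration.donor_concordance(mat, config.min_reads)
        df = pd.DataFrame(rho, columns=[f"donor{d}" for d in range(syn.n_donors)])
        df.insert(0, "mark", mark)
        conc_frames.append(df)
    concordance = pd.concat(conc_frames, ignore_index=True)
    hio.write_tsv(concordance, outdir / "concordance.tsv")
    rows["concordance.pairs"] = len(concordance)
    logger.info("stage=concordance marks=%d", len(syn.marks))

    # ----- heatmap ordering ----------------------------------------------
    promoter_change = np.column_stack(
        [dynamic_tables[m]["mean_log2fc"].to_numpy() for m in synthetic_data.PROMOTER_MARKS]
    )
    chip_matrix = np.column_stack([bc.counts for bc in chip_samples])
    covered = bin_signal.filter_covered_bins(chip_matrix, config.min_reads)
    if config.enrichment_q_cutoff is not None:
        best_q = enrichment.groupby("bin")["q_value"].min().to_numpy()
        covered &= best_q < config.enrichment_q_cutoff
    if covered.sum() >= 3:
        row_order, col_order, _ = expression_integration.heatmap_order(
            promoter_change[covered]
        )
        order_df = pd.DataFrame(
            {"rank": np.arange(len(row_order)), "bin": np.flatnonzero(covered)[row_order]}
        )
    else:
        order_df = pd.DataFrame(columns=["rank", "bin"])
        col_order = np.arange(promoter_change.shape[1])
    hio.write_tsv(order_df, outdir / "heatmap_row_order.tsv")
    hio.write_tsv(
        pd.DataFrame({"order": col_order,
                      "mark": [synthetic_data.PROMOTER_MARKS[i] for i in col_order]}),
        outdir / "heatmap_col_order.tsv",
    )
    rows["heatmap.rows"] = len(order_df)
    logger.info("stage=heatmap rows=%d", len(order_df))

    # ----- motifs ---------------------------------------------------------
    changes = dynamic_tables[config.motif_mark][["bin", "mean_log2fc"]].copy()
    changes = changes.join(bins_df, on="bin")
    changes = changes.rename(columns={"mean_log2fc": "stat"})
    up_set, down_set = motif_enrichment.select_top_regions(
        changes[["chrom", "start", "end", "stat"]], config.top_n
    )
    for rset in (up_set, down_set):
        rset.sequences = [
            annotation.sequences[r.chrom][r.start : r.end]
            for r in rset.regions.itertuples(index=False)
        ]
    up_hits = up_set.hit_counts(pwm, config.rel_threshold)
    down_hits = down_set.hit_counts(pwm, config.rel_threshold)
    result = motif_enrichment.motif_tests(up_hits, down_hits, pwm.motif_id, config.alpha)
    motif_df = pd.DataFrame(
        [
            {
                "motif": result.motif_id,
                "fisher_p": result.fisher_p,
                "wilcoxon_p": result.wilcoxon_p,
                "significant": result.significant,
                "n_up_regions": len(up_set.regions),
                "n_down_regions": len(down_set.regions),
            }
        ]
    )
    hio.write_tsv(motif_df, outdir / "motif_enrichment.tsv")
    rows["motifs.tested"] = len(motif_df)
    logger.info("stage=motifs tested=%d significant=%d", len(motif_df),
                int(motif_df["significant"].sum()))

    # ----- methylation ----------------------------------------------------
    tss_table = annotation.genes[["gene", "chrom", "tss", "strand"]].rename(
        columns={"gene": "tss_id"}
    )
    per_donor = methylation.promoter_methylation_table(
        tss_table, calls_by_sample, config.meth_upstream, config.meth_downstream,
        config.min_cpgs, config.min_cov,
    )
    state_means = methylation.state_methylation(per_donor, config.min_donors)
    flags, summary = methylation.flag_methylation_gains(state_means)
    hio.write_tsv(per_donor, outdir / "promoter_methylation.tsv")
    hio.write_tsv(state_means, outdir / "promoter_methylation_state.tsv")
    hio.write_tsv(flags, outdir / "methylation_flags.tsv")
    with open(outdir / "methylation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    density = methylation.cpg_density_profile(
        calls_by_sample[(0, 0)], annotation.sequences, min_cov=config.min_cov
    )
    density["density_bin"] = density["density_bin"].astype(str)
    hio.write_tsv(density, outdir / "cpg_density_profile.tsv")
    rows["methylation.promoters"] = int(summary["n_examined"])
    logger.info("stage=methylation examined=%d gain50=%d gain25=%d",
                summary["n_examined"], summary["n_gain50"], summary["n_gain25"])

    manifest = RunManifest(
        config_hash=config.hash(),
        version=__version__,
        input_checksums=checksums,
        row_counts=rows,
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _plant_motifs_in_genome(
    annotation, truth, grid: BinGrid, pwm: PWM, syn: SyntheticConfig
) -> None:
    """Insert PWM-sampled instances into gained-acetylation bins in place."""
    if syn.motif_plant_rate <= 0 or truth.differential_bins.empty:
        return
    rng = substream(syn.seed, "genome_motifs")
    bins = grid.to_dataframe()
    up = truth.bins_for("H3K27ac", "increased")
    m = len(pwm)
    for b in up:
        if rng.random() >= syn.motif_plant_rate:
            continue
        row = bins.iloc[int(b)]
        width = int(row.end - row.start)
        if width < m:
            continue
        inst = synthetic_data.sample_motif_instance(pwm.probs, rng)
        pos = int(row.start + rng.integers(0, width - m + 1))
        seq = annotation.sequences[row.chrom]
        annotation.sequences[row.chrom] = seq[:pos] + inst + seq[pos + m :]
        truth.planted_motif_regions.add((row.chrom, pos))
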