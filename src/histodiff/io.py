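"""Readers and writers for the plain-text formats the pipeline touches.

Internal convention: all intervals are 0-based, half-open.  The only
1-based coordinate in the package is the CpG-call TSV position, converted
at this boundary.  Parsers validate rather than coerce: malformed records
raise :class:`ParseError` carrying the file name and line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "read_fasta",
    "write_fasta",
    "read_pwm_jaspar",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_tsv",
    "write_tsv",
    "write_bedgraph",
]

_STRANDS = frozenset("+-")


class ParseError(ValueError):
    """Malformed record in an input file; message carries file and line."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length in bp."""
    sizes: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        try:
            size = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer size {fields[1]!r}") from None
        if size <= 0:
            raise ParseError(path, lineno, f"non-positive size {size}")
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> pd.DataFrame:
    """6-column BED (chrom, start, end, name, score, strand), 0-based half-open.

    Returns a DataFrame with those columns; fewer than 6 columns is accepted
    down to 3 (name/score/strand filled with '.', 0, '+').
    """
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        if end <= start:
            raise ParseError(path, lineno, f"end {end} <= start {start}")
        if start < 0:
            raise ParseError(path, lineno, f"negative start {start}")
        name = fields[3] if len(fields) > 3 else "."
        score = fields[4] if len(fields) > 4 else "0"
        strand = fields[5] if len(fields) > 5 else "+"
        if strand not in _STRANDS:
            raise ParseError(path, lineno, f"unknown strand {strand!r}")
        rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if df.empty:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "name": pd.Series(dtype=str),
                "score": pd.Series(dtype=str),
                "strand": pd.Series(dtype=str),
            }
        )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path) -> pd.DataFrame:
    """BED12 transcript models -> DataFrame of transcripts.

    The name field encodes ``gene|transcript``; a plain name is used for
    both.  Block structure is validated against chromStart/chromEnd.
    Returns columns: gene, transcript, chrom, start, end, strand.
    """
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(path, lineno, f"expected 12 columns, got {len(fields)}")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name, strand = fields[3], fields[5]
        if end <= start:
            raise ParseError(path, lineno, f"end {end} <= start {start}")
        if strand not in _STRANDS:
            raise ParseError(path, lineno, f"unknown strand {strand!r}")
        try:
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError:
            raise ParseError(path, lineno, "malformed block columns") from None
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(path, lineno, "blockCount disagrees with block lists")
        if starts and (starts[0] != 0 or start + starts[-1] + sizes[-1] != end):
            raise ParseError(path, lineno, "blocks inconsistent with chromStart/chromEnd")
        gene, _, tx = name.partition("|")
        rows.append((gene, tx or name, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["gene", "transcript", "chrom", "start", "end", "strand"])


def write_bed12(transcripts: pd.DataFrame, path) -> None:
    """Write single-block BED12 records from a transcript table."""
    with open(path, "w") as fh:
        for t in transcripts.itertuples(index=False):
            size = t.end - t.start
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}|{t.transcript}\t0\t{t.strand}"
                f"\t{t.start}\t{t.end}\t0\t1\t{size},\t0,\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pwm_jaspar(path) -> dict[str, np.ndarray]:
    """JASPAR-format matrices -> {motif id: (4, L) count/probability array}.

    Row order is A, C, G, T.  Ragged rows raise :class:`ParseError`.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = motifs.parse(_io.StringIO(text), "jaspar")
        out: dict[str, np.ndarray] = {}
        for m in parsed:
            mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out[m.matrix_id or m.name] = mat
        return out
    except Exception as exc:  # Biopython raises bare Exceptions for ragged rows
        raise ParseError(path, 0, f"malformed JASPAR matrix: {exc}") from None


def read_cpg_calls(path) -> pd.DataFrame:
    """CpG call TSV (chrom, 1-based position, fraction, coverage).

    Positions are converted to 0-based in the returned ``pos0`` column.
    """
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            pos = int(fields[1])
            frac = float(fields[2])
            cov = int(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "malformed numeric field") from None
        if pos < 1:
            raise ParseError(path, lineno, f"position {pos} < 1 (1-based)")
        if not 0.0 <= frac <= 1.0:
            raise ParseError(path, lineno, f"fraction {frac} outside [0,1]")
        if cov < 1:
            raise ParseError(path, lineno, f"coverage {cov} < 1")
        rows.append((chrom, pos - 1, frac, cov))
    return pd.DataFrame(rows, columns=["chrom", "pos0", "fraction", "coverage"])


def write_cpg_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["pos"] = out["pos0"] + 1
    out[["chrom", "pos", "fraction", "coverage"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def write_bedgraph(grid, values: Iterable[float], path, trackname: str | None = None) -> None:
    """Per-bin signal track over a :class:`~histodiff.bin_signal.BinGrid`."""
    values = np.asarray(list(values))
    bins = grid.to_dataframe()
    if len(values) != len(bins):
        raise ValueError(f"{len(values)} values for {len(bins)} bins")
    with open(path, "w") as fh:
        if trackname:
            fh.write(f'track type=bedGraph name="{trackname}"\n')
        for (chrom, start, end), v in zip(bins.itertuples(index=False), values):
            fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")
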