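"""histodiff: differential histone-mark, motif and promoter-methylation
analysis for two-state, multi-donor ChIP-seq/RRBS/expression designs."""

__version__ = "0.1.0"

from . import (  # noqa: F401
    bin_signal,
    expression_integration,
    gene_marks,
    io,
    methylation,
    motif_enrichment,
    synthetic_data,
)
from .bin_signal import BinGrid  # noqa: F401

__all__ = [
    "__version__",
    "BinGrid",
    "bin_signal",
    "expression_integration",
    "gene_marks",
    "io",
    "methylation",
    "motif_enrichment",
    "synthetic_data",
    "pipeline",
]


def __getattr__(name):
    # pipeline imports back from the package root; load it lazily
    if name == "pipeline":
        from . import pipeline

        return pipeline
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
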