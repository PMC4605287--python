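"""Bundled reference genomes.

The two model bacteriophage genomes used throughout the examples and tests:
RefSeq NC_001416.1 (Escherichia phage lambda, 48,502 bp; 121 TCGA sites)
and NC_001604.1 (Enterobacteria phage T7, 39,937 bp; 111 TCGA sites).
"""

from __future__ import annotations

from importlib import resources

from .core import GenomeSequence
from .io import read_fasta

__all__ = ["load_genome", "AVAILABLE_GENOMES"]

_FILES = {
    "lambda": "NC_001416.fasta",
    "t7": "NC_001604.fasta",
}

AVAILABLE_GENOMES = tuple(_FILES)


def load_genome(name: str) -> GenomeSequence:
    """Load a bundled phage genome by name ('lambda' or 't7')."""
    key = name.lower()
    if key not in _FILES:
        raise KeyError(f"unknown genome {name!r}; available: {AVAILABLE_GENOMES}")
    with resources.as_file(
        resources.files("ambarcode.data").joinpath(_FILES[key])
    ) as path:
        (genome,) = read_fasta(path)
    return genome
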