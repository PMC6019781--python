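"""Small IO and sequence helpers shared by the analysis modules.

Genomes are held in memory as plain ``{record_id: uppercase sequence string}``
dictionaries; FASTA round-tripping goes through Biopython.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Dict, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(genome: Dict[str, str], path: PathLike) -> None:
    """Write an ``{id: sequence}`` dict as FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def genome_from_any(genome: Union[Dict[str, str], PathLike]) -> Dict[str, str]:
    """Accept either a loaded genome dict or a FASTA path."""
    if isinstance(genome, dict):
        return {k: v.upper() for k, v in genome.items()}
    return read_fasta(genome)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def as_rna_base(base: str) -> str:
    """Canonicalize a nucleotide to RNA alphabet (T -> U), uppercase."""
    b = base.upper()
    return "U" if b == "T" else b


def as_dna_base(base: str) -> str:
    """Canonicalize a nucleotide to DNA alphabet (U -> T), uppercase."""
    b = base.upper()
    return "T" if b == "U" else b
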