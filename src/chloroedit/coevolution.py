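"""Cis-element co-evolution profiling.

When an editing event is lost in a lineage (the genome hard-codes T where
other species must edit a C), the cis-element upstream of the site is freed
from the constraint of factor recognition and can diverge.  This module
partitions orthologous cis-element windows by the genomic state at the
edited position, profiles per-position nucleotide usage in the two groups,
flags positions where either group introduces nucleotides the other lacks
(the positions a sequence-logo figure would leave at full opacity), and
translates the windows to amino acids to show the protein-level impact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .io_utils import PathLike, as_dna_base

logger = logging.getLogger(__name__)

STATE_EDITED = "C_requires_editing"
STATE_LOST = "T_editing_lost"
STATE_OTHER = "other"

DEFAULT_SPAN = (-20, 4)  # covers the PPR footprint and the edited codon


@dataclass(frozen=True)
class SpeciesCisElement:
    """One species' aligned cis-element window around the edited position.

    ``span`` gives the relative coordinates covered (start <= 0 <= end);
    position 0 is the edited (or editing-lost) nucleotide.  ``frame_offset``
    is the codon phase of position ``span[0]`` (0-2 bases to trim before the
    first complete codon).
    """

    species: str
    window: str
    frame_offset: int = 0
    span: Tuple[int, int] = DEFAULT_SPAN

    def __post_init__(self):
        lo, hi = self.span
        if not lo <= 0 <= hi:
            raise InputError(f"{self.species}: span {self.span} must contain position 0")
        if len(self.window) != hi - lo + 1:
            raise InputError(
                f"{self.species}: window length {len(self.window)} != span size {hi - lo + 1}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise InputError(f"{self.species}: frame_offset must be 0-2")

    @property
    def base_at_zero(self) -> str:
        return as_dna_base(self.window[-self.span[0]])

    @property
    def genomic_state(self) -> str:
        b = self.base_at_zero
        if b == "C":
            return STATE_EDITED
        if b == "T":
            return STATE_LOST
        return STATE_OTHER


@dataclass
class PositionProfile:
    """Per-position symbol frequencies of the two groups plus the
    highlighted/faded flag (highlighted = the symbol sets differ)."""

    positions: List[int]
    freq_a: List[Dict[str, float]]
    freq_b: List[Dict[str, float]]
    highlighted: List[bool]

    def highlighted_positions(self) -> List[int]:
        return [p for p, h in zip(self.positions, self.highlighted) if h]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, fa, fb, h in zip(self.positions, self.freq_a, self.freq_b, self.highlighted):
            row = {"position": p, "highlighted": h}
            for sym, f in sorted(fa.items()):
                row[f"A_{sym}"] = f
            for sym, f in sorted(fb.items()):
                row[f"B_{sym}"] = f
            rows.append(row)
        return pd.DataFrame(rows)


def partition_by_genomic_state(
    elements: Sequence[SpeciesCisElement],
) -> Tuple[List[SpeciesCisElement], List[SpeciesCisElement], List[SpeciesCisElement]]:
    """Split elements into (C group, T group, other) by the base at position 0."""
    if not elements:
        raise InputError("no cis-elements supplied")
    c_group = [e for e in elements if e.genomic_state == STATE_EDITED]
    t_group = [e for e in elements if e.genomic_state == STATE_LOST]
    other = [e for e in elements if e.genomic_state == STATE_OTHER]
    if other:
        warnings.warn(
            f"{len(other)} element(s) with non-C/T base at position 0 routed to 'other': "
            + ", ".join(e.species for e in other)
        )
    if not c_group or not t_group:
        warnings.warn("one genomic-state group is empty")
    return c_group, t_group, other


def _freqs(windows: Sequence[str], i: int) -> Dict[str, float]:
    counts: Dict[str, int] = {}
    for w in windows:
        sym = as_dna_base(w[i])
        counts[sym] = counts.get(sym, 0) + 1
    n = len(windows)
    return {s: c / n for s, c in counts.items()}


def position_profile(
    group_a: Sequence[SpeciesCisElement],
    group_b: Sequence[SpeciesCisElement],
    *,
    mode: str = "across",
) -> PositionProfile:
    """Per-position composition of the two groups with highlight flags.

    ``mode='across'`` (default): a position is highlighted iff the two
    groups' symbol sets differ — i.e. either group contains a nucleotide the
    other lacks.  ``mode='consensus'``: highlighted iff group B introduces a
    symbol different from group A's consensus (majority) symbol — the
    within-group-consensus reading of "new nucleotides".
    """
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    spans = {e.span for e in list(group_a) + list(group_b)}
    if len(spans) != 1:
        raise InputError(f"all windows must share one span, got {spans}")
    lo, hi = spans.pop()
    wa = [e.window for e in group_a]
    wb = [e.window for e in group_b]

    positions, fa_all, fb_all, flags = [], [], [], []
    for i in range(hi - lo + 1):
        fa = _freqs(wa, i)
        fb = _freqs(wb, i)
        if mode == "across":
            flag = set(fa) != set(fb)
        elif mode == "consensus":
            consensus = max(sorted(fa), key=lambda s: fa[s])
            flag = any(s != consensus for s in fb)
        else:
            raise InputError(f"unknown mode {mode!r}")
        positions.append(lo + i)
        fa_all.append(fa)
        fb_all.append(fb)
        flags.append(flag)
    return PositionProfile(positions, fa_all, fb_all, flags)


def translate_window(window: str, frame_offset: int = 0) -> str:
    """Translate a nucleotide window to amino acids with the standard code.

    ``frame_offset`` bases are trimmed from the 5' end to reach the first
    complete codon; a trailing partial codon is dropped.  T and U are
    equivalent; any other non-nucleotide character is an error.
    """
    if not 0 <= frame_offset <= 2:
        raise InputError("frame_offset must be 0-2")
    dna = "".join(as_dna_base(c) for c in window)
    bad = set(dna) - set("ACGTN")
    if bad:
        raise InputError(f"non-nucleotide character(s) {sorted(bad)} in window")
    trimmed = dna[frame_offset:]
    trimmed = trimmed[: len(trimmed) - (len(trimmed) % 3)]
    if not trimmed:
        raise InputError("window too short to contain a complete codon")
    return str(Seq(trimmed).translate())


def translate_elements(
    elements: Sequence[SpeciesCisElement],
) -> List[Tuple[str, str]]:
    """(species, peptide) for each element, using its own frame offset."""
    return [(e.species, translate_window(e.window, e.frame_offset)) for e in elements]


def read_cis_elements(path: PathLike, span: Tuple[int, int] = DEFAULT_SPAN) -> List[SpeciesCisElement]:
    """Read aligned windows from FASTA; the description may carry
    ``frame=<0-2>`` and ``span=<lo>:<hi>`` tokens overriding the default."""
    elements = []
    for rec in SeqIO.parse(str(path), "fasta"):
        frame = 0
        rec_span = span
        for token in rec.description.split():
            if token.startswith("frame="):
                frame = int(token[6:])
            elif token.startswith("span="):
                lo, hi = token[5:].split(":")
                rec_span = (int(lo), int(hi))
        elements.append(
            SpeciesCisElement(
                species=rec.id,
                window=str(rec.seq).upper(),
                frame_offset=frame,
                span=rec_span,
            )
        )
    return elements


def write_translated_fasta(
    elements: Sequence[SpeciesCisElement], path: PathLike
) -> None:
    recs = [
        SeqRecord(Seq(pep), id=species, description="")
        for species, pep in translate_elements(elements)
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
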