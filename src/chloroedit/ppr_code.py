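"""PPR editing factors and the amino-acid -> nucleotide recognition code.

Pentatricopeptide-repeat (PPR) editing factors bind RNA one motif per base.
The amino acids at the 5th and last positions of each 35-aa motif select the
bound nucleotide; a recognition-code table assigns each (aa5, aa_last)
combination a log-likelihood ratio for each of the four RNA bases.  The score
of a factor/site alignment is the sum of these ratios across the motifs.

The numeric code table is an input: it differs between published derivations
and the bundled example (``example_code_table``) is synthetic, intended for
tests and demonstrations only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DuplicateEntryError, FormatError, InputError, ParseError
from .io_utils import PathLike, as_rna_base

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
RNA_BASES = ("A", "C", "G", "U")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

MOTIF_CLASSES = ("P1", "P2", "L1", "L2", "S1", "S2", "E1", "E2", "DYW", "other")


@dataclass(frozen=True)
class MotifSpec:
    """One PPR motif: its ordinal position (1-based, N- to C-terminal),
    subclass label, and the amino acids at positions 5 and last."""

    index: int
    motif_class: str
    aa5: str
    aa_last: str

    def __post_init__(self):
        if self.index < 1:
            raise InputError(f"motif index must be >= 1, got {self.index}")
        for name, aa in (("aa5", self.aa5), ("aa_last", self.aa_last)):
            if len(aa) != 1 or (aa not in AMINO_ACIDS and aa != "X"):
                raise InputError(
                    f"{name} must be a one-letter amino acid or 'X', got {aa!r}"
                )

    @property
    def key(self) -> Tuple[str, str]:
        return (self.aa5, self.aa_last)


@dataclass
class PPRArray:
    """An editing factor as an ordered motif array plus a mask of which
    motifs participate in scoring (N- to C-terminal order)."""

    protein_id: str
    motifs: List[MotifSpec]
    scored_mask: Optional[List[bool]] = None

    def __post_init__(self):
        if not self.motifs:
            raise InputError(f"{self.protein_id}: motif list is empty")
        if self.scored_mask is None:
            self.scored_mask = [True] * len(self.motifs)
        if len(self.scored_mask) != len(self.motifs):
            raise InputError(
                f"{self.protein_id}: scored_mask length {len(self.scored_mask)} "
                f"!= motif count {len(self.motifs)}"
            )
        if not any(self.scored_mask):
            raise InputError(f"{self.protein_id}: no motif is scored")

    @property
    def scored_motifs(self) -> List[MotifSpec]:
        return [m for m, s in zip(self.motifs, self.scored_mask) if s]

    @property
    def n_scored(self) -> int:
        return sum(self.scored_mask)


@dataclass
class CodeTable:
    """Recognition-code lookup: (aa5, aa_last) -> log-likelihood ratios over
    {A, C, G, U}.  Combinations absent from the table score ``default_score``
    (0 by default: the neutral log-likelihood)."""

    entries: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    default_score: float = 0.0
    metadata: str = ""

    def __post_init__(self):
        for key, vec in self.entries.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (4,):
                raise InputError(f"entry {key}: expected 4 scores, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"entry {key}: scores must be finite")
            self.entries[key] = arr

    def scores_for(self, aa5: str, aa_last: str) -> np.ndarray:
        """4-vector of scores (A, C, G, U) for a motif combination; the
        default vector when the combination is unknown or contains 'X'."""
        if aa5 == "X" or aa_last == "X":
            return np.full(4, self.default_score)
        vec = self.entries.get((aa5, aa_last))
        if vec is None:
            return np.full(4, self.default_score)
        return vec

    def __len__(self) -> int:
        return len(self.entries)


def load_code_table(path: PathLike, default_score: float = 0.0) -> CodeTable:
    """Load a recognition-code table from TSV.

    Expected columns: ``aa5``, ``aa_last``, ``A``, ``C``, ``G``, ``U``;
    lines starting with ``#`` are comments.  Duplicate (aa5, aa_last) keys
    are an error, as are non-numeric scores.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["aa5", "aa_last", "A", "C", "G", "U"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    entries: Dict[Tuple[str, str], np.ndarray] = {}
    for i, row in df.iterrows():
        key = (str(row["aa5"]), str(row["aa_last"]))
        if key in entries:
            raise DuplicateEntryError(f"{path}: duplicate key {key} at data row {i + 1}")
        try:
            vec = np.array([float(row[b]) for b in ("A", "C", "G", "U")])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric score at data row {i + 1}: {exc}") from exc
        entries[key] = vec
    if not entries:
        logger.warning("%s: code table has no data rows", path)
    return CodeTable(entries=entries, default_score=default_score, metadata=str(path))


def write_code_table(table: CodeTable, path: PathLike) -> None:
    """Write a CodeTable back to its TSV format (full float precision)."""
    rows = [
        {"aa5": k[0], "aa_last": k[1], "A": v[0], "C": v[1], "G": v[2], "U": v[3]}
        for k, v in table.entries.items()
    ]
    pd.DataFrame(rows, columns=["aa5", "aa_last", "A", "C", "G", "U"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def example_code_table() -> CodeTable:
    """The bundled *synthetic* example code table.

    The values are invented for demonstration and testing; they are NOT a
    published recognition-code derivation.
    """
    with resources.as_file(
        resources.files("chloroedit.data") / "example_code_table.tsv"
    ) as p:
        return load_code_table(p)


def load_ppr_arrays(path: PathLike) -> List[PPRArray]:
    """Load PPR arrays from TSV with columns
    ``protein_id, index, motif_class, aa5, aa_last, scored`` (scored: 0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["protein_id", "index", "motif_class", "aa5", "aa_last", "scored"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    arrays = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.assign(_idx=grp["index"].astype(int)).sort_values("_idx")
        motifs = [
            MotifSpec(int(r["index"]), r["motif_class"], r["aa5"], r["aa_last"])
            for _, r in grp.iterrows()
        ]
        mask = [bool(int(r["scored"])) for _, r in grp.iterrows()]
        arrays.append(PPRArray(protein_id=str(pid), motifs=motifs, scored_mask=mask))
    return arrays


def write_ppr_arrays(arrays: Sequence[PPRArray], path: PathLike) -> None:
    rows = []
    for arr in arrays:
        for m, s in zip(arr.motifs, arr.scored_mask):
            rows.append(
                {
                    "protein_id": arr.protein_id,
                    "index": m.index,
                    "motif_class": m.motif_class,
                    "aa5": m.aa5,
                    "aa_last": m.aa_last,
                    "scored": int(s),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def motif_base_score(motif: MotifSpec, base: str, table: CodeTable) -> float:
    """Log-likelihood ratio contributed by one motif aligned to one base.

    ``base`` may be DNA or RNA (T is treated as U); 'N' (unknown base) and
    motif combinations absent from the table score ``table.default_score``.
    """
    b = base.upper()
    if b == "N":
        return float(table.default_score)
    if b not in _BASE_INDEX:
        raise InputError(f"base must be one of A/C/G/U/T, got {base!r}")
    return float(table.scores_for(motif.aa5, motif.aa_last)[_BASE_INDEX[b]])


def preferred_window(array: PPRArray, table: CodeTable) -> str:
    """The maximal-scoring RNA window for a factor, one base per scored motif
    in N->C order.  Ties break alphabetically (A < C < G < U), so an
    all-default motif contributes 'A'."""
    bases = []
    for motif in array.scored_motifs:
        vec = table.scores_for(motif.aa5, motif.aa_last)
        bases.append(RNA_BASES[int(np.argmax(vec))])  # argmax takes first max: A<C<G<U
    return "".join(bases)


def normalize_window(window: str) -> str:
    """Canonicalize a window to RNA alphabet, preserving 'N'."""
    return "".join("N" if c.upper() == "N" else as_rna_base(c) for c in window)
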