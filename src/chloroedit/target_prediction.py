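"""Genome-wide candidate-site enumeration, alignment scoring and z-ranking.

Plant C-to-U editing sites sit in a YC context: the edited cytidine is
preceded by a pyrimidine.  Every YC position on either strand of the genome
is a candidate; each carries the upstream window that a PPR array would bind
(one base per scored motif, the C-terminal-most scored motif aligned a fixed
offset 5' of the edited C; default offset 4, the usual PPR-code register).

A factor's affinity for a site is the summed recognition-code score of the
alignment.  Because raw scores are not comparable between factors of
different lengths and compositions, each factor's scores are normalized to
z-scores against the full population of candidate sites in the genome:
z = (s - mu) / sigma with the population (divide-by-n) standard deviation.
Reciprocal ranking — the best factor for a site, the best site for a factor
— is what nominates a factor/site pairing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DegenerateSpreadError, InputError
from .io_utils import PathLike, genome_from_any
from .ppr_code import CodeTable, PPRArray, motif_base_score, normalize_window

logger = logging.getLogger(__name__)

# encoding shared by the vectorized scorer: A C G T/U N
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("U")] = 3
_ENC[ord("u")] = 3

_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class CandidateSite:
    """A YC candidate editing position.

    ``position`` is the 1-based forward-strand coordinate of the (edited) C;
    for strand '-' the C lies on the reverse complement and ``position`` is
    the forward coordinate of the paired G.  ``window`` is the upstream
    cis-element read 5'->3' on the edited strand, ending ``offset`` bases 5'
    of the C; out-of-sequence positions are 'N'.
    """

    seq_id: str
    position: int
    strand: str
    window: str
    context_5prime: str  # 'C' or 'U': the pyrimidine immediately 5' of the C


@dataclass(frozen=True)
class AlignmentResult:
    factor_id: str
    site: CandidateSite
    raw_score: float
    z_score: float


@dataclass
class ScanSummary:
    """All alignments of one factor across a genome, with the population
    moments used for z-normalization."""

    factor_id: str
    n_sites: int
    mean_score: float
    sd_score: float
    results: List[AlignmentResult] = field(default_factory=list)

    def top_hits(self, n: int = 10) -> List[AlignmentResult]:
        return self.results[:n]

    def result_at(self, seq_id: str, position: int, strand: str) -> Optional[AlignmentResult]:
        for r in self.results:
            s = r.site
            if s.seq_id == seq_id and s.position == position and s.strand == strand:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor_id": self.factor_id,
                "seq_id": [r.site.seq_id for r in self.results],
                "position": [r.site.position for r in self.results],
                "strand": [r.site.strand for r in self.results],
                "window": [r.site.window for r in self.results],
                "raw_score": [r.raw_score for r in self.results],
                "z_score": [r.z_score for r in self.results],
            }
        )


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def enumerate_candidate_sites(
    genome: Union[Dict[str, str], PathLike],
    window_len: int,
    offset: int = 4,
    *,
    drop_edge_windows: bool = False,
    circular: bool = False,
) -> List[CandidateSite]:
    """Enumerate every YC position on both strands of every record.

    The window of ``window_len`` bases ends ``offset`` bases 5' of the C and
    is reported 5'->3' on the edited strand.  Windows running off a sequence
    end are 'N'-padded (or dropped with ``drop_edge_windows``); with
    ``circular`` the windows wrap around instead, matching a circular
    plastid map.
    """
    genome = genome_from_any(genome)
    if not genome:
        raise InputError("empty genome")
    if window_len < 1:
        raise InputError("window_len must be >= 1")
    if offset < 0:
        raise InputError("offset must be >= 0")

    sites: List[CandidateSite] = []
    for seq_id, seq in genome.items():
        enc = _encode(seq)
        n = len(enc)
        if n == 0:
            continue
        # forward: C at i (0-based) preceded by pyrimidine (C or T)
        is_c = enc == 1
        prev_pyr = np.zeros(n, dtype=bool)
        prev_pyr[1:] = (enc[:-1] == 1) | (enc[:-1] == 3)
        if circular and n > 1:
            prev_pyr[0] = enc[-1] == 1 or enc[-1] == 3
        for i in np.nonzero(is_c & prev_pyr)[0]:
            pos = int(i) + 1
            win = _extract_window(seq, n, pos, "+", window_len, offset, circular)
            if win is None and drop_edge_windows:
                continue
            ctx = "C" if enc[(i - 1) % n] == 1 else "U"
            sites.append(
                CandidateSite(seq_id, pos, "+", win or _padded(seq, n, pos, "+", window_len, offset), ctx)
            )
        # reverse: forward G at i with forward base at i+1 in {A, G}
        is_g = enc == 2
        next_pur = np.zeros(n, dtype=bool)
        next_pur[:-1] = (enc[1:] == 0) | (enc[1:] == 2)
        if circular and n > 1:
            next_pur[-1] = enc[0] == 0 or enc[0] == 2
        for i in np.nonzero(is_g & next_pur)[0]:
            pos = int(i) + 1
            win = _extract_window(seq, n, pos, "-", window_len, offset, circular)
            if win is None and drop_edge_windows:
                continue
            ctx = "C" if enc[(i + 1) % n] == 2 else "U"  # complement of G is C
            sites.append(
                CandidateSite(seq_id, pos, "-", win or _padded(seq, n, pos, "-", window_len, offset), ctx)
            )
    return sites


def _extract_window(seq, n, pos, strand, window_len, offset, circular):
    """Return the window when it fits (or wraps, in circular mode); None if
    it would run off a linear sequence end."""
    if strand == "+":
        start = pos - offset - window_len  # 0-based inclusive
        stop = pos - offset  # 0-based exclusive
        if circular:
            return "".join(seq[(j % n)] for j in range(start, stop)).replace("T", "U")
        if start < 0:
            return None
        return seq[start:stop].replace("T", "U")
    else:
        start = pos + offset - 1  # 0-based inclusive
        stop = pos + offset - 1 + window_len
        if circular:
            fwd = "".join(seq[(j % n)] for j in range(start, stop))
            return _revcomp_rna(fwd)
        if stop > n:
            return None
        return _revcomp_rna(seq[start:stop])


def _padded(seq, n, pos, strand, window_len, offset):
    """Edge window with 'N' padding on the 5' side."""
    if strand == "+":
        start = pos - offset - window_len
        stop = pos - offset
        core = seq[max(0, start):max(0, stop)].replace("T", "U")
    else:
        start = pos + offset - 1
        stop = start + window_len
        core = _revcomp_rna(seq[min(max(start, 0), n):min(max(stop, 0), n)])
    return "N" * (window_len - len(core)) + core


_RC = str.maketrans("ACGTU", "UGCAA")


def _revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


def score_alignment(array: PPRArray, window: str, table: CodeTable) -> float:
    """Sum of per-motif recognition scores for a factor aligned to a window
    (motifs N->C against window 5'->3'; 'N' bases score the default)."""
    window = normalize_window(window)
    motifs = array.scored_motifs
    if len(window) != len(motifs):
        raise InputError(
            f"{array.protein_id}: window length {len(window)} != scored motifs {len(motifs)}"
        )
    return float(sum(motif_base_score(m, b, table) for m, b in zip(motifs, window)))


def _score_matrix(array: PPRArray, table: CodeTable) -> np.ndarray:
    """(n_scored, 5) score lookup: columns A, C, G, U, N/default."""
    motifs = array.scored_motifs
    mat = np.empty((len(motifs), 5))
    for j, m in enumerate(motifs):
        mat[j, :4] = table.scores_for(m.aa5, m.aa_last)
        mat[j, 4] = table.default_score
    return mat


def score_sites(
    array: PPRArray, sites: Sequence[CandidateSite], table: CodeTable
) -> np.ndarray:
    """Vectorized raw scores of a factor against many candidate sites."""
    mat = _score_matrix(array, table)
    L = mat.shape[0]
    if not sites:
        return np.empty(0)
    wmat = np.vstack([_encode(s.window) for s in sites])
    if wmat.shape[1] != L:
        raise InputError(
            f"{array.protein_id}: site windows have length {wmat.shape[1]}, "
            f"factor scores {L} motifs"
        )
    return mat[np.arange(L)[None, :], wmat].sum(axis=1)


def scan_factor(
    array: PPRArray,
    genome: Union[Dict[str, str], PathLike],
    table: CodeTable,
    offset: int = 4,
    *,
    sites: Optional[Sequence[CandidateSite]] = None,
    drop_edge_windows: bool = False,
    circular: bool = False,
) -> ScanSummary:
    """Score a factor against every YC candidate in the genome and attach
    population z-scores.

    Raises :class:`DegenerateSpreadError` when all scores are identical
    (sigma = 0), which makes z undefined.
    """
    if sites is None:
        sites = enumerate_candidate_sites(
            genome,
            array.n_scored,
            offset,
            drop_edge_windows=drop_edge_windows,
            circular=circular,
        )
    scores = score_sites(array, sites, table)
    if scores.size == 0:
        raise InputError(f"{array.protein_id}: no candidate sites to score")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=0))  # population SD: all alignments, not a sample
    if sigma == 0.0:
        raise DegenerateSpreadError(
            f"{array.protein_id}: all {scores.size} alignment scores identical ({mu})"
        )
    z = (scores - mu) / sigma
    order = sorted(
        range(len(sites)),
        key=lambda i: (-z[i], sites[i].seq_id, sites[i].position, sites[i].strand),
    )
    results = [
        AlignmentResult(array.protein_id, sites[i], float(scores[i]), float(z[i]))
        for i in order
    ]
    return ScanSummary(
        factor_id=array.protein_id,
        n_sites=len(sites),
        mean_score=mu,
        sd_score=sigma,
        results=results,
    )


def rank_factors_for_site(
    arrays: Sequence[PPRArray],
    site: Tuple[str, int, str],
    genome: Union[Dict[str, str], PathLike],
    table: CodeTable,
    offset: int = 4,
) -> List[Tuple[str, Optional[float]]]:
    """Rank factors by the z-score each assigns to one site.

    ``site`` is (seq_id, 1-based position, strand).  Each factor is scanned
    genome-wide (its own window length) and the z of the given site
    extracted.  Factors with degenerate score spread are kept with z = None
    and a warning.  The site must be a YC candidate (5' pyrimidine).
    """
    genome = genome_from_any(genome)
    seq_id, position, strand = site
    if seq_id not in genome:
        raise InputError(f"unknown sequence {seq_id!r}")
    _require_yc(genome[seq_id], position, strand)

    ranked: List[Tuple[str, Optional[float]]] = []
    for array in arrays:
        try:
            summary = scan_factor(array, genome, table, offset)
        except DegenerateSpreadError as exc:
            warnings.warn(str(exc))
            ranked.append((array.protein_id, None))
            continue
        res = summary.result_at(seq_id, position, strand)
        if res is None:
            raise InputError(
                f"site {seq_id}:{position}{strand} not among candidates of {array.protein_id}"
            )
        ranked.append((array.protein_id, res.z_score))
    ranked.sort(key=lambda t: (t[1] is None, -(t[1] or 0.0), t[0]))
    return ranked


def _require_yc(seq: str, position: int, strand: str) -> None:
    n = len(seq)
    if not 1 <= position <= n:
        raise InputError(f"position {position} outside sequence of length {n}")
    base = seq[position - 1]
    if strand == "+":
        if base != "C":
            raise InputError(f"position {position}+ is {base}, not C")
        if position < 2 or seq[position - 2] not in "CT":
            raise InputError(f"site {position}+ lacks a 5' pyrimidine (YC context)")
    elif strand == "-":
        if base != "G":
            raise InputError(f"position {position}- is {base} on forward strand, not G")
        if position >= n or seq[position] not in "AG":
            raise InputError(f"site {position}- lacks a 5' pyrimidine (YC context)")
    else:
        raise InputError(f"strand must be '+' or '-', got {strand!r}")


def write_alignments_tsv(summary: ScanSummary, path: PathLike) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def summaries_frame(summaries: Sequence[ScanSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor_id": [s.factor_id for s in summaries],
            "n_sites": [s.n_sites for s in summaries],
            "mean": [s.mean_score for s in summaries],
            "sd": [s.sd_score for s in summaries],
        }
    )


def score_histogram(summary: ScanSummary, bins: int = 50) -> pd.DataFrame:
    """Plot-ready histogram of a factor's raw scores (bin edges + counts)."""
    scores = np.array([r.raw_score for r in summary.results])
    counts, edges = np.histogram(scores, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
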