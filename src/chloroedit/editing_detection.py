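"""C-to-U editing detection from strand-aware base-count pileups.

Editing extent at a site is (T reads) / (T reads + C reads), in percent, on
the examined transcript strand.  Candidate events must sit on a genomic C,
carry strictly more than ``min_edited_reads`` T reads and a strictly greater
than ``min_fraction_percent`` edited fraction.  Induced events — sites edited
only when a candidate factor is over-expressed — must additionally be
detected in every over-expressor replicate, lie outside homopolymer decoy
contexts (T)nC(T)n / (A)nG(A)n that attract mis-aligned reads, and follow
the genotype ordering low-expressor <= control < over-expressor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, NoCoverageError
from .io_utils import PathLike, complement, genome_from_any

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = [
    "sample_id",
    "seq_id",
    "position",
    "strand",
    "ref_base",
    "nA",
    "nC",
    "nG",
    "nT",
]

GENOTYPES = ("low_expr", "control", "over_expr")

SiteKey = Tuple[str, int, str]  # (seq_id, 1-based position, strand)


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one position on one transcript strand of one sample.

    ``ref_base`` and the counts are expressed on the examined strand: for a
    '-' column, ``nT`` counts reads supporting T on the minus strand.
    """

    sample_id: str
    seq_id: str
    position: int
    strand: str
    ref_base: str
    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self):
        if self.ref_base not in "ACGT":
            raise InputError(f"ref_base must be A/C/G/T, got {self.ref_base!r}")
        if min(self.nA, self.nC, self.nG, self.nT) < 0:
            raise InputError("base counts must be non-negative")
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class EditingMeasurement:
    seq_id: str
    position: int
    strand: str
    sample_id: str
    n_T: int
    n_C: int
    fraction_percent: float

    @property
    def site(self) -> SiteKey:
        return (self.seq_id, self.position, self.strand)


@dataclass
class FilterConfig:
    """Thresholds of the detection and induced-event rules.

    Both detection thresholds are strict (>): 10 edited reads or 1.0% edited
    fraction exactly do NOT pass.
    """

    min_edited_reads: int = 10
    min_fraction_percent: float = 1.0
    homopolymer_min_run: int = 2
    pattern_tolerance: float = 0.0

    def __post_init__(self):
        if self.min_edited_reads < 0 or self.min_fraction_percent < 0:
            raise InputError("detection thresholds must be non-negative")
        if self.homopolymer_min_run < 1:
            raise InputError("homopolymer_min_run must be >= 1")
        if self.pattern_tolerance < 0:
            raise InputError("pattern_tolerance must be >= 0")


def read_pileups(path: PathLike) -> pd.DataFrame:
    """Read a pileup TSV (columns ``sample_id, seq_id, position, strand,
    ref_base, nA, nC, nG, nT``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing pileup column(s) {missing}")
    return df


def editing_fraction(n_T: int, n_C: int) -> float:
    """Editing extent in percent: 100 * T / (T + C)."""
    if n_T < 0 or n_C < 0:
        raise InputError("read counts must be non-negative")
    total = n_T + n_C
    if total == 0:
        raise NoCoverageError("no T or C reads at site")
    return 100.0 * n_T / total


def _check_ref_consistency(df: pd.DataFrame, genome: Dict[str, str]) -> None:
    for seq_id, grp in df.groupby("seq_id"):
        if seq_id not in genome:
            raise ConsistencyError(f"pileup sequence {seq_id!r} not in genome")
        seq = genome[seq_id]
        pos = grp["position"].to_numpy(int)
        if pos.min() < 1 or pos.max() > len(seq):
            bad = pos[(pos < 1) | (pos > len(seq))][0]
            raise InputError(f"pileup position {seq_id}:{bad} outside genome bounds")
        fwd = np.frombuffer(seq.encode(), dtype="S1")[pos - 1].astype("U1")
        expected = np.where(
            grp["strand"].to_numpy() == "+",
            fwd,
            np.array([complement(b) for b in fwd]),
        )
        ref = grp["ref_base"].to_numpy("U1")
        mism = expected != ref
        if mism.any():
            i = int(np.nonzero(mism)[0][0])
            raise ConsistencyError(
                f"pileup ref_base {ref[i]} at {seq_id}:{pos[i]}"
                f"{grp['strand'].iloc[i]} disagrees with genome base {expected[i]}"
            )


def detect_candidate_events(
    pileups: pd.DataFrame,
    genome: Union[Dict[str, str], PathLike],
    cfg: Optional[FilterConfig] = None,
) -> List[EditingMeasurement]:
    """Apply the two-part detection filter to one sample's pileup columns.

    Keeps columns where the examined strand carries a genomic C, the T-read
    count strictly exceeds ``cfg.min_edited_reads`` and the edited fraction
    strictly exceeds ``cfg.min_fraction_percent``.
    """
    cfg = cfg or FilterConfig()
    genome = genome_from_any(genome)
    if pileups["sample_id"].nunique() > 1:
        raise InputError("detect_candidate_events expects a single sample's pileups")
    _check_ref_consistency(pileups, genome)

    on_c = pileups[pileups["ref_base"] == "C"]
    n_T = on_c["nT"].to_numpy(int)
    n_C = on_c["nC"].to_numpy(int)
    total = n_T + n_C
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, 100.0 * n_T / np.maximum(total, 1), 0.0)
    keep = (n_T > cfg.min_edited_reads) & (frac > cfg.min_fraction_percent)
    out = []
    for (_, row), t, c, f in zip(on_c[keep].iterrows(), n_T[keep], n_C[keep], frac[keep]):
        out.append(
            EditingMeasurement(
                seq_id=row["seq_id"],
                position=int(row["position"]),
                strand=row["strand"],
                sample_id=row["sample_id"],
                n_T=int(t),
                n_C=int(c),
                fraction_percent=float(f),
            )
        )
    return out


def _run_length(seq: str, start: int, step: int, base: str) -> int:
    """Length of the run of ``base`` starting at 0-based ``start`` going in
    direction ``step``; truncated at sequence ends."""
    n = len(seq)
    count = 0
    i = start
    while 0 <= i < n and seq[i] == base:
        count += 1
        i += step
    return count


def flag_homopolymer_context(
    genome: Union[Dict[str, str], PathLike],
    site: SiteKey,
    min_run: int = 2,
) -> bool:
    """True when a site sits in the mis-alignment-prone homopolymer context:
    (T)nC(T)n on the forward strand, or (A)nG(A)n read on the forward strand
    for a reverse-strand site; each flank run must reach ``min_run``.
    Flanks truncated by a sequence end are measured on the available bases.
    """
    if min_run < 1:
        raise InputError("min_run must be >= 1")
    genome = genome_from_any(genome)
    seq_id, position, strand = site
    if seq_id not in genome:
        raise InputError(f"unknown sequence {seq_id!r}")
    seq = genome[seq_id]
    if not 1 <= position <= len(seq):
        raise InputError(f"position {position} outside {seq_id}")
    i = position - 1
    flank_base = "T" if strand == "+" else "A"
    left = _run_length(seq, i - 1, -1, flank_base)
    right = _run_length(seq, i + 1, +1, flank_base)
    return left >= min_run and right >= min_run


@dataclass
class GenotypeSeries:
    """Pileup replicates grouped by genotype label.

    ``replicates[genotype]`` is a list of single-sample pileup DataFrames.
    The canonical labels are ``low_expr`` (weak-promoter complementation),
    ``control`` (wild type) and ``over_expr`` (strong-promoter line).
    """

    replicates: Dict[str, List[pd.DataFrame]] = field(default_factory=dict)

    def __post_init__(self):
        for g, reps in self.replicates.items():
            if not reps:
                raise InputError(f"genotype {g!r} has zero replicates")

    @classmethod
    def from_pileups(
        cls, pileups: pd.DataFrame, genotype_map: Mapping[str, str]
    ) -> "GenotypeSeries":
        """Split a multi-sample pileup table by ``{sample_id: genotype}``."""
        reps: Dict[str, List[pd.DataFrame]] = {}
        for sample_id, grp in pileups.groupby("sample_id", sort=True):
            if sample_id not in genotype_map:
                raise InputError(f"sample {sample_id!r} missing from genotype map")
            reps.setdefault(genotype_map[sample_id], []).append(grp.reset_index(drop=True))
        return cls(replicates=reps)


@dataclass(frozen=True)
class InducedCall:
    site: SiteKey
    mean_low: float
    mean_control: float
    mean_over: float


@dataclass
class InducedCallResult:
    calls: List[InducedCall]
    flagged: List[SiteKey]  # homopolymer-context sites, kept for manual review


def _site_fraction(df: pd.DataFrame, site: SiteKey) -> float:
    """Edited fraction of a site in one replicate; 0 when uncovered."""
    seq_id, position, strand = site
    rows = df[
        (df["seq_id"] == seq_id)
        & (df["position"] == position)
        & (df["strand"] == strand)
    ]
    if rows.empty:
        return 0.0
    n_T = int(rows["nT"].iloc[0])
    n_C = int(rows["nC"].iloc[0])
    if n_T + n_C == 0:
        return 0.0
    return 100.0 * n_T / (n_T + n_C)


def call_induced_events(
    series: GenotypeSeries,
    genome: Union[Dict[str, str], PathLike],
    cfg: Optional[FilterConfig] = None,
    *,
    required_over_replicates: int = 3,
) -> InducedCallResult:
    """Call sites whose editing is induced by factor over-expression.

    A site is called iff (1) it passes the detection filter in every
    over-expressor replicate; (2) it is not in a homopolymer decoy context;
    (3) replicate-mean fractions follow low <= control + tol < over.
    Flagged homopolymer sites that pass (1) are reported separately.
    """
    cfg = cfg or FilterConfig()
    genome = genome_from_any(genome)
    for g in GENOTYPES:
        if g not in series.replicates:
            raise InputError(f"genotype {g!r} missing from series")
    over = series.replicates["over_expr"]
    if len(over) != required_over_replicates:
        raise InputError(
            f"expected {required_over_replicates} over_expr replicates, got {len(over)}"
        )

    detected_sets = []
    for rep in over:
        events = detect_candidate_events(rep, genome, cfg)
        detected_sets.append({e.site for e in events})
    common = set.intersection(*detected_sets) if detected_sets else set()

    calls: List[InducedCall] = []
    flagged: List[SiteKey] = []
    for site in sorted(common):
        if flag_homopolymer_context(genome, site, cfg.homopolymer_min_run):
            flagged.append(site)
            continue
        means = {
            g: float(np.mean([_site_fraction(rep, site) for rep in series.replicates[g]]))
            for g in GENOTYPES
        }
        low, ctrl, ov = means["low_expr"], means["control"], means["over_expr"]
        if low <= ctrl + cfg.pattern_tolerance and ctrl + cfg.pattern_tolerance < ov:
            calls.append(InducedCall(site, low, ctrl, ov))
    return InducedCallResult(calls=calls, flagged=flagged)


def quantify_known_sites(
    pileups: pd.DataFrame,
    sites: Sequence[Tuple[str, str, int, str]],
    genotype_map: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site, per-sample editing fractions plus group mean and SE.

    ``sites`` rows are (name, seq_id, position, strand).  Returns
    (per-replicate table, summary table); uncovered site/sample pairs are
    emitted with missing (NaN) fractions, and the SE is the sample SD /
    sqrt(n) over replicates with data (NaN when n < 2).
    """
    samples = sorted(pileups["sample_id"].unique())
    rows = []
    for name, seq_id, position, strand in sites:
        for sample_id in samples:
            sub = pileups[
                (pileups["sample_id"] == sample_id)
                & (pileups["seq_id"] == seq_id)
                & (pileups["position"] == int(position))
                & (pileups["strand"] == strand)
            ]
            if sub.empty or int(sub["nT"].iloc[0]) + int(sub["nC"].iloc[0]) == 0:
                frac, n_T, n_C = math.nan, math.nan, math.nan
            else:
                n_T = int(sub["nT"].iloc[0])
                n_C = int(sub["nC"].iloc[0])
                frac = 100.0 * n_T / (n_T + n_C)
            rows.append(
                {
                    "site": name,
                    "seq_id": seq_id,
                    "position": int(position),
                    "strand": strand,
                    "sample_id": sample_id,
                    "genotype": genotype_map.get(sample_id) if genotype_map else "all",
                    "n_T": n_T,
                    "n_C": n_C,
                    "fraction_percent": frac,
                }
            )
    per_rep = pd.DataFrame(rows)
    uncovered = per_rep["fraction_percent"].isna().sum()
    if uncovered:
        logger.warning("%d site/sample pairs uncovered (reported as missing)", uncovered)

    def _summ(grp: pd.DataFrame) -> pd.Series:
        vals = grp["fraction_percent"].dropna()
        n = len(vals)
        mean = vals.mean() if n else math.nan
        se = vals.std(ddof=1) / math.sqrt(n) if n >= 2 else math.nan
        return pd.Series({"n": n, "mean": mean, "se": se})

    summary = (
        per_rep.groupby(["site", "genotype"], sort=False)
        .apply(_summ, include_groups=False)
        .reset_index()
    )
    return per_rep, summary


def read_known_sites(path: PathLike) -> List[Tuple[str, str, int, str]]:
    """Known-sites TSV: columns ``name, seq_id, position, strand``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("name", "seq_id", "position", "strand") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    return [
        (str(r["name"]), str(r["seq_id"]), int(r["position"]), str(r["strand"]))
        for _, r in df.iterrows()
    ]
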