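"""Expression quantification: RPKM over a curated plastid gene set, qPCR
normalization, and pairing of editing with expression per transgenic line.

RPKM = 1e9 * Ri / (Ti * L), where Ri is the read count of the gene, L its
length and Ti the total reads mapped to the *selected* gene set of the
sample.  The selected set excludes rRNA and tRNA genes, the original
(non-concatenated) rps12 exons and one copy of the inverted repeat — the
duplications that would otherwise double-count reads.

The annotation is first modified the way the read mapping expects: the
concatenated rps12 construct (exon1 + both intron halves + exon2, 60 bp of
flank each end) is appended after the plastid record with its two intron
features, and the ycf3 intron 1 boundary is shifted one nucleotide
downstream to match the true splice site.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, CoordinateError, InputError
from .io_utils import PathLike, genome_from_any

logger = logging.getLogger(__name__)

# Internal layout of the concatenated rps12 construct, 1-based relative to
# its first base: total length and the two intron intervals.
RPS12_CONSTRUCT_LENGTH = 2519
RPS12_INTRON1_REL = (175, 1664)
RPS12_INTRON2_REL = (1897, 2433)


@dataclass(frozen=True)
class GeneRecord:
    """A counted gene: locus span plus the length L used in RPKM (union of
    exon segments by default, locus span on request)."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    biotype: str  # mRNA / rRNA / tRNA / other
    length: int

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.length <= 0:
            raise InputError(f"{self.gene_id}: non-positive length")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR comparison: target and reference Cq with amplification
    efficiencies E (1.0 = perfect doubling per cycle)."""

    sample_id: str
    cq_target: float
    e_target: float
    cq_ref: float
    e_ref: float
    max_cycles: float = 35.0

    def __post_init__(self):
        for name, e in (("e_target", self.e_target), ("e_ref", self.e_ref)):
            if e <= -1:
                raise InputError(f"{name} must be > -1, got {e}")
        for name, cq in (("cq_target", self.cq_target), ("cq_ref", self.cq_ref)):
            if cq > self.max_cycles:
                warnings.warn(f"{name}={cq} exceeds max_cycles={self.max_cycles}")


@dataclass
class ModifiedAnnotation:
    """Result of the annotation modification: the extended genome, the new
    feature intervals, and the shifted ycf3 intron."""

    genome: Dict[str, str]
    plastid_id: str
    construct_interval: Tuple[int, int]
    intron1_interval: Tuple[int, int]
    intron2_interval: Tuple[int, int]
    ycf3_intron_interval: Optional[Tuple[int, int]]
    gff3_lines: List[str] = field(default_factory=list)

    def write_gff3(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for line in self.gff3_lines:
                fh.write(line.rstrip("\n") + "\n")


def build_modified_annotation(
    genome: Union[Dict[str, str], PathLike],
    annotation: Optional[PathLike] = None,
    *,
    plastid_id: str = "ChrC",
    construct_seq: Optional[str] = None,
    construct_length: int = RPS12_CONSTRUCT_LENGTH,
    intron1_rel: Tuple[int, int] = RPS12_INTRON1_REL,
    intron2_rel: Tuple[int, int] = RPS12_INTRON2_REL,
    ycf3_intron: Optional[Tuple[int, int]] = None,
) -> ModifiedAnnotation:
    """Append the concatenated rps12 construct to the plastid record and emit
    the modified feature intervals.

    The construct occupies positions L0+1 .. L0+construct_length of the
    extended plastid record (L0 = original length); the two intron features
    are placed at the relative intervals given (1-based within the
    construct).  ``ycf3_intron`` is the *current* (start, end) of the ycf3
    intron 1 feature, shifted one nucleotide downstream in the output; when
    omitted it is looked up in ``annotation`` (GFF3), if provided.
    """
    genome = genome_from_any(genome)
    if plastid_id not in genome:
        raise InputError(f"plastid record {plastid_id!r} not in genome")
    if construct_seq is not None and len(construct_seq) != construct_length:
        raise CoordinateError(
            f"construct sequence length {len(construct_seq)} != declared "
            f"construct_length {construct_length}"
        )
    for name, (a, b) in (("intron1", intron1_rel), ("intron2", intron2_rel)):
        if not (1 <= a <= b <= construct_length):
            raise CoordinateError(
                f"{name} relative interval {a}-{b} outside construct of "
                f"length {construct_length}"
            )
    if intron2_rel[0] <= intron1_rel[1]:
        raise CoordinateError("rps12 intron intervals overlap")

    L0 = len(genome[plastid_id])
    if construct_seq is None:
        construct_seq = _derive_rps12_construct(genome[plastid_id], annotation, construct_length)
    extended = dict(genome)
    extended[plastid_id] = genome[plastid_id] + construct_seq

    construct = (L0 + 1, L0 + construct_length)
    intron1 = (L0 + intron1_rel[0], L0 + intron1_rel[1])
    intron2 = (L0 + intron2_rel[0], L0 + intron2_rel[1])

    if ycf3_intron is None and annotation is not None:
        ycf3_intron = _find_ycf3_intron(annotation)
    shifted = None
    if ycf3_intron is not None:
        shifted = (ycf3_intron[0] + 1, ycf3_intron[1] + 1)  # one nt downstream

    lines = [
        _gff3_line(plastid_id, "gene", *construct, "+", "ID=rps12_concat"),
        _gff3_line(plastid_id, "intron", *intron1, "+", "ID=rps12_concat_intron1;Parent=rps12_concat"),
        _gff3_line(plastid_id, "intron", *intron2, "+", "ID=rps12_concat_intron2;Parent=rps12_concat"),
    ]
    if shifted is not None:
        lines.append(_gff3_line(plastid_id, "intron", *shifted, "-", "ID=ycf3_intron1;Parent=ycf3"))

    return ModifiedAnnotation(
        genome=extended,
        plastid_id=plastid_id,
        construct_interval=construct,
        intron1_interval=intron1,
        intron2_interval=intron2,
        ycf3_intron_interval=shifted,
        gff3_lines=lines,
    )


def _gff3_line(seq_id, ftype, start, end, strand, attrs) -> str:
    return "\t".join(
        [seq_id, "chloroedit", ftype, str(start), str(end), ".", strand, ".", attrs]
    )


def _find_ycf3_intron(annotation: PathLike) -> Optional[Tuple[int, int]]:
    db = _load_gff(annotation)
    for feat in db.all_features(featuretype="intron"):
        attrs = {k.lower(): v for k, v in feat.attributes.items()}
        text = " ".join(sum(attrs.values(), [])).lower()
        if "ycf3" in text:
            return (feat.start, feat.end)
    logger.warning("%s: no ycf3 intron feature found; no shift applied", annotation)
    return None


def _derive_rps12_construct(plastid_seq: str, annotation, construct_length: int) -> str:
    """Build the appended construct from annotated rps12 exons with 60 bp of
    flank each end when no explicit sequence is supplied; fall back to a
    placeholder of Ns (coordinate arithmetic does not depend on content)."""
    if annotation is not None:
        db = _load_gff(annotation)
        exons = []
        for feat in db.all_features(featuretype="exon"):
            text = " ".join(sum(feat.attributes.values(), [])).lower()
            if "rps12" in text:
                exons.append(feat)
        if exons:
            exons.sort(key=lambda f: f.start)
            lo = max(1, exons[0].start - 60)
            hi = min(len(plastid_seq), exons[-1].end + 60)
            pieces = [plastid_seq[lo - 1:exons[0].start - 1]]
            pieces += [plastid_seq[f.start - 1:f.end] for f in exons]
            pieces.append(plastid_seq[exons[-1].end:hi])
            seq = "".join(pieces)
            if len(seq) >= construct_length:
                return seq[:construct_length]
            return seq + "N" * (construct_length - len(seq))
    return "N" * construct_length


def _load_gff(annotation: PathLike):
    import gffutils

    return gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def gene_records_from_gff(
    annotation: PathLike, *, locus_span: bool = False
) -> List[GeneRecord]:
    """Build GeneRecords from a GFF3: biotype from the child feature type
    (mRNA/rRNA/tRNA), length L from the union of exon segments (or the locus
    span with ``locus_span``)."""
    db = _load_gff(annotation)
    records = []
    for gene in db.all_features(featuretype="gene"):
        biotype = "other"
        exon_iv: List[Tuple[int, int]] = []
        for child in db.children(gene.id):
            if child.featuretype in ("mRNA", "rRNA", "tRNA"):
                biotype = child.featuretype
            if child.featuretype == "exon":
                exon_iv.append((child.start, child.end))
        if locus_span or not exon_iv:
            length = gene.end - gene.start + 1
        else:
            length = _union_length(exon_iv)
        records.append(
            GeneRecord(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                biotype=biotype,
                length=length,
            )
        )
    return records


def _union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_end + 1:
            total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    total += cur_end - cur_start + 1
    return total


def select_gene_set(
    genes: Sequence[GeneRecord],
    *,
    exclude_biotypes: Sequence[str] = ("rRNA", "tRNA"),
    ir_regions: Optional[Mapping[str, Tuple[str, int, int]]] = None,
    exclude_ir: Optional[str] = None,
    exclude_gene_ids: Sequence[str] = (),
) -> List[GeneRecord]:
    """Curate the counted gene set.

    Removes excluded biotypes (rRNA/tRNA by default), explicitly excluded
    gene ids (e.g. the original non-concatenated rps12 exons), and genes
    wholly inside the designated inverted-repeat copy.  ``ir_regions`` maps
    IR copy names to (seq_id, start, end); designating both copies is a
    configuration error, designating none skips IR filtering with a warning.
    """
    if exclude_ir is not None and not isinstance(exclude_ir, str):
        if len(set(exclude_ir)) > 1:
            raise ConfigError("cannot exclude more than one inverted-repeat copy")
        exclude_ir = next(iter(exclude_ir))
    if exclude_ir is not None:
        if ir_regions is None or exclude_ir not in ir_regions:
            raise ConfigError(f"IR copy {exclude_ir!r} not among designated regions")
    if ir_regions is None and exclude_ir is None:
        logger.warning("no inverted-repeat designation; IR filtering skipped")

    excluded_ids = set(exclude_gene_ids)
    kept = []
    for g in genes:
        if g.biotype in exclude_biotypes:
            continue
        if g.gene_id in excluded_ids:
            continue
        if ir_regions is not None and exclude_ir is not None:
            seq_id, lo, hi = ir_regions[exclude_ir]
            if g.seq_id == seq_id and lo <= g.start and g.end <= hi:
                continue
        kept.append(g)
    return kept


def rpkm(Ri: float, Ti: float, L: float) -> float:
    """Reads per kilobase of transcript per million mapped reads:
    1e9 * Ri / (Ti * L)."""
    if Ri < 0:
        raise InputError("read count must be non-negative")
    if Ti <= 0 or L <= 0:
        raise InputError(f"Ti and L must be positive (Ti={Ti}, L={L})")
    return 1e9 * Ri / (Ti * L)


def rpkm_table(
    counts: pd.DataFrame,
    genes: Sequence[GeneRecord],
) -> pd.DataFrame:
    """Per-gene, per-sample RPKM over the selected gene set.

    ``counts`` columns: gene_id, sample_id, reads.  Ti is the per-sample sum
    of reads over the selected genes; counts for genes outside the set are
    ignored.
    """
    lengths = {g.gene_id: g.length for g in genes}
    sel = counts[counts["gene_id"].isin(lengths)].copy()
    if sel.empty:
        raise InputError("no counts for any gene in the selected set")
    ti = sel.groupby("sample_id")["reads"].sum()
    rows = []
    for _, r in sel.iterrows():
        t = float(ti[r["sample_id"]])
        rows.append(
            {
                "gene_id": r["gene_id"],
                "sample_id": r["sample_id"],
                "reads": int(r["reads"]),
                "Ti": t,
                "rpkm": rpkm(float(r["reads"]), t, lengths[r["gene_id"]]),
            }
        )
    return pd.DataFrame(rows)


def qpcr_normalized_expression(m: QpcrMeasurement) -> float:
    """Efficiency-corrected expression of the target relative to the
    reference gene: (1+E_t)^(max_cycles - Cq_t) / (1+E_r)^(max_cycles - Cq_r)."""
    num = (1.0 + m.e_target) ** (m.max_cycles - m.cq_target)
    den = (1.0 + m.e_ref) ** (m.max_cycles - m.cq_ref)
    return num / den


def read_qpcr_table(path: PathLike, max_cycles: float = 35.0) -> List[QpcrMeasurement]:
    """qPCR TSV: columns ``sample_id, cq_target, e_target, cq_ref, e_ref``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample_id", "cq_target", "e_target", "cq_ref", "e_ref"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    return [
        QpcrMeasurement(
            sample_id=str(r["sample_id"]),
            cq_target=float(r["cq_target"]),
            e_target=float(r["e_target"]),
            cq_ref=float(r["cq_ref"]),
            e_ref=float(r["e_ref"]),
            max_cycles=max_cycles,
        )
        for _, r in df.iterrows()
    ]


def _mean_se(values: Sequence[float]) -> Tuple[float, float]:
    vals = [v for v in values if not math.isnan(v)]
    n = len(vals)
    mean = float(np.mean(vals)) if n else math.nan
    se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
    return mean, se


def pair_editing_expression(
    editing: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-line editing and expression replicates into one row per
    transgenic line with means and standard errors on both axes.

    ``editing`` columns: line_id, editing_percent (one row per replicate);
    ``expression`` columns: line_id, expression.  Lines present in only one
    input are dropped with a warning; zero overlap is an error.
    """
    ed_lines = set(editing["line_id"])
    ex_lines = set(expression["line_id"])
    common = sorted(ed_lines & ex_lines)
    if not common:
        raise InputError("no overlapping line identifiers between editing and expression")
    dropped = (ed_lines | ex_lines) - set(common)
    if dropped:
        warnings.warn(f"lines without both measurements dropped: {sorted(dropped)}")
    rows = []
    for line in common:
        e_mean, e_se = _mean_se(editing.loc[editing["line_id"] == line, "editing_percent"].tolist())
        x_mean, x_se = _mean_se(expression.loc[expression["line_id"] == line, "expression"].tolist())
        rows.append(
            {
                "line_id": line,
                "editing_mean": e_mean,
                "editing_se": e_se,
                "expression_mean": x_mean,
                "expression_se": x_se,
            }
        )
    return pd.DataFrame(rows)
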