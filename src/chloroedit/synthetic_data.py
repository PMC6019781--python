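"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study design the pipeline is built for: a random
plastid-like genome; a planted factor-binding site whose upstream window is
the factor's maximal-scoring sequence; per-sample base-count pileups with
binomially sampled edited-read counts at planted sites across three
genotypes (weak-promoter complementation line, wild-type control,
over-expression line) with three replicates each; homopolymer decoy sites
that mimic mis-alignment artifacts; multinomial gene counts with known
RPKM; qPCR Cq tables with known expression ratios; and Mendelian 3:1 seed
segregation from a selfed heterozygote carrying a recessive embryo-lethal
allele.

Every generator takes an explicit seed and is bit-reproducible under
``numpy.random.default_rng``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import CollisionError, InputError
from .io_utils import PathLike, reverse_complement
from .ppr_code import CodeTable, PPRArray, preferred_window

GENOTYPES = ("low_expr", "control", "over_expr")

# Default planted editing pattern: essentially unedited in the weak line,
# half-edited in wild type, near-complete on over-expression.
DEFAULT_PATTERN = {"low_expr": 0.02, "control": 0.50, "over_expr": 0.95}
# Decoys are given a genotype-graded apparent fraction so that only the
# homopolymer-context rule (not the genotype-pattern rule) excludes them.
DEFAULT_DECOY_PATTERN = {"low_expr": 0.05, "control": 0.20, "over_expr": 0.50}

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PlantedSite:
    """A simulated editing site: genomic placement plus the true edited
    fraction per genotype."""

    position: int
    strand: str
    fractions: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN))
    is_decoy: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"strand must be +/-, got {self.strand!r}")
        for g, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise InputError(f"fraction for {g} must be in [0,1], got {f}")


@dataclass
class SimConfig:
    """Study-design parameters for the pileup simulator.

    Defaults mirror the design the pipeline targets: three genotypes x three
    replicates, deep (1000x) coverage, a low uniform sequencing-error rate.
    """

    rng_seed: int = 0
    genome_length: int = 5000
    gc_fraction: float = 0.36  # typical plastid genome GC content
    depth: int = 1000
    seq_error_rate: float = 0.001
    replicates: int = 3
    poisson_depth: bool = False
    strands: Tuple[str, ...] = ("+", "-")

    def __post_init__(self):
        if not 0.0 < self.gc_fraction < 1.0:
            raise InputError("gc_fraction must be in (0,1)")
        if not 0.0 <= self.seq_error_rate <= 0.01:
            raise InputError("seq_error_rate must be in [0, 0.01]")
        if self.depth <= 0:
            raise InputError("depth must be positive")
        if self.genome_length < 50:
            raise InputError("genome_length must be >= 50")


def gen_genome(
    length: int,
    gc_fraction: float = 0.36,
    seed: int = 0,
    seq_id: str = "ChrC",
) -> Dict[str, str]:
    """I.i.d. random genome at the requested GC fraction."""
    if length < 50:
        raise InputError("genome length must be >= 50")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InputError("gc_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return {seq_id: seq}


def plant_target(
    genome: Dict[str, str],
    array: PPRArray,
    table: CodeTable,
    position: int,
    strand: str,
    *,
    seq_id: Optional[str] = None,
    offset: int = 4,
    occupied: Optional[List[Tuple[int, int]]] = None,
) -> Tuple[Dict[str, str], Dict[str, object]]:
    """Overwrite the genome so that ``position``/``strand`` is a maximal-
    scoring target of ``array``: the upstream window becomes the factor's
    preferred window, the site base becomes C and its 5' neighbour a
    pyrimidine (T).  Returns the modified genome and an edit manifest.

    ``occupied`` accumulates planted spans across calls; overlap or running
    off the sequence raises :class:`CollisionError`.
    """
    seq_id = seq_id or next(iter(genome))
    seq = genome[seq_id]
    n = len(seq)
    win_rna = preferred_window(array, table)
    L = len(win_rna)
    win_dna = win_rna.replace("U", "T")

    if strand == "+":
        lo, hi = position - offset - L + 1, position  # 1-based inclusive span
        if position - 1 >= 1:
            lo = min(lo, position - 1)
    else:
        lo, hi = position, position + offset + L - 1
        if position + 1 <= n:
            hi = max(hi, position + 1)
    if lo < 1 or hi > n:
        raise CollisionError(
            f"planted site at {position}{strand} (span {lo}-{hi}) exceeds sequence bounds 1-{n}"
        )
    if occupied is not None:
        for a, b in occupied:
            if lo <= b and a <= hi:
                raise CollisionError(f"planted span {lo}-{hi} overlaps existing {a}-{b}")
        occupied.append((lo, hi))

    chars = list(seq)
    if strand == "+":
        wstart = position - offset - L  # 0-based
        chars[wstart:wstart + L] = list(win_dna)
        chars[position - 1] = "C"
        if position - 2 >= wstart + L:  # 5' neighbour outside the window
            # 'C' keeps the YC context and cannot extend a (T)n run, so a
            # planted site is never mistaken for a homopolymer decoy
            chars[position - 2] = "C"
        elif chars[position - 2] not in "CT":
            raise CollisionError("window base 5' of site is not a pyrimidine")
    else:
        wstart = position + offset - 1  # 0-based start of the forward-strand span
        chars[wstart:wstart + L] = list(reverse_complement(win_dna))
        chars[position - 1] = "G"
        if position < wstart:  # 5' neighbour (forward pos+1) outside the window
            chars[position] = "G"  # purine; cannot extend an (A)n run
        elif chars[position] not in "AG":
            raise CollisionError("window base 5' of site is not a pyrimidine")

    new_genome = dict(genome)
    new_genome[seq_id] = "".join(chars)
    manifest = {
        "seq_id": seq_id,
        "position": position,
        "strand": strand,
        "window": win_rna,
        "span": (lo, hi),
        "factor_id": array.protein_id,
    }
    return new_genome, manifest


def embed_decoy(
    genome: Dict[str, str],
    position: int,
    strand: str,
    run: int = 3,
    *,
    seq_id: Optional[str] = None,
) -> Dict[str, str]:
    """Write a homopolymer decoy context at a position: (T)run C (T)run on
    the forward strand, or (A)run G (A)run for a reverse-strand site."""
    seq_id = seq_id or next(iter(genome))
    seq = genome[seq_id]
    if not run + 1 <= position <= len(seq) - run:
        raise CollisionError(f"decoy at {position} with run {run} exceeds bounds")
    site_base, flank = ("C", "T") if strand == "+" else ("G", "A")
    chars = list(seq)
    chars[position - 1] = site_base
    for k in range(1, run + 1):
        chars[position - 1 - k] = flank
        chars[position - 1 + k] = flank
    new_genome = dict(genome)
    new_genome[seq_id] = "".join(chars)
    return new_genome


def _error_probs(base_idx: int, e: float) -> np.ndarray:
    p = np.full(4, e / 3)
    p[base_idx] = 1 - e
    return p


def simulate_pileups(
    genome: Dict[str, str],
    cfg: SimConfig,
    planted: Sequence[PlantedSite] = (),
) -> pd.DataFrame:
    """Per-sample, per-position strand-aware base counts.

    At a planted site the edited-read count is Binomial(depth, f(1-e) +
    (1-f)e/3); background positions see only sequencing error at rate e
    (uniform over the three alternative bases).  Samples are named
    ``<genotype>_rep<k>``.  Depth is fixed per column unless
    ``cfg.poisson_depth`` adds coverage noise.
    """
    if cfg.depth <= 0:
        raise InputError("depth must be positive")
    rng = np.random.default_rng(cfg.rng_seed)
    e = cfg.seq_error_rate
    frames = []
    planted_by_key = {(s.position, s.strand): s for s in planted}

    for seq_id, seq in genome.items():
        n = len(seq)
        enc = np.array([_BASE_IDX[b] for b in seq], dtype=np.int64)
        for strand in cfg.strands:
            if strand == "+":
                ref_idx = enc
            else:
                ref_idx = 3 - enc  # complement under A<->T, C<->G index map
            base_probs = np.stack([_error_probs(i, e) for i in range(4)])[ref_idx]
            t_probs = np.broadcast_to(_error_probs(3, e), (n, 4))
            for genotype in GENOTYPES:
                frac = np.zeros(n)
                for (pos, s), site in planted_by_key.items():
                    if s == strand and seq[pos - 1] == ("C" if s == "+" else "G"):
                        frac[pos - 1] = site.fractions.get(genotype, 0.0)
                probs = (1 - frac)[:, None] * base_probs + frac[:, None] * t_probs
                for rep in range(1, cfg.replicates + 1):
                    if cfg.poisson_depth:
                        depth = rng.poisson(cfg.depth, size=n)
                        depth = np.maximum(depth, 1)
                    else:
                        depth = np.full(n, cfg.depth)
                    counts = rng.multinomial(depth, probs)
                    frames.append(
                        pd.DataFrame(
                            {
                                "sample_id": f"{genotype}_rep{rep}",
                                "seq_id": seq_id,
                                "position": np.arange(1, n + 1),
                                "strand": strand,
                                "ref_base": _BASES[ref_idx],
                                "nA": counts[:, 0],
                                "nC": counts[:, 1],
                                "nG": counts[:, 2],
                                "nT": counts[:, 3],
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedStudy:
    """A complete synthetic experiment: genome with planted target and
    decoys, the pileups of all nine samples, and the ground truth."""

    genome: Dict[str, str]
    pileups: pd.DataFrame
    target: Dict[str, object]
    decoys: List[Tuple[int, str]]
    config: SimConfig


def simulate_study(
    array: PPRArray,
    table: CodeTable,
    cfg: Optional[SimConfig] = None,
    *,
    target_position: Optional[int] = None,
    target_strand: str = "+",
    pattern: Optional[Mapping[str, float]] = None,
    n_decoys: int = 3,
    decoy_run: int = 3,
    decoy_pattern: Optional[Mapping[str, float]] = None,
    offset: int = 4,
) -> SimulatedStudy:
    """Generate the full induced-editing experiment for one factor.

    Plants one preferred-window target with the genotype fraction pattern,
    embeds homopolymer decoy sites with graded apparent fractions, and
    simulates pileups for three genotypes x ``cfg.replicates`` replicates.
    """
    cfg = cfg or SimConfig()
    pattern = dict(pattern or DEFAULT_PATTERN)
    decoy_pattern = dict(decoy_pattern or DEFAULT_DECOY_PATTERN)
    rng = np.random.default_rng(cfg.rng_seed)

    genome = gen_genome(cfg.genome_length, cfg.gc_fraction, seed=int(rng.integers(2**31)))
    L = array.n_scored
    if target_position is None:
        target_position = cfg.genome_length // 2
    occupied: List[Tuple[int, int]] = []
    genome, manifest = plant_target(
        genome, array, table, target_position, target_strand,
        offset=offset, occupied=occupied,
    )

    decoys: List[Tuple[int, str]] = []
    margin = L + offset + decoy_run + 2
    for k in range(n_decoys):
        for _ in range(100):
            pos = int(rng.integers(margin, cfg.genome_length - margin))
            strand = "+" if rng.integers(2) == 0 else "-"
            span = (pos - decoy_run, pos + decoy_run)
            if all(not (span[0] <= b and a <= span[1]) for a, b in occupied):
                occupied.append(span)
                genome = embed_decoy(genome, pos, strand, decoy_run)
                decoys.append((pos, strand))
                break
        else:
            raise CollisionError("could not place decoy without collision")

    planted = [PlantedSite(target_position, target_strand, dict(pattern))]
    planted += [
        PlantedSite(pos, strand, dict(decoy_pattern), is_decoy=True)
        for pos, strand in decoys
    ]
    pileups = simulate_pileups(genome, cfg, planted)
    return SimulatedStudy(
        genome=genome, pileups=pileups, target=manifest, decoys=decoys, config=cfg
    )


def simulate_counts(
    lengths: Mapping[str, int],
    true_rpkm: Mapping[str, float],
    total_reads: int,
    seed: int = 0,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Multinomial gene counts whose expectation recovers ``true_rpkm``
    under the RPKM formula (read probability proportional to rpkm * L)."""
    if total_reads <= 0:
        raise InputError("total_reads must be positive")
    genes = list(lengths)
    weights = np.array([true_rpkm[g] * lengths[g] for g in genes], dtype=float)
    if np.any(weights < 0):
        raise InputError("true_rpkm must be non-negative")
    if weights.sum() == 0:
        raise InputError("all true_rpkm are zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_reads, weights / weights.sum())
    return pd.DataFrame(
        {"gene_id": genes, "sample_id": sample_id, "reads": counts}
    )


def simulate_qpcr(
    true_ratio: float,
    e_target: float = 1.0,
    e_ref: float = 1.0,
    cq_noise_sd: float = 0.1,
    n: int = 3,
    seed: int = 0,
    cq_ref_center: float = 25.0,
    max_cycles: float = 35.0,
) -> pd.DataFrame:
    """Cq pairs whose noiseless efficiency-corrected ratio equals
    ``true_ratio``; Gaussian noise of ``cq_noise_sd`` cycles on each Cq."""
    if true_ratio <= 0:
        raise InputError("true_ratio must be positive")
    if e_target <= -1 or e_ref <= -1:
        raise InputError("efficiencies must be > -1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cq_ref = cq_ref_center
        # solve (1+Et)^(M-cqt) = ratio * (1+Er)^(M-cqr) for cqt
        cq_target = max_cycles - (
            np.log(true_ratio) + (max_cycles - cq_ref) * np.log(1 + e_ref)
        ) / np.log(1 + e_target)
        rows.append(
            {
                "sample_id": f"rep{i + 1}",
                "cq_target": cq_target + rng.normal(0, cq_noise_sd),
                "e_target": e_target,
                "cq_ref": cq_ref + rng.normal(0, cq_noise_sd),
                "e_ref": e_ref,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SegregationDraw:
    """Seed-color census from a selfed heterozygote carrying a recessive
    embryo-lethal allele: each seed is white (homozygous mutant) with
    probability 1/4, green otherwise — the Mendelian 3:1 ratio."""

    n_seeds: int
    n_green: int
    n_white: int
    rng_seed: int

    @property
    def white_fraction(self) -> float:
        return self.n_white / self.n_seeds if self.n_seeds else 0.0


WHITE_SEED_PROBABILITY = 0.25  # homozygous-recessive progeny of a selfed Aa x Aa


def simulate_seed_segregation(n_seeds: int, seed: int = 0) -> SegregationDraw:
    if n_seeds < 0:
        raise InputError("n_seeds must be >= 0")
    rng = np.random.default_rng(seed)
    n_white = int(rng.binomial(n_seeds, WHITE_SEED_PROBABILITY)) if n_seeds else 0
    return SegregationDraw(
        n_seeds=n_seeds, n_green=n_seeds - n_white, n_white=n_white, rng_seed=seed
    )


def write_truth_manifest(study: SimulatedStudy, path: PathLike) -> None:
    payload = {
        "target": study.target,
        "decoys": [{"position": p, "strand": s} for p, s in study.decoys],
        "config": asdict(study.config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
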