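# Methods

This note records the models implemented in `chloroedit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user relying on the outputs should
know.

## PPR-code scoring and genome-wide ranking

A PPR editing factor is an ordered array of ~35-aa motifs, each binding one
RNA base. Base preference is carried by the amino acids at motif positions
5 and last; the recognition-code table maps each (aa5, aa_last) pair to a
log-likelihood-ratio 4-vector over {A, C, G, U}. An alignment score is the
sum of per-motif ratios over the factor's *scored* motifs (N→C) against the
site's upstream window (5′→3′).

Choices and rationale:

- **Code table as input.** Published code-table derivations differ and no
  single table is canonical here; the table is a required input and the
  bundled `example_code_table()` is synthetic, for demonstrations and tests
  only. Unknown (aa5, aa_last) combinations — including anything containing
  `X` — score `default_score` (0, the neutral log-likelihood): non-canonical
  amino-acid combinations have poorly understood selectivity and should
  neither reward nor penalize an alignment.
- **Which motifs score** is caller-controlled (`scored_mask`); the default
  scores every motif. Which subclasses (P/L/S vs E1/E2) contribute is not
  settled; the mask keeps that decision explicit and testable.
- **Alignment register.** The C-terminal-most scored motif aligns to
  position −4 relative to the edited C — the usual PPR-code register —
  with `offset` exposed as a parameter since the register is a convention,
  not a law.
- **Candidate universe.** Every cytidine preceded by a pyrimidine (YC), on
  both strands of every record. Windows that would run off a linear
  sequence end are 5′-padded with `N` (scoring the default) so that the
  census of candidates does not depend on factor length; a
  `drop_edge_windows` flag discards them instead, and a `circular` mode
  wraps windows around the (circular) plastid map. Coordinates are 1-based
  inclusive on the forward strand; a '−'-strand site is reported at the
  forward coordinate of its paired G.
- **z-scores** standardize each factor against the *population* of all its
  candidate alignments: z = (S − μ)/σ with σ the divide-by-n SD, because
  the candidate set is the full population, not a sample. A factor whose
  scores are all identical has no defined z; scans raise a
  degenerate-spread error, and the multi-factor ranking keeps such factors
  with a null z and a warning rather than dropping them silently.
- Ties in the ranking break deterministically by (z desc, seq_id,
  position, strand); the per-position argmax used for preferred windows
  breaks ties alphabetically (A < C < G < U).

The scanner is vectorized (per-factor score matrix gathered over encoded
windows); tests pin it to an independent per-position summation oracle and
to exhaustive window enumeration at small sizes.

## Editing detection and the induced-event caller

Editing extent is 100·T/(T+C) on the examined strand; pileup rows carry
strand-oriented counts, so no re-complementing is done at measure time (the
pileup's `ref_base` is cross-checked against the genome and mismatches are
hard errors). The detection filter keeps sites with a genomic C on the
examined strand, **strictly more than** `min_edited_reads` (default 10)
T reads and a **strictly greater than** `min_fraction_percent` (default
1.0) edited fraction — both strict by design; the boundary cases are
asserted in tests.

Induced-event calling requires (1) detection in every over-expressor
replicate (exactly 3 by default), (2) a negative homopolymer-context flag,
and (3) replicate-mean ordering low ≤ control + tol < over with
`pattern_tolerance` tol = 0 by default. The ≤/< asymmetry is deliberate:
the weak-promoter line may legitimately equal the control, but the
over-expressor must strictly exceed it. Sites failing only the homopolymer
rule are reported in a separate flagged table for manual review, not
silently dropped, since that rule is a heuristic for mis-alignment rather
than a biological impossibility. The homopolymer context is (T)ₙC(T)ₙ on
the forward strand or (A)ₙG(A)ₙ for a '−'-strand site read on the forward
strand, with `homopolymer_min_run` n = 2 per flank by default (the rule's n
is inherently a judgement call; 2 is the smallest run that creates real
mis-alignment pressure, and flank runs truncated by a sequence end are
measured on the available bases). A site uncovered in some replicate
contributes fraction 0 to that replicate's mean — absence of evidence of
editing, which is conservative for rule (3)'s lower genotypes.

Known-site quantification emits per-replicate fractions plus per-genotype
mean and SE (sample SD/√n; SE is null for n = 1 and uncovered pairs are
missing values, never zeros).

## Expression

RPKM = 10⁹·Rᵢ/(Tᵢ·L). Tᵢ is the per-sample read total over the
*selected* gene set: rRNA and tRNA biotypes excluded, explicitly listed
gene ids (the original, non-concatenated rps12 exons) excluded, and genes
wholly inside one designated inverted-repeat copy excluded (designating
both copies is a configuration error; designating none skips IR filtering
with a warning). Gene length L is the union of exon segments by default,
the naive locus span behind `locus_span=True`. When the counted set covers
all mapped reads, Σ rpkm·L·Tᵢ/10⁹ = Tᵢ to floating precision — asserted
as an invariant.

The annotation modification reproduces the mapping-reference edits this
kind of pipeline uses: a concatenated rps12 construct (2519 nt; exons plus
both intron halves with 60 bp flanks) appended after the plastid record,
with intron features at relative positions 175–1664 and 1897–2433 within
the construct, and the ycf3 intron 1 shifted one nucleotide downstream.
On a 154,478-bp plastid record these produce the absolute intervals
154479–156997, 154653–156142, 156375–156911 and 43753–44466; the
arithmetic is independent of sequence content and is asserted bit-exactly.

qPCR expression is (1+E_t)^(M−Cq_t)/(1+E_r)^(M−Cq_r) with `max_cycles`
M = 35 (a named constant, configurable); E ≤ −1 is rejected and Cq > M
warns. Editing/expression pairing produces one row per transgenic line with
means and SEs on both axes; no correlation statistic is computed — the
paired table is the deliverable and any formal statistic is left to the
caller.

## Cis-element co-evolution

Windows span −20…+4 around the edited position by default (the PPR
footprint plus the edited codon), aligned and gap-free. Partitioning reads
the genomic state directly from position 0 (C = editing required,
T = editing lost; anything else goes to an "other" bin with a warning).
"New nucleotides introduced" is formalized as *symbol-set inequality
between the groups at a position*, which is direction-agnostic and
therefore symmetric and invariant to duplicating sequences — both asserted
as properties. A within-group-consensus reading (`mode="consensus"`:
highlight when the editing-lost group deviates from the editing-required
group's majority base) is available behind a flag; the across-group
reading is the default because it is the minimal formalization, but no
claim is made that it is the only defensible one. Translation uses the
standard code with the element's own codon phase; partial codons are
trimmed, T/U are interchangeable.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical* structure of the study design:

- **Genome**: i.i.d. bases at GC = 0.36 (typical plastid composition).
  Real plastid genomes have inverted repeats, operons and strong local
  composition structure; none of that is simulated, so passing tests say
  nothing about, e.g., IR-induced multi-mapping.
- **Planted target**: the upstream window is overwritten with the factor's
  argmax window, the site base set to C and its 5′ neighbour to C — a
  pyrimidine that preserves the YC context and cannot extend a (T)ₙ run,
  so a planted site can never collide with the homopolymer decoy rule.
  By construction the planted site attains the factor's maximum achievable
  score; a second site tying that score by chance is possible (and more
  likely for short arrays), which is why recovery tests assert attainment
  of the maximal score.
- **Pileups**: one multinomial per column with p(T) = f(1−e) + (1−f)e/3,
  p(C) = (1−f)(1−e) + f·e/3, p(A) = p(G) = e/3 at a C-reference site with
  edited fraction f and uniform miscall rate e (default 0.001). This
  matches the binomial marginal for the edited-read count while conserving
  depth exactly. Depth is fixed (default 1000×, matching deep plastid
  coverage) with a Poisson option; read-level artifacts (quality, soft
  clipping, strand bias) are not modelled beyond the homopolymer decoys.
- **Decoys** sit in (T)ₙC(T)ₙ / (A)ₙG(A)ₙ contexts (run 3) and carry a
  genotype-graded apparent fraction (0.05/0.20/0.50) so they would pass
  detection *and* the genotype-pattern rule; their exclusion in end-to-end
  tests is therefore attributable to the homopolymer rule alone.
- **Genotype pattern** defaults to 0.02/0.50/0.95
  (weak-promoter / wild-type / over-expressor), three replicates each —
  the factor-limited regime the induced-caller is designed for.
- **Counts** are one multinomial draw with probabilities ∝ rpkm·L, so RPKM
  on the draw recovers the truth (exactly when Σ rpkm·L = 10⁹, otherwise
  up to that scale); **qPCR** Cq pairs invert the normalization formula
  exactly before Gaussian noise is added; **segregation** draws each seed
  white with probability 1/4.

All generators take explicit integer seeds and use
`numpy.random.default_rng`; identical seeds give bit-identical outputs.

## Problem sizes used in tests and the acceptance script

Scans and recovery runs use 2–5 kb genomes (hundreds to ~1,800 candidate
sites), 200 oracle instances at ≤ 500 bp, 20-seed recovery sweeps,
1,000-site fraction-recovery panels at depth 1,000, and one plastid-scale
(154,478 bp) enumeration for the census-convention and annotation checks.
These sizes exercise every code path at full statistical fidelity while
keeping any single run in seconds.

## Known limitations

- The bundled code table is illustrative; scientific use requires a real
  recognition-code derivation supplied by the user.
- The scanner scores fixed-register, gap-free alignments only; factors
  whose arrays skip or double-count bases are out of scope.
- Pileup ingestion starts from the neutral TSV format; generating pileups
  from BAM (alignment, duplicate handling) is an upstream step.
- The across-group fading rule treats a single divergent sequence the same
  as many; with very unbalanced group sizes the consensus-mode flag may be
  the more informative reading.
- Editing fractions assume independent reads; UMI-less duplicate inflation
  would narrow the apparent binomial error.
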