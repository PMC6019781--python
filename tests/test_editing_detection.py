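"""Editing-fraction arithmetic, detection filters and the induced-event caller."""

import math

import numpy as np
import pandas as pd
import pytest

from chloroedit.editing_detection import (
    FilterConfig,
    GenotypeSeries,
    call_induced_events,
    detect_candidate_events,
    editing_fraction,
    flag_homopolymer_context,
    quantify_known_sites,
)
from chloroedit.errors import ConsistencyError, InputError, NoCoverageError
from chloroedit.ppr_code import example_code_table
from chloroedit.synthetic_data import SimConfig, simulate_study

from conftest import pileup_frame, pileup_row


class TestEditingFraction:
    def test_hand_arithmetic(self):
        assert editing_fraction(30, 70) == pytest.approx(30.0)

    def test_zero_numerator(self):
        assert editing_fraction(0, 50) == 0.0

    def test_no_coverage_is_error(self):
        with pytest.raises(NoCoverageError):
            editing_fraction(0, 0)


GENOME = {"g": "ATCCA"}  # C at 3 (prev T) and 4 (prev C)


def one_site_pileup(nT, nC, position=3, ref="C", strand="+"):
    return pileup_frame(
        [pileup_row("s1", "g", position, strand, ref, nC=nC, nT=nT)]
    )


class TestDetectionFilter:
    def test_exactly_ten_edited_reads_rejected(self):
        """The edited-read threshold is strict: 10 is not > 10."""
        events = detect_candidate_events(one_site_pileup(10, 0), GENOME)
        assert events == []

    def test_eleven_of_thousand_accepted(self):
        events = detect_candidate_events(one_site_pileup(11, 989), GENOME)
        assert len(events) == 1
        assert events[0].fraction_percent == pytest.approx(1.1)

    def test_fifty_of_ten_thousand_rejected(self):
        """0.5% does not exceed the 1% fraction threshold."""
        assert detect_candidate_events(one_site_pileup(50, 9950), GENOME) == []

    def test_exactly_one_percent_rejected(self):
        assert detect_candidate_events(one_site_pileup(20, 1980), GENOME) == []

    def test_non_c_reference_ignored(self):
        pile = pileup_frame([pileup_row("s1", "g", 1, "+", "A", nA=500, nT=500)])
        assert detect_candidate_events(pile, GENOME) == []

    def test_reverse_strand_counts_used_directly(self):
        # forward base at 5 is A; minus-strand ref is T -> not a C site
        pile = pileup_frame([pileup_row("s1", "g", 5, "-", "T", nT=100)])
        assert detect_candidate_events(pile, GENOME) == []

    def test_ref_mismatch_names_position(self):
        pile = pileup_frame([pileup_row("s1", "g", 1, "+", "C", nC=10)])
        with pytest.raises(ConsistencyError, match="g:1"):
            detect_candidate_events(pile, GENOME)

    def test_multi_sample_frame_rejected(self):
        pile = pileup_frame(
            [
                pileup_row("s1", "g", 3, "+", "C", nC=10),
                pileup_row("s2", "g", 3, "+", "C", nC=10),
            ]
        )
        with pytest.raises(InputError):
            detect_candidate_events(pile, GENOME)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_filter_monotonicity(self, seed):
        """Raising either threshold never increases the number of events."""
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(200):
            total = int(rng.integers(20, 2000))
            nT = int(rng.integers(0, 60))
            rows.append(pileup_row("s1", "big", i * 2 + 2, "+", "C", nC=total - nT, nT=nT))
        genome = {"big": "TC" * 220}
        pile = pileup_frame(rows)
        prev = None
        for min_edited in (0, 5, 10, 20, 40):
            n = len(detect_candidate_events(pile, genome, FilterConfig(min_edited_reads=min_edited)))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for min_frac in (0.0, 0.5, 1.0, 2.0, 5.0):
            n = len(
                detect_candidate_events(
                    pile, genome, FilterConfig(min_fraction_percent=min_frac)
                )
            )
            if prev is not None:
                assert n <= prev
            prev = n

    def test_null_simulation_yields_no_calls(self):
        """Sequencing error alone (0.1%) cannot produce >10 edited reads at
        depth 1000 in practice: specificity check over seeds."""
        from chloroedit.synthetic_data import gen_genome, simulate_pileups

        for seed in range(5):
            cfg = SimConfig(
                rng_seed=seed, genome_length=1000, depth=1000,
                seq_error_rate=0.001, replicates=1, strands=("+",),
            )
            genome = gen_genome(cfg.genome_length, seed=seed + 50)
            pile = simulate_pileups(genome, cfg)
            one = pile[pile["sample_id"] == "control_rep1"].reset_index(drop=True)
            assert detect_candidate_events(one, genome) == []


class TestHomopolymerContext:
    def test_t_flanked_forward_site(self):
        genome = {"g": "AATTCTTAA"}
        assert flag_homopolymer_context(genome, ("g", 5, "+"), min_run=2)

    def test_no_flanking_t(self):
        assert not flag_homopolymer_context({"g": "AGCGA"}, ("g", 3, "+"), min_run=1)

    def test_a_flanked_reverse_site(self):
        genome = {"g": "TTAAGAATT"}
        assert flag_homopolymer_context(genome, ("g", 5, "-"), min_run=2)

    def test_run_requirement_respected(self):
        genome = {"g": "AATTCTTAA"}
        assert not flag_homopolymer_context(genome, ("g", 5, "+"), min_run=3)

    def test_boundary_truncates_runs(self):
        # C at position 1 has no 5' flank at all: left run 0 < min_run
        assert not flag_homopolymer_context({"g": "CTT"}, ("g", 1, "+"), min_run=1)


def constant_series(low, control, over, depth=1000, position=3, genome=GENOME):
    """Three genotypes x three replicates with exact (noise-free) fractions."""
    reps = {}
    for genotype, frac in (("low_expr", low), ("control", control), ("over_expr", over)):
        frames = []
        for r in range(3):
            nT = round(depth * frac / 100)
            frames.append(
                pileup_frame(
                    [pileup_row(f"{genotype}_rep{r}", "g", position, "+", "C",
                                nC=depth - nT, nT=nT)]
                )
            )
        reps[genotype] = frames
    return GenotypeSeries(replicates=reps)


class TestInducedCaller:
    def test_planted_pattern_called(self):
        series = constant_series(2.0, 50.0, 95.0)
        result = call_induced_events(series, GENOME)
        assert [c.site for c in result.calls] == [("g", 3, "+")]
        call = result.calls[0]
        assert call.mean_low == pytest.approx(2.0)
        assert call.mean_over == pytest.approx(95.0)

    def test_missing_in_one_over_replicate_not_called(self):
        series = constant_series(2.0, 50.0, 95.0)
        # knock one over_expr replicate below the detection threshold
        df = series.replicates["over_expr"][1]
        df.loc[0, "nT"] = 5
        df.loc[0, "nC"] = 995
        result = call_induced_events(series, GENOME)
        assert result.calls == []

    def test_control_above_over_not_called(self):
        series = constant_series(2.0, 96.0, 95.0)
        assert call_induced_events(series, GENOME).calls == []

    def test_low_above_control_not_called(self):
        series = constant_series(60.0, 50.0, 95.0)
        assert call_induced_events(series, GENOME).calls == []

    def test_equal_true_fractions_not_called_without_noise(self):
        """With replicate means replaced by exact fractions the ordering
        control < over is an equality and the call vanishes."""
        series = constant_series(50.0, 50.0, 50.0)
        assert call_induced_events(series, GENOME).calls == []

    def test_homopolymer_site_flagged_not_called(self):
        genome = {"g": "AATTCTTAA"}
        series = constant_series(2.0, 50.0, 95.0, position=5, genome=genome)
        result = call_induced_events(series, genome)
        assert result.calls == []
        assert result.flagged == [("g", 5, "+")]

    def test_wrong_replicate_count_rejected(self):
        series = constant_series(2.0, 50.0, 95.0)
        series.replicates["over_expr"].pop()
        with pytest.raises(InputError):
            call_induced_events(series, GENOME)

    def test_end_to_end_synthetic_study(self):
        """Full simulator: the planted site is called, decoys are excluded."""
        table = example_code_table()
        from conftest import random_array

        arr = random_array(np.random.default_rng(0), table, 8, "E2E")
        cfg = SimConfig(rng_seed=42, genome_length=2000, depth=1000)
        study = simulate_study(arr, table, cfg)
        gmap = {
            f"{g}_rep{r}": g
            for g in ("low_expr", "control", "over_expr")
            for r in (1, 2, 3)
        }
        series = GenotypeSeries.from_pileups(study.pileups, gmap)
        result = call_induced_events(series, study.genome)
        assert [c.site for c in result.calls] == [
            ("ChrC", study.target["position"], study.target["strand"])
        ]
        assert {(p, s) for _, p, s in result.flagged} == set(study.decoys)


class TestQuantifyKnownSites:
    def make_pileups(self):
        rows = []
        for sample, frac in (("a_rep1", 10), ("a_rep2", 20), ("a_rep3", 30)):
            rows.append(
                pileup_row(sample, "g", 3, "+", "C", nC=100 - frac, nT=frac)
            )
        return pileup_frame(rows)

    def test_mean_and_se(self):
        per_rep, summary = quantify_known_sites(
            self.make_pileups(), [("site1", "g", 3, "+")]
        )
        row = summary.iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["se"] == pytest.approx(5.7735, abs=1e-4)

    def test_single_replicate_se_is_missing(self):
        pile = pileup_frame([pileup_row("only", "g", 3, "+", "C", nC=90, nT=10)])
        _, summary = quantify_known_sites(pile, [("site1", "g", 3, "+")])
        assert summary.iloc[0]["mean"] == pytest.approx(10.0)
        assert math.isnan(summary.iloc[0]["se"])

    def test_uncovered_site_reported_missing(self):
        per_rep, summary = quantify_known_sites(
            self.make_pileups(), [("ghost", "g", 4, "+")]
        )
        assert len(per_rep) == 3
        assert per_rep["fraction_percent"].isna().all()
        assert summary.iloc[0]["n"] == 0

    def test_genotype_grouping(self):
        rows = [
            pileup_row("a_rep1", "g", 3, "+", "C", nC=90, nT=10),
            pileup_row("b_rep1", "g", 3, "+", "C", nC=50, nT=50),
        ]
        _, summary = quantify_known_sites(
            pileup_frame(rows),
            [("s", "g", 3, "+")],
            genotype_map={"a_rep1": "low", "b_rep1": "high"},
        )
        by_geno = summary.set_index("genotype")["mean"]
        assert by_geno["low"] == pytest.approx(10.0)
        assert by_geno["high"] == pytest.approx(50.0)


@pytest.mark.parametrize("seed", [0, 1])
def test_fraction_recovery_within_binomial_error(seed):
    """Fractions measured from simulated pileups land within 3 binomial SEs
    of the planted truth for >= 99% of sites."""
    from chloroedit.synthetic_data import PlantedSite, simulate_pileups

    rng = np.random.default_rng(seed)
    n_sites, depth = 300, 1000
    genome = {"g": "TC" * n_sites}
    p = rng.uniform(0.05, 0.95, size=n_sites)
    planted = [
        PlantedSite(2 * i + 2, "+", {g: p[i] for g in ("low_expr", "control", "over_expr")})
        for i in range(n_sites)
    ]
    cfg = SimConfig(
        rng_seed=seed + 10, genome_length=2 * n_sites, depth=depth,
        seq_error_rate=0.0, replicates=1, strands=("+",),
    )
    pile = simulate_pileups(genome, cfg, planted)
    one = pile[pile["sample_id"] == "control_rep1"].set_index("position")
    est = np.array(
        [
            editing_fraction(int(one.loc[2 * i + 2, "nT"]), int(one.loc[2 * i + 2, "nC"])) / 100
            for i in range(n_sites)
        ]
    )
    se = np.sqrt(p * (1 - p) / depth)
    assert (np.abs(est - p) <= 3 * se).mean() >= 0.99
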