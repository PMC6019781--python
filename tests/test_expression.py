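"""RPKM over the curated gene set, qPCR normalization, annotation arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from chloroedit.errors import ConfigError, CoordinateError, InputError
from chloroedit.expression import (
    GeneRecord,
    QpcrMeasurement,
    build_modified_annotation,
    gene_records_from_gff,
    pair_editing_expression,
    qpcr_normalized_expression,
    rpkm,
    rpkm_table,
    select_gene_set,
)
from chloroedit.synthetic_data import gen_genome


class TestRpkm:
    def test_hand_arithmetic(self):
        assert rpkm(100, 1e6, 1000) == pytest.approx(100.0)

    def test_zero_reads(self):
        assert rpkm(0, 1e6, 1000) == 0.0

    def test_zero_ti_rejected(self):
        with pytest.raises(InputError):
            rpkm(10, 0, 1000)

    def test_homogeneity(self):
        base = rpkm(100, 1e6, 1000)
        assert rpkm(200, 1e6, 1000) == pytest.approx(2 * base)
        assert rpkm(100, 2e6, 1000) == pytest.approx(base / 2)
        assert rpkm(100, 1e6, 2000) == pytest.approx(base / 2)

    def test_conservation_over_full_gene_set(self):
        """If the counted set accounts for all Ti reads,
        sum(rpkm * L * Ti / 1e9) returns Ti."""
        rng = np.random.default_rng(0)
        genes = [
            GeneRecord(f"g{i}", "ChrC", 1 + 10 * i, 10 + 10 * i, "+", "mRNA",
                       length=int(rng.integers(200, 3000)))
            for i in range(8)
        ]
        reads = rng.integers(0, 10000, size=8)
        counts = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes], "sample_id": "s", "reads": reads}
        )
        table = rpkm_table(counts, genes)
        ti = float(reads.sum())
        lengths = {g.gene_id: g.length for g in genes}
        total = sum(
            r["rpkm"] * lengths[r["gene_id"]] * ti / 1e9 for _, r in table.iterrows()
        )
        assert total == pytest.approx(ti, rel=1e-9)


class TestQpcr:
    def test_symmetric_cancellation(self):
        m = QpcrMeasurement("s", 30, 1.0, 30, 1.0)
        assert qpcr_normalized_expression(m) == 1.0

    def test_delta_cq_with_perfect_efficiency(self):
        m = QpcrMeasurement("s", 30, 1.0, 32, 1.0)
        assert qpcr_normalized_expression(m) == pytest.approx(4.0)

    def test_zero_efficiency_is_unity(self):
        m = QpcrMeasurement("s", 10, 0.0, 33, 0.0)
        assert qpcr_normalized_expression(m) == 1.0

    def test_identical_target_and_reference_exact_one(self):
        m = QpcrMeasurement("s", 27.3, 0.93, 27.3, 0.93)
        assert qpcr_normalized_expression(m) == 1.0

    def test_efficiency_below_minus_one_rejected(self):
        with pytest.raises(InputError):
            QpcrMeasurement("s", 30, -1.5, 30, 1.0)

    def test_cq_above_max_cycles_warns(self):
        with pytest.warns(UserWarning):
            QpcrMeasurement("s", 36.0, 1.0, 30.0, 1.0)


class TestModifiedAnnotation:
    def test_printed_intervals_on_full_length_record(self):
        """On a 154,478-bp plastid record the emitted intervals match the
        documented mapping coordinates exactly."""
        genome = gen_genome(154478, seed=0)
        mod = build_modified_annotation(genome, ycf3_intron=(43752, 44465))
        assert mod.construct_interval == (154479, 156997)
        assert mod.intron1_interval == (154653, 156142)
        assert mod.intron2_interval == (156375, 156911)
        assert mod.ycf3_intron_interval == (43753, 44466)

    def test_interval_lengths(self):
        genome = gen_genome(154478, seed=0)
        mod = build_modified_annotation(genome, ycf3_intron=(43752, 44465))
        a, b = mod.construct_interval
        assert b - a + 1 == 2519
        a, b = mod.intron1_interval
        assert b - a + 1 == 1490
        a, b = mod.ycf3_intron_interval
        assert b - a + 1 == 714

    def test_genome_extended_by_construct(self):
        genome = gen_genome(1000, seed=1)
        construct = "A" * 300
        mod = build_modified_annotation(
            genome, construct_seq=construct, construct_length=300,
            intron1_rel=(50, 100), intron2_rel=(150, 200),
        )
        assert len(mod.genome["ChrC"]) == 1300
        assert mod.construct_interval == (1001, 1300)
        assert mod.intron1_interval == (1050, 1100)

    def test_gff3_lines_reproduce_intervals(self, tmp_path):
        genome = gen_genome(154478, seed=0)
        mod = build_modified_annotation(genome, ycf3_intron=(43752, 44465))
        out = tmp_path / "mod.gff3"
        mod.write_gff3(out)
        text = out.read_text()
        for lo, hi in (
            (154479, 156997), (154653, 156142), (156375, 156911), (43753, 44466),
        ):
            assert f"\t{lo}\t{hi}\t" in text

    def test_wrong_construct_length_rejected(self):
        genome = gen_genome(1000, seed=1)
        with pytest.raises(CoordinateError):
            build_modified_annotation(genome, construct_seq="A" * 10, construct_length=300)

    def test_intron_outside_construct_rejected(self):
        genome = gen_genome(1000, seed=1)
        with pytest.raises(CoordinateError):
            build_modified_annotation(
                genome, construct_seq="A" * 100, construct_length=100,
                intron1_rel=(50, 150), intron2_rel=(160, 170),
            )


def make_genes():
    genes = []
    for i in range(5):
        genes.append(GeneRecord(f"m{i}", "ChrC", 1000 * i + 1, 1000 * i + 500, "+", "mRNA", 500))
    for i in range(2):
        genes.append(GeneRecord(f"r{i}", "ChrC", 6000 + 1000 * i, 6400 + 1000 * i, "+", "rRNA", 400))
    for i in range(3):
        genes.append(GeneRecord(f"t{i}", "ChrC", 9000 + 100 * i, 9070 + 100 * i, "+", "tRNA", 70))
    return genes


class TestSelectGeneSet:
    def test_biotype_exclusions(self):
        kept = select_gene_set(make_genes())
        assert sorted(g.gene_id for g in kept) == [f"m{i}" for i in range(5)]

    def test_ir_copy_dedup(self):
        genes = [
            GeneRecord("dup_A", "ChrC", 100, 200, "+", "mRNA", 101),
            GeneRecord("dup_B", "ChrC", 5100, 5200, "-", "mRNA", 101),
        ]
        ir = {"IRA": ("ChrC", 50, 300), "IRB": ("ChrC", 5000, 5300)}
        kept = select_gene_set(genes, ir_regions=ir, exclude_ir="IRB")
        assert [g.gene_id for g in kept] == ["dup_A"]

    def test_missing_ir_designation_warns_and_keeps(self, caplog):
        with caplog.at_level("WARNING"):
            kept = select_gene_set(make_genes()[:5])
        assert len(kept) == 5
        assert any("IR filtering skipped" in r.message for r in caplog.records)

    def test_both_copies_excluded_is_config_error(self):
        ir = {"IRA": ("ChrC", 1, 10), "IRB": ("ChrC", 20, 30)}
        with pytest.raises(ConfigError):
            select_gene_set(make_genes(), ir_regions=ir, exclude_ir=["IRA", "IRB"])

    def test_original_rps12_exons_excluded_by_id(self):
        genes = make_genes() + [
            GeneRecord("rps12", "ChrC", 70000, 71000, "-", "mRNA", 600),
            GeneRecord("rps12_concat", "ChrC", 154479, 156997, "+", "mRNA", 2519),
        ]
        kept = select_gene_set(genes, exclude_gene_ids=["rps12"])
        ids = {g.gene_id for g in kept}
        assert "rps12" not in ids and "rps12_concat" in ids


GFF_TEXT = """##gff-version 3
ChrC\tsrc\tgene\t101\t800\t.\t+\t.\tID=geneA
ChrC\tsrc\tmRNA\t101\t800\t.\t+\t.\tID=geneA.1;Parent=geneA
ChrC\tsrc\texon\t101\t300\t.\t+\t.\tID=geneA.e1;Parent=geneA.1
ChrC\tsrc\texon\t501\t800\t.\t+\t.\tID=geneA.e2;Parent=geneA.1
ChrC\tsrc\tgene\t1001\t1200\t.\t-\t.\tID=geneB
ChrC\tsrc\trRNA\t1001\t1200\t.\t-\t.\tID=geneB.1;Parent=geneB
ChrC\tsrc\texon\t1001\t1200\t.\t-\t.\tID=geneB.e1;Parent=geneB.1
"""


class TestGeneRecordsFromGff:
    def test_exon_union_length(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_TEXT)
        recs = {g.gene_id: g for g in gene_records_from_gff(p)}
        assert recs["geneA"].length == 200 + 300
        assert recs["geneA"].biotype == "mRNA"
        assert recs["geneB"].biotype == "rRNA"

    def test_locus_span_flag(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_TEXT)
        recs = {g.gene_id: g for g in gene_records_from_gff(p, locus_span=True)}
        assert recs["geneA"].length == 700


class TestPairEditingExpression:
    def make_inputs(self):
        editing = pd.DataFrame(
            {
                "line_id": ["L1"] * 3 + ["L2"] * 3 + ["L3"] * 3,
                "editing_percent": [10, 20, 30, 40, 50, 60, 70, 80, 90],
            }
        )
        expression = pd.DataFrame(
            {
                "line_id": ["L1"] * 3 + ["L2"] * 3 + ["L3"] * 3,
                "expression": [1, 2, 3, 4, 5, 6, 7, 8, 9],
            }
        )
        return editing, expression

    def test_three_lines_three_replicates(self):
        editing, expression = self.make_inputs()
        paired = pair_editing_expression(editing, expression)
        assert len(paired) == 3
        row = paired.set_index("line_id").loc["L1"]
        assert row["editing_mean"] == pytest.approx(20.0)
        assert row["editing_se"] == pytest.approx(10 / math.sqrt(3))
        assert row["expression_se"] == pytest.approx(1 / math.sqrt(3))

    def test_single_replicate_se_missing(self):
        editing = pd.DataFrame({"line_id": ["L1"], "editing_percent": [50.0]})
        expression = pd.DataFrame({"line_id": ["L1"], "expression": [2.0]})
        paired = pair_editing_expression(editing, expression)
        assert math.isnan(paired.iloc[0]["editing_se"])

    def test_unmatched_lines_dropped_with_warning(self):
        editing, expression = self.make_inputs()
        expression = expression[expression["line_id"] != "L3"]
        with pytest.warns(UserWarning, match="L3"):
            paired = pair_editing_expression(editing, expression)
        assert sorted(paired["line_id"]) == ["L1", "L2"]

    def test_disjoint_lines_rejected(self):
        editing, expression = self.make_inputs()
        expression = expression.assign(line_id="X")
        with pytest.raises(InputError):
            pair_editing_expression(editing, expression)
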