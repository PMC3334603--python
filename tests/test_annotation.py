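"""Gene/repeat readers, chromosome filters, regions, orientation classes."""

import pytest

from aluhsf.annotation import (
    AluElement,
    GeneModel,
    assign_alu_orientation,
    assign_alus_to_regions,
    extract_regions,
    load_alus,
    load_gene_models,
)
from aluhsf.io import write_bed6, write_repeatmasker_out


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadGeneModels:
    def test_ambiguous_chromosomes_filtered(self, tmp_path):
        bed = _write(
            tmp_path,
            "g.bed",
            "chr1\t100\t200\tgeneA\t0\t+\n"
            "chr1_random\t100\t200\tgeneB\t0\t+\n"
            "chr6_hap2\t100\t200\tgeneC\t0\t-\n"
            "chr2\t300\t900\tgeneD\t0\t-\n",
        )
        genes = load_gene_models(bed)
        assert [g.gene_id for g in genes] == ["geneA", "geneD"]

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert load_gene_models(_write(tmp_path, "e.bed", "")) == []

    def test_duplicate_gene_id_rejected(self, tmp_path):
        bed = _write(
            tmp_path, "d.bed",
            "chr1\t1\t10\tg\t0\t+\nchr2\t1\t10\tg\t0\t+\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_gene_models(bed)

    def test_unparseable_row_reports_line_number(self, tmp_path):
        bed = _write(tmp_path, "b.bed", "chr1\t1\t10\tg\t0\t+\nchr2\tnotanumber\n")
        with pytest.raises(ValueError, match=":2"):
            load_gene_models(bed)

    def test_refflat_dialect_and_class_table(self, tmp_path):
        flat = _write(
            tmp_path, "g.txt",
            "geneA\tNM_1\tchr1\t+\t1000\t5000\t1000\t5000\t1\t1000,\t5000,\n",
        )
        genes = load_gene_models(flat, class_table={"geneA": "down"})
        assert genes[0].strand == "+"
        assert genes[0].tx_start == 1000
        assert genes[0].expression_class == "down"

    def test_unlisted_gene_defaults_to_unchanged(self, tmp_path):
        bed = _write(tmp_path, "g.bed", "chr1\t1\t10\tg\t0\t+\n")
        assert load_gene_models(bed, class_table={})[0].expression_class == "unchanged"


class TestExtractRegions:
    def test_plus_strand_definition(self):
        g = GeneModel("g", "c", "+", 10000, 20000)
        up, genic = extract_regions(g, contig_len=30000)
        assert (up.start, up.end) == (5000, 10000)
        assert (genic.start, genic.end) == (10000, 20000)

    def test_minus_strand_mirror(self):
        g = GeneModel("g", "c", "-", 10000, 20000)
        up, _ = extract_regions(g, contig_len=30000)
        assert (up.start, up.end) == (20000, 25000)

    def test_truncation_at_contig_edge(self):
        g = GeneModel("g", "c", "+", 2000, 9000)
        up, _ = extract_regions(g, contig_len=30000)
        assert (up.start, up.end) == (0, 2000)
        assert up.length == 2000


class TestLoadAlus:
    RM = (
        "   SW  perc ...\nscore  div. ...\n\n"
        "  225  10.0  0.0  0.0  chr1  101  400  (0)  +  AluYa5  SINE/Alu  1  300  (0)  1\n"
        "  200  12.0  0.0  0.0  chr1  900  1100  (0)  C  AluSx  SINE/Alu  1  200  (0)  2\n"
        "  180  15.0  0.0  0.0  chr1  2000  2500  (0)  +  L1PA3  LINE/L1  1  500  (0)  3\n"
    )

    def test_out_coordinates_converted_to_half_open(self, tmp_path):
        alus = load_alus(_write(tmp_path, "a.out", self.RM), "repeatmasker_out")
        assert (alus[0].start, alus[0].end) == (100, 400)

    def test_out_c_orientation_becomes_minus(self, tmp_path):
        alus = load_alus(_write(tmp_path, "a.out", self.RM), "repeatmasker_out")
        assert alus[1].strand == "-"

    def test_non_alu_families_excluded(self, tmp_path):
        alus = load_alus(_write(tmp_path, "a.out", self.RM), "repeatmasker_out")
        assert all(a.subfamily.startswith("Alu") for a in alus)
        bed = _write(tmp_path, "a.bed", "chr1\t0\t300\tL1PA3\t0\t+\n")
        assert load_alus(bed, "bed6") == []

    def test_flam_kept_only_with_flag(self, tmp_path):
        bed = _write(tmp_path, "f.bed", "chr1\t0\t120\tFLAM_C\t0\t+\n")
        assert load_alus(bed, "bed6") == []
        assert len(load_alus(bed, "bed6", include_flam_fram=True)) == 1

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            load_alus(_write(tmp_path, "x.bed", ""), "gff3")

    def test_roundtrip_both_dialects(self, tmp_path):
        original = [
            AluElement("alu000001", "chr1", 50, 350, "+", "AluYa5"),
            AluElement("alu000002", "chr2", 700, 980, "-", "AluSx"),
        ]
        bed, out = tmp_path / "rt.bed", tmp_path / "rt.out"
        write_bed6(original, bed)
        write_repeatmasker_out(original, out)
        for path, dialect in ((bed, "bed6"), (out, "repeatmasker_out")):
            back = load_alus(path, dialect)
            assert [(a.chrom, a.start, a.end, a.strand, a.subfamily) for a in back] == [
                (a.chrom, a.start, a.end, a.strand, a.subfamily) for a in original
            ]


class TestOrientation:
    @pytest.mark.parametrize(
        "alu_strand,gene_strand,expected",
        [("+", "+", "sense"), ("-", "-", "sense"), ("+", "-", "antisense"), ("-", "+", "antisense")],
    )
    def test_strand_comparison(self, alu_strand, gene_strand, expected):
        alu = AluElement("a", "c", 0, 300, alu_strand, "AluY")
        gene = GeneModel("g", "c", gene_strand, 0, 1000)
        assert assign_alu_orientation(alu, gene) == expected

    def test_undefined_strand_rejected(self):
        alu = AluElement("a", "c", 0, 300, ".", "AluY")
        gene = GeneModel("g", "c", "+", 0, 1000)
        with pytest.raises(ValueError, match="strand"):
            assign_alu_orientation(alu, gene)


class TestAssignAlusToRegions:
    def test_midpoint_rule_and_partition(self):
        gene = GeneModel("g", "c", "+", 10000, 20000, "down")
        up, genic = extract_regions(gene, contig_len=30000)
        alus = [
            AluElement("a1", "c", 9900, 10200, "+", "AluY"),   # midpoint 10050 -> genic
            AluElement("a2", "c", 9700, 10000, "-", "AluY"),   # midpoint 9850 -> upstream
            AluElement("a3", "c", 25000, 25300, "+", "AluY"),  # outside both
        ]
        hosted = assign_alus_to_regions(alus, {"g": gene}, [up, genic])
        by_id = {a.alu_id: a for a in hosted}
        assert by_id["a1"].region_kind == "genic"
        assert by_id["a2"].region_kind == "upstream5kb"
        assert "a3" not in by_id
        # sense/antisense partition the hosted set
        sense = {a.alu_id for a in hosted if a.orientation_class == "sense"}
        anti = {a.alu_id for a in hosted if a.orientation_class == "antisense"}
        assert sense | anti == set(by_id) and not sense & anti

    def test_alu_shared_by_two_genes_duplicated(self):
        g1 = GeneModel("g1", "c", "+", 0, 10000)
        g2 = GeneModel("g2", "c", "-", 8000, 18000)
        regions = list(extract_regions(g1, 40000)) + list(extract_regions(g2, 40000))
        alu = AluElement("a", "c", 8800, 9100, "+", "AluY")
        hosted = assign_alus_to_regions([alu], {"g1": g1, "g2": g2}, regions)
        hosts = sorted((a.host_gene, a.orientation_class) for a in hosted)
        assert hosts == [("g1", "sense"), ("g2", "antisense")]
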