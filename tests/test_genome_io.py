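"""Parsing, writing and genome-level statistics."""

import logging

import pytest

import linchrom as lc
from linchrom.io import _parse_gff3


def write_text(path, text):
    path.write_text(text)
    return path


class TestFasta:
    def test_parse_two_records(self, tmp_path):
        path = write_text(tmp_path / "a.fasta", ">one\n" + "A" * 100 + "\n>two\n" + "C" * 200 + "\n")
        chroms = lc.parse_fasta(path)
        assert [(c.id, c.length) for c in chroms] == [("one", 100), ("two", 200)]

    def test_lowercase_normalized(self, tmp_path):
        path = write_text(tmp_path / "a.fasta", ">x\nacgt\n")
        assert lc.parse_fasta(path)[0].seq == "ACGT"

    def test_ambiguity_codes_become_n(self, tmp_path, caplog):
        path = write_text(tmp_path / "a.fasta", ">x\nACGRT\n")
        with caplog.at_level(logging.WARNING, logger="linchrom.io"):
            chroms = lc.parse_fasta(path)
        assert chroms[0].seq == "ACGNT"
        assert any("replaced by N" in r.message for r in caplog.records)

    def test_empty_file_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA records"):
            lc.parse_fasta(write_text(tmp_path / "e.fasta", ""))

    def test_duplicate_ids_are_error(self, tmp_path):
        path = write_text(tmp_path / "d.fasta", ">x\nAC\n>x\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            lc.parse_fasta(path)

    def test_round_trip(self, tmp_path):
        cfg = lc.SynthConfig(L=5_000, n_core=0, seed=1)
        chrom, _, _ = lc.generate_chromosome(cfg)
        out = tmp_path / "rt.fasta"
        lc.write_fasta([chrom], out)
        back = lc.parse_fasta(out)
        assert back[0].id == chrom.id and back[0].seq == chrom.seq


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        path = write_text(
            tmp_path / "a.gff3",
            "##gff-version 3\nchr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n",
        )
        (rec,) = lc.parse_feature_table(path, "gff3")
        assert (rec.start, rec.end) == (0, 100)

    def test_write_parse_involution_on_text(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\tlinchrom\tgene\t5\t250\t.\t-\t.\tID=dnaA\n"
            "chr1\tlinchrom\tprotocluster\t300\t900\t.\t+\t.\tID=p1;category=PKS\n"
        )
        path = write_text(tmp_path / "x.gff3", text)
        features = lc.parse_feature_table(path, "gff3")
        out = tmp_path / "y.gff3"
        lc.write_gff3(features, out)
        assert out.read_text() == text

    def test_records_round_trip(self, tmp_path):
        features = [
            lc.FeatureRecord("chr1", "core_gene", "m1", 10, 40, "-", qualifiers={"status": "Complete"}),
            lc.FeatureRecord("chr1", "protocluster", "p1", 100, 900, "+", category="NRPS"),
        ]
        path = tmp_path / "rt.gff3"
        lc.write_gff3(features, path)
        assert _parse_gff3(path) == features

    def test_reversed_interval_is_error(self, tmp_path):
        path = write_text(tmp_path / "bad.gff3", "chr1\tsrc\tgene\t100\t1\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError, match="start 100 > end 1"):
            lc.parse_feature_table(path, "gff3")


BUSCO_TEXT = """# BUSCO version is: 5.1.2
# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength
1at2\tComplete\tchr1\t1\t100\t+\t500.0\t99
2at2\tDuplicated\tchr1\t200\t300\t-\t400.0\t99
2at2\tDuplicated\tchr1\t5000\t5100\t+\t390.0\t99
3at2\tMissing
334658at1760\tFragmented\tchr1\t900\t950\t+\t50.0\t40
"""


class TestBusco:
    def test_status_rules(self, tmp_path):
        path = write_text(tmp_path / "full_table.tsv", BUSCO_TEXT)
        records = lc.parse_feature_table(path, "busco_tsv")
        by_model = {}
        for r in records:
            by_model.setdefault(r.model_id, []).append(r)
        assert "3at2" not in by_model  # Missing skipped
        assert len(by_model["2at2"]) == 2  # Duplicated rows all retained
        assert by_model["334658at1760"][0].qualifiers["fragmented"] == "true"
        assert (by_model["1at2"][0].start, by_model["1at2"][0].end) == (0, 100)

    def test_reversed_interval_names_row(self, tmp_path):
        path = write_text(tmp_path / "bad.tsv", "9at2\tComplete\tchr1\t50\t10\t+\t1.0\t40\n")
        with pytest.raises(ValueError, match="9at2"):
            lc.parse_feature_table(path, "busco_tsv")

    def test_unknown_format_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="unknown feature table format"):
            lc.parse_feature_table(tmp_path / "x", "bed")


class TestAntismash:
    def test_hybrid_region_yields_one_record_per_protocluster(self, hybrid_genbank):
        records = lc.parse_antismash_protoclusters(hybrid_genbank)
        assert len(records) == 2
        assert sorted(r.category for r in records) == ["NRPS", "PKS"]
        assert all(r.qualifiers["region"] == "1" for r in records)

    def test_no_protoclusters_yields_empty_list(self, tmp_path):
        from conftest import make_antismash_genbank

        path = make_antismash_genbank(tmp_path / "empty.gbk", [])
        assert lc.parse_antismash_protoclusters(path) == []

    def test_disjoint_coordinates_preserved(self, disjoint_genbank):
        records = lc.parse_antismash_protoclusters(disjoint_genbank)
        assert [(r.start, r.end) for r in records] == [(1_000, 9_000), (15_000, 24_000), (30_000, 55_000)]
        assert [r.category for r in records] == ["terpene", "RiPP", "PKS"]

    def test_count_matches_independent_text_scan(self, disjoint_genbank):
        n_text = sum(
            1
            for line in open(disjoint_genbank)
            if line.strip().startswith("protocluster") and ".." in line
        )
        assert len(lc.parse_antismash_protoclusters(disjoint_genbank)) == n_text == 3

    def test_missing_product_is_error(self, tmp_path):
        from conftest import make_antismash_genbank
        from Bio import SeqIO

        path = make_antismash_genbank(tmp_path / "x.gbk", [(10, 500, "T1PKS", "PKS")], length=1_000)
        rec = next(SeqIO.parse(str(path), "genbank"))
        for f in rec.features:
            f.qualifiers.pop("product", None)
        SeqIO.write([rec], str(path), "genbank")
        with pytest.raises(ValueError, match="product"):
            lc.parse_antismash_protoclusters(path)


@pytest.mark.parametrize(
    "level,n_contigs,expected",
    [
        ("chromosome", 3, "HQ"),
        ("complete", 1, "HQ"),
        ("contig", 100, "MQ"),
        ("contig", 101, "LQ"),
        ("scaffold", 1, "MQ"),
    ],
)
def test_assembly_quality_class(level, n_contigs, expected):
    contigs = [lc.LinearChromosome(f"c{i}", "ACGT") for i in range(n_contigs)]
    assert lc.assembly_quality_class(lc.AssemblyRecord("g", contigs, level)) == expected


@pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATGC", 0.5), ("ANGC", 2 / 3)])
def test_gc_content(seq, expected):
    assert lc.gc_content(lc.LinearChromosome("x", seq)) == pytest.approx(expected)


def test_gc_content_all_n_is_error():
    with pytest.raises(ValueError, match="no unambiguous"):
        lc.gc_content(lc.LinearChromosome("x", "NNNN"))


def test_assembly_requires_unique_contig_ids():
    with pytest.raises(ValueError, match="unique"):
        lc.AssemblyRecord("g", [lc.LinearChromosome("c", "AC"), lc.LinearChromosome("c", "GT")], "contig")
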