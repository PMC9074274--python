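"""Gene records, completeness classification, and file round-trips."""

import pytest

from mixcat.records import (
    AnnotationTable,
    Completeness,
    GeneRecord,
    Read,
    ReadSet,
    Source,
    classify_completeness,
)
from mixcat import io as mio


class TestCompleteness:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("00", Completeness.COMPLETE),
            ("01", Completeness.PARTIAL),
            ("10", Completeness.PARTIAL),
            ("11", Completeness.INCOMPLETE),
        ],
    )
    def test_code_mapping(self, code, expected):
        assert classify_completeness(code) == expected

    @pytest.mark.parametrize("bad", ["", "0", "000", "12", "ab", "0 "])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_completeness(bad)

    def test_classification_partitions_any_gene_set(self):
        codes = ["00", "01", "10", "11"] * 7 + ["00", "11"]
        classes = [classify_completeness(c) for c in codes]
        counts = {c: classes.count(c) for c in Completeness}
        assert sum(counts.values()) == len(codes)


class TestGeneRecord:
    def test_coordinate_validation(self):
        with pytest.raises(ValueError):
            GeneRecord(gene_id="g", start=10, end=5)
        with pytest.raises(ValueError):
            GeneRecord(gene_id="g", nt_seq="ATGAAA", start=1, end=9)
        rec = GeneRecord(gene_id="g", nt_seq="ATGAAATAA", start=1, end=9)
        assert rec.nt_length == 9

    def test_invalid_partial_code_rejected(self):
        with pytest.raises(ValueError):
            GeneRecord(gene_id="g", partial_code="02")

    def test_individual_source_requires_sample(self):
        with pytest.raises(ValueError):
            GeneRecord(gene_id="g", source=Source.INDIVIDUAL)


class TestFastaGff:
    def test_prodigal_header_parsing(self, tmp_path):
        fasta = tmp_path / "genes.fna"
        fasta.write_text(
            ">g1 # 1 # 9 # 1 # ID=1_1;partial=00;start_type=ATG\nATGAAATAA\n"
            ">g2 # 5 # 13 # -1 # ID=1_2;partial=10\nATGCCCTAA\n"
        )
        records = mio.read_genes(fasta)
        by_id = {r.gene_id: r for r in records}
        assert by_id["g1"].partial_code == "00"
        assert by_id["g1"].completeness == Completeness.COMPLETE
        assert by_id["g1"].start == 1 and by_id["g1"].end == 9
        assert by_id["g2"].completeness == Completeness.PARTIAL
        assert by_id["g2"].strand == "-"

    def test_empty_file_gives_empty_list(self, tmp_path):
        fasta = tmp_path / "empty.fna"
        fasta.write_text("")
        assert mio.read_genes(fasta) == []

    def test_duplicate_ids_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fna"
        fasta.write_text(">g partial=00\nATG\n>g partial=00\nATG\n")
        with pytest.raises(ValueError, match="duplicate"):
            mio.read_genes(fasta)

    def test_missing_partial_code_requires_default(self, tmp_path):
        fasta = tmp_path / "nocode.fna"
        fasta.write_text(">g1\nATGAAATAA\n")
        with pytest.raises(ValueError, match="partial"):
            mio.read_genes(fasta)
        records = mio.read_genes(fasta, default_partial="00")
        assert records[0].partial_code == "00"

    def test_gff_takes_precedence_but_conflict_is_an_error(self, tmp_path):
        fasta = tmp_path / "genes.fna"
        gff = tmp_path / "genes.gff"
        fasta.write_text(">g1 partial=01\nATGAAATAA\n")
        gff.write_text(
            "##gff-version 3\n"
            "contig1\tprodigal\tCDS\t1\t9\t.\t+\t0\tID=g1;partial=10\n"
        )
        with pytest.raises(ValueError, match="conflict"):
            mio.read_genes(fasta, gff)
        gff.write_text(
            "##gff-version 3\n"
            "contig1\tprodigal\tCDS\t1\t9\t.\t+\t0\tID=g1;partial=01\n"
        )
        records = mio.read_genes(fasta, gff)
        assert records[0].partial_code == "01"
        assert records[0].contig_id == "contig1"

    def test_round_trip_preserves_sequence_coordinates_and_codes(self, tmp_path):
        records = [
            GeneRecord(
                gene_id=f"g{i}",
                nt_seq="ATG" + "AAA" * (i + 2) + "TAA",
                aa_seq="M" + "K" * (i + 2),
                contig_id=f"c{i}",
                start=1,
                end=3 * (i + 4),
                strand="+" if i % 2 else "-",
                partial_code=code,
            )
            for i, code in enumerate(["00", "01", "10", "11"])
        ]
        fasta, gff = tmp_path / "rt.fna", tmp_path / "rt.gff"
        mio.write_genes_fasta(records, fasta, kind="nt")
        mio.write_gff(records, gff)
        back = mio.read_genes(fasta, gff)
        assert [r.gene_id for r in back] == [r.gene_id for r in records]
        for orig, new in zip(records, back):
            assert new.nt_seq == orig.nt_seq
            assert new.partial_code == orig.partial_code
            assert (new.start, new.end, new.strand) == (
                orig.start,
                orig.end,
                orig.strand,
            )

    def test_protein_fasta_uppercased_and_stops_stripped(self, tmp_path):
        fasta = tmp_path / "prot.faa"
        fasta.write_text(">p1 partial=00\nmklvw*\n")
        records = mio.read_genes(fasta)
        assert records[0].aa_seq == "MKLVW"


class TestAnnotationTable:
    def test_round_trip(self, tmp_path):
        table = AnnotationTable(
            {
                "g1": [("Pfam", "PF00001"), ("Pfam", "PF00002"), ("EggNOG", "COG1")],
                "g2": [("dbCAN", "GH5")],
            }
        )
        path = tmp_path / "ann.tsv"
        mio.write_annotation_table(table, path)
        assert mio.read_annotation_table(path) == table

    def test_toy_table(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text("g1\tPfam\tPF00001\ng2\tEggNOG\tCOG123\n")
        table = mio.read_annotation_table(path)
        assert table.gene_ids() == {"g1", "g2"}

    def test_unknown_database_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("g1\tKEGG\tK00001\n")
        with pytest.raises(ValueError, match="database"):
            mio.read_annotation_table(path)

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("g1\tPfam\n")
        with pytest.raises(ValueError):
            mio.read_annotation_table(path)


class TestReadsAndIdLists:
    def test_fastq_round_trip_with_mates(self, tmp_path):
        rs = ReadSet(
            sample_id="s0",
            reads=[Read("r1", "ACGT", 1), Read("r1", "TTGG", 2), Read("r2", "GGCC", 1)],
        )
        path = tmp_path / "reads.fastq"
        mio.write_reads(rs, path)
        back = mio.read_reads(path, "s0")
        assert [(r.read_id, r.sequence, r.mate) for r in back.reads] == [
            (r.read_id, r.sequence, r.mate) for r in rs.reads
        ]

    def test_id_list_round_trip(self, tmp_path):
        path = tmp_path / "ids.txt"
        mio.write_id_list({"b", "a"}, path)
        assert mio.read_id_list(path) == {"a", "b"}

    def test_duplicate_read_ids_rejected(self):
        with pytest.raises(ValueError):
            ReadSet(sample_id="s", reads=[Read("r", "AC", 1), Read("r", "GG", 1)])

    def test_mean_read_pair_length_single_end_doubles(self):
        rs = ReadSet(sample_id="s", reads=[Read("r1", "A" * 100, 1)])
        assert rs.mean_read_pair_length() == 200.0


class TestCatalogueRoundTrip:
    def test_write_then_read_identical_records(self, tmp_path):
        from mixcat.catalogue import Catalogue
        from mixcat.io import read_catalogue, write_catalogue

        reps = [
            GeneRecord(
                gene_id=f"g{i}",
                nt_seq="ATG" + "GGC" * (i + 3) + "TAA",
                start=1,
                end=3 * (i + 5),
                partial_code="00" if i % 2 else "10",
            )
            for i in range(10)
        ]
        cat = Catalogue(
            name="ten",
            representatives=reps,
            provenance={r.gene_id: "from_coassembly" for r in reps},
            membership={r.gene_id: [r.gene_id, f"m_{r.gene_id}"] for r in reps},
        )
        fasta, tsv = tmp_path / "cat.fna", tmp_path / "cat.tsv"
        write_catalogue(cat, fasta, tsv)
        back = read_catalogue(fasta, tsv, name="ten")
        assert back.gene_ids() == cat.gene_ids()
        for a, b in zip(cat.representatives, back.representatives):
            assert (a.nt_seq, a.partial_code, a.start, a.end) == (
                b.nt_seq, b.partial_code, b.start, b.end
            )
        assert back.provenance == cat.provenance
        assert back.membership == cat.membership
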