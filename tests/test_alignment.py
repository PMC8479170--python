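"""Aligned-FASTA I/O, coordinate maps, and column context classification."""

import numpy as np
import pytest

from plastdiv.alignment import AlignedGenomeSet, read_alignment, write_alignment
from plastdiv.annotation import AnnotationSet, Feature, read_annotation, write_annotation
from plastdiv.context import ContextIndex, classify_column
from plastdiv.errors import (
    DuplicateIdError,
    FrameError,
    MissingReferenceError,
    OutOfRangeError,
    RaggedAlignmentError,
)
from plastdiv.structure import RegionPartition


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadAlignment:
    def test_minimal_set(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("r", "ACGTACGT"), ("a", "ACCTACGT"), ("b", "acgtacgA")])
        aln = read_alignment(p, "r")
        assert aln.n == 3 and aln.length == 8
        assert aln.sequence("b") == "ACGTACGA"  # lowercase normalised

    def test_ragged_records_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("r", "ACGTACGT"), ("a", "ACGTACG")])
        with pytest.raises(RaggedAlignmentError):
            read_alignment(p, "r")

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("r", "ACGT"), ("r", "ACGT")])
        with pytest.raises(DuplicateIdError):
            read_alignment(p, "r")

    def test_missing_reference_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(MissingReferenceError):
            read_alignment(p, "a2")

    def test_all_gap_column_rejected(self):
        with pytest.raises(RaggedAlignmentError):
            AlignedGenomeSet.from_sequences({"r": "A-G", "b": "A-G"}, "r")

    def test_roundtrip(self, tmp_path, toy_aln):
        p = tmp_path / "rt.fasta"
        write_alignment(toy_aln, p)
        again = read_alignment(p, "ref")
        assert again.accessions == toy_aln.accessions
        assert np.array_equal(again.matrix, toy_aln.matrix)

    def test_paper_scale_parse(self, tmp_path):
        """22 records x 152,010 columns parse into n=22."""
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=152_010)
        seq = "".join(base)
        p = tmp_path / "big.fasta"
        write_fasta(p, [(f"acc{i}", seq) for i in range(22)])
        aln = read_alignment(p, "acc0")
        assert aln.n == 22 and aln.length == 152_010


class TestCoordinateMap:
    def test_roundtrip_random_columns(self, toy_aln):
        cmap = toy_aln.coordinate_map("s3")
        rng = np.random.default_rng(1)
        for col in rng.integers(0, toy_aln.length, size=1000):
            pos = cmap.position(int(col))
            if pos is not None:
                assert cmap.column(pos) == col

    def test_nongap_count_equals_ungapped_length(self, toy_aln):
        for acc in toy_aln.accessions:
            cmap = toy_aln.coordinate_map(acc)
            assert cmap.ungapped_length == len(toy_aln.ungapped(acc))

    def test_strictly_increasing(self, toy_aln):
        cmap = toy_aln.coordinate_map("s3")
        cols = [cmap.column(p) for p in range(cmap.ungapped_length)]
        assert cols == sorted(cols) and len(set(cols)) == len(cols)


class TestAnnotationIO:
    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "x\t.\tgene\t1\t3\t.\t+\t.\tID=g;gene=g\n"
            "x\t.\tCDS\t1\t3\t.\t+\t0\tID=g.c;gene=g\n"
        )
        ann = read_annotation(p, 10)
        assert ann.feature("g", "gene").parts == [(0, 3)]

    def test_out_of_range_interval(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("x\t.\tgene\t5\t30\t.\t+\t.\tgene=g\n")
        with pytest.raises(OutOfRangeError):
            read_annotation(p, 10)

    def test_cds_frame_error(self, tmp_path):
        # 10 + 11 = 21 bp: fine; 10 + 12 = 22 bp: frame error
        p = tmp_path / "a.gff3"
        p.write_text(
            "x\t.\tCDS\t1\t10\t.\t+\t0\tgene=g\n"
            "x\t.\tCDS\t21\t32\t.\t+\t0\tgene=g\n"
        )
        with pytest.raises(FrameError):
            read_annotation(p, 50)

    def test_two_exon_minus_strand_length(self):
        ann = AnnotationSet(
            [Feature("g", "CDS", "-", [(0, 30), (50, 95)], phases=[0, 0])], 100
        )
        feat = ann.feature("g", "CDS")
        assert feat.length == 75
        # transcription order on '-' is reverse genomic order
        assert feat.transcription_parts() == [(50, 95), (0, 30)]

    def test_gff_roundtrip_preserves_transcription_order(self, tmp_path):
        ann = AnnotationSet(
            [Feature("g", "CDS", "-", [(0, 30), (50, 95)], phases=[0, 0])], 100
        )
        p = tmp_path / "a.gff3"
        write_annotation(ann, p)
        again = read_annotation(p, 100)
        feat = again.feature("g", "CDS")
        assert feat.transcription_parts() == [(50, 95), (0, 30)]


class TestClassifyColumn:
    @pytest.fixture
    def setup(self):
        # 40-bp genome: gene A [5,20) with exon [5,11)+[17,20) (intron between),
        # nested CDS B [12,15) inside A's intron; partition splits at 24/30/34
        ann = AnnotationSet(
            [
                Feature("A", "tRNA", "+", [(5, 20)]),
                Feature("A", "exon", "+", [(5, 11), (17, 20)]),
                Feature("B", "gene", "+", [(12, 15)]),
                Feature("B", "CDS", "+", [(12, 15)], phases=[0]),
            ],
            40,
        )
        part = RegionPartition((0, 24), (24, 30), (30, 34), (34, 40), 40)
        rows = {
            "ref": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT",
            "oth": "ACGTACG--CGTACGTACGTACGTACGTACGTACGTACGT",
        }
        aln = AlignedGenomeSet.from_sequences(rows, "ref")
        return aln, ContextIndex(ann, part)

    def test_exon_intron_spacer(self, setup):
        aln, index = setup
        assert classify_column(6, aln, index).site_class == "exon"
        assert classify_column(11, aln, index) .site_class == "intron"
        ctx = classify_column(2, aln, index)
        assert ctx.site_class == "spacer" and ctx.gene is None

    def test_nested_cds_wins_over_intron(self, setup):
        aln, index = setup
        ctx = classify_column(13, aln, index)
        assert (ctx.site_class, ctx.gene) == ("exon", "B")

    def test_every_column_classified_once(self, setup):
        aln, index = setup
        classes = [classify_column(c, aln, index).site_class for c in range(aln.length)]
        assert len(classes) == aln.length
        assert set(classes) <= {"exon", "intron", "spacer"}

    def test_gap_in_reference_inherits_previous_context(self):
        ann = AnnotationSet(
            [
                Feature("A", "tRNA", "+", [(2, 6)]),
                Feature("A", "exon", "+", [(2, 6)]),
            ],
            8,
        )
        rows = {"ref": "ACGTA--CGT", "oth": "ACGTAGGCGT"}
        aln = AlignedGenomeSet.from_sequences(rows, "ref")

        # a quadripartite partition is not constructible for 8 bp; build the
        # index arrays directly
        index = ContextIndex.__new__(ContextIndex)
        index.ann = ann
        index.genes = ["A"]
        index.class_code = np.array([0, 0, 2, 2, 2, 2, 0, 0], dtype=np.int8)
        index.gene_idx = np.array([-1, -1, 0, 0, 0, 0, -1, -1], dtype=np.int32)
        index.region_code = np.zeros(8, dtype=np.int8)
        # columns 5,6 are reference gaps following reference position 4 (exon)
        ctx = classify_column(5, aln, index)
        assert ctx.site_class == "exon" and ctx.gene == "A"
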