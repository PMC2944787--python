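import numpy as np
import pytest

from capmap.intervals import GenomeInterval
from capmap.track_io import (
    DepthTrack,
    GeneModel,
    WigParseError,
    bin_track,
    read_bed,
    read_fasta,
    read_gtf,
    read_wig,
    write_bed,
    write_fasta,
    write_gtf,
    write_wig,
)


class TestWig:
    def test_fixedstep_one_based_conversion(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=1 step=1\n5\n5\n5\n")
        track = read_wig(p)
        assert list(track.data["chr1"]) == [5.0, 5.0, 5.0]

    def test_variablestep_span_expansion(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("variableStep chrom=chr1 span=10\n11 2\n")
        track = read_wig(p)
        arr = track.data["chr1"]
        assert len(arr) == 20
        assert np.all(arr[:10] == 0) and np.all(arr[10:20] == 2)

    def test_empty_file_with_track_line(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text('track type=wiggle_0 name="x"\n')
        assert read_wig(p).data == {}

    def test_uncovered_bases_are_zero(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=11 step=1\n3\n")
        arr = read_wig(p).data["chr1"]
        assert list(arr) == [0] * 10 + [3.0]

    @pytest.mark.parametrize("body", ["fixedStep start=1\n1\n", "fixedStep chrom=c start=x\n1\n",
                                      "variableStep chrom=c\nnot-a-number 1\n"])
    def test_malformed_lines_name_line_number(self, tmp_path, body):
        p = tmp_path / "t.wig"
        p.write_text(body)
        with pytest.raises(WigParseError, match="line"):
            read_wig(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=c start=1 step=1\n-1\n")
        with pytest.raises(WigParseError, match="negative"):
            read_wig(p)

    def test_roundtrip_integer_track(self, tmp_path, rng):
        track = DepthTrack({"chr1": rng.integers(0, 50, 1000).astype(float),
                            "chr2": np.zeros(100)})
        write_wig(track, tmp_path / "t.wig")
        assert read_wig(tmp_path / "t.wig") == track

    def test_roundtrip_fractional_track(self, tmp_path, rng):
        # normalization produces non-integer depths; repr round-trips float64
        track = DepthTrack({"chr1": rng.integers(0, 50, 300) * 1.2345678901234e-3})
        write_wig(track, tmp_path / "t.wig")
        assert read_wig(tmp_path / "t.wig") == track

    def test_roundtrip_all_zero(self, tmp_path):
        track = DepthTrack({"chr1": np.zeros(50)})
        write_wig(track, tmp_path / "t.wig")
        assert read_wig(tmp_path / "t.wig") == track


class TestBed:
    def test_bed6_parse(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\tcgi1\t0\t+\n")
        (iv,) = read_bed(p)
        assert iv == GenomeInterval("chr1", 100, 200, "+", "cgi1")
        assert iv.name == "cgi1"

    def test_overlapping_intervals_preserved(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        ivs = read_bed(p)
        assert [(i.start, i.end) for i in ivs] == [(0, 100), (50, 150)]

    def test_twelve_column_warns_and_parses(self, tmp_path, caplog):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t10\tx\t0\t-\t0\t10\t0\t1\t10\t0\n")
        with caplog.at_level("WARNING"):
            (iv,) = read_bed(p)
        assert iv.strand == "-" and iv.name == "x"
        assert any("ignored" in r.message for r in caplog.records)

    def test_start_ge_end_rejected_with_line(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t10\nchr1\t20\t20\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_roundtrip(self, tmp_path):
        ivs = [GenomeInterval("chr1", 0, 10, "+", "a"), GenomeInterval("chr2", 5, 9, "-", "b")]
        write_bed(ivs, tmp_path / "t.bed")
        assert read_bed(tmp_path / "t.bed") == ivs


class TestFasta:
    def test_case_normalized(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">chr1\nacgt\n")
        assert read_fasta(p) == {"chr1": "ACGT"}

    def test_multi_record(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">a desc ignored\nAC\nGT\n>b\nNNNA\n")
        assert read_fasta(p) == {"a": "ACGT", "b": "NNNA"}

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_bad_character_names_position(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">a\nACXT\n")
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        seqs = {"chr1": "ACGT" * 50, "chr2": "NNACGTNN"}
        write_fasta(seqs, tmp_path / "t.fa")
        assert read_fasta(tmp_path / "t.fa") == seqs


class TestGtf:
    def test_coordinate_conversion_and_tss(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text('chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
                     'chr1\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "g2";\n')
        g1, g2 = read_gtf(p)
        assert (g1.interval.start, g1.interval.end) == (100, 200)
        assert g1.tss == 100
        assert g2.tss == 399  # 5' end of the minus-strand gene

    def test_missing_gene_id_rejected(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text("chr1\tsrc\tgene\t1\t10\t.\t+\t.\tother \"x\";\n")
        with pytest.raises(ValueError, match="gene_id"):
            read_gtf(p)

    def test_roundtrip(self, tmp_path):
        genes = [GeneModel(GenomeInterval("chr1", 100, 200, "+", "g1"), "g1")]
        write_gtf(genes, tmp_path / "t.gtf")
        assert read_gtf(tmp_path / "t.gtf") == genes

    def test_strandless_gene_has_no_tss(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel(GenomeInterval("chr1", 0, 10, "."), "g")


class TestBinTrack:
    def test_constant_track(self):
        track = DepthTrack({"c": np.full(3000, 7.0)})
        assert np.all(bin_track(track, 1000)["c"] == 7.0)

    def test_half_covered_window(self):
        arr = np.zeros(1000)
        arr[:500] = 10
        assert bin_track(DepthTrack({"c": arr}), 1000)["c"][0] == 5.0

    def test_trailing_partial_window_dropped(self):
        track = DepthTrack({"c": np.ones(1500)})
        assert len(bin_track(track, 1000)["c"]) == 1

    def test_width_longer_than_chromosome(self):
        track = DepthTrack({"c": np.ones(10)})
        assert len(bin_track(track, 1000)["c"]) == 0

    def test_window_count_and_mass(self, rng):
        arr = rng.poisson(2.0, 2345).astype(float)
        track = DepthTrack({"c": arr})
        for width in (1, 7, 100, 1000):
            means = bin_track(track, width)["c"]
            assert len(means) == 2345 // width
            assert means.sum() * width <= arr.sum() + 1e-9


def test_depth_track_validation():
    with pytest.raises(ValueError):
        DepthTrack({"c": np.array([1.0, -1.0])})
    with pytest.raises(ValueError):
        DepthTrack({"c": np.array([np.inf])})
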