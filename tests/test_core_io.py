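"""Data model, read preprocessing, file formats, and coverage construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsrnatk import (
    AlignedRead,
    GenomicInterval,
    build_coverage,
    collapse_reads,
    covered_length,
    preprocess_reads,
    read_bed,
    read_gff3,
    trim_adapter,
    write_bed,
)
from dsrnatk.core_io import RecordError, read_chrom_sizes, write_chrom_sizes

from conftest import read


class TestIntervals:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 31, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "x")

    def test_overlap_arithmetic(self):
        a = GenomicInterval("chr1", 10, 20)
        assert a.overlap(GenomicInterval("chr1", 15, 30)) == 5
        assert a.overlap(GenomicInterval("chr1", 20, 30)) == 0
        assert a.overlap(GenomicInterval("chr2", 10, 20)) == 0

    def test_read_weight_is_copies_over_hits(self):
        r = read("chr1", 10, 31, copies=4, n_hits=2)
        assert r.weight == 2.0
        assert r.length == 21


class TestCollapse:
    def test_counting(self):
        assert collapse_reads(["ACG", "ACG", "TTT"]) == {"ACG": 2, "TTT": 1}
        assert collapse_reads(["A"]) == {"A": 1}
        assert collapse_reads([]) == {}

    def test_copies_conserved_on_random_pool(self):
        rng = np.random.default_rng(42)
        pool = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(100)]
        draws = [pool[i] for i in rng.integers(0, 100, size=1000)]
        nr = collapse_reads(draws)
        assert sum(nr.values()) == 1000
        assert len(nr) <= 100
        # brute-force tally over the same draw
        for seq, copies in nr.items():
            assert copies == sum(1 for d in draws if d == seq)


class TestTrimAdapter:
    @pytest.mark.parametrize(
        "seq,adapter,min_overlap,expected",
        [
            ("ACGTGATCG", "GATCG", 5, ("ACGT", True)),
            ("ACGTACGT", "TTTTT", 5, ("ACGTACGT", False)),  # retained untrimmed
            ("GATCG", "GATCG", 5, ("", True)),  # full-adapter read
            ("ACGTGAT", "GATCG", 3, ("ACGT", True)),  # partial 3' overlap
            ("ACG", "GATCGGATCG", 5, ("ACG", False)),  # adapter longer than read
        ],
    )
    def test_examples(self, seq, adapter, min_overlap, expected):
        assert trim_adapter(seq, adapter, min_overlap) == expected

    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=40),
        adapter=st.text(alphabet="ACGT", min_size=5, max_size=12),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_trimmed_product_is_prefix(self, seq, adapter):
        trimmed, found = trim_adapter(seq, adapter, 5)
        assert seq.startswith(trimmed)
        if not found:
            assert trimmed == seq
        else:
            # the removed tail is a prefix of the adapter
            tail = seq[len(trimmed):]
            assert adapter.startswith(tail) or tail == ""

    def test_empty_product_discarded_by_preprocess(self):
        nr = preprocess_reads(["GATCG", "A" * 20], adapter="GATCG")
        assert nr == {"A" * 20: 1}


class TestBedRoundTrip:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t10\t31\tnr7/2\t4\t+\n")
        (r,) = read_bed(p)
        assert r.interval == GenomicInterval("chr1", 10, 31, "+")
        assert (r.copies, r.n_hits, r.weight) == (4, 2, 2.0)

    def test_round_trip_lossless(self, tmp_path):
        reads = [
            read("chr1", 10, 31, "+", copies=4, n_hits=2, name="nr7"),
            read("chr2", 0, 21, "-", copies=1, n_hits=1, name="nr8"),
            read("chr1", 500, 524, ".", copies=9, n_hits=3, name="nr9"),
        ]
        p = tmp_path / "r.bed"
        write_bed(reads, p)
        assert read_bed(p) == reads
        # byte-level round trip
        q = tmp_path / "r2.bed"
        write_bed(read_bed(p), q)
        assert p.read_text() == q.read_text()

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t31\t10\tnr/1\t1\t+",  # start >= end
            "chr1\t10\t31\tnr/1\t1\tx",  # bad strand
            "chr1\tten\t31\tnr/1\t1\t+",  # non-integer
        ],
    )
    def test_malformed_record_names_line(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t5\tnr/1\t1\t+\n" + line + "\n")
        with pytest.raises(RecordError, match=":2:"):
            read_bed(p)

    def test_unknown_chrom_rejected_with_sizes(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chrX\t0\t5\tnr/1\t1\t+\n")
        with pytest.raises(RecordError, match="chrX"):
            read_bed(p, {"chr1": 100})


class TestGff3:
    def test_coordinate_conversion_and_mapping(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttRNA\t101\t180\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\tfive_prime_UTR\t1\t50\t.\t-\t.\tID=u1;Parent=g1\n"
        )
        feats = read_gff3(p)
        assert feats[0].interval == GenomicInterval("chr1", 100, 180, "+")
        assert feats[0].category == "tRNA"
        assert feats[1].category == "UTR5"
        assert feats[1].parent_id == "g1"

    def test_unmapped_type_routed_to_other_ncRNA(self, tmp_path, caplog):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\tweird_type\t1\t10\t.\t+\t.\tID=w1\n")
        with caplog.at_level("WARNING", logger="dsrnatk"):
            feats = read_gff3(p)
        assert feats[0].category == "other_ncRNA"
        assert "weird_type" in caplog.text

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr1\tsrc\ttRNA\t180\t101\t.\t+\t.\tID=t1\n")
        with pytest.raises(RecordError, match=":1:"):
            read_gff3(p)


class TestCoverage:
    def test_single_read_depths(self, chrom_sizes):
        track = build_coverage([read("chr1", 2, 5, "+")], chrom_sizes)
        assert list(track.plus["chr1"][:6]) == [0, 0, 1, 1, 1, 0]

    def test_linearity_of_weights(self, chrom_sizes):
        half = [
            read("chr1", 2, 5, "+", copies=1, n_hits=2),
            read("chr1", 2, 5, "+", copies=1, n_hits=2),
        ]
        one = [read("chr1", 2, 5, "+")]
        t_half = build_coverage(half, chrom_sizes)
        t_one = build_coverage(one, chrom_sizes)
        assert np.array_equal(t_half.plus["chr1"], t_one.plus["chr1"])

    def test_total_mass_matches_brute_force(self, chrom_sizes):
        rng = np.random.default_rng(7)
        reads = []
        for _ in range(200):
            start = int(rng.integers(0, 9_000))
            length = int(rng.integers(1, 80))
            strand = "+" if rng.random() < 0.5 else "-"
            copies = int(rng.integers(1, 5))
            n_hits = int(rng.integers(1, 4))
            reads.append(read("chr1", start, start + length, strand, copies, n_hits))
        track = build_coverage(reads, chrom_sizes)
        expected = sum(r.weight * r.length for r in reads)
        assert track.total_mass() == pytest.approx(expected, abs=1e-9)

    def test_additive_over_read_subsets(self, chrom_sizes):
        rng = np.random.default_rng(11)
        reads = [
            read("chr1", int(s), int(s) + 20, "+")
            for s in rng.integers(0, 9000, size=50)
        ]
        t_all = build_coverage(reads, chrom_sizes)
        t_a = build_coverage(reads[:25], chrom_sizes)
        t_b = build_coverage(reads[25:], chrom_sizes)
        assert np.allclose(t_all.plus["chr1"], t_a.plus["chr1"] + t_b.plus["chr1"])

    def test_read_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            build_coverage([read("chr1", 90, 120)], {"chr1": 100})


class TestCoveredLength:
    def test_examples(self, chrom_sizes):
        empty = build_coverage([], chrom_sizes)
        assert covered_length(empty, GenomicInterval("chr1", 0, 10)) == 0
        one = build_coverage([read("chr1", 2, 5)], chrom_sizes)
        assert covered_length(one, GenomicInterval("chr1", 0, 10)) == 3
        two = build_coverage([read("chr1", 2, 5), read("chr1", 4, 8, "-")], chrom_sizes)
        assert covered_length(two, GenomicInterval("chr1", 0, 10)) == 6

    def test_matches_per_base_brute_force(self, chrom_sizes):
        rng = np.random.default_rng(3)
        reads = [
            read("chr1", int(s), int(s) + int(l), "+" if rng.random() < 0.5 else "-")
            for s, l in zip(rng.integers(0, 900, 80), rng.integers(1, 60, 80))
        ]
        track = build_coverage(reads, chrom_sizes)
        covered = set()
        for r in reads:
            covered.update(range(r.interval.start, r.interval.end))
        region = GenomicInterval("chr1", 0, 1000)
        assert covered_length(track, region) == len(
            [b for b in covered if b < 1000]
        )


def test_chrom_sizes_round_trip(tmp_path):
    p = tmp_path / "c.sizes"
    write_chrom_sizes({"chr1": 1000, "chrM": 367}, p)
    assert read_chrom_sizes(p) == {"chr1": 1000, "chrM": 367}
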