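"""Read-1 layout presets, tag extraction and FASTQ reformatting."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stprep.read_structure import (
    PLATFORMS,
    SLIDE_SEQ_BRIDGE,
    ReadStructure,
    RejectReason,
    SegmentRole,
    SegmentSpec,
    get_preset,
    make_header,
    parse_read1,
    reformat_fastq_pair,
    split_header,
)

NUCS = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestPresets:
    @pytest.mark.parametrize(
        "platform,barcode_len,umi_len",
        [
            ("visium", 16, 12),
            ("slide_seq_v1", 16, 8),
            ("slide_seq_v2", 15, 9),
            ("curio_seeker", 15, 9),
            ("stereo_seq", 25, 10),
        ],
    )
    def test_total_lengths(self, platform, barcode_len, umi_len):
        rs = get_preset(platform)
        assert rs.barcode_total_len == barcode_len
        assert rs.umi_total_len == umi_len

    def test_visium_segment_order(self):
        segs = get_preset("visium").segments
        assert [(s.role.value, s.length) for s in segs] == [("barcode", 16), ("umi", 12)]

    @pytest.mark.parametrize("platform", ["slide_seq_v1", "slide_seq_v2"])
    def test_slide_seq_bridge(self, platform):
        linkers = [s for s in get_preset(platform).segments if s.role is SegmentRole.LINKER]
        assert len(linkers) == 1
        assert linkers[0].length == 18
        assert linkers[0].expected_sequence == SLIDE_SEQ_BRIDGE

    def test_slide_seq_v2_layout(self):
        segs = get_preset("slide_seq_v2").segments
        assert [(s.role.value, s.length) for s in segs] == [
            ("barcode", 8), ("linker", 18), ("barcode", 7), ("umi", 9),
        ]

    def test_version_string_folds_into_platform(self):
        assert get_preset("slide_seq", "v2").platform == "slide_seq_v2"

    def test_custom_echoes_segments(self):
        segs = (SegmentSpec(SegmentRole.BARCODE, 4), SegmentSpec(SegmentRole.UMI, 4))
        assert get_preset("custom", segments=segs).segments == segs

    def test_unknown_platform_names_valid_options(self):
        with pytest.raises(ValueError, match="visium"):
            get_preset("nanopore_spatial")

    def test_stereo_umi_len_configurable(self):
        assert get_preset("stereo_seq", stereo_umi_len=12).umi_total_len == 12


class TestSegmentInvariants:
    def test_linker_requires_expected_sequence(self):
        with pytest.raises(ValueError):
            SegmentSpec(SegmentRole.LINKER, 5)

    def test_expected_sequence_length_must_match(self):
        with pytest.raises(ValueError):
            SegmentSpec(SegmentRole.LINKER, 5, expected_sequence="ACGT")

    def test_non_linker_rejects_expected_sequence(self):
        with pytest.raises(ValueError):
            SegmentSpec(SegmentRole.BARCODE, 4, expected_sequence="ACGT")


class TestParseRead1:
    def test_visium_extraction(self):
        tags = parse_read1("A" * 16 + "C" * 12 + "GGGG", get_preset("visium"))
        assert tags.ok
        assert tags.barcode == "A" * 16
        assert tags.umi == "C" * 12

    def test_too_short(self):
        tags = parse_read1("ACGTACGTAC", get_preset("visium"))
        assert tags.reject_reason is RejectReason.TOO_SHORT

    def test_linker_mismatch_at_boundary(self):
        """A bridge with exactly max_mismatch+1 substitutions is rejected,
        one with max_mismatch is accepted (brute-force Hamming count)."""
        rs = get_preset("slide_seq_v1", linker_max_mismatch=3)
        bridge_bad = "AAAA" + SLIDE_SEQ_BRIDGE[4:]  # 4 mismatches vs TCTT start
        assert sum(a != b for a, b in zip(bridge_bad, SLIDE_SEQ_BRIDGE)) == 4
        seq_bad = "G" * 8 + bridge_bad + "G" * 8 + "T" * 8
        assert parse_read1(seq_bad, rs).reject_reason is RejectReason.LINKER_MISMATCH
        bridge_ok = "AAA" + SLIDE_SEQ_BRIDGE[3:]  # 3 mismatches
        assert sum(a != b for a, b in zip(bridge_ok, SLIDE_SEQ_BRIDGE)) == 3
        seq_ok = "G" * 8 + bridge_ok + "G" * 8 + "T" * 8
        assert parse_read1(seq_ok, rs).ok

    def test_multi_segment_barcode_concatenation(self):
        rs = get_preset("slide_seq_v2")
        seq = "A" * 8 + SLIDE_SEQ_BRIDGE + "C" * 7 + "G" * 9
        tags = parse_read1(seq, rs)
        assert tags.barcode == "A" * 8 + "C" * 7
        assert tags.umi == "G" * 9

    def test_ambiguous_base_policy(self):
        rs = get_preset("visium")
        one_n = "N" + "A" * 15 + "C" * 12
        assert parse_read1(one_n, rs).ok  # one N tolerated by default
        two_n = "NN" + "A" * 14 + "C" * 12
        assert parse_read1(two_n, rs).reject_reason is RejectReason.AMBIGUOUS_BASE_OVERFLOW

    @given(seq=st.text(alphabet="ACGTN", min_size=28, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_pure_function(self, seq):
        rs = get_preset("visium")
        assert parse_read1(seq, rs) == parse_read1(seq, rs)


class TestHeaderRoundTrip:
    @given(barcode=NUCS, umi=NUCS, rid=st.text(alphabet="abc0_9.:", min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_split_inverts_make(self, barcode, umi, rid):
        assert split_header(make_header(barcode, umi, rid)) == (barcode, umi, rid)


def _write_fastq(path, records):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestReformat:
    def test_single_pair_header(self, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(r1, [("RID", "A" * 16 + "C" * 12)])
        _write_fastq(r2, [("RID", "GATTACA" * 5)])
        out = tmp_path / "out.fastq"
        stats = reformat_fastq_pair(r1, r2, get_preset("visium"), out)
        assert stats.passed == 1
        line = out.read_text().splitlines()[0]
        assert line == "@" + "A" * 16 + "_" + "C" * 12 + "#RID"

    def test_empty_input(self, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(r1, [])
        _write_fastq(r2, [])
        stats = reformat_fastq_pair(r1, r2, get_preset("visium"), tmp_path / "o.fastq")
        assert stats.total_pairs == 0
        assert (tmp_path / "o.fastq").read_text() == ""

    def test_known_reject_counts_and_conservation(self, tmp_path):
        rs = get_preset("visium")
        records1, records2 = [], []
        for i in range(90):
            records1.append((f"p{i}", "A" * 16 + "C" * 12))
            records2.append((f"p{i}", "G" * 30))
        for i in range(10):
            records1.append((f"s{i}", "ACGT"))  # too short for the layout
            records2.append((f"s{i}", "G" * 30))
        r1, r2 = tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz"
        _write_fastq(r1, records1)
        _write_fastq(r2, records2)
        stats = reformat_fastq_pair(r1, r2, rs, tmp_path / "o.fastq.gz")
        assert stats.passed == 90
        assert stats.rejected_by_reason["too_short"] == 10
        assert stats.check_conservation()

    def test_unequal_pair_counts_is_error(self, tmp_path):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(r1, [("a", "A" * 28), ("b", "A" * 28)])
        _write_fastq(r2, [("a", "G" * 30)])
        with pytest.raises(ValueError, match="unequal"):
            reformat_fastq_pair(r1, r2, get_preset("visium"), tmp_path / "o.fastq")
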