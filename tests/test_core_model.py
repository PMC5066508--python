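"""Normalization, 75-nt core segmentation and D/V-loop classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import minihelix as mx
from minihelix.core_model import (
    SEGMENT_ORDER,
    AlphabetError,
    SegmentationError,
    normalize_sequence,
    segment_set,
)

CORE = mx.ANCESTRAL_CORE


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("GCGGAUUUA", "GCGGATTTA"),  # RNA alphabet
            ("P", "T"),                  # pseudo-uridine is a uridine derivative
            ("5", "C"),                  # 5-methyl-cytosine
            ("1", "A"),                  # adenosine derivative
            ("Y", "A"),                  # adenosine derivative
            ("acgu", "ACGT"),
        ],
    )
    def test_modified_code_mapping(self, raw, expected):
        assert normalize_sequence(raw).residues == expected

    def test_gaps_removed_and_recorded(self):
        ns = normalize_sequence("AC-GU .T")
        assert ns.residues == "ACGTT"
        assert ns.gap_positions == (3, 6, 7)
        assert ns.raw == "AC-GU .T"

    def test_strict_rejects_unknown_with_position(self):
        with pytest.raises(AlphabetError, match=r"'Z' at position 3"):
            normalize_sequence("ACZGT")

    def test_strict_rejects_ambiguous_o(self):
        with pytest.raises(AlphabetError, match="position 2"):
            normalize_sequence("AOC")

    def test_lenient_maps_unknown_to_n(self):
        assert normalize_sequence("AOZC", strict=False).residues == "ANNC"

    def test_empty_rejected(self):
        with pytest.raises(AlphabetError):
            normalize_sequence("   ")


class TestScheme:
    def test_ranges_and_derived_constants(self):
        scheme = mx.DEFAULT_SCHEME
        assert scheme.ranges["ACMH"] == (30, 46)
        assert scheme.ranges["TMH"] == (52, 68)
        assert sum(scheme.length(n) for n in SEGMENT_ORDER) == 75
        assert 3 * scheme.minihelix_len - 2 * scheme.deletion_len == scheme.core_len
        assert scheme.intact_d_region_len == 22

    def test_non_tiling_ranges_rejected(self):
        bad = dict(mx.DEFAULT_SCHEME.ranges)
        bad["AS5"] = (1, 8)
        with pytest.raises(ValueError):
            mx.SegmentScheme(ranges=bad)


class TestSegmentTRNA:
    def test_ancestral_core_recovers_all_segments(self, ancestral_segmented):
        t = ancestral_segmented
        assert t.segments == {
            "AS5": "GCGGCCG",
            "DMH": "TAGTCTAGCCTGGACTA",
            "DREM": "GACCG",
            "ACMH": "CCGGGCTTGTAACCCGG",
            "VLOOP": "CGGCC",
            "TMH": "CCGGGTTCAAATCCCGG",
            "AS3": "CGGCCGC",
        }
        assert t.coords["ACMH"] == (30, 46)
        assert (t.d_status, t.v_status) == ("intact", "simple")
        assert (t.d_region_length, t.v_region_length) == (22, 5)

    def test_d_deletion_detected(self):
        mutated = CORE[:10] + CORE[13:]  # 3 nt out of the D-arm microhelix
        t = mx.segment_trna(mutated)
        assert t.d_region_length == 19
        assert t.d_status == "deleted"
        assert t.v_status == "simple"

    def test_v_insertion_detected(self):
        mutated = CORE[:48] + "AG" + CORE[48:]
        t = mx.segment_trna(mutated)
        assert t.v_region_length == 7
        assert t.v_status == "inserted"
        assert t.d_status == "intact"

    @pytest.mark.parametrize("suffix", ["", "CCA", "CA", "A"])
    def test_cca_invariance(self, suffix, ancestral_segmented):
        t = mx.segment_trna(CORE + suffix)
        assert t.segments == ancestral_segmented.segments
        assert t.cca_stripped == suffix

    def test_segments_concatenate_to_input(self):
        t = mx.segment_trna(CORE + "CCA")
        assert "".join(t.segments[n] for n in SEGMENT_ORDER) == CORE

    def test_d_region_longer_than_22_is_model_violation(self):
        # 4 extra nt in the D region push it to 26 nt; with the anticodon
        # hairpin pinned by a structure line the violation is flagged rather
        # than silently reinterpreted
        mutated = CORE[:15] + "TTTT" + CORE[15:]
        struct = (
            "((((((("
            + "(((((" + "." * 11 + ")))))"  # 21-nt D-arm hairpin
            + "....."
            + "(((((.......)))))"
            + "....."
            + "(((((.......)))))"
            + ")))))))"
        )
        assert len(struct) == len(mutated)
        with pytest.raises(SegmentationError, match="model violation"):
            mx.segment_trna(mutated, struct)

    def test_length_window_enforced(self):
        with pytest.raises(SegmentationError, match=r"\[55, 100\]"):
            mx.segment_trna("ACGT" * 10)

    def test_unfoldable_sequence_fails_with_diagnostic(self):
        with pytest.raises(SegmentationError, match="T arm|anticodon"):
            mx.segment_trna("A" * 75)

    def test_structure_line_guides_segmentation(self):
        # dot-bracket for the ancestral core: acceptor stem + three hairpins
        struct = (
            "((((((("            # AS5
            + "(((((.......)))))"  # D-arm hairpin
            + "....."              # DREM
            + "(((((.......)))))"  # anticodon hairpin
            + "....."              # V loop
            + "(((((.......)))))"  # T-arm hairpin
            + ")))))))"            # AS3
        )
        t = mx.segment_trna(CORE, struct)
        assert t.coords["ACMH"] == (30, 46)
        assert t.d_status == "intact"

    def test_mismatched_structure_length_rejected(self):
        with pytest.raises(SegmentationError, match="length"):
            mx.segment_trna(CORE, "." * 10)

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError, match="nbalanced"):
            mx.segment_trna(CORE, "(" + "." * 74)


class TestClassifySet:
    def test_single_intact(self, ancestral_segmented):
        summary = mx.classify_set([ancestral_segmented])
        assert summary.d_counts == {"intact": 1}
        assert summary.intact_fraction == 1.0

    def test_mixed_ten_ten(self):
        intact = mx.segment_trna(CORE)
        deleted = mx.segment_trna(CORE[:10] + CORE[13:])
        summary = mx.classify_set([intact] * 10 + [deleted] * 10)
        assert summary.d_counts == {"intact": 10, "deleted": 10}
        assert summary.joint_counts[("intact", "simple")] == 10

    def test_counts_partition_input(self, synthetic_500):
        _synth, segmented, _failures = synthetic_500
        summary = mx.classify_set(segmented)
        assert sum(summary.d_counts.values()) == summary.n == len(segmented)
        assert sum(summary.v_counts.values()) == summary.n
        assert sum(summary.joint_counts.values()) == summary.n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.classify_set([])


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(f">a desc\n{CORE}\n>b\n{CORE[:40]}\n{CORE[40:]}\n")
        records = mx.read_sequences(path)
        assert [(r[0], r[1]) for r in records] == [("a", CORE), ("b", CORE)]
        assert all(r[2] is None for r in records)

    def test_interleaved_structure_lines(self, tmp_path):
        struct = "." * 75
        path = tmp_path / "in.fasta"
        path.write_text(f">a\n{CORE}\n{struct}\n")
        records = mx.read_sequences(path)
        assert records == [("a", CORE, struct)]

    def test_separate_structure_file(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(f">a\n{CORE}\n")
        structs = tmp_path / "in.db"
        structs.write_text(">a\n" + "." * 75 + "\n")
        records = mx.read_sequences(fasta, structs)
        assert records == [("a", CORE, "." * 75)]

    def test_segmentation_table_has_seven_rows_per_trna(self, ancestral_segmented):
        table = mx.segmentation_table([ancestral_segmented])
        assert len(table) == 7
        assert list(table["segment"]) == list(SEGMENT_ORDER)
        row = table[table.segment == "VLOOP"].iloc[0]
        assert (row.start, row.end, row.subsequence) == (47, 51, "CGGCC")

    def test_segment_set_reports_failures(self):
        segmented, failures = segment_set([("good", CORE), ("bad", "A" * 75)])
        assert [t.source_id for t in segmented] == ["good"]
        assert failures[0][0] == "bad" and "stem-loop" in failures[0][1]
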