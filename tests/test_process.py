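import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tardis_barseq import (
    ProcessingParams,
    ReadRecord,
    deduplicate,
    demultiplex,
    extract_umi,
    extract_umis,
    filter_and_crop,
    trim_to_barcode,
)
from tardis_barseq.process import (
    expected_errors,
    nextseq_trim_index,
    quality_trim_index,
    read_sample_sheet,
)


def make_read(bases: str, q: int | list[int] = 40, read_id: str = "r") -> ReadRecord:
    quals = [q] * len(bases) if isinstance(q, int) else q
    return ReadRecord(read_id, bases, quals)


PARAMS = ProcessingParams()


class TestFilterAndCrop:
    def test_clean_long_read_is_cropped_to_87(self):
        kept, tally = filter_and_crop([make_read("A" * 100)], PARAMS)
        assert tally == {"input": 1, "kept": 1}
        assert len(kept[0].bases) == 87

    def test_read_with_N_discarded(self):
        read = make_read("A" * 40 + "N" + "A" * 46)
        kept, tally = filter_and_crop([read], PARAMS)
        assert kept == []
        assert tally["discard_contains_N"] == 1

    def test_expected_error_boundary_read_kept_in_trim_mode(self):
        # 87 bases at Q20 guarded by a final Q40 base: the 3' trim leaves
        # the read intact and EE = 87 * 0.01 + 1e-4 = 0.87 <= 1 -> kept;
        # strict per-base mode discards the same read outright
        read = make_read("A" * 88, q=[20] * 87 + [40])
        kept, _ = filter_and_crop([read], PARAMS)
        assert len(kept) == 1
        strict = ProcessingParams(quality_filter_mode="strict_per_base")
        kept_strict, tally = filter_and_crop([read], strict)
        assert kept_strict == []
        assert tally["discard_low_quality"] == 1

    def test_uniformly_mediocre_read_is_fully_trimmed(self):
        # all-Q20 with nothing above the threshold: the running-sum trim
        # removes the entire read, which is then discarded as too short
        kept, tally = filter_and_crop([make_read("A" * 87, q=20)], PARAMS)
        assert kept == []
        assert tally["discard_too_short"] == 1

    def test_ee_filter_discards_noisy_read(self):
        # 87 bases at Q15: EE = 87 * 10^-1.5 = 2.75 > 1
        # (Q15 survives the Q30 3' trim only if high-quality bases follow)
        read = make_read("A" * 88, q=[15] * 87 + [40])
        kept, tally = filter_and_crop([read], PARAMS)
        assert kept == []
        assert tally["discard_expected_error"] == 1

    def test_low_quality_tail_is_trimmed_then_too_short(self):
        read = make_read("A" * 87, q=[40] * 20 + [2] * 67)
        kept, tally = filter_and_crop([read], PARAMS)
        assert kept == []
        assert tally["discard_too_short"] == 1

    def test_modes_agree_on_uniformly_good_reads(self):
        reads = [make_read("ACGT" * 22, q=35, read_id=f"r{i}") for i in range(5)]
        strict = ProcessingParams(quality_filter_mode="strict_per_base")
        kept_a, _ = filter_and_crop(reads, PARAMS)
        kept_b, _ = filter_and_crop(reads, strict)
        assert [r.bases for r in kept_a] == [r.bases for r in kept_b]

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGTN", min_size=1, max_size=120),
                st.integers(min_value=2, max_value=41),
            ),
            max_size=30,
        )
    )
    def test_conservation_holds_for_arbitrary_reads(self, specs):
        reads = [make_read(b, q, read_id=f"r{i}") for i, (b, q) in enumerate(specs)]
        kept, tally = filter_and_crop(reads, PARAMS)
        discards = sum(v for k, v in tally.items() if k.startswith("discard_"))
        assert tally.get("input", 0) == len(kept) + discards
        assert tally.get("kept", 0) == len(kept)


class TestQualityTrim:
    def test_running_sum_trim_cuts_bad_tail_only(self):
        quals = [40] * 50 + [10] * 10
        assert quality_trim_index(quals, 30) == 50

    def test_good_read_untouched(self):
        assert quality_trim_index([40] * 30, 30) == 30

    def test_nextseq_trim_treats_trailing_g_as_dark(self):
        bases = "A" * 50 + "G" * 20
        quals = [40] * 70  # poly-G tail reported confidently
        assert nextseq_trim_index(bases, quals, 30) == 50
        assert quality_trim_index(quals, 30) == 70  # plain trim keeps it

    def test_expected_errors_closed_form(self):
        assert expected_errors([20] * 87 ) == pytest.approx(0.87)


class TestExtractUmi:
    def test_anchored_match(self):
        umi, rem = extract_umi("CACAAAAAAAAAAGACTTTTT", PARAMS)
        assert umi == "AAAAAAAAAA"
        assert rem == "TTTTT"

    def test_flank_mismatch_is_no_match(self):
        assert extract_umi("CATAAAAAAAAAAGACTTTTT", PARAMS) is None

    def test_internal_match_concatenates_prefix_and_suffix(self):
        umi, rem = extract_umi("GGCACGGGGGGGGGGGACTTT", PARAMS)
        assert umi == "GGGGGGGGGG"
        assert rem == "GGTTT"

    def test_first_occurrence_wins(self):
        # brute-force scan oracle: leftmost window satisfying the pattern
        bases = "CACAAAAAAAAAAGACCACCCCCCCCCCGACTT"
        umi, rem = extract_umi(bases, PARAMS)
        assert umi == "AAAAAAAAAA"
        assert rem == "CACCCCCCCCCCGACTT"

    def test_one_mismatch_tolerance(self):
        tol = ProcessingParams(umi_flank_mismatches=1)
        umi, _ = extract_umi("CATAAAAAAAAAAGACTTTTT", tol)
        assert umi == "AAAAAAAAAA"
        assert extract_umi("TATAAAAAAAAAAGACTTTTT", tol) is None  # 2 mismatches

    def test_unmatched_reads_are_tallied_not_raised(self):
        reads = [make_read("T" * 40), make_read("CAC" + "A" * 10 + "GAC" + "T" * 20)]
        pairs, tally = extract_umis(reads, PARAMS)
        assert len(pairs) == 1
        assert tally == {"input": 2, "umi_unmatched": 1, "kept": 1}


class TestDeduplicate:
    def test_identical_triplicate_collapses(self):
        table = deduplicate([("AAA", "SEQ")] * 3)
        assert table.counts == {("AAA", "SEQ"): 3}
        assert table.n_reads == 3

    def test_same_umi_different_sequence_kept_apart(self):
        table = deduplicate([("AAA", "SEQ1"), ("AAA", "SEQ2")])
        assert table.n_unique == 2

    def test_empty_input(self):
        assert deduplicate([]).counts == {}

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGT", min_size=3, max_size=3),
                st.text(alphabet="ACGT", min_size=1, max_size=6),
            ),
            max_size=40,
        )
    )
    def test_idempotent_and_order_invariant(self, pairs):
        table = deduplicate(pairs)
        assert table.n_reads == len(pairs)
        again = deduplicate(list(table.counts))
        assert set(again.counts) == set(table.counts)
        assert all(v == 1 for v in again.counts.values())
        reversed_table = deduplicate(pairs[::-1])
        assert reversed_table.counts == table.counts


class TestTrimToBarcode:
    def test_first_fifteen_bases_kept(self):
        table = deduplicate([("A" * 10, "ACGTACGTACGTACGTTTT")])
        counts, tally = trim_to_barcode(table, 15)
        assert counts == {"ACGTACGTACGTACG": 1}
        assert tally == {"input": 1, "kept": 1}

    def test_short_remainder_dropped(self):
        table = deduplicate([("A" * 10, "ACGTACGTAC")])
        counts, tally = trim_to_barcode(table, 15)
        assert counts == {}
        assert tally["too_short"] == 1

    def test_identical_prefixes_aggregate(self):
        table = deduplicate(
            [("A" * 10, "ACGTACGTACGTACG" + "TTT"), ("C" * 10, "ACGTACGTACGTACG" + "GGG")]
        )
        counts, _ = trim_to_barcode(table, 15)
        assert counts == {"ACGTACGTACGTACG": 2}


class TestDemultiplex:
    def test_header_index_assignment(self):
        sheet = {"ACGT": "s1", "TTTT": "s2"}
        reads = [make_read("AAAA", read_id="m:1:ACGT"),
                 make_read("CCCC", read_id="m:2:TTTT"),
                 make_read("GGGG", read_id="m:3:GGGG")]
        out = demultiplex(reads, sheet, index_from="header")
        assert [r.bases for r in out["s1"]] == ["AAAA"]
        assert [r.bases for r in out["s2"]] == ["CCCC"]
        assert [r.bases for r in out["undetermined"]] == ["GGGG"]

    def test_prefix_index_assignment_strips_index(self):
        sheet = {"AC": "s1"}
        out = demultiplex([make_read("ACGGGG", q=[40] * 6)], sheet, index_from="prefix")
        assert out["s1"][0].bases == "GGGG"

    def test_duplicate_index_rejected(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        path.write_text("sample\tindex\ns1\tACGT\ns2\tACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_sheet(path)

    def test_exact_partition_recovery(self):
        sheet = {"AAAA": "left", "CCCC": "right"}
        reads = [
            make_read("AAAA" + "G" * 20, read_id=f"l{i}") for i in range(60)
        ] + [make_read("CCCC" + "T" * 20, read_id=f"r{i}") for i in range(40)]
        out = demultiplex(reads, sheet, index_from="prefix")
        assert len(out["left"]) == 60
        assert len(out["right"]) == 40
        assert not out["undetermined"]
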