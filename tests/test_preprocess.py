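"""Read cleanup: adapter trimming, length/junk/contaminant filters, ledger."""

import pytest
from hypothesis import given, settings, strategies as st

from stemloop.preprocess import (
    ContaminantIndex,
    ReadRecord,
    build_accounting,
    collapse,
    filter_by_length,
    is_junk,
    remove_contaminants,
    remove_junk,
    run_preprocess,
    surviving_after_cleanup,
    trim_3p_adapter,
)
from stemloop.seqs import revcomp

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
INSERT = "TGACCGAGTAGACCGATAGTC"  # a real mature miRNA sequence


def _rec(seq, count=1, rid="r1"):
    return ReadRecord(rid, seq, count)


class TestAdapterTrimming:
    def test_full_adapter_suffix_is_trimmed(self):
        out = trim_3p_adapter(_rec(INSERT + ADAPTER), ADAPTER)
        assert out.kept and out.sequence == INSERT

    def test_partial_adapter_at_read_end(self):
        out = trim_3p_adapter(_rec(INSERT + ADAPTER[:8]), ADAPTER)
        assert out.kept and out.sequence == INSERT

    def test_no_adapter_flags_no_3adt(self):
        out = trim_3p_adapter(_rec("ACGTACGTACGTACGTACGTACGT"), ADAPTER)
        assert not out.kept and out.removal_reason == "no_3adt"

    def test_adapter_only_read_yields_empty_insert(self):
        out = trim_3p_adapter(_rec(ADAPTER), ADAPTER)
        assert out.kept and out.sequence == ""
        removed = filter_by_length([out])
        assert removed[0].removal_reason == "too_short"

    def test_leftmost_match_wins(self):
        read = _rec("ACGTAC" + ADAPTER + "TTTT" + ADAPTER)
        assert trim_3p_adapter(read, ADAPTER).sequence == "ACGTAC"

    def test_mismatch_tolerance(self):
        corrupted = "TCGAATTCTCGGGTGCCAAGG"  # 1 mismatch in 21 (rate < 0.1)
        out = trim_3p_adapter(_rec(INSERT + corrupted), ADAPTER)
        assert out.kept and out.sequence == INSERT

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            trim_3p_adapter(_rec("ACGTXACGT" + ADAPTER), ADAPTER)

    def test_min_overlap_bounds(self):
        with pytest.raises(ValueError):
            trim_3p_adapter(_rec(INSERT), ADAPTER, min_overlap=4)
        with pytest.raises(ValueError):
            trim_3p_adapter(_rec(INSERT), "ACGTA", min_overlap=6)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,reason",
        [(14, "too_short"), (15, "none"), (30, "none"), (31, "too_long")],
    )
    def test_inclusive_bounds(self, length, reason):
        seq = ("ACGT" * 10)[:length]
        out = filter_by_length([_rec(seq)])
        assert out[0].removal_reason == reason

    def test_bad_configuration(self):
        with pytest.raises(ValueError):
            filter_by_length([_rec("ACGT")], min_len=20, max_len=10)


class TestJunkFilter:
    def test_homopolymer_is_junk(self):
        assert is_junk("A" * 17)

    def test_dimer_repeat_is_junk(self):
        assert is_junk("AGAGAGAGAGAGAGAGAG")

    def test_n_fraction(self):
        assert is_junk("ACGTNNNACGTACGTACGTA")  # 3 N / 20 > 0.1
        assert not is_junk("ACGTNACGTACGTACGTACG")  # 1 N / 20 <= 0.1

    def test_real_mature_survives(self):
        assert not is_junk(INSERT)


class TestContaminants:
    def test_exact_window_matches(self):
        rrna = "ACGGCTACCTTGTTACGACTTCACCCCAGTCATCGG"
        read = _rec(rrna[5:26])
        out = remove_contaminants([read], [rrna], [])
        assert out[0].removal_reason == "rfam"

    def test_reverse_strand_matches(self):
        rrna = "ACGGCTACCTTGTTACGACTTCACCCCAGTCATCGG"
        out = remove_contaminants([_rec(revcomp(rrna[5:26]))], [rrna], [])
        assert out[0].removal_reason == "rfam"

    def test_precedence_rfam_before_repbase(self):
        shared = "ACGGCTACCTTGTTACGACTT"
        out = remove_contaminants([_rec(shared)], [shared + "AA"], [shared + "CC"])
        assert out[0].removal_reason == "rfam"

    def test_no_match_kept(self):
        out = remove_contaminants([_rec(INSERT)], ["ACGT" * 20], ["TTTTAAAA" * 5])
        assert out[0].kept

    def test_empty_sets_are_noop(self):
        out = remove_contaminants([_rec(INSERT)], [], [])
        assert out[0].kept


class TestAccounting:
    def test_published_ledger_arithmetic(self):
        # the two flower-bud libraries' printed removal counts
        assert surviving_after_cleanup(6998586, 507331, 1365432, 27276) == 5098547
        assert surviving_after_cleanup(6792888, 212884, 1237678, 33207) == 5309119

    def test_zero_reads(self):
        report = build_accounting([])
        assert report.raw_total == 0 and report.mappable_total == 0

    def test_report_frame_layout(self):
        report = build_accounting([_rec(INSERT, 5)])
        frame = report.to_frame()
        assert list(frame.columns) == ["Category", "Sequences", "Unique sequences"]
        assert frame.iloc[0]["Sequences"] == 5


# -- whole-chain properties --------------------------------------------------

reads_strategy = st.lists(
    st.builds(
        ReadRecord,
        read_id=st.just("r"),
        sequence=st.text(alphabet="ACGTN", min_size=1, max_size=40),
        count=st.integers(min_value=1, max_value=50),
    ),
    max_size=25,
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(reads_strategy)
def test_chain_partitions_and_conserves(records):
    """Every read lands in exactly one category; totals are conserved."""
    rfam = ["ACGGCTACCTTGTTACGACTTCACCCCAGTCATCGGACGT"]
    staged, report = run_preprocess(records, ADAPTER, rfam, [])
    assert report.raw_total == sum(r.count for r in records)
    assert report.raw_total == report.mappable_total + sum(report.removed.values())
    for rec in staged:
        assert rec.kept == (rec.removal_reason == "none")


@settings(max_examples=40, deadline=None, derandomize=True)
@given(reads_strategy)
def test_chain_is_idempotent_on_kept_output(records):
    """Re-filtering the kept output (already trimmed) changes nothing."""
    staged, _ = run_preprocess(records, ADAPTER)
    kept = [r for r in staged if r.kept]
    again, report = run_preprocess(kept, adapter=None)
    assert sorted((r.sequence, r.count) for r in again if r.kept) == sorted(
        (r.sequence, r.count) for r in kept
    )
    assert report.mappable_total == sum(r.count for r in kept)


def test_collapse_merges_counts():
    merged = collapse([_rec("ACGT", 2, "a"), _rec("ACGT", 3, "b"), _rec("AAAA", 1, "c")])
    assert sorted((r.sequence, r.count) for r in merged) == [("AAAA", 1), ("ACGT", 5)]
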