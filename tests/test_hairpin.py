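"""Duplex evaluation, thermodynamic metrics and the five-criterion screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stemloop.annotate import LocusHit
from stemloop.hairpin import (
    DuplexReport,
    classify_candidate,
    compute_metrics,
    evaluate_duplex,
    extract_precursor_windows,
    infer_star_span,
)

from _synth import random_duplex_case


class TestMetrics:
    @pytest.mark.parametrize(
        "length,gc,mfe,expected_mfei",
        [
            (134, 35.0, -47.6, 1.0),   # published precursor rows whose printed
            (204, 29.1, -103.6, 1.7),  # MFEI agrees with the AMFE/GC% formula
            (201, 29.0, -101.4, 1.7),
            (84, 36.7, -38.3, 1.2),
            (128, 31.8, -52.5, 1.3),
        ],
    )
    def test_published_mfei_rows(self, length, gc, mfe, expected_mfei):
        m = compute_metrics(mfe, length=length, gc=gc)
        assert round(m.mfei, 1) == expected_mfei

    def test_amfe_definition(self):
        m = compute_metrics(-50.0, length=100, gc=40.0)
        assert m.amfe == 50.0 and m.mfei == 1.25

    def test_from_sequence(self):
        m = compute_metrics(-6.0, sequence="GGGAAAACCC")
        assert m.gc_percent == 60.0 and m.amfe == 60.0

    def test_zero_mfe(self):
        m = compute_metrics(0.0, length=100, gc=50.0)
        assert m.amfe == 0.0 and m.mfei == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(-10.0, sequence="")
        with pytest.raises(ValueError):
            compute_metrics(-10.0, length=100, gc=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=200.0),
           st.floats(min_value=1.1, max_value=5.0))
    def test_mfei_scales_linearly_with_mfe(self, mfe_mag, factor):
        base = compute_metrics(-mfe_mag, length=120, gc=40.0)
        scaled = compute_metrics(-mfe_mag * factor, length=120, gc=40.0)
        assert scaled.mfei == pytest.approx(base.mfei * factor)


def _perfect_hairpin_structure(n_pairs=19, loop=8, overhang=2, flank=5):
    """Dot-bracket for a canonical duplex with 2-nt 3' overhangs."""
    left = "(" * n_pairs + "." * overhang
    right = ")" * n_pairs + "." * overhang
    structure = "." * flank + left + "." * loop + right + "." * flank
    mir = (flank, flank + n_pairs + overhang)
    star = (flank + n_pairs + overhang + loop, flank + n_pairs + overhang + loop + n_pairs + overhang)
    return structure, mir, star


class TestDuplexEvaluation:
    def test_perfect_duplex(self):
        structure, mir, star = _perfect_hairpin_structure()
        rep = evaluate_duplex(structure, mir, star)
        assert rep.mismatch_count == 0
        assert rep.asymmetric_bulge_count == 0
        assert rep.overhang_3p_ok and rep.opposite_arms_ok

    def test_single_one_nt_star_bulge_passes_criterion(self):
        # one extra unpaired base on the star strand, none opposite
        left = "(" * 19 + ".."
        right = ")" * 10 + "." + ")" * 9 + ".."
        structure = left + "." * 8 + right
        mir = (0, 21)
        star = (29, 29 + len(right))
        rep = evaluate_duplex(structure, mir, star)
        assert rep.mismatch_count == 0
        assert rep.asymmetric_bulge_count == 1
        assert rep.max_asymmetric_bulge_size == 1

    def test_four_mismatches_counted(self):
        # 4 scattered 1x1 internal loops
        cols = "(((.(((.(((.(((.((("
        left = cols + ".."
        right = cols.replace("(", ")")[::-1] + ".."
        structure = left + "." * 8 + right
        rep = evaluate_duplex(structure, (0, 21), (29, 29 + 21))
        assert rep.mismatch_count == 4
        assert rep.max_consecutive_mismatches == 1
        assert rep.asymmetric_bulge_count == 0

    def test_overlapping_spans_rejected(self):
        structure, mir, star = _perfect_hairpin_structure()
        with pytest.raises(ValueError):
            evaluate_duplex(structure, mir, (mir[0] + 1, mir[1] + 1))

    def test_oracle_equivalence_sample(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            case = random_duplex_case(rng, mir_is_left=bool(rng.integers(2)))
            rep = evaluate_duplex(case.structure, case.mir_span, case.star_span)
            assert rep.mismatch_count == case.mismatch_count
            assert rep.max_consecutive_mismatches == case.max_run
            assert rep.asymmetric_bulge_count == case.bulge_count
            assert rep.max_asymmetric_bulge_size == case.max_bulge
            assert rep.overhang_3p_ok == case.overhang_ok
            assert rep.opposite_arms_ok == case.opposite_ok


class TestInferStarSpan:
    def test_star_inferred_with_overhang(self):
        structure, mir, star = _perfect_hairpin_structure()
        assert infer_star_span(structure, mir) == star

    def test_unpaired_candidate_has_no_star(self):
        assert infer_star_span("." * 40, (5, 26)) is None


class TestClassification:
    def _ok_duplex(self):
        return DuplexReport(0, 0, 0, 0, True, True)

    def _metrics(self, mfei):
        return compute_metrics(-mfei * 40.0, length=100, gc=40.0)

    def test_all_pass(self):
        v = classify_candidate(self._ok_duplex(), self._metrics(1.2), True)
        assert v.passed and v.failed == ()

    def test_mfei_strictly_above_threshold(self):
        v = classify_candidate(self._ok_duplex(), self._metrics(0.8), True)
        assert not v.passed and v.failed == ("mfei",)

    def test_unobserved_star_fails_first_criterion(self):
        v = classify_candidate(self._ok_duplex(), self._metrics(1.5), False)
        assert v.failed == ("star_detected",)

    def test_mismatch_bounds(self):
        d = DuplexReport(4, 1, 0, 0, True, True)
        assert classify_candidate(d, self._metrics(1.5), True).failed == ("duplex_mismatches",)
        d = DuplexReport(3, 3, 0, 0, True, True)
        assert classify_candidate(d, self._metrics(1.5), True).passed

    def test_bulge_bounds(self):
        d = DuplexReport(0, 0, 2, 1, True, True)
        assert classify_candidate(d, self._metrics(1.5), True).failed == ("asymmetric_bulges",)
        d = DuplexReport(0, 0, 1, 3, True, True)
        assert classify_candidate(d, self._metrics(1.5), True).failed == ("asymmetric_bulges",)
        d = DuplexReport(0, 0, 1, 2, True, True)
        assert classify_candidate(d, self._metrics(1.5), True).passed


class TestWindowExtraction:
    GENOME = {"c1": "A" * 300 + "GGGAAAACCC" + "A" * 300}

    def test_window_arithmetic(self):
        locus = LocusHit("c1", 300, 321, "+", "G" * 10 + "A" * 4 + "C" * 7)
        wins = extract_precursor_windows(self.GENOME, locus, (50,))
        (w,) = wins
        assert w.window_start == 250 and w.window_end == 371
        assert len(w.sequence) == 121 and w.mir_span == (50, 71)

    def test_truncation_at_contig_start(self):
        locus = LocusHit("c1", 5, 26, "+", "A" * 21)
        (w,) = extract_precursor_windows(self.GENOME, locus, (50,))
        assert w.window_start == 0 and w.mir_span == (5, 26)

    def test_minus_strand_orientation(self):
        genome = {"c1": "TTTT" + "GGGTTAACCC" + "TTTT"}
        locus = LocusHit("c1", 4, 14, "-", "GGGTTAACCC")
        (w,) = extract_precursor_windows(genome, locus, (4,))
        # the window reads 5'->3' on the minus strand
        from stemloop.seqs import revcomp

        assert w.sequence == revcomp(genome["c1"])
        assert w.sequence[w.mir_span[0] : w.mir_span[1]] == "GGGTTAACCC"
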