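"""Read classification (known/conserved/novel), genome mapping, naming."""

import numpy as np
import pytest

from stemloop.annotate import (
    HairpinRecord,
    LocusHit,
    assign_names,
    find_conserved_candidates,
    map_to_genome,
    match_known,
    parse_family,
)
from stemloop.seqs import hamming, revcomp


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
    )
    def test_distances(self, a, b, d):
        assert hamming(a, b) == d

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            hamming("ACGT", "ACG")


class TestKnownMatching:
    KNOWN = {"bra-miR9001-5p": "UGACCGAGUAGACCGAUAGUC", "bra-miR9002": "ACGGCUACCUUGUUACGACUU"}

    def test_exact_identity_only(self):
        reads = ["TGACCGAGTAGACCGATAGTC", "TGACCGAGTAGACCGATAGTA"]
        out = match_known(reads, self.KNOWN)
        assert out == {"TGACCGAGTAGACCGATAGTC": ["bra-miR9001-5p"]}

    def test_duplicate_sequences_report_all_names(self):
        known = {"n1": "ACGTACGTACGTACGTACGTA", "n2": "ACGTACGTACGTACGTACGTA"}
        out = match_known(["ACGTACGTACGTACGTACGTA"], known)
        assert out["ACGTACGTACGTACGTACGTA"] == ["n1", "n2"]

    def test_empty_set(self):
        assert match_known(["ACGT"], {}) == {}


class TestGenomeMapping:
    def test_planted_read_single_hit(self):
        read = "TGACCGAGTAGACCGATAGTC"
        genome = {"c1": "A" * 50 + read + "A" * 50}
        hits = map_to_genome([read], genome)
        assert hits[read] == [LocusHit("c1", 50, 71, "+", read)]

    def test_two_loci_are_both_reported(self):
        read = "TGACCGAGTAGACCGATAGTC"
        genome = {"c1": "A" * 10 + read + "T" * 30 + read + "A" * 10}
        assert [h.start for h in map_to_genome([read], genome)[read]] == [10, 61]

    def test_minus_strand_hit(self):
        read = "TGACCGAGTAGACCGATAGTC"
        genome = {"c1": "A" * 20 + revcomp(read) + "A" * 20}
        (hit,) = map_to_genome([read], genome)[read]
        assert hit.strand == "-" and hit.start == 20

    def test_unmapped_and_repetitive_dropped(self):
        read = "ACGTACGTACGTACGTACGTA"
        genome = {"c1": ("T" * 5 + read) * 25}
        out = map_to_genome([read, "GGGCCCGGGCCCGGGCCCGGG"], genome, max_hits=20)
        assert out == {}


class TestConservedMatching:
    PLANT = {
        "ath-miR156a-5p": "TGACAGAAGAGAGTGAGCACA",
        "osa-miR156b-5p": "TGACAGAAGAGAGTGAGCACC",
        "ath-miR172a": "AGAATCTTGATGATGCTGCAT",
    }

    def test_within_three_mismatches_is_conserved(self):
        read = "TGACAGAAGAGAGTGAGCTCA"  # 1 mm to miR156a
        conserved, novel = find_conserved_candidates([read], self.PLANT)
        assert read in conserved and conserved[read].family == "miR156"
        assert conserved[read].mismatches == 1

    def test_four_mismatches_is_novel(self):
        read = "TGACAGAAGAGAGTGAGGGGG"  # 4 mm to every reference
        conserved, novel = find_conserved_candidates([read], self.PLANT)
        assert novel == [read]

    def test_equal_length_required(self):
        read = "TGACAGAAGAGAGTGAGCAC"  # 20 nt: no equal-length reference
        conserved, novel = find_conserved_candidates([read], self.PLANT)
        assert novel == [read]

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        refs = {
            f"ath-miR{i}": "".join(rng.choice(list("ACGT"), size=21)) for i in range(20)
        }
        reads = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(120)]
        conserved, novel = find_conserved_candidates(reads, refs)
        for read in reads:
            best = min(hamming(read, s) for s in refs.values())
            assert (read in conserved) == (best <= 3)
            if read in conserved:
                assert conserved[read].mismatches == best

    def test_tie_prefers_lexicographic_family(self):
        refs = {"zma-miR399a": "A" * 21, "ath-miR166b": "A" * 20 + "T"}
        read = "A" * 20 + "C"  # 1 mm to both
        conserved, _ = find_conserved_candidates([read], refs)
        assert conserved[read].family == "miR166"
        assert conserved[read].tied_families == ("miR166", "miR399")


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("ath-miR156a-5p", "miR156"),
            ("bra-miR1885b", "miR1885"),
            ("xxx-miRn12-3p", "miRn12"),
            ("osa-miR396e-3p", "miR396"),
        ],
    )
    def test_families(self, name, family):
        assert parse_family(name) == family


def _record(start, mature, star, arm="5p", family=None, known=None, observed=True):
    return HairpinRecord(
        chrom="c1", start=start, end=start + 121, strand="+",
        mature_seq=mature, mature_arm=arm, star_seq=star,
        star_observed=observed, family=family, known_name=known,
    )


class TestNaming:
    def test_arms_and_determinism(self):
        recs = [_record(100, "G" * 21, "C" * 21)]
        out = assign_names(recs, species="xxx")
        assert [m.name for m in out] == ["xxx-miRn1-5p", "xxx-miRn1-3p"]
        assert out[0].sequence == "G" * 21 and out[1].sequence == "C" * 21
        # input order must not matter
        again = assign_names(list(reversed(recs)), species="xxx")
        assert [m.name for m in again] == [m.name for m in out]

    def test_submembers_numbered_in_coordinate_order(self):
        recs = [
            _record(500, "G" * 21, "C" * 21),
            _record(100, "G" * 21, "C" * 21),
        ]
        out = assign_names(recs, species="xxx")
        names = {m.name: m for m in out}
        assert set(names) == {
            "xxx-miRn1-1-5p", "xxx-miRn1-1-3p", "xxx-miRn1-2-5p", "xxx-miRn1-2-3p"
        }
        assert all(m.submember_index in (1, 2) for m in out)

    def test_predicted_partner_gets_P_prefix(self):
        recs = [_record(100, "G" * 21, "C" * 21, observed=False)]
        out = assign_names(recs, species="xxx")
        assert out[0].name == "xxx-miRn1-5p" and not out[0].predicted_only_flag
        assert out[1].name == "P-xxx-miRn1-3p" and out[1].predicted_only_flag

    def test_conserved_letters_per_family(self):
        recs = [
            _record(100, "G" * 21, "C" * 21, family="miR156"),
            _record(300, "GC" * 10 + "G", "CG" * 10 + "C", family="miR156"),
            _record(500, "GGC" * 7, "GCC" * 7, family="miR172"),
        ]
        out = assign_names(recs, species="bca")
        names = [m.name for m in out]
        assert "bca-miR156a-5p" in names and "bca-miR156b-5p" in names
        assert "bca-miR172-5p" in names  # single member: no letter

    def test_p5_style(self):
        out = assign_names([_record(100, "G" * 21, "C" * 21)], arm_style="p5")
        assert [m.name for m in out] == ["xxx-miRn1-p5", "xxx-miRn1-p3"]

    def test_3p_arm_mature(self):
        out = assign_names([_record(100, "G" * 21, "C" * 21, arm="3p")])
        assert out[0].name.endswith("-3p") and out[1].name.endswith("-5p")
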