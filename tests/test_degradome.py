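"""Degradome mapping, t-plot categories, target alignment and calling."""

import numpy as np
import pytest

from stemloop.degradome import (
    DegradomeProfile,
    HomologyEntry,
    align_mir_target,
    assign_category,
    call_targets,
    check_cleavage_position,
    emit_tplot,
    map_degradome_reads,
    score_duplex,
)
from stemloop.seqs import revcomp

MIR = "TGACCGAGTAGACCGATAGTC"  # 21 nt


def _profile(counts, tid="T1", length=2000):
    p = DegradomeProfile(tid, length)
    for pos, c in counts.items():
        p.add(pos, c)
    return p


class TestMapping:
    def test_planted_position(self):
        t = "A" * 553 + "GATTACAGATTACAGATTACA" + "A" * 500
        reads = [(t[553:573], 5)]
        profiles = map_degradome_reads(reads, {"T1": t})
        assert profiles["T1"].count_at(553) == 5

    def test_multi_mapping_counts_on_both(self):
        window = "GATTACAGATTACAGATTACACGCG"
        t1 = "C" * 100 + window + "C" * 100
        t2 = "G" * 50 + window + "G" * 150
        profiles = map_degradome_reads([(window[:20], 3)], {"T1": t1, "T2": t2})
        assert profiles["T1"].count_at(100) == 3
        assert profiles["T2"].count_at(50) == 3
        assert 100 in profiles["T1"].multi_mapped

    def test_one_mismatch_is_unmapped(self):
        t = "A" * 100 + "GATTACAGATTACAGATTACA" + "A" * 100
        read = "GATTACAGATTACAGATTACA".replace("C", "T", 1)[:20]
        profiles = map_degradome_reads([(read, 1)], {"T1": t})
        assert profiles["T1"].position_counts == {}

    def test_short_reads_skipped(self):
        t = "GATTACAGATTACAGATTACA" * 3
        profiles = map_degradome_reads([("GATTACAGATTACA", 1)], {"T1": t})
        assert profiles["T1"].position_counts == {}


class TestCategories:
    def test_unique_maximum_above_one(self):
        p = _profile({553: 5, 599: 1, 600: 1})
        assert assign_category(p, 553) == 0

    def test_shared_maximum(self):
        p = _profile({553: 5, 599: 5})
        assert assign_category(p, 553) == 1

    def test_single_read_site(self):
        p = _profile({553: 1, 599: 5})
        assert assign_category(p, 553) == 4

    def test_above_median_below_max(self):
        p = _profile({10: 10, 20: 4, 30: 1, 40: 1, 50: 1})
        assert assign_category(p, 20) == 2  # median 1, below max 10

    def test_at_or_below_median(self):
        p = _profile({10: 10, 20: 4, 30: 2, 40: 4, 50: 6})
        assert assign_category(p, 30) == 3  # median 4, count 2 > 1

    def test_no_evidence_raises(self):
        with pytest.raises(ValueError):
            assign_category(_profile({10: 1}), 20)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(1, 30))
            counts = {}
            for pos in rng.choice(1000, size=n, replace=False):
                counts[int(pos)] = int(rng.integers(1, 12))
            p = _profile(counts)
            site = int(rng.choice(list(counts)))
            got = assign_category(p, site)
            assert got == _oracle_category(counts, site)


def _oracle_category(counts, site):
    values = sorted(counts.values())
    c = counts[site]
    maximum = values[-1]
    mid = len(values) // 2
    median = (
        values[mid] if len(values) % 2 == 1 else (values[mid - 1] + values[mid]) / 2
    )
    if c == 1:
        return 4
    if c == maximum and values.count(maximum) == 1:
        return 0
    if c == maximum:
        return 1
    if c > median:
        return 2
    return 3


class TestAlignmentScoring:
    def test_perfect_reverse_complement_scores_zero(self):
        score, labels = score_duplex(MIR, revcomp(MIR))
        assert score == 0.0 and set(labels) == {"|"}

    def test_gu_wobble_in_core_scores_one(self):
        window = list(revcomp(MIR))
        # miRNA position 5 faces window index L-5; make a G:U wobble
        k = 5
        assert MIR[k - 1] == "C"
        # C cannot wobble; use a position where the miRNA base is G or T
        k = next(i + 1 for i, b in enumerate(MIR) if b == "G" and 2 <= i + 1 <= 13)
        window[len(MIR) - k] = "T"  # G:U pair on the RNA duplex
        score, labels = score_duplex(MIR, "".join(window))
        assert score == 1.0  # 0.5 doubled in the core region
        assert labels.count("o") == 1

    def test_mismatch_outside_core_scores_one(self):
        window = list(revcomp(MIR))
        k = 20  # outside positions 2-13
        old = window[len(MIR) - k]
        window[len(MIR) - k] = {"A": "C", "C": "A", "G": "A", "T": "C"}[old]
        score, labels = score_duplex(MIR, "".join(window))
        assert score == 1.0 and labels.count("x") == 1

    def test_scan_finds_planted_site(self):
        t = "A" * 400 + revcomp(MIR) + "A" * 400
        (aln,) = align_mir_target("mir", MIR, "T1", t)
        assert (aln.binding_start, aln.binding_end) == (400, 421)
        assert aln.predicted_cleavage_site == 400 + 21 - 10
        assert aln.score == 0.0


class TestCleavagePosition:
    def test_mirna_anchored_default(self):
        # binding region [100, 121): sites opposite miRNA positions 9/10
        assert check_cleavage_position(100, 121, 112)  # opposite position 9
        assert check_cleavage_position(100, 121, 111)  # opposite position 10
        assert not check_cleavage_position(100, 121, 108)

    def test_five_prime_counting(self):
        # 1-based 9th/10th nt of the region counted from its 5' end
        assert check_cleavage_position(99, 120, 107, counting="five_prime")
        assert check_cleavage_position(99, 120, 108, counting="five_prime")
        assert not check_cleavage_position(99, 120, 114, counting="five_prime")

    def test_outside_region_false(self):
        assert not check_cleavage_position(100, 121, 121)

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            check_cleavage_position(0, 21, 10, counting="bogus")


class TestCalling:
    def _setup(self, site_offset=11):
        t = "C" * 300 + revcomp(MIR) + "C" * 300
        aln = align_mir_target("mir-1", MIR, "T1", t)[0]
        site = aln.binding_start + site_offset  # offset 11 = opposite miRNA 10
        profile = _profile({site: 8, 40: 1, 50: 1}, length=len(t))
        return aln, profile, site

    def test_planted_site_called_category_zero(self):
        aln, profile, site = self._setup()
        calls = call_targets([aln], {"T1": profile},
                             {"T1": HomologyEntry("AT1G01010", True)})
        (c,) = calls
        assert c.cleavage_site == site + 1 and c.category == 0
        assert c.homolog == "AT1G01010" and c.conserved_flag

    def test_peak_off_slice_site_not_called(self):
        aln, _, _ = self._setup()
        bad = _profile({aln.binding_start + 2: 9}, length=700)
        assert call_targets([aln], {"T1": bad}) == []

    def test_missing_homology_map_is_advisory(self):
        aln, profile, _ = self._setup()
        (c,) = call_targets([aln], {"T1": profile}, homology_map=None)
        assert c.homolog is None and not c.conserved_flag

    def test_tplot_table(self):
        profile = _profile({5: 3, 9: 1})
        frame = emit_tplot(profile, sites=[5])
        assert bool(frame.loc[frame.position == 6, "is_site"].item())
        assert list(frame.columns) == ["position", "reads", "is_site"]
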