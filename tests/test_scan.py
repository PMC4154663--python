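"""Motif scanning, pair classification and double-calling."""

import numpy as np
import pytest

import tcfscan as t
from tcfscan.scan import MotifHit

from conftest import oracle_pairs, oracle_scan, random_dna, rc


def hit(kind, start, end, strand, seq_id="s", score=10.0):
    return MotifHit(kind, seq_id, start, end, strand, score)


class TestScanMotifs:
    def test_poly_a_has_no_helper_hits(self, helper_pwm):
        assert t.scan_motifs("s", "A" * 200, helper_pwm, 6.5) == []

    def test_planted_consensus_found_at_position(self, helper_pwm):
        cons = helper_pwm.consensus()
        seq = "A" * 37 + cons + "A" * 30
        hits = [h for h in t.scan_motifs("s", seq, helper_pwm, 6.5) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].start == 37
        assert hits[0].end == 37 + helper_pwm.length
        assert hits[0].score == pytest.approx(t.max_score(helper_pwm))

    def test_short_sequence_yields_empty(self, hmg_pwm):
        assert t.scan_motifs("s", "ACGT", hmg_pwm, 0.0) == []

    def test_empty_name_rejected(self, hmg_pwm):
        with pytest.raises(ValueError, match="name"):
            t.scan_motifs("", "ACGT" * 10, hmg_pwm, 0.0)

    def test_non_acgt_windows_skipped(self, helper_pwm):
        cons = helper_pwm.consensus()
        seq = "A" * 10 + "N" + cons + "N" + "A" * 10
        hits = t.scan_motifs("s", seq, helper_pwm, 6.5)
        assert [h.start for h in hits if h.strand == "+"] == [11]

    @pytest.mark.parametrize("profile", ["figure1", "stringent", "relaxed"])
    def test_equals_bruteforce_oracle(self, hmg_pwm, helper_pwm, profile):
        thresholds = t.get_profile(profile)
        rng = np.random.default_rng(hash(profile) % 2**31)
        for _ in range(10):
            seq = random_dna(rng, 500)
            for pwm, cutoff in (
                (hmg_pwm, thresholds.hmg_cutoff),
                (helper_pwm, thresholds.helper_cutoff),
            ):
                got = sorted(
                    (h.start, h.strand, round(h.score, 9))
                    for h in t.scan_motifs("s", seq, pwm, cutoff)
                )
                assert got == oracle_scan(seq, pwm.weights.tolist(), cutoff)

    def test_mixed_case_scans_identically(self, helper_pwm):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        mixed = "".join(
            b.lower() if rng.random() < 0.5 else b for b in seq
        )
        a = t.scan_motifs("s", seq, helper_pwm, 3.0)
        b = t.scan_motifs("s", mixed, helper_pwm, 3.0)
        assert a == b


class TestClassifyPair:
    """Worked examples of the four orientations."""

    def test_kk0_junction(self):
        # forward HMG immediately followed by the Helper read on the
        # opposite strand: KK with spacer 0
        o, s = t.classify_pair(
            hit("HMG", 100, 111, "+"), hit("Helper", 111, 118, "-")
        )
        assert (o, s) == ("KK", 0)

    def test_ak6_helper_upstream_same_strand(self):
        o, s = t.classify_pair(
            hit("HMG", 100, 111, "+"), hit("Helper", 87, 94, "+")
        )
        assert (o, s) == ("AK", 6)

    def test_ff0_helper_immediately_downstream(self):
        o, s = t.classify_pair(
            hit("HMG", 100, 111, "+"), hit("Helper", 111, 118, "+")
        )
        assert (o, s) == ("FF", 0)

    def test_rw_upstream_opposite_strand(self):
        o, s = t.classify_pair(
            hit("HMG", 100, 111, "+"), hit("Helper", 91, 98, "-")
        )
        assert (o, s) == ("RW", 2)

    def test_minus_strand_hmg_flips_upstream_downstream(self):
        # genomic-left Helper is downstream of a '-' HMG reading
        o, s = t.classify_pair(
            hit("HMG", 100, 111, "-"), hit("Helper", 90, 97, "-")
        )
        assert (o, s) == ("FF", 3)

    def test_overlap_is_not_a_pair(self):
        with pytest.raises(t.NotAPair):
            t.classify_pair(hit("HMG", 100, 111, "+"), hit("Helper", 105, 112, "+"))

    def test_different_sequences_rejected(self):
        with pytest.raises(ValueError, match="different sequences"):
            t.classify_pair(
                hit("HMG", 0, 11, "+", seq_id="a"),
                hit("Helper", 20, 27, "+", seq_id="b"),
            )

    def test_orientation_total_over_disjoint_geometries(self):
        """Every disjoint geometry maps to exactly one of the four labels."""
        seen = set()
        for hmg_strand in "+-":
            for helper_strand in "+-":
                for helper_start in (80, 120):  # upstream / downstream of 100-111
                    o, _ = t.classify_pair(
                        hit("HMG", 100, 111, hmg_strand),
                        hit("Helper", helper_start, helper_start + 7, helper_strand),
                    )
                    assert o in t.ORIENTATIONS
                    seen.add((hmg_strand, helper_strand, helper_start, o))
        assert len({x[3] for x in seen}) == 4


class TestFindPairs:
    def test_flanked_hmg_yields_ak_and_ff(self, hmg_pwm, helper_pwm, stringent):
        cons_h = helper_pwm.consensus()
        cons_m = hmg_pwm.consensus()
        seq = "A" * 20 + cons_h + "AAAA" + cons_m + "AAAAAA" + cons_h + "A" * 20
        pairs = t.find_pairs("s", seq, hmg_pwm, helper_pwm, stringent)
        assert sorted((p.orientation, p.spacer) for p in pairs) == [
            ("AK", 4),
            ("FF", 6),
        ]

    def test_palindromic_helper_double_called(self, hmg_pwm, helper_pwm, stringent):
        # YGCCGGCR downstream of the HMG site reads as Helper on both
        # strands at a 1-bp offset: FF1 + KK0 sharing the physical site
        seq = "A" * 20 + hmg_pwm.consensus() + "TGCCGGCA" + "A" * 20
        pairs = t.find_pairs("s", seq, hmg_pwm, helper_pwm, stringent)
        assert sorted((p.orientation, p.spacer) for p in pairs) == [
            ("FF", 1),
            ("KK", 0),
        ]
        assert all(p.double_call for p in pairs)
        assert len({p.footprint_key for p in pairs}) == 1

    def test_plain_kk0_junction_not_double_called(
        self, hmg_pwm, helper_pwm, stringent
    ):
        # the HMG-TGGCGGCG junction is a single KK0 at the stringent
        # profile: its forward 7-mer GGCGGCG misses the Helper consensus
        # at two positions
        seq = "A" * 20 + hmg_pwm.consensus() + "TGGCGGCG" + "A" * 20
        pairs = t.find_pairs("s", seq, hmg_pwm, helper_pwm, stringent)
        assert [(p.orientation, p.spacer, p.double_call) for p in pairs] == [
            ("KK", 0, False)
        ]

    def test_equals_all_pairs_oracle(self, hmg_pwm, helper_pwm, relaxed):
        rng = np.random.default_rng(42)
        for _ in range(10):
            seq = random_dna(rng, 1000)
            got = sorted(
                (
                    p.hmg.start, p.hmg.strand, p.helper.start, p.helper.strand,
                    p.orientation, p.spacer,
                )
                for p in t.find_pairs("s", seq, hmg_pwm, helper_pwm, relaxed)
            )
            expected = oracle_pairs(
                seq, hmg_pwm.weights.tolist(), helper_pwm.weights.tolist(),
                relaxed.hmg_cutoff, relaxed.helper_cutoff, 15,
            )
            assert got == expected

    def test_strand_symmetry(self, hmg_pwm, helper_pwm, relaxed):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_dna(rng, 800)
            fwd = t.find_pairs("s", seq, hmg_pwm, helper_pwm, relaxed)
            rev = t.find_pairs("s", rc(seq), hmg_pwm, helper_pwm, relaxed)
            key = lambda ps: sorted(
                (p.orientation, p.spacer,
                 round(p.hmg.score, 6), round(p.helper.score, 6))
                for p in ps
            )
            assert key(fwd) == key(rev)
            # coordinates mirror
            mirrored = sorted(len(seq) - p.end for p in rev)
            assert mirrored == sorted(p.start for p in fwd)

    def test_raising_cutoffs_never_adds_pairs(self, hmg_pwm, helper_pwm):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 2000)
        counts = []
        for profile in ("relaxed", "stringent", "figure1"):
            counts.append(
                len(t.find_pairs("s", seq, hmg_pwm, helper_pwm, t.get_profile(profile)))
            )
        assert counts[0] >= counts[1] >= counts[2]


class TestAnnotate:
    def test_ordered_motif_table(self, hmg_pwm, helper_pwm):
        cons_m, cons_h = hmg_pwm.consensus(), helper_pwm.consensus()
        seq = "A" * 10 + cons_m + "AAA" + cons_h + "A" * 10
        rows = t.annotate_regions(
            {"crm": seq}, hmg_pwm, helper_pwm, t.get_profile("figure1")
        )
        assert [r["motif"] for r in rows] == ["HMG", "Helper"]
        assert rows[0]["start_1based"] == 11
        assert rows[1]["gap_to_previous"] == 3
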