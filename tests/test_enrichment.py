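"""Pair counting per orientation x spacer bin and fold enrichment."""

import numpy as np
import pandas as pd
import pytest

import tcfscan as t
from tcfscan.background import Region
from tcfscan.enrichment import PairCounts, _empty_bins

from conftest import oracle_pairs, random_dna


def region(seq, seq_id="chr", start=0, cls="intergenic"):
    return Region(
        t.GenomicInterval(seq_id, start, start + len(seq), "r"), cls, seq
    )


def counts_from_bins(bins_dict, max_spacer=15, **kw):
    pc = PairCounts(max_spacer, _empty_bins(max_spacer), **kw)
    for (o, s), v in bins_dict.items():
        pc.bins.loc[o, s] = v
    for fam in ((("AK", "RW")), (("FF", "KK"))):
        pc.venn[fam] = {fam[0]: 0, fam[1]: 0, "shared": 0}
    return pc


class TestCountInRegions:
    def test_planted_ff0_pairs_only(self, hmg_pwm, helper_pwm, stringent):
        cassette = hmg_pwm.consensus() + helper_pwm.consensus()
        regions = [
            region("T" * 30 + cassette + "T" * 30) for _ in range(3)
        ]
        counts = t.count_in_regions(regions, hmg_pwm, helper_pwm, stringent)
        assert counts.bins.loc["FF", 0] == 3
        assert counts.total_pairs == 3
        assert (counts.bins.values.sum() - counts.bins.loc["FF", 0]) == 0

    def test_batch_additivity(self, hmg_pwm, helper_pwm, relaxed):
        rng = np.random.default_rng(13)
        regions = [region(random_dna(rng, 600)) for _ in range(8)]
        whole = t.count_in_regions(regions, hmg_pwm, helper_pwm, relaxed)
        a = t.count_in_regions(regions[:4], hmg_pwm, helper_pwm, relaxed)
        b = t.count_in_regions(regions[4:], hmg_pwm, helper_pwm, relaxed)
        merged = a.add(b)
        assert merged.bins.equals(whole.bins)
        assert merged.hmg_total == whole.hmg_total
        assert merged.helper_total == whole.helper_total
        assert merged.venn == whole.venn

    def test_matches_scanner_oracle_summed_over_regions(
        self, hmg_pwm, helper_pwm, relaxed
    ):
        rng = np.random.default_rng(14)
        regions = [region(random_dna(rng, 500)) for _ in range(6)]
        counts = t.count_in_regions(regions, hmg_pwm, helper_pwm, relaxed)
        expected = _empty_bins(15)
        for r in regions:
            for *_, o, s in oracle_pairs(
                r.sequence, hmg_pwm.weights.tolist(), helper_pwm.weights.tolist(),
                relaxed.hmg_cutoff, relaxed.helper_cutoff, 15,
            ):
                expected.loc[o, s] += 1
        assert counts.bins.equals(expected)

    def test_region_without_sequence_rejected(self, hmg_pwm, helper_pwm, stringent):
        bad = Region(t.GenomicInterval("c", 0, 10, "r"), "intergenic", "")
        with pytest.raises(ValueError, match="no sequence"):
            t.count_in_regions([bad], hmg_pwm, helper_pwm, stringent)

    def test_unpaired_motif_totals(self, hmg_pwm, helper_pwm, stringent):
        # one paired HMG+Helper, plus one lone HMG far away
        seq = (
            "T" * 20 + hmg_pwm.consensus() + helper_pwm.consensus()
            + "T" * 60 + hmg_pwm.consensus() + "T" * 20
        )
        counts = t.count_in_regions([region(seq)], hmg_pwm, helper_pwm, stringent)
        assert counts.hmg_total == 2
        assert counts.hmg_unpaired_total == 1
        assert counts.helper_total == 1
        assert counts.helper_unpaired_total == 0


class TestComputeEnrichment:
    def test_null_gives_unit_folds(self):
        bins = {("FF", 0): 4, ("AK", 6): 2}
        bound = counts_from_bins(bins, hmg_total=10, helper_total=20)
        bg = [counts_from_bins(bins, hmg_total=10, helper_total=20)] * 3
        table = t.compute_enrichment(bound, bg)
        assert table.fold.loc["FF", 0] == 1.0
        assert table.fold.loc["AK", 6] == 1.0
        assert table.aggregates["all_pairs_fold"] == 1.0
        assert table.aggregates["hmg_only_fold"] == 1.0
        assert table.aggregates["helper_only_fold"] == 1.0

    def test_fold_arithmetic(self):
        bound = counts_from_bins({("FF", 0): 6})
        bg = [counts_from_bins({("FF", 0): k}) for k in (1, 2, 3)]
        table = t.compute_enrichment(bound, bg)
        assert table.fold.loc["FF", 0] == pytest.approx(3.0)
        # fold * random_mean recovers the bound count
        assert table.fold.loc["FF", 0] * table.random_mean.loc["FF", 0] == 6

    def test_zero_background_mean_is_nan_unless_pseudocount(self):
        bound = counts_from_bins({("KK", 3): 5})
        bg = [counts_from_bins({})]
        table = t.compute_enrichment(bound, bg)
        assert np.isnan(table.fold.loc["KK", 3])
        with_pc = t.compute_enrichment(bound, bg, pseudocount=0.5)
        assert with_pc.fold.loc["KK", 3] == pytest.approx(5.5 / 0.5)

    def test_doubling_background_halves_folds(self):
        bins = {("FF", 0): 8, ("RW", 2): 4}
        bound = counts_from_bins(bins)
        bg1 = [counts_from_bins({("FF", 0): 2, ("RW", 2): 2})]
        bg2 = [counts_from_bins({("FF", 0): 4, ("RW", 2): 4})]
        t1 = t.compute_enrichment(bound, bg1)
        t2 = t.compute_enrichment(bound, bg2)
        assert np.allclose(
            t2.fold.values[np.isfinite(t2.fold.values)],
            t1.fold.values[np.isfinite(t1.fold.values)] / 2,
        )

    def test_shape_mismatch_rejected(self):
        bound = counts_from_bins({}, max_spacer=15)
        with pytest.raises(ValueError, match="max_spacer"):
            t.compute_enrichment(bound, [counts_from_bins({}, max_spacer=10)])


class TestGroupFold:
    def make_table(self):
        bound = counts_from_bins({("FF", 0): 6, ("FF", 1): 2, ("AK", 3): 4})
        bg = [counts_from_bins({("FF", 0): 2, ("FF", 1): 2, ("AK", 3): 1})]
        return t.compute_enrichment(bound, bg)

    def test_single_bin_group_equals_bin_fold(self):
        table = self.make_table()
        assert t.group_fold(table, [("FF", 0)]) == table.fold.loc["FF", 0]

    def test_all_bins_group_equals_aggregate(self):
        table = self.make_table()
        all_bins = [(o, s) for o in t.ORIENTATIONS for s in range(16)]
        assert t.group_fold(table, all_bins) == pytest.approx(
            table.aggregates["all_pairs_fold"]
        )

    def test_favored_group_is_ratio_of_summed_counts(self):
        table = self.make_table()
        group = t.spacer_range_group({"FF": (0, 2), "AK": (0, 6)})
        # hand-summed: bound 6+2+4 = 12, background 2+2+1 = 5
        assert t.group_fold(table, group) == pytest.approx(12 / 5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            t.group_fold(self.make_table(), [])


class TestVennConservation:
    def test_double_calls_counted_under_both_labels(
        self, hmg_pwm, helper_pwm, stringent
    ):
        # two palindromic (double-called) plants and one plain FF0
        pal = hmg_pwm.consensus() + "TGCCGGCA"
        plain = hmg_pwm.consensus() + helper_pwm.consensus()
        seq = "T" * 20 + pal + "T" * 40 + pal + "T" * 40 + plain + "T" * 20
        counts = t.count_in_regions([region(seq)], hmg_pwm, helper_pwm, stringent)
        assert counts.bins.loc["FF", 1] == 2
        assert counts.bins.loc["KK", 0] == 2
        assert counts.bins.loc["FF", 0] == 1
        venn = counts.venn[("FF", "KK")]
        assert venn["shared"] == 2
        assert venn["FF"] == 1
        assert venn["KK"] == 0
        # per-label totals = exclusive + shared
        ff_total = int(counts.bins.loc["FF"].sum())
        kk_total = int(counts.bins.loc["KK"].sum())
        assert ff_total == venn["FF"] + venn["shared"]
        assert kk_total == venn["KK"] + venn["shared"]

    def test_count_once_assigns_best_strand_only(
        self, hmg_pwm, helper_pwm, stringent
    ):
        pal = hmg_pwm.consensus() + "TGCCGGCA"
        seq = "T" * 20 + pal + "T" * 20
        once = t.count_in_regions(
            [region(seq)], hmg_pwm, helper_pwm, stringent, count_once=True
        )
        assert once.total_pairs == 1
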