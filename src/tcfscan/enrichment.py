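"""Orientation x spacer pair counting and fold enrichment.

Fold enrichment is a ratio of raw counts: pairs (or single motifs) found in
the bound regions divided by the mean count over seeded random background
draws of matched total bp. No per-bp density correction is applied when the
final background region overshoots the bp target. Double-called pairs
(semi-palindromic Helper windows) contribute to both of their orientation
labels by default, with the overlap reported separately as Venn counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import BackgroundSample, Region
from .pwm import PWM, ScoreThresholds
from .scan import DOUBLE_CALL_PARTNER, ORIENTATIONS, PairCall, find_pairs, scan_motifs

VENN_FAMILIES = (("AK", "RW"), ("FF", "KK"))


@dataclass
class PairCounts:
    """Counts of pairs and single motifs accumulated over a region set."""

    max_spacer: int
    bins: pd.DataFrame  # index ORIENTATIONS, columns 0..max_spacer
    hmg_total: int = 0
    helper_total: int = 0
    hmg_unpaired_total: int = 0
    helper_unpaired_total: int = 0
    total_bp: int = 0
    # per family: label -> exclusive count; "shared" -> double-called physical sites
    venn: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return int(self.bins.values.sum())

    def add(self, other: "PairCounts") -> "PairCounts":
        if other.max_spacer != self.max_spacer:
            raise ValueError("cannot add counts with different max_spacer")
        merged = PairCounts(
            self.max_spacer,
            self.bins + other.bins,
            self.hmg_total + other.hmg_total,
            self.helper_total + other.helper_total,
            self.hmg_unpaired_total + other.hmg_unpaired_total,
            self.helper_unpaired_total + other.helper_unpaired_total,
            self.total_bp + other.total_bp,
        )
        for fam in VENN_FAMILIES:
            a = self.venn.get(fam, {})
            b = other.venn.get(fam, {})
            merged.venn[fam] = {
                k: a.get(k, 0) + b.get(k, 0)
                for k in set(a) | set(b) | {fam[0], fam[1], "shared"}
            }
        return merged


def _empty_bins(max_spacer: int) -> pd.DataFrame:
    return pd.DataFrame(
        0, index=list(ORIENTATIONS), columns=range(max_spacer + 1), dtype=int
    )


def tally_pairs(pairs: list[PairCall], max_spacer: int) -> PairCounts:
    """Bin a PairCall list by orientation x spacer and compute Venn counts.

    A double-called physical site contributes one count to each of its two
    labels and one to the family's shared (intersection) tally.
    """
    counts = PairCounts(max_spacer, _empty_bins(max_spacer))
    for fam in VENN_FAMILIES:
        counts.venn[fam] = {fam[0]: 0, fam[1]: 0, "shared": 0}
    seen_shared: set = set()
    for p in pairs:
        counts.bins.loc[p.orientation, p.spacer] += 1
        fam = next(f for f in VENN_FAMILIES if p.orientation in f)
        if p.double_call:
            key = p.footprint_key
            if key not in seen_shared:
                seen_shared.add(key)
                counts.venn[fam]["shared"] += 1
        else:
            counts.venn[fam][p.orientation] += 1
    return counts


def count_in_regions(
    regions: list[Region],
    hmg_pwm: PWM,
    helper_pwm: PWM,
    thresholds: ScoreThresholds,
    max_spacer: int = 15,
    count_once: bool = False,
) -> PairCounts:
    """Accumulate per-region find_pairs results into orientation x spacer bins.

    Pairs are confined within a region: no cross-region pairing. Single-motif
    totals count every hit above cutoff (paired or not); the *_unpaired
    totals exclude hits that participate in at least one pair. With
    count_once=True a double-called physical site is assigned only its
    best-scoring Helper strand call (sensitivity-analysis mode).
    """
    total = PairCounts(max_spacer, _empty_bins(max_spacer))
    for fam in VENN_FAMILIES:
        total.venn[fam] = {fam[0]: 0, fam[1]: 0, "shared": 0}
    for k, region in enumerate(regions):
        if region.sequence is None or region.sequence == "":
            raise ValueError(f"region {k} carries no sequence")
        pairs = find_pairs(
            region.interval.seq_id + f"#{k}",
            region.sequence,
            hmg_pwm,
            helper_pwm,
            thresholds,
            max_spacer,
        )
        if count_once:
            best: dict[tuple, PairCall] = {}
            for p in pairs:
                key = p.footprint_key
                if key not in best or p.helper.score > best[key].helper.score:
                    best[key] = p
            pairs = sorted(best.values(), key=lambda p: (p.start, p.end))
        hmg_hits = scan_motifs(
            "r", region.sequence, hmg_pwm, thresholds.hmg_cutoff
        )
        helper_hits = scan_motifs(
            "r", region.sequence, helper_pwm, thresholds.helper_cutoff
        )
        paired_hmg = {(p.hmg.start, p.hmg.strand) for p in pairs}
        paired_helper = {(p.helper.start, p.helper.strand) for p in pairs}
        part = tally_pairs(pairs, max_spacer)
        part.hmg_total = len(hmg_hits)
        part.helper_total = len(helper_hits)
        part.hmg_unpaired_total = sum(
            1 for h in hmg_hits if (h.start, h.strand) not in paired_hmg
        )
        part.helper_unpaired_total = sum(
            1 for h in helper_hits if (h.start, h.strand) not in paired_helper
        )
        part.total_bp = len(region.sequence)
        total = total.add(part)
    return total


def count_in_background(
    sample: BackgroundSample,
    hmg_pwm: PWM,
    helper_pwm: PWM,
    thresholds: ScoreThresholds,
    max_spacer: int = 15,
) -> PairCounts:
    return count_in_regions(sample.chosen, hmg_pwm, helper_pwm, thresholds, max_spacer)


@dataclass
class EnrichmentTable:
    """Bound vs background counts and fold enrichment per orientation x spacer."""

    bound: PairCounts
    random_mean: pd.DataFrame
    fold: pd.DataFrame  # NaN where the background mean is zero
    aggregates: dict[str, float]
    venn: dict[tuple[str, str], dict[str, int]]
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        """Long-form TSV-ready table: one row per orientation x spacer."""
        rows = []
        for o in ORIENTATIONS:
            for s in self.fold.columns:
                rows.append(
                    {
                        "orientation": o,
                        "spacer": s,
                        "bound": int(self.bound.bins.loc[o, s]),
                        "random_mean": float(self.random_mean.loc[o, s]),
                        "fold": float(self.fold.loc[o, s]),
                    }
                )
        return pd.DataFrame(rows)


def _safe_fold(bound, random_mean, pseudocount: float = 0.0):
    b = np.asarray(bound, dtype=float) + pseudocount
    r = np.asarray(random_mean, dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(r > 0, b / np.where(r > 0, r, 1.0), np.nan)
    return f


def compute_enrichment(
    bound_counts: PairCounts,
    background_runs_counts: list[PairCounts],
    pseudocount: float = 0.0,
) -> EnrichmentTable:
    """Fold per bin = bound / mean(background runs), plus aggregates.

    Aggregates: all-pairs fold over the full spacer range, HMG-only and
    Helper-only single-motif folds. A zero background mean yields NaN
    ("undefined") unless a pseudocount is supplied.
    """
    if not background_runs_counts:
        raise ValueError("need at least one background run")
    for c in background_runs_counts:
        if c.max_spacer != bound_counts.max_spacer:
            raise ValueError("background run counted with different max_spacer")
    stack = np.stack([c.bins.values for c in background_runs_counts])
    random_mean = pd.DataFrame(
        stack.mean(axis=0),
        index=bound_counts.bins.index,
        columns=bound_counts.bins.columns,
    )
    fold = pd.DataFrame(
        _safe_fold(bound_counts.bins.values, random_mean.values, pseudocount),
        index=bound_counts.bins.index,
        columns=bound_counts.bins.columns,
    )
    bg_pairs_mean = float(np.mean([c.total_pairs for c in background_runs_counts]))
    bg_hmg_mean = float(np.mean([c.hmg_total for c in background_runs_counts]))
    bg_helper_mean = float(np.mean([c.helper_total for c in background_runs_counts]))
    aggregates = {
        "all_pairs_fold": float(
            _safe_fold(bound_counts.total_pairs, bg_pairs_mean, pseudocount)
        ),
        "hmg_only_fold": float(
            _safe_fold(bound_counts.hmg_total, bg_hmg_mean, pseudocount)
        ),
        "helper_only_fold": float(
            _safe_fold(bound_counts.helper_total, bg_helper_mean, pseudocount)
        ),
        "bound_pairs": float(bound_counts.total_pairs),
        "random_pairs_mean": bg_pairs_mean,
    }
    table = EnrichmentTable(
        bound_counts,
        random_mean,
        fold,
        aggregates,
        bound_counts.venn,
        len(background_runs_counts),
    )
    return table


def group_fold(table: EnrichmentTable, group: list[tuple[str, int]]) -> float:
    """Fold of summed counts over a bin group, e.g. FF0-2 union AK0-6.

    The ratio is of summed counts, not the mean of per-bin folds. Raises on
    an empty group; returns NaN when the summed background mean is zero.
    """
    if not group:
        raise ValueError("empty bin group")
    for o, s in group:
        if o not in table.fold.index or s not in table.fold.columns:
            raise ValueError(f"bin ({o},{s}) not in table")
    bound = sum(int(table.bound.bins.loc[o, s]) for o, s in group)
    rand = sum(float(table.random_mean.loc[o, s]) for o, s in group)
    return float(bound / rand) if rand > 0 else float("nan")


def spacer_range_group(spec: dict[str, tuple[int, int]]) -> list[tuple[str, int]]:
    """Expand {'FF': (0, 2), 'AK': (0, 6)} into explicit (orientation, spacer)
    bins. The favored-configuration group of the genome survey is
    FF spacers 0-2 union AK spacers 0-6."""
    group = []
    for orientation, (lo, hi) in spec.items():
        group.extend((orientation, s) for s in range(lo, hi + 1))
    return group
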