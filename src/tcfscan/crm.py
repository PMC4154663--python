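"""Candidate W-CRM discovery.

Strategy: scan a genome (or chromosome arm) for high-stringency anchor
pairs of one favored configuration — FF with a 1-bp spacer by default,
the configuration most enriched in bound chromatin and most active in
reporters — then, around each anchor, collect additional lower-stringency
pairs and rank candidates by how many such secondary pairs cluster there.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomicInterval
from .pwm import PWM, ScoreThresholds
from .scan import PairCall, find_pairs


@dataclass
class CrmCandidate:
    anchor: PairCall
    window: GenomicInterval
    secondary_pairs: list[PairCall]
    rank_score: int

    @property
    def tiebreak(self) -> float:
        return self.anchor.score_sum + sum(p.score_sum for p in self.secondary_pairs)


def search_anchors(
    genome: dict[str, str],
    hmg_pwm: PWM,
    helper_pwm: PWM,
    stringent: ScoreThresholds,
    anchor_orientation: str = "FF",
    anchor_spacer: int = 1,
) -> list[PairCall]:
    """All pairs matching exactly (anchor_orientation, anchor_spacer) with
    both motifs at or above the stringent cutoffs, per chromosome."""
    if anchor_orientation not in ("AK", "RW", "FF", "KK"):
        raise ValueError(f"invalid anchor orientation {anchor_orientation!r}")
    if anchor_spacer < 0:
        raise ValueError("anchor spacer must be >= 0")
    anchors: list[PairCall] = []
    for chrom, seq in genome.items():
        for pair in find_pairs(
            chrom, seq, hmg_pwm, helper_pwm, stringent, max_spacer=anchor_spacer
        ):
            if pair.orientation == anchor_orientation and pair.spacer == anchor_spacer:
                anchors.append(pair)
    return anchors


def _shift_pair(pair: PairCall, offset: int) -> PairCall:
    from dataclasses import replace

    def shift(hit):
        return replace(hit, start=hit.start + offset, end=hit.end + offset)

    hmg, helper = shift(pair.hmg), shift(pair.helper)
    pair_id = (
        f"{hmg.seq_id}:{hmg.start}{hmg.strand}:"
        f"{helper.start}{helper.strand}:{pair.orientation}{pair.spacer}"
    )
    return replace(pair, hmg=hmg, helper=helper, pair_id=pair_id)


def expand_candidates(
    anchors: list[PairCall],
    genome: dict[str, str],
    hmg_pwm: PWM,
    helper_pwm: PWM,
    relaxed: ScoreThresholds,
    window_halfwidth: int = 500,
    max_spacer: int = 15,
) -> list[CrmCandidate]:
    """Collect relaxed-profile secondary pairs within +-window_halfwidth of
    each anchor midpoint; rank by secondary-pair count (ties broken by
    summed PWM scores); merge overlapping candidate windows, keeping the
    best-ranked anchor and the union of secondary pairs."""
    candidates: list[CrmCandidate] = []
    for anchor in anchors:
        chrom = anchor.hmg.seq_id
        seq = genome[chrom]
        mid = (anchor.start + anchor.end) // 2
        lo = max(0, mid - window_halfwidth)
        hi = min(len(seq), mid + window_halfwidth)
        window = GenomicInterval(chrom, lo, hi, f"crm_{chrom}_{lo}")
        anchor_footprints = {
            (anchor.hmg.start, anchor.hmg.strand, anchor.helper.start)
        }
        secondary = [
            p
            for p in (
                _shift_pair(q, lo)
                for q in find_pairs(
                    chrom, seq[lo:hi], hmg_pwm, helper_pwm, relaxed, max_spacer
                )
            )
            if (p.hmg.start, p.hmg.strand, p.helper.start) not in anchor_footprints
        ]
        candidates.append(CrmCandidate(anchor, window, secondary, len(secondary)))
    candidates = _merge_overlapping(candidates)
    candidates.sort(key=lambda c: (-c.rank_score, -c.tiebreak, c.window.seq_id,
                                   c.window.start))
    return candidates


def _merge_overlapping(candidates: list[CrmCandidate]) -> list[CrmCandidate]:
    """Merge candidates whose windows overlap on the same chromosome.

    The merged candidate keeps the best anchor (highest rank_score, ties by
    tiebreak) and deduplicated secondary pairs over the union window."""
    by_chrom: dict[str, list[CrmCandidate]] = {}
    for c in candidates:
        by_chrom.setdefault(c.window.seq_id, []).append(c)
    merged: list[CrmCandidate] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: c.window.start)
        cluster: list[CrmCandidate] = []
        cluster_end = -1
        for c in group + [None]:
            if c is not None and (not cluster or c.window.start < cluster_end):
                cluster.append(c)
                cluster_end = max(cluster_end, c.window.end)
                continue
            if cluster:
                best = max(cluster, key=lambda x: (x.rank_score, x.tiebreak))
                lo = min(x.window.start for x in cluster)
                hi = max(x.window.end for x in cluster)
                window = GenomicInterval(chrom, lo, hi, f"crm_{chrom}_{lo}")
                seen: set[str] = set()
                secondary = []
                anchor_key = (
                    best.anchor.hmg.start,
                    best.anchor.hmg.strand,
                    best.anchor.helper.start,
                )
                for x in cluster:
                    for p in x.secondary_pairs:
                        key = (p.hmg.start, p.hmg.strand, p.helper.start,
                               p.orientation)
                        if key in seen:
                            continue
                        if (p.hmg.start, p.hmg.strand, p.helper.start) == anchor_key:
                            continue
                        seen.add(key)
                        secondary.append(p)
                merged.append(
                    CrmCandidate(best.anchor, window, secondary, len(secondary))
                )
            if c is not None:
                cluster = [c]
                cluster_end = c.window.end
            else:
                cluster = []
    return merged


def composite_pwm(
    hmg_pwm: PWM, helper_pwm: PWM, spacer: int = 1, orientation: str = "FF"
) -> PWM:
    """Compose a single fixed-spacer matrix from the two motif PWMs.

    Equivalent, up to the composite training set, to training one matrix on
    concatenated site pairs: weights are the two matrices laid end to end
    (Helper strand/side per *orientation*) with zero-weight (uninformative)
    spacer columns between. Useful for single-matrix search tools."""
    import numpy as _np

    if orientation not in ("FF", "AK", "KK", "RW"):
        raise ValueError(f"invalid orientation {orientation!r}")
    helper_w = helper_pwm.weights
    helper_c = helper_pwm.counts
    if orientation in ("KK", "RW"):  # Helper consensus on the opposite strand
        helper_w = helper_w[::-1, ::-1]
        helper_c = helper_c[::-1, ::-1]
    spacer_w = _np.zeros((spacer, 4))
    # spacer counts at background proportions keep the weight formula identity
    n = hmg_pwm.n_train
    spacer_c = _np.tile(hmg_pwm.background * n, (spacer, 1))
    if orientation in ("FF", "KK"):  # Helper downstream of the HMG reading
        blocks_w = [hmg_pwm.weights, spacer_w, helper_w]
        blocks_c = [hmg_pwm.counts, spacer_c, helper_c]
    else:
        blocks_w = [helper_w, spacer_w, hmg_pwm.weights]
        blocks_c = [helper_c, spacer_c, hmg_pwm.counts]
    return PWM(
        f"{orientation}{spacer}-composite",
        _np.vstack(blocks_c),
        n,
        hmg_pwm.background,
        _np.vstack(blocks_w),
    )
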