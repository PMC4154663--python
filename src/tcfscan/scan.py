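"""Bipartite HMG-Helper site scanning and orientation/spacing classification.

TCF/Pangolin binds DNA through two domains: the HMG box, which recognizes an
AT-rich HMG site, and the C-clamp, which recognizes a GC-rich Helper site.
A candidate bipartite binding site is therefore a *pair* of nearby PWM
matches. After normalizing so that the HMG consensus reads 5'->3', the pair
falls into one of four orientation classes depending on whether the Helper
consensus is on the same or the opposite strand, and whether it lies
downstream or upstream of the HMG footprint:

    same strand, downstream  -> FF  (Fast Forward)
    same strand, upstream    -> AK  (Akimbo)
    opposite strand, downstream -> KK  (Knock Knee)
    opposite strand, upstream   -> RW  (Rewind)

The spacer is the number of bp strictly between the two footprints.
Because the Helper consensus is semi-palindromic, some windows score above
cutoff on both strands; such one physical site yields two PairCalls (AK+RW
or FF+KK) flagged double_call, mirroring how aggregate counts present the
overlap of the two labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pwm import BASE_INDEX, PWM, ScoreThresholds, reverse_complement

#: Geometry -> orientation label. Keys are (helper_same_strand_as_hmg,
#: helper_downstream_of_hmg_reading). Relabeling the four geometric classes
#: is a configuration change here, not a scanner change.
ORIENTATION_LABELS: dict[tuple[bool, bool], str] = {
    (True, True): "FF",
    (True, False): "AK",
    (False, True): "KK",
    (False, False): "RW",
}

ORIENTATIONS = ("AK", "RW", "FF", "KK")

#: Sibling label under a Helper double call (same footprints, other strand).
DOUBLE_CALL_PARTNER = {"FF": "KK", "KK": "FF", "AK": "RW", "RW": "AK"}


@dataclass(frozen=True)
class MotifHit:
    """One PWM match. Coordinates are 0-based half-open on the forward
    reference; strand is the strand bearing the consensus reading."""

    motif_kind: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class PairCall:
    """One classified HMG-Helper pair.

    helper_site indexes the physical Helper site: overlapping Helper hits
    (the two strand readings of a semi-palindromic word sit 1 bp apart)
    share one helper_site. A pair is double_call when the same (HMG,
    physical Helper site) also yields the partner-orientation pair (AK<->RW
    or FF<->KK) in the same scan.
    """

    hmg: MotifHit
    helper: MotifHit
    orientation: str
    spacer: int
    double_call: bool = False
    pair_id: str = ""
    helper_site: int = -1

    @property
    def start(self) -> int:
        return min(self.hmg.start, self.helper.start)

    @property
    def end(self) -> int:
        return max(self.hmg.end, self.helper.end)

    @property
    def score_sum(self) -> float:
        return self.hmg.score + self.helper.score

    @property
    def footprint_key(self) -> tuple:
        """Identifies the physical (HMG, Helper site) combination
        irrespective of the Helper strand call."""
        return (
            self.hmg.seq_id,
            self.hmg.start,
            self.hmg.strand,
            self.helper_site,
        )


class NotAPair(Exception):
    """Raised when two hits cannot form a pair (overlapping footprints)."""


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3, anything else to -1."""
    out = np.full(len(sequence), -1, dtype=np.int64)
    for base, idx in BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score every window of len(weights); windows with non-ACGT get NaN."""
    length = weights.shape[0]
    n_windows = encoded.size - length + 1
    if n_windows <= 0:
        return np.empty(0)
    scores = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(length):
        col = encoded[j : j + n_windows]
        bad = col < 0
        valid &= ~bad
        scores += weights[j, np.where(bad, 0, col)]
    scores[~valid] = np.nan
    return scores


def scan_motifs(
    seq_id: str, sequence: str, pwm: PWM, cutoff: float
) -> list[MotifHit]:
    """All windows (both strands) scoring >= cutoff, sorted by start.

    Windows containing non-ACGT characters are skipped. A sequence shorter
    than the motif yields an empty list.
    """
    if not seq_id:
        raise ValueError("sequence name must be nonempty")
    sequence = sequence.upper()
    encoded = _encode(sequence)
    # reverse-complement reading scored on the forward window via the
    # strand-flipped matrix: W_rc[j, b] = W[L-1-j, complement(b)]
    rc_weights = pwm.weights[::-1, ::-1]
    fwd = _window_scores(encoded, pwm.weights)
    rev = _window_scores(encoded, rc_weights)
    hits: list[MotifHit] = []
    for start in range(fwd.size):
        for strand, score in (("+", fwd[start]), ("-", rev[start])):
            if not np.isnan(score) and score >= cutoff:
                hits.append(
                    MotifHit(
                        pwm.motif_kind, seq_id, start, start + pwm.length,
                        strand, float(score),
                    )
                )
    return hits


def classify_pair(hmg: MotifHit, helper: MotifHit) -> tuple[str, int]:
    """Orientation label and spacer for a disjoint (HMG, Helper) hit pair.

    Raises NotAPair for overlapping footprints and ValueError for hits on
    different sequences.
    """
    if hmg.seq_id != helper.seq_id:
        raise ValueError("hits on different sequences cannot form a pair")
    if helper.start < hmg.end and hmg.start < helper.end:
        raise NotAPair(
            f"footprints overlap: HMG {hmg.start}-{hmg.end}, "
            f"Helper {helper.start}-{helper.end}"
        )
    helper_right = helper.start >= hmg.end
    # normalize to the HMG reading direction: on a '-' HMG, genomic left
    # is downstream
    downstream = helper_right if hmg.strand == "+" else not helper_right
    same_strand = helper.strand == hmg.strand
    spacer = (helper.start - hmg.end) if helper_right else (hmg.start - helper.end)
    return ORIENTATION_LABELS[(same_strand, downstream)], spacer


def find_pairs(
    seq_id: str,
    sequence: str,
    hmg_pwm: PWM,
    helper_pwm: PWM,
    thresholds: ScoreThresholds,
    max_spacer: int = 15,
) -> list[PairCall]:
    """All HMG-Helper pairs with disjoint footprints and spacer <= max_spacer.

    Every qualifying (HMG hit, Helper hit) combination counts once; one hit
    may participate in several pairs.

    Because the Helper consensus is semi-palindromic, the two strand
    readings of one physical site sit at overlapping footprints (offset by
    1 bp for the YGCCGGCR word). Overlapping Helper hits are therefore
    grouped into one physical site; when that site pairs with the same HMG
    hit under both strand readings, both PairCalls are emitted flagged
    double_call — the Venn overlap of the per-label aggregate counts.
    """
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    hmg_hits = scan_motifs(seq_id, sequence, hmg_pwm, thresholds.hmg_cutoff)
    helper_hits = scan_motifs(seq_id, sequence, helper_pwm, thresholds.helper_cutoff)
    # group overlapping Helper hits into physical sites by a left-to-right
    # sweep (scan_motifs returns hits sorted by start)
    site_of: dict[int, int] = {}
    site_end = -1
    site_id = -1
    for k, h in enumerate(helper_hits):
        if h.start >= site_end:
            site_id += 1
            site_end = h.end
        else:
            site_end = max(site_end, h.end)
        site_of[k] = site_id

    raw: list[PairCall] = []
    for hmg in hmg_hits:
        for k, helper in enumerate(helper_hits):
            try:
                orientation, spacer = classify_pair(hmg, helper)
            except NotAPair:
                continue
            if spacer > max_spacer:
                continue
            pair_id = (
                f"{seq_id}:{hmg.start}{hmg.strand}:"
                f"{helper.start}{helper.strand}:{orientation}{spacer}"
            )
            raw.append(
                PairCall(hmg, helper, orientation, spacer, False, pair_id,
                         site_of[k])
            )
    # double-call: the same (HMG hit, physical Helper site) called under
    # both orientation labels of a family (AK/RW or FF/KK)
    labels: dict[tuple, set[str]] = {}
    for p in raw:
        labels.setdefault(p.footprint_key, set()).add(p.orientation)
    pairs = [
        replace(p, double_call=True)
        if DOUBLE_CALL_PARTNER[p.orientation] in labels[p.footprint_key]
        else p
        for p in raw
    ]
    pairs.sort(key=lambda p: (p.start, p.end, p.orientation))
    return pairs


def mirror_hit(hit: MotifHit, seq_len: int) -> MotifHit:
    """Coordinates of *hit* after reverse-complementing its sequence."""
    return replace(
        hit,
        start=seq_len - hit.end,
        end=seq_len - hit.start,
        strand="-" if hit.strand == "+" else "+",
    )


def annotate_regions(
    sequences: dict[str, str],
    hmg_pwm: PWM,
    helper_pwm: PWM,
    thresholds: ScoreThresholds,
) -> list[dict]:
    """Ordered motif/spacing table for a set of CRM fragments.

    Returns one row per motif hit per sequence, with 1-based inclusive
    display coordinates and the gap to the previous motif on the same
    sequence — the style of a per-CRM motif annotation map.
    """
    rows: list[dict] = []
    for name, seq in sequences.items():
        hits = scan_motifs(name, seq, hmg_pwm, thresholds.hmg_cutoff)
        hits += scan_motifs(name, seq, helper_pwm, thresholds.helper_cutoff)
        hits.sort(key=lambda h: (h.start, h.end, h.motif_kind))
        prev_end = None
        for h in hits:
            rows.append(
                {
                    "seq_id": name,
                    "motif": h.motif_kind,
                    "start_1based": h.start + 1,
                    "end_1based": h.end,
                    "strand": h.strand,
                    "score": round(h.score, 3),
                    "gap_to_previous": "" if prev_end is None else h.start - prev_end,
                }
            )
            prev_end = h.end
    return rows
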