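"""Partition a ChIP peak set by proximity to other TFs' peaks.

A TCF peak is "shared" with TF X when its center (floor of the interval
midpoint) lies within a radius (150 bp by default, boundary inclusive) of
the nearest point of any of X's peak intervals; a peak shared with no
tested TF is "unique". A peak may be shared with several TFs; the unique
class is disjoint from every shared class, and the partition is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomicInterval


@dataclass
class PeakSet:
    name: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.seq_id, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PartitionResult:
    unique: list[GenomicInterval]
    shared: dict[str, list[GenomicInterval]]
    multi_shared: list[GenomicInterval]
    radius: int

    @property
    def shared_any(self) -> list[GenomicInterval]:
        seen = set()
        out = []
        for peaks in self.shared.values():
            for p in peaks:
                key = (p.seq_id, p.start, p.end)
                if key not in seen:
                    seen.add(key)
                    out.append(p)
        return out


def _min_distance_to_set(
    center: int, starts: np.ndarray, ends: np.ndarray, centers: np.ndarray,
    mode: str,
) -> int:
    if mode == "center-to-edge":
        # distance from a point to [start, end) as bp positions start..end-1
        d = np.maximum.reduce(
            [starts - center, center - (ends - 1), np.zeros_like(starts)]
        )
    elif mode == "center-to-center":
        d = np.abs(centers - center)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return int(d.min())


def partition_peaks(
    tcf: PeakSet,
    others: list[PeakSet],
    radius: int = 150,
    mode: str = "center-to-edge",
) -> PartitionResult:
    """Split *tcf* peaks into unique / shared-with-<TF> / multi-shared.

    *mode* selects the distance definition: "center-to-edge" (default)
    measures from the TCF peak center to the nearest point of the other
    peak's interval; "center-to-center" to the other peak's center. The
    radius comparison is inclusive.
    """
    if not tcf.peaks:
        raise ValueError("empty TCF peak set")
    result = PartitionResult([], {o.name: [] for o in others}, [], radius)
    by_chrom: dict[str, dict[str, tuple]] = {}
    for other in others:
        for p in other.peaks:
            by_chrom.setdefault(other.name, {}).setdefault(p.seq_id, []).append(p)
    arrays: dict[str, dict[str, tuple]] = {}
    for name, chroms in by_chrom.items():
        arrays[name] = {}
        for chrom, peaks in chroms.items():
            arrays[name][chrom] = (
                np.array([p.start for p in peaks]),
                np.array([p.end for p in peaks]),
                np.array([p.center for p in peaks]),
            )
    for peak in tcf.peaks:
        shared_with = []
        for other in others:
            trip = arrays.get(other.name, {}).get(peak.seq_id)
            if trip is None:
                continue
            if _min_distance_to_set(peak.center, *trip, mode) <= radius:
                shared_with.append(other.name)
        if not shared_with:
            result.unique.append(peak)
        else:
            for name in shared_with:
                result.shared[name].append(peak)
            if len(shared_with) > 1:
                result.multi_shared.append(peak)
    return result
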