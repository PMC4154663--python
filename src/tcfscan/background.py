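"""Random genomic background selection for enrichment comparisons.

The comparison set for bound-region motif counts is drawn from an aggregate
pool of 5'UTR, intergenic, intronic and 3'UTR regions: a seeded random
permutation of region indices is walked, regions shorter than 50 bp are
skipped, and accumulation stops as soon as the sampled bp total reaches the
bound-region bp total. Each region can be chosen at most once per run, and
successive runs use distinct derived seeds so they sample different
fragments; downstream enrichment uses the mean per-bin count over runs
(ten by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomicInterval, extract_sequence

MIN_REGION_BP = 50

REGION_CLASSES = ("5UTR", "intergenic", "intronic", "3UTR")


@dataclass(frozen=True)
class Region:
    interval: GenomicInterval
    region_class: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RegionPool:
    """Aggregate list of classed regions with retrievable sequence."""

    regions: list[Region] = field(default_factory=list)

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class BackgroundSample:
    run_seed: int
    chosen: list[Region]
    sampled_bp: int


class InsufficientBackgroundError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------


def _subtract(spans: list[tuple[int, int]], holes: list[tuple[int, int]]):
    """Interval subtraction on sorted, merged span lists."""
    out = []
    for s, e in spans:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, min(hs, e)))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _merge(spans: list[tuple[int, int]]):
    spans = sorted(spans)
    out: list[list[int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def build_pool(
    sequences: dict[str, str],
    genes: list[GenomicInterval] | None = None,
    exons: list[GenomicInterval] | None = None,
    utr5: list[GenomicInterval] | None = None,
    utr3: list[GenomicInterval] | None = None,
    class_beds: dict[str, list[GenomicInterval]] | None = None,
) -> RegionPool:
    """Build an aggregate background pool.

    Either pass precomputed per-class interval lists via *class_beds*
    (keys from REGION_CLASSES), or a gene model: intergenic is the
    complement of gene spans, intronic is gene spans minus exons, and UTR
    classes come from the annotated UTR features. Out-of-bounds features
    are rejected.
    """
    pool = RegionPool()

    def add(ivs: list[GenomicInterval], cls: str):
        offenders = [
            iv for iv in ivs
            if iv.seq_id not in sequences or iv.end > len(sequences[iv.seq_id])
        ]
        if offenders:
            raise ValueError(
                "annotation features outside sequence bounds: "
                + ", ".join(f"{o.seq_id}:{o.start}-{o.end}" for o in offenders[:5])
            )
        for iv in ivs:
            pool.regions.append(Region(iv, cls, extract_sequence(iv, sequences)))

    if class_beds is not None:
        for cls, ivs in class_beds.items():
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")
            add(ivs, cls)
        return pool

    genes = genes or []
    exons = exons or []
    for iv in genes + exons + (utr5 or []) + (utr3 or []):
        if iv.seq_id not in sequences or iv.end > len(sequences[iv.seq_id]):
            raise ValueError(
                f"annotation feature outside sequence bounds: "
                f"{iv.seq_id}:{iv.start}-{iv.end}"
            )
    for seq_id, seq in sequences.items():
        gene_spans = _merge(
            [(g.start, g.end) for g in genes if g.seq_id == seq_id]
        )
        exon_spans = _merge(
            [(x.start, x.end) for x in exons if x.seq_id == seq_id]
        )
        intergenic = _subtract([(0, len(seq))], gene_spans)
        intronic = _subtract(gene_spans, exon_spans)
        for cls, spans in (("intergenic", intergenic), ("intronic", intronic)):
            add(
                [
                    GenomicInterval(seq_id, s, e, f"{cls}_{seq_id}_{s}")
                    for s, e in spans
                ],
                cls,
            )
    add(list(utr5 or []), "5UTR")
    add(list(utr3 or []), "3UTR")
    return pool


def pool_from_regions(
    intervals: list[GenomicInterval],
    sequences: dict[str, str],
    region_class: str = "intergenic",
) -> RegionPool:
    """Wrap explicit intervals (e.g. a written pool BED) into a RegionPool."""
    return RegionPool(
        [
            Region(iv, region_class, extract_sequence(iv, sequences))
            for iv in intervals
        ]
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_background(
    pool: RegionPool, target_bp: int, seed: int
) -> BackgroundSample:
    """One seeded background draw.

    Walks a random permutation of pool indices, skipping regions shorter
    than MIN_REGION_BP, until the accumulated bp reaches *target_bp*.
    Deterministic for fixed (pool, target_bp, seed). Raises
    InsufficientBackgroundError if the pool runs out first.
    """
    if target_bp <= 0:
        raise ValueError("target_bp must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool.regions))
    chosen: list[Region] = []
    sampled = 0
    for idx in order:
        region = pool.regions[idx]
        if len(region) < MIN_REGION_BP:
            continue
        chosen.append(region)
        sampled += len(region)
        if sampled >= target_bp:
            return BackgroundSample(seed, chosen, sampled)
    raise InsufficientBackgroundError(
        f"pool exhausted at {sampled} bp before reaching target {target_bp} bp"
    )


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Deterministic per-run seed: SeedSequence(master, spawn_key=(k,))."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(run_index,))
    return int(ss.generate_state(1)[0])


def sample_background_runs(
    pool: RegionPool, target_bp: int, n_runs: int = 10, master_seed: int = 0
) -> list[BackgroundSample]:
    """n_runs independent draws with distinct derived seeds."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [
        sample_background(pool, target_bp, derive_run_seed(master_seed, k))
        for k in range(n_runs)
    ]
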