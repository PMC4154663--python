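"""Synthetic genomes, planted HMG-Helper pairs, and peak fixtures.

Every pipeline stage is testable without external downloads: this module
generates i.i.d. background DNA, plants HMG-Helper pair instances at known
orientation/spacer/strand (recorded in a truth table), and assembles
"bound" peak sets whose planted-pair density exceeds the background pool's
by a configured multiplier — the statistical structure the enrichment
comparison is designed to detect. Other-TF peak sets are placed at
controlled center distances to exercise the proximity partition.

What it does NOT emulate: real genomic base composition heterogeneity,
repeats, chromatin accessibility, or conservation structure. Passing
recovery tests on these fixtures demonstrates correctness of the counting
and sampling machinery, not performance on real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background import Region, RegionPool, REGION_CLASSES
from .io import GenomicInterval, write_bed, write_fasta
from .partition import PeakSet
from .pwm import BASES, PWM, reverse_complement


class PlacementError(RuntimeError):
    """Could not place all requested instances without overlap."""


@dataclass(frozen=True)
class PlantSpec:
    """One planting request: how many pairs of which configuration."""

    orientation: str
    spacer: int
    count: int
    mode: str = "consensus"  # or "pwm"
    strand: str = "random"  # "+", "-" or "random"

    def __post_init__(self) -> None:
        if self.orientation not in ("AK", "RW", "FF", "KK"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.mode not in ("consensus", "pwm"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.strand not in ("+", "-", "random"):
            raise ValueError(f"invalid strand policy {self.strand!r}")


def make_background(
    length: int, composition=None, seed: int | np.random.Generator = 0
) -> str:
    """i.i.d. DNA of *length* bp with the given A/C/G/T composition."""
    if length < 0:
        raise ValueError("length must be >= 0")
    comp = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-6:
        raise ValueError("composition must be 4 nonnegative frequencies summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=comp)])


def _draw_motif(pwm: PWM, mode: str, rng: np.random.Generator) -> str:
    if mode == "consensus":
        return pwm.consensus()
    freqs = pwm.implied_frequencies()
    return "".join(
        BASES[rng.choice(4, p=freqs[j] / freqs[j].sum())] for j in range(pwm.length)
    )


def pair_cassette(
    spec: PlantSpec,
    hmg_pwm: PWM,
    helper_pwm: PWM,
    rng: np.random.Generator,
    composition=None,
) -> tuple[str, str, int, int]:
    """Build one planted-pair sequence.

    Returns (cassette, strand, hmg_offset, helper_offset): offsets are the
    forward-reference starts of the two footprints within the cassette,
    after any reverse-complementing for a '-' strand plant.
    """
    hmg = _draw_motif(hmg_pwm, spec.mode, rng)
    helper = _draw_motif(helper_pwm, spec.mode, rng)
    gap = make_background(spec.spacer, composition, rng)
    if spec.orientation == "FF":
        parts, order = [hmg, gap, helper], ("hmg", "helper")
    elif spec.orientation == "KK":
        parts, order = [hmg, gap, reverse_complement(helper)], ("hmg", "helper")
    elif spec.orientation == "AK":
        parts, order = [helper, gap, hmg], ("helper", "hmg")
    else:  # RW
        parts, order = [reverse_complement(helper), gap, hmg], ("helper", "hmg")
    cassette = "".join(parts)
    first_len = len(parts[0])
    offsets = {order[0]: 0, order[1]: first_len + spec.spacer}
    strand = spec.strand
    if strand == "random":
        strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        cassette = reverse_complement(cassette)
        lengths = {"hmg": hmg_pwm.length, "helper": helper_pwm.length}
        offsets = {
            k: len(cassette) - off - lengths[k] for k, off in offsets.items()
        }
    return cassette, strand, offsets["hmg"], offsets["helper"]


def plant_pairs(
    sequence: str,
    specs: list[PlantSpec],
    hmg_pwm: PWM,
    helper_pwm: PWM,
    seed: int | np.random.Generator = 0,
    min_separation: int = 20,
    max_tries_per_instance: int = 1000,
    composition=None,
) -> tuple[str, pd.DataFrame]:
    """Write planted pair instances into *sequence*; return it with a truth
    table (columns: orientation, spacer, strand, start, end, hmg_start,
    helper_start, mode).

    Instances never overlap each other (a min_separation margin keeps
    neighboring plants from forming spurious cross-pairs) or the sequence
    ends; positions are found by seeded rejection sampling with a bounded
    retry count per instance (PlacementError when exceeded).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(sequence)
    placed: list[tuple[int, int]] = []
    records = []
    for spec in specs:
        for _ in range(spec.count):
            cassette, strand, hmg_off, helper_off = pair_cassette(
                spec, hmg_pwm, helper_pwm, rng, composition
            )
            clen = len(cassette)
            if clen > len(seq):
                raise PlacementError("sequence shorter than one cassette")
            for attempt in range(max_tries_per_instance):
                start = int(rng.integers(0, len(seq) - clen + 1))
                lo, hi = start - min_separation, start + clen + min_separation
                if all(e <= lo or s >= hi for s, e in placed):
                    break
            else:
                raise PlacementError(
                    f"could not place instance of {spec} after "
                    f"{max_tries_per_instance} tries"
                )
            seq[start : start + clen] = cassette
            placed.append((start, start + clen))
            records.append(
                {
                    "orientation": spec.orientation,
                    "spacer": spec.spacer,
                    "strand": strand,
                    "start": start,
                    "end": start + clen,
                    "hmg_start": start + hmg_off,
                    "helper_start": start + helper_off,
                    "mode": spec.mode,
                }
            )
    truth = pd.DataFrame(
        records,
        columns=[
            "orientation", "spacer", "strand", "start", "end",
            "hmg_start", "helper_start", "mode",
        ],
    )
    return "".join(seq), truth.sort_values("start").reset_index(drop=True)


#: Default orientation/spacer mix for planted pairs, weighted toward the
#: configurations most enriched in bound chromatin (FF0-2, AK0-6).
DEFAULT_PLANT_MIX: tuple[tuple[str, int, float], ...] = (
    ("FF", 0, 0.30),
    ("AK", 6, 0.30),
    ("FF", 1, 0.20),
    ("KK", 0, 0.10),
    ("RW", 3, 0.10),
)


@dataclass
class PeakFixture:
    genome: dict[str, str]
    tcf_peaks: PeakSet
    other_peaks: list[PeakSet]
    pool: RegionPool
    truth: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def bound_regions(self) -> list[Region]:
        seq = self.genome[self.tcf_peaks.peaks[0].seq_id]
        return [
            Region(p, "intergenic", seq[p.start : p.end])
            for p in self.tcf_peaks.peaks
        ]


def make_peak_fixture(
    hmg_pwm: PWM,
    helper_pwm: PWM,
    n_peaks: int = 40,
    peak_width: int = 1000,
    n_pool_regions: int = 160,
    pairs_per_region: float = 1.0,
    bound_rate_multiplier: float = 5.0,
    plant_mix=DEFAULT_PLANT_MIX,
    other_tf_offsets: dict[str, int] | None = None,
    other_tf_fraction: float = 0.5,
    other_tf_width: int = 200,
    gap: int = 50,
    seed: int = 0,
    mode: str = "consensus",
) -> PeakFixture:
    """Assemble a chromosome of "bound" peaks and background pool regions.

    Bound peaks carry Poisson(multiplier x pairs_per_region) planted pairs
    each; pool regions carry Poisson(pairs_per_region). Regions are tiled
    onto one chromosome separated by *gap* bp. For each TF named in
    *other_tf_offsets*, peaks of *other_tf_width* are centered at the given
    signed offset from the centers of the first other_tf_fraction of bound
    peaks, exercising the 150-bp proximity partition with exact distances.

    With matched bp (pool regions share the bound peak width), the expected
    aggregate fold enrichment is the multiplier, up to Poisson noise and a
    small chance-match background.
    """
    if bound_rate_multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    mix = np.array([w for _, _, w in plant_mix], float)
    mix = mix / mix.sum()

    # feasibility cap on plants per region: each cassette plus its
    # non-overlap margin occupies ~80 bp; keep the Poisson truncation bias
    # negligible by sizing peak_width >> 80 x the plant rate
    max_plants = max(1, peak_width // 80)

    def planted_region(lam: float) -> tuple[str, pd.DataFrame]:
        raw = make_background(peak_width, None, rng)
        k = min(int(rng.poisson(lam)), max_plants)
        draws = rng.choice(len(plant_mix), size=k, p=mix)
        specs = [
            PlantSpec(plant_mix[i][0], plant_mix[i][1], 1, mode=mode)
            for i in draws
        ]
        return plant_pairs(raw, specs, hmg_pwm, helper_pwm, rng, min_separation=16)

    chrom_parts: list[str] = []
    pos = 0
    tcf_intervals: list[GenomicInterval] = []
    pool_regions_meta: list[tuple[int, int, str]] = []
    truth_frames: list[pd.DataFrame] = []

    def append_region(seq_part: str, truth: pd.DataFrame, kind: str, cls: str = ""):
        nonlocal pos
        start = pos
        chrom_parts.append(seq_part)
        pos += len(seq_part)
        chrom_parts.append(make_background(gap, None, rng))
        end = start + len(seq_part)
        pos += gap
        if not truth.empty:
            t = truth.copy()
            for col in ("start", "end", "hmg_start", "helper_start"):
                t[col] += start
            t["region_kind"] = kind
            truth_frames.append(t)
        if kind == "bound":
            tcf_intervals.append(
                GenomicInterval("chrSim", start, end, f"tcf_peak_{len(tcf_intervals)}")
            )
        else:
            pool_regions_meta.append((start, end, cls))

    for _ in range(n_peaks):
        seq_part, truth = planted_region(bound_rate_multiplier * pairs_per_region)
        append_region(seq_part, truth, "bound")
    for i in range(n_pool_regions):
        seq_part, truth = planted_region(pairs_per_region)
        append_region(seq_part, truth, "pool", REGION_CLASSES[i % len(REGION_CLASSES)])

    chrom = "".join(chrom_parts)
    genome = {"chrSim": chrom}
    pool = RegionPool(
        [
            Region(
                GenomicInterval("chrSim", s, e, f"pool_{i}"),
                cls,
                chrom[s:e],
            )
            for i, (s, e, cls) in enumerate(pool_regions_meta)
        ]
    )
    tcf = PeakSet("TCF", tcf_intervals)

    other_tf_offsets = other_tf_offsets or {}
    other_sets: list[PeakSet] = []
    n_coloc = int(round(other_tf_fraction * len(tcf_intervals)))
    for tf, offset in other_tf_offsets.items():
        peaks = []
        for j, p in enumerate(tcf_intervals[:n_coloc]):
            c = p.center + offset
            start = max(0, c - other_tf_width // 2)
            peaks.append(
                GenomicInterval(
                    "chrSim", start, start + other_tf_width, f"{tf}_peak_{j}"
                )
            )
        other_sets.append(PeakSet(tf, peaks))

    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(
            columns=[
                "orientation", "spacer", "strand", "start", "end",
                "hmg_start", "helper_start", "mode", "region_kind",
            ]
        )
    )
    params = {
        "n_peaks": n_peaks,
        "peak_width": peak_width,
        "n_pool_regions": n_pool_regions,
        "pairs_per_region": pairs_per_region,
        "bound_rate_multiplier": bound_rate_multiplier,
        "plant_mix": [list(t) for t in plant_mix],
        "other_tf_offsets": dict(other_tf_offsets),
        "other_tf_fraction": other_tf_fraction,
        "other_tf_width": other_tf_width,
        "gap": gap,
        "seed": seed,
        "mode": mode,
    }
    return PeakFixture(genome, tcf, other_sets, pool, truth, params)


def write_fixture(fixture: PeakFixture, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, per-TF peak BEDs, pool BED, truth BED and a JSON
    manifest of generator parameters. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(fixture.genome, paths["genome"])
    paths["tcf_peaks"] = outdir / "tcf_peaks.bed"
    write_bed(fixture.tcf_peaks.peaks, paths["tcf_peaks"])
    for ps in fixture.other_peaks:
        paths[f"peaks_{ps.name}"] = outdir / f"{ps.name}_peaks.bed"
        write_bed(ps.peaks, paths[f"peaks_{ps.name}"])
    paths["pool"] = outdir / "pool.bed"
    write_bed(
        [r.interval for r in fixture.pool.regions],
        paths["pool"],
        extra_cols=[(r.region_class,) for r in fixture.pool.regions],
    )
    paths["truth"] = outdir / "truth.bed"
    truth_ivs = [
        GenomicInterval(
            "chrSim", int(r.start), int(r.end),
            f"{r.orientation}{r.spacer}", None, r.strand,
        )
        for r in fixture.truth.itertuples()
    ]
    write_bed(truth_ivs, paths["truth"])
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(fixture.params, indent=2))
    return paths
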