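"""Sequence and interval file I/O.

All intervals are 0-based half-open (BED convention). 1-based inclusive
coordinates appear only in human-readable reports and are labeled there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GenomicInterval:
    """A named, optionally stranded interval on a reference sequence."""

    seq_id: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("interval seq_id must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}, bases upper-cased.

    Non-ACGT characters (N, IUPAC codes) are preserved; downstream scanners
    skip windows containing them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(
    path: str | Path, sequences: dict[str, str] | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6(+) intervals.

    If *sequences* is given, coordinates are validated against sequence
    lengths and out-of-bounds records rejected.
    """
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            try:
                iv = GenomicInterval(chrom, start, end, name, score, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if sequences is not None:
                if chrom not in sequences:
                    raise ValueError(f"{path}:{lineno}: unknown sequence {chrom!r}")
                if end > len(sequences[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} beyond "
                        f"{chrom} length {len(sequences[chrom])}"
                    )
            intervals.append(iv)
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval], path: str | Path, extra_cols=None
) -> None:
    """Write BED6; *extra_cols* is an optional parallel list of tuples
    appended after the strand column (BED6+)."""
    intervals = list(intervals)
    if extra_cols is not None:
        extra_cols = list(extra_cols)
        if len(extra_cols) != len(intervals):
            raise ValueError("extra_cols length mismatch")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = "." if iv.score is None else f"{iv.score:g}"
            strand = iv.strand or "."
            row = [iv.seq_id, str(iv.start), str(iv.end), iv.name, score, strand]
            if extra_cols is not None:
                row.extend(str(x) for x in extra_cols[i])
            fh.write("\t".join(row) + "\n")


#: GFF/GTF feature types mapped to the pool builder's inputs
_GFF_FEATURE_KEYS = {
    "gene": "genes",
    "exon": "exons",
    "five_prime_utr": "utr5",
    "5utr": "utr5",
    "three_prime_utr": "utr3",
    "3utr": "utr3",
}


def read_gff_features(path: str | Path) -> dict[str, list[GenomicInterval]]:
    """Read gene/exon/UTR features from a GFF3 or GTF file (read-only, for
    background pool building).

    Returns {"genes": [...], "exons": [...], "utr5": [...], "utr3": [...]}.
    GFF coordinates are 1-based inclusive and converted to 0-based half-open.
    Unrecognized feature types are ignored.
    """
    out: dict[str, list[GenomicInterval]] = {
        "genes": [], "exons": [], "utr5": [], "utr3": []
    }
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 GFF fields")
            key = _GFF_FEATURE_KEYS.get(fields[2].lower())
            if key is None:
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            strand = fields[6] if fields[6] in ("+", "-") else None
            out[key].append(
                GenomicInterval(fields[0], start, end, fields[2], None, strand)
            )
    return out


def extract_sequence(interval: GenomicInterval, sequences: dict[str, str]) -> str:
    if interval.seq_id not in sequences:
        raise KeyError(f"no sequence for {interval.seq_id!r}")
    seq = sequences[interval.seq_id]
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval.seq_id}:{interval.start}-{interval.end} "
            f"exceeds sequence length {len(seq)}"
        )
    return seq[interval.start : interval.end]
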