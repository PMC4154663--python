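"""Position weight matrices for HMG and Helper sites.

The matrix is built from an alignment of equal-length functional sites by
the pseudocount log-odds rule

    weight[i, j] = ln( ((n[i, j] + p[i]) / (N + 1)) / p[i] )

where n[i, j] counts base i at position j over the N training sequences and
p[i] is the background (prior) frequency of base i. The background
pseudocount makes every weight finite and gives the algebraic identity

    sum_i p[i] * exp(weight[i, j]) = 1      at every position j,

which the test suite checks on every constructed matrix. For large N the
weight approaches the familiar ln(f/p) log-odds of observed frequency over
background.

Window scores are the sum over positions of the weight of the observed
base; a window is called a site when its score is >= the cutoff (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with its training counts retained for audit.

    Attributes
    ----------
    motif_kind:
        "HMG" or "Helper" (free-form labels are allowed for composites).
    counts:
        (length, 4) observation counts, columns in A, C, G, T order.
    n_train:
        Number of training sequences N.
    background:
        Per-base prior frequencies p, A/C/G/T order, summing to 1.
    weights:
        (length, 4) log-odds weights.
    """

    motif_kind: str
    counts: np.ndarray
    n_train: int
    background: np.ndarray
    weights: np.ndarray

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        """Per-position argmax base string (ties broken in A<C<G<T order)."""
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))

    def implied_frequencies(self) -> np.ndarray:
        """(n + p) / (N + 1): the smoothed per-position base frequencies."""
        return (self.counts + self.background) / (self.n_train + 1)


def build_pwm(
    training_sequences: list[str],
    background: np.ndarray | list[float] | None = None,
    motif_kind: str = "motif",
) -> PWM:
    """Build a PWM from equal-length ACGT training sequences.

    Raises ValueError for an empty training set, unequal lengths (the
    offending sequence is named), non-ACGT characters, or a background that
    is not strictly positive and summing to 1.
    """
    if not training_sequences:
        raise ValueError("need at least one training sequence")
    background = (
        UNIFORM_BACKGROUND.copy()
        if background is None
        else np.asarray(background, dtype=float)
    )
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive frequencies")
    if not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"background frequencies sum to {background.sum()!r}, not 1")

    length = len(training_sequences[0])
    counts = np.zeros((length, 4), dtype=float)
    for k, seq in enumerate(training_sequences):
        seq = seq.upper()
        if len(seq) != length:
            raise ValueError(
                f"training sequence {k} ({seq!r}) has length {len(seq)}, "
                f"expected {length}"
            )
        for j, base in enumerate(seq):
            if base not in BASE_INDEX:
                raise ValueError(f"training sequence {k}: non-ACGT character {base!r}")
            counts[j, BASE_INDEX[base]] += 1

    n = len(training_sequences)
    weights = np.log(((counts + background) / (n + 1)) / background)
    return PWM(motif_kind, counts, n, background, weights)


def score_window(pwm: PWM, window: str) -> float:
    """Additive score of a window exactly pwm.length long."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    try:
        idx = [BASE_INDEX[b] for b in window.upper()]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in window: {exc.args[0]!r}") from exc
    return float(pwm.weights[np.arange(pwm.length), idx].sum())


def max_score(pwm: PWM) -> float:
    return float(pwm.weights.max(axis=1).sum())


def min_score(pwm: PWM) -> float:
    return float(pwm.weights.min(axis=1).sum())


@dataclass(frozen=True)
class ScoreThresholds:
    """A pair of inclusive score cutoffs for calling HMG and Helper sites."""

    hmg_cutoff: float
    helper_cutoff: float
    profile_name: str = "custom"


#: Named cutoff profiles. "figure1" is the annotation profile used for
#: per-CRM motif maps; "stringent" and "relaxed" are the genome-survey
#: calling criteria.
PROFILES: dict[str, ScoreThresholds] = {
    "figure1": ScoreThresholds(5.35, 6.5, "figure1"),
    "stringent": ScoreThresholds(4.5, 6.5, "stringent"),
    "relaxed": ScoreThresholds(3.5, 5.0, "relaxed"),
}


def get_profile(name: str) -> ScoreThresholds:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown threshold profile {name!r}; known: {sorted(PROFILES)}"
        ) from None


# ---------------------------------------------------------------------------
# serialization: tab-separated counts matrix with a metadata header
# ---------------------------------------------------------------------------


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write a PWM as TSV. Counts, N and background are stored; weights are
    recomputed on read, so the round-trip is lossless."""
    with open(path, "w") as fh:
        fh.write(f"#motif_kind={pwm.motif_kind}\n")
        fh.write(f"#n_train={pwm.n_train}\n")
        fh.write(
            "#background=" + ",".join(repr(float(p)) for p in pwm.background) + "\n"
        )
        fh.write("pos\t" + "\t".join(BASES) + "\n")
        for j in range(pwm.length):
            fh.write(
                str(j) + "\t" + "\t".join(f"{c:g}" for c in pwm.counts[j]) + "\n"
            )


def read_pwm(path: str | Path) -> PWM:
    motif_kind = None
    n_train = None
    background = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "motif_kind":
                    motif_kind = value
                elif key == "n_train":
                    n_train = int(value)
                elif key == "background":
                    background = np.array([float(x) for x in value.split(",")])
            elif line.startswith("pos\t") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    if motif_kind is None or n_train is None or background is None or not rows:
        raise ValueError(f"malformed PWM file {path}")
    counts = np.array(rows)
    weights = np.log(((counts + background) / (n_train + 1)) / background)
    return PWM(motif_kind, counts, n_train, background, weights)


# ---------------------------------------------------------------------------
# packaged default training sets
# ---------------------------------------------------------------------------


def _read_training_fasta_text(text: str) -> list[str]:
    seqs: list[str] = []
    cur: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
                cur = []
        elif line.startswith(";"):
            continue
        elif line:
            cur.append(line.upper())
    if cur:
        seqs.append("".join(cur))
    return seqs


def load_training_sequences(path: str | Path) -> list[str]:
    """Read training sites from FASTA or plain one-sequence-per-line text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        return _read_training_fasta_text(text)
    return [
        ln.strip().upper()
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith(("#", ";"))
    ]


def default_training_sequences(motif_kind: str) -> list[str]:
    """Packaged synthetic training sets (see the data files' own headers).

    These are stand-ins constructed from the published consensus motifs
    (HMG: SCTTTGWWSWW; Helper: GCCGCCR) with realistic degeneracy, not the
    original experimentally derived alignments; supply your own training
    FASTA to build_pwm for production use on real genomes.
    """
    fname = {"HMG": "hmg_training.synthetic.fa", "Helper": "helper_training.synthetic.fa"}
    try:
        text = (
            resources.files("tcfscan.data").joinpath(fname[motif_kind]).read_text()
        )
    except KeyError:
        raise ValueError(f"no default training set for motif kind {motif_kind!r}")
    return _read_training_fasta_text(text)


def default_pwm(motif_kind: str, background=None) -> PWM:
    """PWM built from the packaged synthetic training set for *motif_kind*."""
    return build_pwm(default_training_sequences(motif_kind), background, motif_kind)
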