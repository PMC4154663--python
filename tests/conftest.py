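import numpy as np
import pytest

import tcfscan as t


@pytest.fixture(scope="session")
def hmg_pwm():
    return t.default_pwm("HMG")


@pytest.fixture(scope="session")
def helper_pwm():
    return t.default_pwm("Helper")


@pytest.fixture(scope="session")
def stringent():
    return t.get_profile("stringent")


@pytest.fixture(scope="session")
def relaxed():
    return t.get_profile("relaxed")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain-python, no shared code with tcfscan
# internals beyond the public weight matrices)
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_score(weights, window: str) -> float:
    order = "ACGT"
    return sum(weights[j][order.index(b)] for j, b in enumerate(window))


def oracle_scan(seq: str, weights, cutoff: float):
    """(start, strand, score) for every window scoring >= cutoff."""
    length = len(weights)
    hits = []
    for s in range(len(seq) - length + 1):
        window = seq[s : s + length]
        if any(b not in "ACGT" for b in window):
            continue
        for strand, w in (("+", window), ("-", rc(window))):
            score = oracle_score(weights, w)
            if score >= cutoff:
                hits.append((s, strand, round(score, 9)))
    return sorted(hits)


def oracle_classify(hmg_start, hmg_end, hmg_strand, h_start, h_end, h_strand):
    """Orientation + spacer from first principles, or None on overlap."""
    if h_start < hmg_end and hmg_start < h_end:
        return None
    right = h_start >= hmg_end
    downstream = right if hmg_strand == "+" else not right
    same = h_strand == hmg_strand
    label = {
        (True, True): "FF", (True, False): "AK",
        (False, True): "KK", (False, False): "RW",
    }[(same, downstream)]
    spacer = (h_start - hmg_end) if right else (hmg_start - h_end)
    return label, spacer


def oracle_pairs(seq, hmg_weights, helper_weights, hmg_cut, helper_cut, max_spacer):
    """Multiset of (hmg_start, hmg_strand, helper_start, helper_strand,
    orientation, spacer) over all qualifying hit combinations."""
    hmg_len, helper_len = len(hmg_weights), len(helper_weights)
    out = []
    for hs, hstrand, _ in oracle_scan(seq, hmg_weights, hmg_cut):
        for ps, pstrand, _ in oracle_scan(seq, helper_weights, helper_cut):
            res = oracle_classify(
                hs, hs + hmg_len, hstrand, ps, ps + helper_len, pstrand
            )
            if res is None or res[1] > max_spacer:
                continue
            out.append((hs, hstrand, ps, pstrand, res[0], res[1]))
    return sorted(out)
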