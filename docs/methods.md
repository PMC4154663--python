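# Methods

## Motif model

Both motifs are modeled as independent-position weight matrices. Given N
equal-length training sites with per-position base counts `n[i, j]` and a
strictly positive background distribution `p` (default uniform 0.25), the
weight of base *i* at position *j* is

    w[i, j] = ln( ((n[i, j] + p[i]) / (N + 1)) / p[i] ).

The background acts as the pseudocount, so every weight is finite even for
unobserved bases, and the smoothed frequencies `(n + p) / (N + 1)` sum to
one across bases at each position. That gives the algebraic identity

    sum_i p[i] * exp(w[i, j]) = 1   for every j,

which the test suite asserts (tolerance 1e-9) on every matrix it builds —
a cheap, complete check that the formula was implemented cell-by-cell. As
N grows with fixed empirical frequencies f, the weights approach the
familiar log-odds ln(f/p) monotonically.

A window is scored additively and called a site when score ≥ cutoff
(inclusive: a score exactly at the cutoff is a hit). Scores are not rounded
before comparison. Named cutoff profiles:

| profile   | HMG cutoff | Helper cutoff | use |
|-----------|-----------|---------------|-----|
| stringent | 4.5       | 6.5           | genome surveys, CRM anchors |
| relaxed   | 3.5       | 5.0           | sensitive surveys, secondary pairs |
| figure1   | 5.35      | 6.5           | per-fragment annotation maps |

### Default training sets

The packaged training alignments (`data/*.synthetic.fa`) are synthetic:
12 HMG sites written from the 11-bp consensus SCTTTGWWSWW with one
off-consensus position, and 10 Helper sites from GCCGCCR including two
GCCGGCR variants. The Helper variants make the semi-palindromic YGCCGGCR
word callable on both strands at the stringent cutoff, which is required
for double-calling to be exercised at all. These sets are stand-ins for
experimentally derived functional-site alignments, which are not
redistributable here; every entry point accepts a user training FASTA, and
real-genome work should supply one. The HMG consensus is treated as 11 bp
(the shorter 10-letter spelling that circulates for this motif drops one W;
the matrix length always follows the training alignment, not a consensus
string).

## Pair scanning and orientation classes

`scan_motifs` scores every window on both strands (the reverse-strand
reading is computed with the strand-flipped matrix on the forward window)
and skips windows containing non-ACGT characters. `find_pairs` forms every
(HMG hit, Helper hit) combination with disjoint footprints and spacer ≤ 15
(configurable); one hit may participate in several pairs, and no greedy
exclusion is applied. Overlapping footprints are "not a pair" rather than
an error.

Orientation is a pure function of the pair geometry after normalizing to
the HMG reading direction:

| Helper strand vs HMG | Helper position vs HMG reading | label |
|----------------------|--------------------------------|-------|
| same                 | downstream                     | FF    |
| same                 | upstream                       | AK    |
| opposite             | downstream                     | KK    |
| opposite             | upstream                       | RW    |

The label↔geometry table is module-level configuration
(`tcfscan.scan.ORIENTATION_LABELS`), so the four geometric classes can be
relabeled without touching the scanner. The spacer counts bp strictly
between footprints. This convention reproduces the three anchoring worked
cases: a Helper ending 6 bp before a forward HMG is AK6; a Helper starting
immediately after it is FF0; and an HMG followed immediately by TGGCGGCG is
KK0 (the reverse-complement reading CGCCGCCA carries the consensus).

**Double-calling.** The Helper core GCCGCC is semi-palindromic, so one
physical site can score above cutoff on both strands — at footprints offset
by 1 bp, not the same window (YGCCGGCR downstream of an HMG is FF1 on the
forward reading and KK0 on the reverse; the same off-by-one links AK and
RW). Overlapping Helper hits are therefore grouped into one physical site
by a sweep; when a site pairs with the same HMG hit under both strand
readings, both PairCalls are emitted with `double_call` set. Aggregate
counts include double-called pairs under both labels, with the intersection
reported per label family (AK/RW, FF/KK) as Venn counts; a `count_once`
mode assigns each site only its best-scoring strand for sensitivity
analysis. Note the two members of a double call may land in different
spacer bins (FF1/KK0), which is the intended reading of the degenerate
configurations.

## Background sampling and enrichment

The background pool is an aggregate list of classed regions (5′UTR,
intergenic, intronic, 3′UTR). From a gene model, intergenic = complement of
gene spans, intronic = gene spans minus exons, UTRs from annotated
features; precomputed class BEDs are also accepted, and the class
conventions are explicit configuration rather than an attempt to guess any
particular genome release's dataset derivation. Pool regions are used
whole, sampled uniformly by index without class stratification or GC
matching (a stratification option exists but is off by default).

One background run walks a seeded random permutation of region indices,
skips regions shorter than 50 bp, and accumulates whole regions until the
sampled bp total reaches the bound bp total; indices cannot repeat within a
run, and the final region may overshoot the target (no correction is
applied). Run *k* of a multi-run draw is seeded with
`SeedSequence(master_seed, spawn_key=(k,))`, so runs are deterministic,
distinct, and reproducible from the master seed alone. Enrichment uses the
mean per-bin count over runs (default 10).

Fold enrichment is a ratio of raw counts at matched bp: bound count /
background mean, per orientation × spacer bin, plus aggregates (all pairs,
HMG-only hits, Helper-only hits, and bin groups such as FF0–2 ∪ AK0–6,
whose fold is the ratio of summed counts, not a mean of folds). A zero
background mean yields NaN ("undefined") unless a pseudocount is requested.
Single-motif aggregates count every hit above cutoff whether or not it is
in a pair; `*_unpaired` totals excluding paired hits are also recorded.
Pairs must lie wholly inside a region; pairs spanning region boundaries are
not counted.

## Peak partition

A TCF peak's center is `floor((start + end) / 2)` in half-open coordinates.
The peak is shared with TF X when the distance from its center to the
nearest point of any X peak interval is ≤ the radius (default 150 bp,
boundary inclusive); "within r of another TF's peak" is read as
center-to-edge because the proximity criterion names the other factor's
peak, not its center — a center-to-center mode is provided for sensitivity
analysis. Unique = shared with no tested TF (a statement only about the
TFs supplied). The partition is exhaustive; shared classes may overlap, and
peaks shared with ≥ 2 TFs are additionally reported as multi-shared.

## W-CRM search

Anchors are pairs matching one exact configuration (default FF, spacer 1 —
the configuration most enriched in bound chromatin and most active in
reporter assays) with both motifs at stringent cutoffs, found per
chromosome. Around each anchor midpoint, relaxed-profile pairs within
± 500 bp (configurable; enhancers with clustered sites are a few hundred bp,
so the default window comfortably covers one module) are collected as
secondary pairs, excluding the anchor itself. Candidates rank by secondary
pair count, ties broken by summed PWM scores; overlapping windows merge,
keeping the best anchor and the deduplicated union of secondary pairs.
`composite_pwm` additionally composes the two motif matrices into a single
fixed-spacer matrix (zero-weight spacer columns, which preserve the
normalization identity) for use with single-matrix search tools, and a
user-supplied composite is accepted.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. background DNA of configurable composition,
plants pair cassettes (consensus or PWM-sampled; PWM mode draws each base
from the smoothed frequencies `(n + p) / (N + 1)`) at configured
orientation/spacer/strand by seeded rejection sampling (non-overlapping,
with a 16–20 bp separation margin so neighboring plants cannot form
spurious cross-pairs; bounded retries, then an explicit placement error),
and records every instance in a truth table. Peak fixtures tile bound
peaks and pool regions onto one chromosome: bound peaks carry
Poisson(multiplier × rate) planted pairs, pool regions Poisson(rate), so
the expected aggregate fold equals the multiplier up to Poisson noise and a
small chance-match floor. The per-region plant count is capped at a
feasibility limit (~ width / 80 bp); default region width 1000 bp keeps the
truncation bias of the Poisson negligible. Other-TF peak sets are placed
at exact center offsets from bound peaks (e.g. 100 bp vs 400 bp) to
exercise the 150-bp partition boundary.

These fixtures deliberately lack real-genome structure: no GC
heterogeneity, repeats, chromatin accessibility or conservation. Passing
recovery tests therefore demonstrates correctness of the scanning,
sampling, counting and partitioning machinery — not expected performance
on real chromatin, where background composition and peak-calling noise
dominate.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale: 50 random
1-kb sequences per profile for brute-force equivalence, 20–50 seeds for
null calibration (24 bound peaks / 96 pool regions of 500 bp each), a
40-peak / 160-region fixture for multiplier recovery (mean over three
fixtures), and a 100-kb chromosome for anchor recovery. Coordinates are
0-based half-open everywhere internally; 1-based inclusive appears only in
annotation reports, labeled as such. Threshold comparisons are inclusive;
score ties are irrelevant because all hits above cutoff are kept. Fold
ratios with zero background are reported as NaN rather than 0 to keep
"absent from background" distinct from "absent from bound".

## Known limitations

- The shipped PWMs are consensus-derived stand-ins; absolute score scales
  and hit densities on real genomes will differ from matrices trained on
  experimentally validated sites.
- Published genome-survey numbers for this system (e.g. bound-region pair
  counts and fold enrichments on a specific fly assembly and ChIP peak set)
  require those external inputs plus the original training alignments; the
  pipeline accepts them (`tests/test_acceptance.py` wires the full
  computation) but they are not bundled.
- No statistical significance testing of enrichment is performed; the
  method reports ratios, matching its design.
- Gapped or variable-length motif models, dinucleotide backgrounds, and
  conservation-based filtering are out of scope.
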