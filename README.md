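# tcfscan

Bipartite DNA-recognition analysis for TCF/Pangolin, the single *Drosophila*
TCF-family transcription factor. TCF/Pan binds DNA through two domains: the
HMG box, recognizing an AT-rich **HMG site** (consensus `SCTTTGWWSWW`,
S = C/G, W = A/T), and the C-clamp, recognizing a GC-rich **Helper site**
(consensus `GCCGCCR`, R = A/G). A candidate bipartite binding site is a
*pair* of nearby motif matches, and the geometry of the pair — which strand
carries each consensus, which motif comes first, and how many bp separate
them — governs binding affinity and Wnt-dependent enhancer activity.

`tcfscan` is for regulatory genomicists who want to find and quantify such
pairs: annotate cis-regulatory fragments, measure pair enrichment in
ChIP-bound versus random genomic DNA, split peak sets by co-localization
with other factors, and search chromosomes for candidate Wnt-dependent
cis-regulatory modules (W-CRMs).

## The model

**Motif model.** Each motif is a position weight matrix built from an
alignment of N functional sites with the pseudocount log-odds rule

```
w[i, j] = ln( ((n[i, j] + p[i]) / (N + 1)) / p[i] )  ≈  ln( f[i, j] / p[i] )
```

where `n[i, j]` counts base *i* at position *j* and `p[i]` is the background
frequency (uniform 0.25 by default). A window is a site when its additive
score reaches the cutoff; the named profiles are `stringent` (HMG ≥ 4.5,
Helper ≥ 6.5), `relaxed` (3.5 / 5.0) and `figure1` (5.35 / 6.5, used for
per-fragment annotation maps).

**Pair classification.** After normalizing so the HMG consensus reads
5′→3′, a disjoint HMG–Helper hit pair is one of four orientations:
**FF** (Fast Forward: Helper on the same strand, downstream), **AK**
(Akimbo: same strand, upstream), **KK** (Knock Knee: opposite strand,
downstream), **RW** (Rewind: opposite strand, upstream). The *spacer* is
the bp count strictly between the footprints (pairs are binned at spacers
0–15). Because the Helper site is semi-palindromic, one physical site can
read as a Helper on both strands at a 1-bp offset — e.g. `YGCCGGCR`
downstream of an HMG site is both an FF1 and a KK0 — and such pairs are
emitted under both labels, flagged `double_call`, with the overlap reported
as a Venn intersection.

**Enrichment.** Fold enrichment of a bin (or bin group, e.g. FF0–2 ∪
AK0–6) is the raw pair count in bound regions divided by the mean count
over seeded random draws from an aggregate background pool (5′UTR /
intergenic / intronic / 3′UTR regions, ≥ 50 bp each, drawn without
replacement until the sampled bp matches the bound bp; ten runs by
default).

## Worked example

Scan a 51-bp fragment containing a planted AK4 pair and a planted
palindromic Helper word one bp downstream of the HMG site:

```python
import tcfscan as t

hmg, helper = t.default_pwm("HMG"), t.default_pwm("Helper")
seq = "TTTGACCTTTTGCCGCCAAGTCCCTTTGAACTATGCCGGCATTTTTACGTT"
for p in t.find_pairs("crm", seq, hmg, helper, t.get_profile("stringent")):
    print(p.pair_id, p.orientation, p.spacer,
          round(p.hmg.score, 2), round(p.helper.score, 2), p.double_call)
```

prints

```
crm:22+:11+:AK4 AK 4 10.92 8.32 False
crm:22+:33-:KK0 KK 0 10.92 7.02 True
crm:22+:34+:FF1 FF 1 10.92 7.02 True
```

One HMG hit (start 22, `+` strand, score 10.92) pairs with the upstream
Helper as an AK with a 4-bp spacer, and with the downstream semi-palindromic
`TGCCGGCA` word twice — as a KK0 (Helper read on the `-` strand) and as an
FF1 (`+` strand), both flagged as a double call because they are the same
physical site.

The same stages are available from the shell:

```bash
tcfscan simulate --multiplier 5 --outdir fixture/     # synthetic genome + peaks
tcfscan enrich --genome fixture/genome.fa --peaks fixture/tcf_peaks.bed \
               --pool fixture/pool.bed --out enrichment   # TSV + JSON summary
tcfscan partition tcf.bed pannier.bed pmad.bed --out-prefix classes
tcfscan search genome.fa --orientation FF --spacer 1 --out-prefix crm
```

The default PWMs ship as synthetic training sets written from the published
consensus motifs (see `src/tcfscan/data/*.synthetic.fa`); pass your own
training FASTA (`tcfscan build-pwm`, or `RunConfig.hmg_training`) to analyze
real genomes with experimentally derived matrices.

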