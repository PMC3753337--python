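# svjl — structural-variant junction lab

`svjl` is a simulation-backed toolkit for the breakpoint analysis of cancer
genomes sequenced with mate-pair libraries and RNA-seq. It is aimed at
method developers and analysts who need a fully controlled, ground-truthed
re-implementation of the classic tumour rearrangement workflow: calling
structural variants (SVs) from paired-end mapping (PEM) signatures,
segmenting read-depth copy-number profiles, annotating the expected
consequence of each SV on gene structure, resolving junction sequences to
base-pair resolution, testing junction microhomology against a theoretical
null, scanning breakpoint neighbourhoods for motifs, confirming expressed
SVs from RNA-seq read pairs, and detecting chromothripsis.

Every stage can be exercised on synthetic rearranged genomes whose ground
truth — breakpoints, junction classes, microhomology lengths, copy states,
chimeric transcripts — is known exactly, so each detector is testable
against the truth that generated its input.

## The core quantities

**Effective (clone) coverage.** A mate-pair library with insert size *s*
and *N* concordant pairs spans `N·s / G` of a genome of size *G* — the
clone coverage, which governs SV detectability even when base coverage is
below 1X. Twenty million 3 kb pairs over a 6 Gbp diploid genome give 10X.

**PEM signatures.** A concordant mate pair maps in outward orientation
(stored as `strand1='-'`, `strand2='+'`, `pos1 < pos2`) with insert inside
`μ ± kσ` (robust μ, σ from the median/MAD of the insert distribution,
k = 4). Discordant pairs are clustered by single linkage and each cluster's
orientation/spacing pattern maps to one of the eight PEM types: DELETION,
INS_FRAGMT, INV_INS_FRAGMT, INV_FRAGMENT, INVERSION, LARGE_DUPLICATION,
TRANSLOCATION, INTER.

**Junction microhomology.** At a resolved junction the breakpoint can slide
over the interval where both donor sequences agree; the slide length *m* is
the microhomology. Under the null of independent flanks with per-base
match probability `p = Σ f_x²` (base composition `f`),

    P(M = m) = (m + 1) · pᵐ · (1 − p)²,   m ≥ 0,

so with uniform composition `P(M ≥ 1) = 7/16`. Observed spectra are
compared to this null by a chi-square goodness-of-fit test over bins
`{0, …, K−1, ≥K}` with K set by the Cochran rule, stratified by
chromothripsis status. Frequent microhomology is the signature of
microhomology-mediated repair (NHEJ/MMBIR/FoSTeS); templated insertions of
nearby sequence point to replicative template switching.

**Chromothripsis.** A shattered chromosome oscillates between two copy
states (one and two) and concentrates the sample's SV link ends. A
chromosome (or an inter-linked chromosome pair) is flagged when it shows
≥ 10 state switches, ≤ 3 distinct states with the two dominant states
covering ≥ 90% of segments, and ≥ 50% of all link ends.

## Worked example

Plant a deletion whose junction carries 6 bp of microhomology, resolve the
junction read against the reference, and test a microhomology spectrum:

```python
from svjl import simgenome as sg, junctionlab as jl, mhstats, io

g = sg.simulate_genome(1, [120_000], seed=7)
plan = sg.make_deletion_plan(
    g, "chr1", [(40_000, 70_000)],
    specs=[sg.JunctionSpec("microhomology", mh_len=6)])
res = sg.render_derived_genome(g, plan)

_, read, _ = sg.junction_reads(res)[0]
call = jl.resolve_junction(read, res.genome)[0]
print("resolved:", call.chromA, call.posA, "->", call.chromB, call.posB,
      call.kind, "mh =", call.mh_len)
print(io.alignment_block(call, res.genome, flank=20))

null = mhstats.null_pmf(res.genome.base_frequencies)
r = mhstats.mh_chisq([6, 3, 1, 0, 2, 5, 4, 1, 1, 2, 7, 3, 2, 1, 4, 2, 0, 3,
                      1, 6], null)
print(f"chi2 = {r.chi2:.1f}, df = {r.df}, p = {r.p_value:.2e}")
```

prints

```
resolved: chr1 40000 -> chr1 70007 microhomology mh = 6
# junction j class=microhomology microhomology=6
segA chr1:40000(+) ...TCAAGACCTTGATCGCCGAA|
segB chr1:70007(+)    |TCTCGCCTCCGCATTGCCAG...
chi2 = 17.4, df = 1, p = 3.05e-05
```

The resolver recovers the planted breakpoints exactly (`posA` carries the
microhomology bases; `posB` is the first base after the slide interval),
and a spectrum of 20 junctions rich in microhomology rejects the
independent-flank null at p ≈ 3e-05.

The same machinery is available from the shell:

```
svjl simulate --mode chromothripsis --seed 1 --outdir out/
svjl detect   --pairs out/pairs.bedpe --out out/links.bedpe
svjl cnv      --pairs out/pairs.bedpe --ref out/reference.fa --out out/cnv.tsv
svjl junction --reads out/junction_reads.fa --ref out/reference.fa --out out/calls.tsv
svjl run      --config pipeline.yaml          # full pipeline + manifest
```

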