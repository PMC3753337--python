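# Methods

This note documents the models, algorithms and numerical choices behind
`svjl`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Synthetic rearranged genomes (`simgenome`)

Reference chromosomes are i.i.d. draws from a base-composition vector
(uniform by default). Gene models are placed non-overlapping with 2–8
exons; TSS/transcription-end are stored strand-resolved (the TSS of a
minus-strand gene is its larger coordinate).

A rearrangement plan is an ordered list of donor segments with one junction
specification between neighbours. Junctions are blunt, carry planted
microhomology *m* (0–28 bp by default), an untemplated insertion of
1–17 bp, or an inserted mapped fragment: a *templated insertion* when the
fragment comes from within 10 kb of a breakpoint, a *genomic shard* when it
comes from further away (`shard_min = 10 kb` is our convention; the
literature says only "at some distance"). The default junction-pattern mix
(68% microhomology / 20% blunt / 12% insertion, truncated-geometric
microhomology lengths with ratio 0.65) reflects the pattern census of
validated junction sets in tumour mate-pair studies.

**Exact microhomology planting.** For the junction resolver to measure *m*
bases of homology, both donors must actually share the terminal word, so
rendering overwrites the first *m* bases of the acceptor flank *in the
reference* with the donor's terminal word before the derived sequence is
assembled. Single-base *guard* substitutions adjacent to each junction
(donor continuation vs. first derived base on each side) prevent accidental
extension of the homology, so planted and realised *m* agree exactly.
Homology words and acceptor flanks become immutable once planted; guard
bases remain editable under recorded inequality constraints, which lets
densely packed junctions (chromothripsis) coexist. Irreconcilable layouts
(overlapping flanks, seamless re-joins of reference-adjacent fragments)
raise a conflict error rather than emitting inexact truth.

**Chromothripsis plans** shatter one chromosome into `2·n_events`
fragments (≥ `min_segment` each), retain an alternating-with-noise subset —
so the true copy profile has exactly two states (1: lost, 2: retained, on
top of the intact homologue) and at least `n_events` state switches — and
reassemble retained fragments in random order and orientation, rejecting
orderings that rejoin reference neighbours seamlessly.

**Mate pairs** are drawn uniformly along each haplotype with Gaussian
insert (default 3000 ± 300 bp, read length 50). The haplotype set is either
clonal (derived chromosomes plus intact copies of untouched chromosomes) or
diploid (every chromosome keeps one intact homologue), the latter producing
the one/two-copy oscillation of chromothripsis. Reads are emitted as
already-mapped coordinates; a concordant pair is stored outward
(`-`/`+`, pos1 < pos2). Reads falling across a junction or inside an
untemplated insertion are dropped as unmappable — the coordinate-level
analogue of an unaligned split read. Allocation of pairs across haplotypes
is proportional to length, so "effective coverage" `n·insert/Σlength`
equals the per-copy clone coverage.

**RNA-seq pairs** are drawn from weighted transcripts (normal spliced
genes, 5′X→3′Y fusion transcripts, exon-deletion transcripts, optionally
with retained breakpoint introns); fragment length 300 ± 30. Weights are
TPM-like relative abundances; weight 0 silences a transcript.

*Not emulated:* base-call errors, quality values, mappability or GC bias,
repeat-driven mis-mapping, subclonal mixtures beyond a single purity
parameter, and splice-graph complexity beyond the transcript forms above.
Passing tests therefore demonstrate correctness of the detectors' logic
under idealised mapping, not robustness to alignment artefacts of real
data.

## PEM-signature SV calling (`pemdetect`)

The insert model is fitted robustly (median and 1.4826·MAD) with one
trim-and-refit pass inside the provisional `μ ± kσ` window, which removes
the systematic median shift that one-sided contamination (discordant pairs
up to ~10%) would otherwise cause. `k = 4` defines the concordant window: a
Gaussian tail of ~6e-5 keeps false discordant pairs rare at 10X clone
coverage.

PCR duplicates (identical coordinates/strands) are collapsed. Discordant
pairs sharing chromosome pair, strand pair and signature are clustered by
single linkage with both ends within `μ + kσ`; clusters need `min_support`
(default 2) distinct pairs. Pairs are sorted before clustering, making the
output order-independent. Breakpoints are estimated from the retained
flank: a `-` end's junction lies just right of its rightmost read, a `+`
end's just left of its leftmost read.

The decision table mapping cluster geometry to the eight PEM types is:
intra-chromosomal outward+stretched → DELETION; outward+shrunk →
INS_FRAGMT; same-strand with a reciprocal opposite-sign cluster →
INV_FRAGMENT; same-strand with short span → INV_INS_FRAGMT; other
same-strand → INVERSION; inward ("order-swapped") with span above the mean
insert → LARGE_DUPLICATION; inter-chromosomal with opposite strands
(compatible with a simple derivative chromosome) → TRANSLOCATION, otherwise
INTER. Unclassifiable geometries are labelled UNDEFINED and counted.

## Copy-number profiling (`readprofile`)

Read starts are counted in 30 kb windows, normalised by the genome-wide
median, and segmented per chromosome by recursive binary splitting of the
squared error: a split is accepted when its SSE gain exceeds
`penalty · log(n)`. The default penalty is chosen by deterministic 2-fold
cross-validation (odd windows segmented, even windows predicted) over a
grid of multiples of the noise variance estimated from successive
differences. Integer states are `round(ploidy · segment median ratio)`;
known tumour purity rescales ratios as `(r − (1−purity))/purity` first.
GC-bias correction is deliberately omitted (synthetic reads are unbiased);
the configuration leaves room for a quadratic count~GC fit on real data.
Median normalisation assumes the majority of windows sit at the modal
ploidy — samples where oscillating states cover most of the genome need an
external baseline.

## Gene-impact annotation (`svannotate`)

A link end falls in a gene if its read interval overlaps
[TSS, transcription end]; within 2 kb upstream of a TSS it is a promoter
end. The category logic is a documented reconstruction (the published
material states the location rules but not the category table): fusions
joining the 5′ part of one gene to the 3′ part of another in compatible
transcriptional orientation → *Possible chimera*; other genic fusions and
one-sided genic ends → *Truncated*; intragenic events removing, inverting
or duplicating ≥ 1 exon → *May change function*; fully intronic events →
*Does not change function*; tandem duplications spanning a whole gene →
*May not change function*; otherwise *Promoter* / *Intergenic*. With
several overlapping genes the most damaging category wins and all genes
are listed. The damaging rollup is {Truncated, Possible chimera, May
change function}. Retained-side logic: a `-` cluster strand retains the
left flank, so an end keeps the 5′ part of a gene iff (strand is `-`) ==
(gene on `+`).

## Junction resolution (`junctionlab`)

Junction reads are anchored by maximal exact extension of a `min_anchor`
(20 bp) seed from each read end, both strands; 20 bp guarantees uniqueness
in the synthetic genomes used here (4²⁰ ≫ genome size). Overlap of the two
alignments on the read is the microhomology; a gap is a candidate inserted
sequence. Gaps ≥ 15 bp are re-seeded from their centre with a 10-mer: a
unique mapping makes the read three segments (fragment classified
templated/shard by the 10 kb rule, with microhomology measured at both
sub-junctions); otherwise the gap is an untemplated insertion. Reported
coordinates assign microhomology bases to segA, with the slide length
recorded; microhomology and insertion are mutually exclusive outputs.
Sanger-quality synthetic reads are assumed near-perfect, so extension is
mismatch-free. Rearrangements resolving to ≥ 2 junctions are labelled
complex.

## Microhomology statistics (`mhstats`)

The null is the independent-flank slide model: `p = Σ f_x²` from base
composition, `P(M=m) = (m+1)pᵐ(1−p)²` (the convolution of two geometric
extensions). It matches brute-force enumeration exactly and Monte-Carlo
draws within sampling error. The chi-square test pools lengths into
`{0,…,K−1, ≥K}` with K chosen by the Cochran rule (all expected ≥ 1, ≥ 80%
of bins ≥ 5); df = K. Insertion-class junctions are excluded from the test
(an inserted sequence and a microhomology are mutually exclusive junction
patterns). The null is pluggable — anything exposing `pmf`/`tail` can
replace it. Strata are pooled across samples per chromothripsis flag.

## Motif enrichment (`motifscan`)

Windows of 40 and 250 bp centred on breakpoints are scanned for IUPAC
motifs (optional mismatch budget) on both strands. Enrichment is empirical:
`n_background` chromosome-matched random breakpoint sets, add-one-smoothed
`p = (1 + #{bg ≥ obs})/(1 + n_background)`, Benjamini–Hochberg across
motifs × windows. The permutation construction respects genome
heterogeneity but is conservative for discrete hit counts. The shipped
catalog (S/MAR AT-rich rule, topoisomerase I/II consensus, translin sites,
Alu core, deletion hotspot TGRRKM, Ig-switch repeat) is a documented
default, editable as TSV; the machinery is catalog-agnostic. Composition
metrics (GC, polypurine/polypyrimidine and alternating purine–pyrimidine
run lengths) are reported with z-scores against the same background.

## Expressed SVs (`rnaevidence`)

SVs annotated *Possible chimera* or *May change function* are eligible. A
pair supports an SV when one end maps sense within the upstream gene on the
retained side of its breakpoint (an exon, or the single intron containing
the breakpoint — the narrowest reading of "intronic regions adjacent to the
breakpoints") and the other end symmetrically in the downstream gene;
anti-sense pairs are not support. An SV is expressed with ≥ 2 supporting
pairs. Eligible SVs partition into expressed / silent partner genes (zero
RNA pairs over both genes) / expressed-but-unsupported. Patterns follow the
`5'X -> 3'Y` / `5'X -> intron Y` / `exon-deletion X` grammar with per-pair
counts.

## Chromothripsis detection (`shatterscan`)

Per chromosome: state switches between adjacent segments, distinct-state
count, share of segments in the two dominant states, and the fraction of
all SV link ends. Defaults flag a chromosome with ≥ 10 switches, ≤ 3
distinct states, two-state share ≥ 0.9 and end fraction ≥ 0.5 — explicit,
configurable thresholds reconstructing the oscillating-two-state
phenomenology; no single published criterion is canonical. Chromosome
pairs joined by ≥ 5 inter-chromosomal links are additionally scored as one
unit (switches summed within chromosomes, ends pooled), capturing
two-chromosome shattering. Scores are invariant to chromosome renaming.
`run_pipeline` chains all stages with per-stage error labelling and writes
a manifest (version, seed, parameters) plus Circos-compatible link files.

## Problem sizes and determinism

All randomness flows through explicit integer seeds; identical seeds give
byte-identical outputs. The test and acceptance simulations use
chromosomes of 0.1–4.5 Mb, 8–12 chromothripsis events with ≥ 165 kb
fragments, simple SVs of 60–200 kb, and 25–100 seeded replicates per
operating-characteristic estimate — sizes chosen so the complete suite
runs in about a minute on one CPU while keeping per-junction clone support
(≈ coverage × (1 − 2·read_len/insert)) in the regime the detectors are
designed for. Recovery and sensitivity rates quoted by the acceptance
script are Monte-Carlo estimates at those sizes.

## Known limitations

* Idealised mapping: no mis-mapping, no mappability holes, so measured
  operating characteristics are upper bounds for real data.
* Median-based copy-number normalisation assumes a dominant modal ploidy.
* The annotation category table and the chromothripsis thresholds are
  explicit reconstructions, exposed as configuration rather than fixed
  truths.
* The empirical motif test is conservative for very small breakpoint sets;
  exact identities of historically used motif catalogs vary, so the default
  set is a curated stand-in.
* Amplicon structures are represented only as extra copy states, not as an
  assembly graph.
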