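"""Synthetic rearranged genomes with base-pair ground truth.

This module is the data side of the toolkit.  It simulates reference genomes
and gene models, plans rearrangements (simple unbalanced events and
chromothripsis), renders the derived (rearranged) sequence together with a
ground-truth list of junction calls, and emits mate-pair and RNA-seq read
pairs as already-mapped coordinate tables — the statistical stand-in for a
tumour mate-pair / RNA-seq experiment.

Ground truth is exact by construction: a junction planted with microhomology
``m`` is realised by overwriting the first ``m`` bases of the acceptor flank
in the reference with the donor's terminal word, so that both flanks share
the ``m``-base word, and single-base guard substitutions adjacent to each
junction prevent accidental extension of the homology.  Untemplated
insertions appear verbatim (up to a rare guard substitution of a terminal
base when the neighbouring context cannot be edited).

Coordinates are 0-based half-open internally; read-pair tables and reported
junctions use 1-based positions (conversion at the I/O boundary only).
Mate-pair orientation follows the outward convention: a concordant pair is
stored with ``strand1='-'``, ``strand2='+'`` and ``pos1 < pos2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .junctionlab import SHARD_MIN, JunctionCall
from .seq import BASES, base_frequencies, random_dna, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class JunctionConflictError(ValueError):
    """Junction specs collide (overlapping flanks, frozen guard bases...)."""


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

class Genome:
    """Named chromosome sequences over the ACGT alphabet."""

    def __init__(self, chromosomes: dict, validate: bool = True):
        if validate:
            for name, seq in chromosomes.items():
                if not seq:
                    raise ValueError(f"chromosome {name!r} is empty")
                if set(seq) - set("ACGT"):
                    raise ValueError(f"chromosome {name!r} has non-ACGT characters")
        self.chromosomes = dict(chromosomes)

    @property
    def base_frequencies(self) -> np.ndarray:
        return base_frequencies(list(self.chromosomes.values()))

    def chrom_length(self, name: str) -> int:
        return len(self.chromosomes[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __repr__(self):
        return f"Genome({len(self.chromosomes)} chromosomes, {self.total_length} bp)"


def simulate_genome(n_chrom: int, lengths, base_freqs=None, seed: int = 0,
                    names=None) -> Genome:
    """Simulate a genome of ``n_chrom`` chromosomes with i.i.d. bases.

    ``base_freqs`` is the ACGT probability vector (uniform by default); it
    must sum to 1 within 1e-9.  Reproducible for a fixed ``seed``.
    """
    lengths = list(lengths)
    if len(lengths) != n_chrom:
        raise ValueError("len(lengths) must equal n_chrom")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    if base_freqs is None:
        base_freqs = np.full(4, 0.25)
    f = np.asarray(base_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must be a 4-vector summing to 1")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chrom)]
    rng = np.random.default_rng(seed)
    chroms = {nm: random_dna(rng, L, p=f) for nm, L in zip(names, lengths)}
    return Genome(chroms, validate=False)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-resolved TSS/transcription end and exons.

    ``tss`` and ``tx_end`` are 1-based genomic positions with ``tss`` the
    transcription start (so ``tss > tx_end`` on the minus strand); exons are
    1-based closed intervals sorted in genomic order.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tx_end: int
    exons: tuple

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.strand == "+" and not self.tss < self.tx_end:
            raise ValueError("plus-strand gene requires tss < tx_end")
        if self.strand == "-" and not self.tss > self.tx_end:
            raise ValueError("minus-strand gene requires tss > tx_end")
        lo, hi = self.span
        prev_end = lo - 1
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError("exons must be sorted, non-overlapping")
            prev_end = e
        if self.exons and (self.exons[0][0] < lo or self.exons[-1][1] > hi):
            raise ValueError("exons outside the transcription unit")

    @property
    def span(self):
        """1-based closed genomic interval [start, end] of the gene."""
        return (min(self.tss, self.tx_end), max(self.tss, self.tx_end))

    @property
    def exons0(self):
        """Exons as 0-based half-open intervals in genomic order."""
        return [(s - 1, e) for s, e in self.exons]


def simulate_gene_models(genome: Genome, n_genes: int, seed: int = 0,
                         gene_length=(5_000, 30_000), n_exons=(2, 8),
                         exon_length=(100, 300), margin: int = 3_000):
    """Random non-overlapping gene models spread across the genome."""
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    genes = []
    occupied = {c: [] for c in chrom_names}
    attempts = 0
    while len(genes) < n_genes and attempts < 50 * n_genes:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        L = genome.chrom_length(chrom)
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        if L < glen + 2 * margin:
            continue
        start = int(rng.integers(margin, L - margin - glen))  # 0-based
        end = start + glen
        if any(s < end + margin and start < e + margin for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        k = int(rng.integers(n_exons[0], n_exons[1] + 1))
        # first exon at the gene start, last at the gene end, rest spread out
        cuts = np.sort(rng.choice(np.arange(1, glen - exon_length[1]),
                                  size=max(k - 1, 1), replace=False))
        exons = []
        pos = 0
        for i in range(k):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            s = pos if i == 0 else int(cuts[min(i - 1, len(cuts) - 1)])
            s = max(s, pos)
            e = min(s + elen, glen)
            if i == k - 1:
                e = glen
                s = max(s, e - elen)
            if s >= e or (exons and s <= exons[-1][1]):
                continue
            exons.append((s, e))
            pos = e + 1
        strand = "+" if rng.random() < 0.5 else "-"
        exons_1 = tuple((start + s + 1, start + e) for s, e in exons)
        if strand == "+":
            gm = GeneModel(f"G{len(genes) + 1:04d}", chrom, "+",
                           start + 1, end, exons_1)
        else:
            gm = GeneModel(f"G{len(genes) + 1:04d}", chrom, "-",
                           end, start + 1, exons_1)
        genes.append(gm)
    if len(genes) < n_genes:
        raise ValueError("could not place the requested number of genes")
    return genes


# ---------------------------------------------------------------------------
# rearrangement plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """Reference interval (0-based half-open) taken into the derived genome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.strand not in "+-":
            raise ValueError("segment strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class JunctionSpec:
    """How two consecutive plan segments are joined."""

    kind: str = "blunt"  # blunt | microhomology | insertion | shard | templated
    mh_len: int = 0
    insertion_seq: str = ""
    fragment: Segment | None = None
    fragment_mh: tuple = (0, 0)  # microhomology at the two fragment joins

    def __post_init__(self):
        if self.kind == "microhomology" and self.mh_len < 1:
            raise ValueError("microhomology spec requires mh_len >= 1")
        if self.kind == "insertion" and not self.insertion_seq:
            raise ValueError("insertion spec requires a sequence")
        if self.kind in ("shard", "templated") and self.fragment is None:
            raise ValueError(f"{self.kind} spec requires a fragment segment")


@dataclass
class RearrangementPlan:
    """Ordered donor segments with one junction spec between neighbours."""

    name: str
    segments: list
    junctions: list
    sv_type: str = "custom"
    chromothripsis: bool = False
    target_chrom: str | None = None
    true_states: list | None = None  # [(chrom, start, end, state)] ref order

    def __post_init__(self):
        if len(self.junctions) != len(self.segments) - 1:
            raise ValueError("need exactly one junction spec between "
                             "consecutive segments")


def validate_plan(genome: Genome, plan: RearrangementPlan):
    for seg in plan.segments:
        if seg.chrom not in genome.chromosomes:
            raise ValueError(f"unknown chromosome {seg.chrom!r}")
        if seg.end > genome.chrom_length(seg.chrom):
            raise ValueError("segment outside chromosome bounds")
    for spec in plan.junctions:
        if spec.fragment is not None:
            f = spec.fragment
            if f.chrom not in genome.chromosomes or \
                    f.end > genome.chrom_length(f.chrom):
                raise ValueError("fragment outside genome bounds")


@dataclass
class JunctionDistribution:
    """Distribution of junction patterns used by the planner.

    Defaults reflect the observed mix on resolved junctions: roughly 68%
    microhomology, 20% blunt and 12% short untemplated insertions, with
    microhomology lengths following a truncated geometric law on 1..28 bp
    and insertions of 1-17 bp.
    """

    p_microhomology: float = 40 / 59
    p_blunt: float = 12 / 59
    p_insertion: float = 7 / 59
    mh_pmf: dict | None = None
    mh_geom_q: float = 0.65
    max_mh: int = 28
    ins_len_range: tuple = (1, 17)

    def _mh_support(self):
        if self.mh_pmf is not None:
            ms = sorted(self.mh_pmf)
            ps = np.array([self.mh_pmf[m] for m in ms], dtype=float)
        else:
            ms = list(range(1, self.max_mh + 1))
            ps = self.mh_geom_q ** (np.arange(self.max_mh, dtype=float))
        return ms, ps / ps.sum()

    def draw(self, rng: np.random.Generator) -> JunctionSpec:
        probs = np.array([self.p_microhomology, self.p_blunt, self.p_insertion])
        probs = probs / probs.sum()
        kind = ["microhomology", "blunt", "insertion"][int(rng.choice(3, p=probs))]
        if kind == "microhomology":
            ms, ps = self._mh_support()
            m = int(np.asarray(ms)[int(rng.choice(len(ms), p=ps))])
            return JunctionSpec("microhomology", mh_len=m)
        if kind == "insertion":
            n = int(rng.integers(self.ins_len_range[0], self.ins_len_range[1] + 1))
            return JunctionSpec("insertion", insertion_seq=random_dna(rng, n))
        return JunctionSpec("blunt")


# --- convenience plan builders ---------------------------------------------

def make_deletion_plan(genome: Genome, chrom: str, intervals, specs=None,
                       name: str = "del") -> RearrangementPlan:
    """Delete one or more (start, end) 0-based intervals from a chromosome."""
    L = genome.chrom_length(chrom)
    ivs = sorted(intervals)
    segments, pos = [], 0
    for s, e in ivs:
        if s <= pos or e >= L:
            raise ValueError("deletion intervals must be internal and sorted")
        segments.append(Segment(chrom, pos, s))
        pos = e
    segments.append(Segment(chrom, pos, L))
    if specs is None:
        specs = [JunctionSpec() for _ in ivs]
    return RearrangementPlan(name, segments, list(specs), sv_type="deletion")


def make_inversion_plan(genome: Genome, chrom: str, start: int, end: int,
                        specs=None, name: str = "inv") -> RearrangementPlan:
    L = genome.chrom_length(chrom)
    if not 0 < start < end < L:
        raise ValueError("inversion must be internal to the chromosome")
    segments = [Segment(chrom, 0, start), Segment(chrom, start, end, "-"),
                Segment(chrom, end, L)]
    if specs is None:
        specs = [JunctionSpec(), JunctionSpec()]
    return RearrangementPlan(name, segments, list(specs), sv_type="inversion")


def make_duplication_plan(genome: Genome, chrom: str, start: int, end: int,
                          specs=None, name: str = "dup") -> RearrangementPlan:
    """Tandem duplication of [start, end)."""
    L = genome.chrom_length(chrom)
    if not 0 < start < end < L:
        raise ValueError("duplication must be internal to the chromosome")
    segments = [Segment(chrom, 0, end), Segment(chrom, start, L)]
    if specs is None:
        specs = [JunctionSpec()]
    return RearrangementPlan(name, segments, list(specs), sv_type="duplication")


def make_translocation_plan(genome: Genome, chromA: str, bpA: int,
                            chromB: str, bpB: int, specs=None,
                            name: str = "tra") -> RearrangementPlan:
    """Unbalanced translocation joining chromA[:bpA] to chromB[bpB:]."""
    segments = [Segment(chromA, 0, bpA),
                Segment(chromB, bpB, genome.chrom_length(chromB))]
    if specs is None:
        specs = [JunctionSpec()]
    return RearrangementPlan(name, segments, list(specs),
                             sv_type="translocation")


def make_fragment_insertion_plan(genome: Genome, chrom: str, start: int,
                                 end: int, fragment: Segment, kind: str,
                                 name: str = "frag") -> RearrangementPlan:
    """Deletion of [start, end) with a mapped fragment inserted at the gap
    (``kind`` is 'templated' or 'shard')."""
    plan = make_deletion_plan(genome, chrom, [(start, end)], name=name)
    plan.junctions = [JunctionSpec(kind, fragment=fragment)]
    plan.sv_type = kind
    return plan


_SIMPLE_TYPES = ("deletion", "duplication", "inversion", "translocation")


def plan_rearrangements(genome: Genome, mode: str, n_events: int,
                        junction_dist: JunctionDistribution | None = None,
                        seed: int = 0, target_chrom: str | None = None,
                        size_range=(50_000, 5_000_000), sv_types=None,
                        min_segment: int = 150_000, margin: int = 20_000,
                        states=(1, 2)):
    """Plan ``n_events`` rearrangements.

    In ``simple`` mode each event occupies its own chromosome(s) and has size
    drawn log-uniformly from ``size_range`` (honouring the >50 kb large-SV
    convention by default).  In ``chromothripsis`` mode the designated
    chromosome is shattered into ``2 * n_events`` fragments; a subset is
    retained so the true copy profile alternates between exactly two states,
    and retained fragments are reassembled in random order and orientation.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    dist = junction_dist or JunctionDistribution()
    if mode == "simple":
        return _plan_simple(genome, n_events, dist, rng, size_range,
                            sv_types, margin)
    if mode == "chromothripsis":
        return [_plan_chromothripsis(genome, n_events, dist, rng,
                                     target_chrom, min_segment, states)]
    raise ValueError(f"unknown mode {mode!r}")


def _plan_simple(genome, n_events, dist, rng, size_range, sv_types, margin):
    types = list(sv_types) if sv_types else list(_SIMPLE_TYPES)
    pool = list(genome.chromosomes)
    rng.shuffle(pool)
    plans = []
    for i in range(n_events):
        t = types[i % len(types)]
        need = 2 if t == "translocation" else 1
        if len(pool) < need:
            raise ValueError("not enough chromosomes for the requested events")
        name = f"sv{i + 1}"
        if t == "translocation":
            ca, cb = pool.pop(), pool.pop()
            bpa = int(rng.integers(margin, genome.chrom_length(ca) - margin))
            bpb = int(rng.integers(margin, genome.chrom_length(cb) - margin))
            plan = make_translocation_plan(genome, ca, bpa, cb, bpb,
                                           specs=[dist.draw(rng)], name=name)
        else:
            c = pool.pop()
            L = genome.chrom_length(c)
            lo, hi = size_range
            hi = min(hi, L - 2 * margin - 1)
            if hi <= lo:
                raise ValueError(f"chromosome {c} too short for a "
                                 f">={lo} bp event")
            size = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
            start = int(rng.integers(margin, L - margin - size))
            if t == "deletion":
                plan = make_deletion_plan(genome, c, [(start, start + size)],
                                          specs=[dist.draw(rng)], name=name)
            elif t == "inversion":
                plan = make_inversion_plan(genome, c, start, start + size,
                                           specs=[dist.draw(rng),
                                                  dist.draw(rng)], name=name)
            else:
                plan = make_duplication_plan(genome, c, start, start + size,
                                             specs=[dist.draw(rng)], name=name)
        plans.append(plan)
    return plans


def _draw_simple_spec(dist, rng):
    spec = dist.draw(rng)
    while spec.kind in ("shard", "templated"):  # pragma: no cover - defensive
        spec = dist.draw(rng)
    return spec


def _plan_chromothripsis(genome, n_events, dist, rng, target_chrom,
                         min_segment, states):
    chrom = target_chrom or max(genome.chromosomes,
                                key=genome.chrom_length)
    L = genome.chrom_length(chrom)
    n_frag = 2 * n_events
    if L < n_frag * min_segment:
        raise ValueError(f"chromosome {chrom} too short to shatter into "
                         f"{n_frag} fragments of >= {min_segment} bp")
    extra = rng.multinomial(L - n_frag * min_segment, np.full(n_frag, 1 / n_frag))
    lengths = min_segment + extra
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    fragments = [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_frag)]

    # retention pattern: alternating with random flips, both states present
    # and at least n_events state switches
    for _ in range(100):
        start = int(rng.integers(2))
        pattern = np.array([(i + start) % 2 for i in range(n_frag)], dtype=bool)
        flips = rng.random(n_frag) < 0.1
        pattern ^= flips
        switches = int(np.sum(pattern[1:] != pattern[:-1]))
        if pattern.any() and (~pattern).any() and switches >= min(n_events, n_frag - 1):
            break
    else:  # strict alternation always satisfies the contract
        pattern = np.array([i % 2 == 0 for i in range(n_frag)])

    retained = [i for i in range(n_frag) if pattern[i]]
    # random order/orientation, rejecting seamless reference-adjacent joins
    for _ in range(200):
        order = list(rng.permutation(len(retained)))
        strands = ["+" if rng.random() < 0.5 else "-" for _ in retained]
        segs = [Segment(chrom, *fragments[retained[j]], strands[k])
                for k, j in enumerate(order)]
        if not any(_seamless(a, b) for a, b in zip(segs, segs[1:])):
            break
    else:
        raise ValueError("could not shuffle fragments without seamless joins")

    junctions = [_draw_simple_spec(dist, rng) for _ in range(len(segs) - 1)]
    true_states = [(chrom, s, e, states[1] if pattern[i] else states[0])
                   for i, (s, e) in enumerate(fragments)]
    return RearrangementPlan("ct", segs, junctions, sv_type="chromothripsis",
                             chromothripsis=True, target_chrom=chrom,
                             true_states=true_states)


def _seamless(a: Segment, b: Segment) -> bool:
    """True when joining a to b reproduces the reference contiguously."""
    if a.chrom != b.chrom:
        return False
    if a.strand == "+" and b.strand == "+" and a.end == b.start:
        return True
    if a.strand == "-" and b.strand == "-" and b.end == a.start:
        return True
    return False


def merged_true_states(plan: RearrangementPlan):
    """Merge adjacent equal-state fragments of the true copy profile."""
    if plan.true_states is None:
        raise ValueError("plan has no true copy states")
    merged = []
    for chrom, s, e, st in plan.true_states:
        if merged and merged[-1][0] == chrom and merged[-1][3] == st \
                and merged[-1][2] == s:
            merged[-1] = (chrom, merged[-1][1], e, st)
        else:
            merged.append((chrom, s, e, st))
    return merged


# ---------------------------------------------------------------------------
# rendering the derived genome
# ---------------------------------------------------------------------------

class DerivedGenome:
    """A derived (rearranged) sequence with its block map to the reference."""

    def __init__(self, name, blocks, boundary_labels, sequence=None):
        # blocks: list of (chrom|None, ref_lo, length, strand)
        self.name = name
        self.sequence = sequence
        self.boundary_labels = list(boundary_labels)
        chrom_names = []
        codes = []
        for chrom, *_ in blocks:
            if chrom is not None and chrom not in chrom_names:
                chrom_names.append(chrom)
            codes.append(-1 if chrom is None else chrom_names.index(chrom))
        self.chrom_names = chrom_names
        self.chrom_code = np.array(codes, dtype=np.int64)
        self.ref_lo = np.array([b[1] for b in blocks], dtype=np.int64)
        self.block_len = np.array([b[2] for b in blocks], dtype=np.int64)
        self.strand = np.array([1 if b[3] == "+" else -1 for b in blocks],
                               dtype=np.int64)
        self.block_start = np.concatenate([[0], np.cumsum(self.block_len)])[:-1]
        self.length = int(self.block_len.sum())

    def map_reads(self, starts: np.ndarray, read_len: int):
        """Map derived read-start positions to reference coordinates.

        Returns (chrom_code, ref_start0, strand_flip, ok, block_idx); reads
        crossing a block boundary or inside an unmapped block get ok=False.
        """
        idx = np.searchsorted(self.block_start, starts, side="right") - 1
        off = starts - self.block_start[idx]
        ok = (off + read_len <= self.block_len[idx]) & (self.chrom_code[idx] >= 0)
        plus = self.strand[idx] == 1
        ref = np.where(plus, self.ref_lo[idx] + off,
                       self.ref_lo[idx] + self.block_len[idx] - off - read_len)
        return self.chrom_code[idx], ref, ~plus, ok, idx


def identity_derived(genome: Genome, chrom: str, name=None,
                     with_sequence: bool = False) -> DerivedGenome:
    """An intact chromosome wrapped as a trivial derived genome."""
    L = genome.chrom_length(chrom)
    seq = genome.chromosomes[chrom] if with_sequence else None
    return DerivedGenome(name or chrom, [(chrom, 0, L, "+")], [], sequence=seq)


@dataclass
class RenderResult:
    derived: DerivedGenome
    truth: list
    genome: Genome  # reference after homology planting / guard substitutions
    plan: RearrangementPlan


class _Buffers:
    """Mutable chromosome byte buffers with frozen-interval bookkeeping."""

    def __init__(self, genome: Genome):
        self.buf = {c: bytearray(s, "ascii")
                    for c, s in genome.chromosomes.items()}
        self.frozen = {c: [] for c in genome.chromosomes}

    def _pos(self, seg: Segment, i: int) -> int:
        return seg.start + i if seg.strand == "+" else seg.end - 1 - i

    def base(self, seg: Segment, i: int):
        """Base at derived-orientation index ``i`` of ``seg`` (may address
        donor context outside the segment); None beyond chromosome ends."""
        p = self._pos(seg, i)
        if p < 0 or p >= len(self.buf[seg.chrom]):
            return None
        b = chr(self.buf[seg.chrom][p])
        return b if seg.strand == "+" else _COMP[b]

    def word(self, seg: Segment, start: int, length: int) -> str:
        return "".join(self.base(seg, i) for i in range(start, start + length))

    def is_frozen(self, chrom: str, lo: int, hi: int) -> bool:
        return any(s < hi and lo < e for s, e in self.frozen[chrom])

    def freeze(self, chrom: str, lo: int, hi: int):
        self.frozen[chrom].append((lo, hi))

    def write(self, seg: Segment, i: int, base: str):
        """Set the derived-orientation base at index ``i`` of ``seg``."""
        p = self._pos(seg, i)
        b = base if seg.strand == "+" else _COMP[base]
        self.buf[seg.chrom][p] = ord(b)

    def write_word(self, seg: Segment, start: int, word: str):
        lo = min(self._pos(seg, start), self._pos(seg, start + len(word) - 1))
        hi = max(self._pos(seg, start), self._pos(seg, start + len(word) - 1)) + 1
        if self.is_frozen(seg.chrom, lo, hi):
            raise JunctionConflictError("acceptor flank overlaps a region "
                                        "required by another junction")
        for k, ch in enumerate(word):
            self.write(seg, start + k, ch)
        self.freeze(seg.chrom, lo, hi)

    def ref_endpoint(self, seg: Segment, i: int):
        """Guard endpoint descriptor for oriented index ``i`` of ``seg``."""
        return ("ref", seg.chrom, self._pos(seg, i), seg.strand)


def _seg_len(seg: Segment) -> int:
    return seg.end - seg.start


def _oriented_ref_pos(seg: Segment, i: int) -> int:
    return seg.start + i if seg.strand == "+" else seg.end - 1 - i


class _GuardLedger:
    """Inequality constraints between guard bases.

    Homology words and acceptor flanks are immutable once planted (tracked
    by the buffer's frozen intervals).  Guard bases — the single positions
    flanking each junction whose equality would extend an alignment — stay
    mutable, subject to the inequality constraints already established for
    earlier junctions.  An endpoint is ``('ref', chrom, pos, orient)`` (its
    derived-orientation value is the complement when orient is '-') or
    ``('ins', ins_list, idx)`` for untemplated-insertion characters.
    """

    def __init__(self, bufs: _Buffers):
        self.bufs = bufs
        self.constraints = {}

    def _key(self, ep):
        if ep[0] == "ref":
            return ("ref", ep[1], ep[2])
        return ("ins", id(ep[1]), ep[2])

    def value(self, ep):
        if ep[0] == "ref":
            _, chrom, pos, orient = ep
            buf = self.bufs.buf[chrom]
            if pos < 0 or pos >= len(buf):
                return None
            b = chr(buf[pos])
            return b if orient == "+" else _COMP[b]
        return ep[1][ep[2]]

    def mutable(self, ep) -> bool:
        if ep[0] == "ins":
            return True
        _, chrom, pos, _ = ep
        return not self.bufs.is_frozen(chrom, pos, pos + 1)

    def _set(self, ep, derived_value):
        if ep[0] == "ref":
            _, chrom, pos, orient = ep
            b = derived_value if orient == "+" else _COMP[derived_value]
            self.bufs.buf[chrom][pos] = ord(b)
        else:
            ep[1][ep[2]] = derived_value

    def _forbidden(self, ep):
        vals = {self.value(p) for p in self.constraints.get(self._key(ep), [])}
        vals.discard(None)
        return vals

    def _register(self, ep_a, ep_b):
        self.constraints.setdefault(self._key(ep_a), []).append(ep_b)
        self.constraints.setdefault(self._key(ep_b), []).append(ep_a)

    def ensure_diff(self, ep_a, ep_b):
        """Make the derived-orientation values of the two endpoints differ,
        mutating whichever side is editable, and record the constraint."""
        va, vb = self.value(ep_a), self.value(ep_b)
        if va is None or vb is None:  # chromosome edge: no extension possible
            return
        if va != vb:
            self._register(ep_a, ep_b)
            return
        for ep, other in ((ep_a, ep_b), (ep_b, ep_a)):
            if not self.mutable(ep):
                continue
            avoid = self._forbidden(ep) | {self.value(other)}
            choice = next((b for b in BASES if b not in avoid), None)
            if choice is None:
                continue
            self._set(ep, choice)
            self._register(ep_a, ep_b)
            return
        raise JunctionConflictError(
            "guard bases of neighbouring junctions collide")


def render_derived_genome(genome: Genome, plan: RearrangementPlan,
                          materialize_sequence: bool = True,
                          sample: str = "") -> RenderResult:
    """Realise a plan: derived sequence, ground-truth junctions, and the
    reference after microhomology planting.

    Returns a :class:`RenderResult`; ``truth`` lists one
    :class:`~svjl.junctionlab.JunctionCall` per junction (two for shard /
    templated-fragment junctions, sharing a rearrangement id).
    """
    validate_plan(genome, plan)
    bufs = _Buffers(genome)

    # expand fragments into the atom sequence
    atoms = [plan.segments[0]]
    descs = []
    for i, spec in enumerate(plan.junctions):
        rid = f"{plan.name}:r{i + 1}"
        if spec.kind in ("shard", "templated"):
            frag = spec.fragment
            m1, m2 = spec.fragment_mh
            atoms.append(frag)
            descs.append({"kind": spec.kind, "mh": m1, "ins": None,
                          "rid": rid, "frag": frag})
            descs.append({"kind": "microhomology" if m2 else "blunt",
                          "mh": m2, "ins": None, "rid": rid})
        else:
            ins = list(spec.insertion_seq) if spec.kind == "insertion" else None
            descs.append({"kind": spec.kind, "mh": spec.mh_len, "ins": ins,
                          "rid": rid})
        atoms.append(plan.segments[i + 1])

    for a, b in zip(atoms, atoms[1:]):
        if _seamless(a, b):
            raise JunctionConflictError(
                "consecutive segments rejoin the reference seamlessly")

    # fragment/flank overlap check (a shard overlapping a breakpoint flank
    # would make the junction unresolvable)
    pad = 200
    for i, d in enumerate(descs):
        if "frag" in d:
            f = d["frag"]
            a, b = atoms[i], atoms[i + 2]  # segments flanking the fragment
            for chrom, pos in ((a.chrom, _oriented_ref_pos(a, _seg_len(a) - 1)),
                               (b.chrom, _oriented_ref_pos(b, 0))):
                if f.chrom == chrom and f.start < pos + pad and pos - pad < f.end:
                    raise JunctionConflictError(
                        "fragment overlaps a breakpoint flank")

    # pass 1: plant every homology word into its acceptor flank
    for bi, d in enumerate(descs):
        A, B = atoms[bi], atoms[bi + 1]
        m = d["mh"]
        if m >= _seg_len(B) or m >= _seg_len(A):
            raise JunctionConflictError("microhomology longer than a segment")
        if m > 0:
            word = bufs.word(A, _seg_len(A) - m, m)
            # freeze the word source, then overwrite the acceptor flank
            lo = min(_oriented_ref_pos(A, _seg_len(A) - m),
                     _oriented_ref_pos(A, _seg_len(A) - 1))
            if bufs.is_frozen(A.chrom, lo, lo + m):
                raise JunctionConflictError("homology word source overlaps "
                                            "another junction's flank")
            bufs.freeze(A.chrom, lo, lo + m)
            bufs.write_word(B, 0, word)

    # pass 2: guard substitutions so no junction's homology extends beyond
    # its planted length
    ledger = _GuardLedger(bufs)
    for bi, d in enumerate(descs):
        A, B = atoms[bi], atoms[bi + 1]
        m, ins = d["mh"], d["ins"]
        ctx_a = bufs.ref_endpoint(A, _seg_len(A))  # donor-A continuation
        ctx_b = bufs.ref_endpoint(B, -1)           # donor-B pre-context
        if ins is not None:
            ledger.ensure_diff(ctx_a, ("ins", ins, 0))
            ledger.ensure_diff(ctx_b, ("ins", ins, len(ins) - 1))
        else:
            # prefix: donor-A continuation vs first derived base after segA;
            # suffix: donor-B pre-context vs last derived base before segB
            ledger.ensure_diff(ctx_a, bufs.ref_endpoint(B, m))
            ledger.ensure_diff(ctx_b, bufs.ref_endpoint(A, _seg_len(A) - m - 1))

    # pass 3: ground-truth calls
    truth = []
    cum = _seg_len(atoms[0])
    for bi, d in enumerate(descs):
        A, B = atoms[bi], atoms[bi + 1]
        m, ins = d["mh"], d["ins"]
        pos_a = _oriented_ref_pos(A, _seg_len(A) - 1) + 1
        pos_b = _oriented_ref_pos(B, m) + 1
        ins_seq = "".join(ins) if ins else ""
        if "frag" in d:
            kind = d["kind"]
        elif m > 0:
            kind = "microhomology"
        elif ins_seq:
            kind = "insertion"
        else:
            kind = "blunt"
        call = JunctionCall(f"{plan.name}:j{bi + 1}", A.chrom, pos_a, A.strand,
                            B.chrom, pos_b, B.strand, mh_len=m,
                            insertion_seq=ins_seq, kind=kind,
                            rearrangement=d["rid"], sample=sample,
                            derived_pos=cum,
                            chromothripsis=plan.chromothripsis)
        if "frag" in d:
            f = d["frag"]
            nxt = descs[bi + 1]
            bp_b = _oriented_ref_pos(atoms[bi + 2], nxt["mh"]) + 1
            dist = _frag_distance(f, (A.chrom, pos_a), (atoms[bi + 2].chrom, bp_b))
            call.kind = "templated" if dist <= SHARD_MIN else "shard"
            call.shard_or_template = (f.chrom, f.start + 1, f.end, f.strand, dist)
        truth.append(call)
        cum += (len(ins) if ins else 0) + _seg_len(B) - m

    # assemble blocks / sequence
    blocks, labels, parts = [], [], []
    first = atoms[0]
    blocks.append((first.chrom, first.start, _seg_len(first), first.strand))
    if materialize_sequence:
        parts.append(_oriented_seq(bufs, first))
    for bi, d in enumerate(descs):
        B = atoms[bi + 1]
        m, ins = d["mh"], d["ins"]
        label = f"sv:{d['rid']}"
        if ins:
            blocks.append((None, 0, len(ins), "+"))
            labels.append(label)
            label = label  # both boundaries around the insertion
            if materialize_sequence:
                parts.append("".join(ins))
        if B.strand == "+":
            blocks.append((B.chrom, B.start + m, _seg_len(B) - m, "+"))
        else:
            blocks.append((B.chrom, B.start, _seg_len(B) - m, "-"))
        labels.append(label)
        if materialize_sequence:
            parts.append(_oriented_seq(bufs, B)[m:])

    planted = Genome({c: bytes(b).decode("ascii")
                      for c, b in bufs.buf.items()}, validate=False)
    seq = "".join(parts) if materialize_sequence else None
    derived = DerivedGenome(plan.name, blocks, labels, sequence=seq)
    return RenderResult(derived, truth, planted, plan)


def _oriented_seq(bufs: _Buffers, seg: Segment) -> str:
    raw = bytes(bufs.buf[seg.chrom][seg.start:seg.end]).decode("ascii")
    return raw if seg.strand == "+" else revcomp(raw)


def _frag_distance(frag: Segment, bp_a, bp_b) -> float:
    dist = float("inf")
    for chrom, pos in (bp_a, bp_b):
        if chrom != frag.chrom:
            continue
        p0 = pos - 1
        if frag.start <= p0 < frag.end:
            dist = 0.0
        else:
            dist = min(dist, float(frag.start - p0 if p0 < frag.start
                                   else p0 - frag.end + 1))
    return dist


def render_sample(genome: Genome, plans, sample: str = "",
                  materialize_sequence: bool = True):
    """Render several plans against one (threaded) reference.

    Returns (derived_list, truth, planted_genome).
    """
    derived, truth = [], []
    g = genome
    for plan in plans:
        res = render_derived_genome(g, plan, materialize_sequence, sample)
        derived.append(res.derived)
        truth.extend(res.truth)
        g = res.genome
    return derived, truth, g


def build_haplotypes(genome: Genome, plans, derived_list, diploid=False):
    """Haplotype set for read simulation.

    ``diploid=False`` (clonal): the derived chromosomes plus one intact copy
    of every untouched chromosome.  ``diploid=True``: every chromosome keeps
    an intact homologue; chromosomes carrying a rearrangement get the derived
    version as the second copy, all others a second intact copy — the scheme
    that makes a chromothriptic chromosome oscillate between one and two
    copies while the rest of the genome stays at two.
    """
    touched = set()
    for plan in plans:
        touched.update(seg.chrom for seg in plan.segments)
    haps = list(derived_list)
    for chrom in genome.chromosomes:
        if diploid:
            haps.append(identity_derived(genome, chrom))
            if chrom not in touched:
                haps.append(identity_derived(genome, chrom, name=chrom + "b"))
        elif chrom not in touched:
            haps.append(identity_derived(genome, chrom))
    return haps


# ---------------------------------------------------------------------------
# mate-pair simulation
# ---------------------------------------------------------------------------

def pairs_for_coverage(haplotypes, coverage: float,
                       insert_mean: int = 3000) -> int:
    """Pair count giving the requested effective (clone) coverage."""
    total = sum(h.length for h in haplotypes)
    return int(math.ceil(coverage * total / insert_mean))


def simulate_mate_pairs(haplotypes, n_pairs: int, insert_mean: int = 3000,
                        insert_sd: int = 300, read_len: int = 50,
                        seed: int = 0) -> pd.DataFrame:
    """Draw mate pairs uniformly along the haplotype sequences.

    Each end is reported in reference coordinates (1-based leftmost mapped
    base) with its mapped strand; concordant pairs come out in outward
    orientation (strand1='-', strand2='+', pos1 < pos2).  Reads falling on a
    junction or inside an untemplated insertion are unmappable and dropped;
    pairs whose two reads map to different blocks are labelled with the
    junction they span.
    """
    if isinstance(haplotypes, DerivedGenome):
        haplotypes = [haplotypes]
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    for h in haplotypes:
        if h.length < insert_mean + 6 * insert_sd:
            raise ValueError(f"haplotype {h.name} shorter than "
                             "insert_mean + 6 * insert_sd")
    rng = np.random.default_rng(seed)
    lengths = np.array([h.length for h in haplotypes], dtype=float)
    alloc = rng.multinomial(n_pairs, lengths / lengths.sum())
    frames = []
    pair_id = 0
    for h, n_h in zip(haplotypes, alloc):
        if n_h == 0:
            continue
        ins = np.rint(rng.normal(insert_mean, insert_sd, n_h)).astype(np.int64)
        ins = np.clip(ins, 2 * read_len + 1, h.length)
        start = (rng.random(n_h) * (h.length - ins + 1)).astype(np.int64)
        r1, r2 = start, start + ins - read_len
        c1, p1, f1, ok1, b1 = h.map_reads(r1, read_len)
        c2, p2, f2, ok2, b2 = h.map_reads(r2, read_len)
        keep = ok1 & ok2
        if not keep.any():
            continue
        c1, p1, f1, b1 = c1[keep], p1[keep], f1[keep], b1[keep]
        c2, p2, f2, b2 = c2[keep], p2[keep], f2[keep], b2[keep]
        names = np.array(h.chrom_names, dtype=object)
        chrom1, chrom2 = names[c1], names[c2]
        # derived-orientation strands: read1 '-', read2 '+' (outward);
        # a minus block flips the mapped strand
        s1 = np.where(f1, "+", "-")
        s2 = np.where(f2, "-", "+")
        same = b1 == b2
        source = np.where(same, "normal", "")
        if (~same).any():
            lab = np.array(h.boundary_labels + ["?"], dtype=object)
            source = np.where(same, "normal", lab[np.minimum(b1, len(lab) - 1)])
        n_k = len(p1)
        df = pd.DataFrame({
            "id": [f"p{pair_id + i}" for i in range(n_k)],
            "chrom1": chrom1, "pos1": p1 + 1, "strand1": s1,
            "chrom2": chrom2, "pos2": p2 + 1, "strand2": s2,
            "read_len": read_len, "source": source,
        })
        pair_id += n_k
        frames.append(df)
    if not frames:
        return _empty_pairs()
    pairs = pd.concat(frames, ignore_index=True)
    return canonicalize_pairs(pairs)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "chrom1", "pos1", "strand1",
                                 "chrom2", "pos2", "strand2",
                                 "read_len", "source"])


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair so end1 <= end2 in genome order (swapping strands)."""
    swap = (pairs["chrom2"] < pairs["chrom1"]) | (
        (pairs["chrom2"] == pairs["chrom1"]) & (pairs["pos2"] < pairs["pos1"]))
    if swap.any():
        cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
        sw = pairs.loc[swap, cols].to_numpy()
        pairs.loc[swap, cols] = sw[:, [3, 4, 5, 0, 1, 2]]
        pairs["pos1"] = pairs["pos1"].astype(np.int64)
        pairs["pos2"] = pairs["pos2"].astype(np.int64)
    return pairs


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """A transcript as ordered genomic blocks in transcription order."""

    name: str
    blocks: list  # (chrom, start, end, strand) 0-based half-open

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e, _ in self.blocks)

    def map_pos(self, t: int):
        """Genomic (chrom, pos0, strand) of transcript coordinate ``t``."""
        for chrom, s, e, strand in self.blocks:
            n = e - s
            if t < n:
                pos = s + t if strand == "+" else e - 1 - t
                return chrom, pos, strand
            t -= n
        raise IndexError("transcript coordinate out of range")


def transcript_from_gene(gene: GeneModel) -> Transcript:
    exons = gene.exons0
    if gene.strand == "-":
        exons = exons[::-1]
    return Transcript(gene.gene_id,
                      [(gene.chrom, s, e, gene.strand) for s, e in exons])


def _five_prime_blocks(gene: GeneModel, bp1: int, retain_intron: bool):
    """Blocks of the gene's 5' portion up to the (1-based) breakpoint."""
    bp0 = bp1 - 1
    blocks = []
    if gene.strand == "+":
        for s, e in gene.exons0:
            if e <= bp0:
                blocks.append((gene.chrom, s, e, "+"))
            elif s <= bp0:
                blocks.append((gene.chrom, s, bp0 + 1, "+"))
        if retain_intron and blocks:
            last = blocks[-1][2]
            if last <= bp0:
                blocks.append((gene.chrom, last, bp0 + 1, "+"))
    else:
        for s, e in reversed(gene.exons0):
            if s > bp0:
                blocks.append((gene.chrom, s, e, "-"))
            elif e > bp0:
                blocks.append((gene.chrom, bp0, e, "-"))
        if retain_intron and blocks:
            first = blocks[-1][1]
            if first > bp0:
                blocks.append((gene.chrom, bp0, first, "-"))
    return blocks


def _three_prime_blocks(gene: GeneModel, bp1: int, retain_intron: bool):
    bp0 = bp1 - 1
    blocks = []
    if gene.strand == "+":
        for s, e in gene.exons0:
            if s >= bp0:
                blocks.append((gene.chrom, s, e, "+"))
            elif e > bp0:
                blocks.append((gene.chrom, bp0, e, "+"))
        if retain_intron and blocks and blocks[0][1] > bp0:
            blocks.insert(0, (gene.chrom, bp0, blocks[0][1], "+"))
    else:
        for s, e in reversed(gene.exons0):
            if e <= bp0 + 1:
                blocks.append((gene.chrom, s, e, "-"))
            elif s <= bp0:
                blocks.append((gene.chrom, s, bp0 + 1, "-"))
        if retain_intron and blocks and blocks[0][2] <= bp0:
            blocks.insert(0, (gene.chrom, blocks[0][2], bp0 + 1, "-"))
    return blocks


def fusion_transcript(gene5: GeneModel, bp5: int, gene3: GeneModel, bp3: int,
                      retain_introns: bool = False, name=None) -> Transcript:
    """Chimeric transcript: 5' part of ``gene5`` joined to 3' of ``gene3``."""
    blocks = (_five_prime_blocks(gene5, bp5, retain_introns)
              + _three_prime_blocks(gene3, bp3, retain_introns))
    if not blocks:
        raise ValueError("fusion transcript has no exonic content")
    return Transcript(name or f"{gene5.gene_id}::{gene3.gene_id}", blocks)


def exon_deletion_transcript(gene: GeneModel, bp1: int, bp2: int,
                             name=None) -> Transcript:
    """Transcript skipping everything between two intragenic breakpoints."""
    lo, hi = sorted((bp1, bp2))
    if gene.strand == "+":
        blocks5 = _five_prime_blocks(gene, lo, False)
        blocks3 = _three_prime_blocks(gene, hi, False)
    else:
        blocks5 = _five_prime_blocks(gene, hi, False)
        blocks3 = _three_prime_blocks(gene, lo, False)
    return Transcript(name or f"{gene.gene_id}::del", blocks5 + blocks3)


def simulate_rnaseq_pairs(transcripts, weights, n_pairs: int,
                          read_len: int = 50, frag_mean: int = 300,
                          frag_sd: int = 30, seed: int = 0) -> pd.DataFrame:
    """RNA-seq read pairs over a weighted transcript set.

    ``weights`` are TPM-like relative abundances (>= 0); transcripts with
    weight 0 yield no pairs.  Each pair's ends are reported at their genomic
    positions with the sense strand of the block they start in.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("expression weights must be >= 0")
    if w.sum() == 0 or n_pairs == 0:
        return _empty_pairs()
    rng = np.random.default_rng(seed)
    alloc = rng.multinomial(n_pairs, w / w.sum())
    rows = []
    pid = 0
    for tr, n_t in zip(transcripts, alloc):
        L = tr.length
        for _ in range(int(n_t)):
            frag = int(np.clip(rng.normal(frag_mean, frag_sd),
                               2 * read_len, max(L, 2 * read_len)))
            if frag > L:
                frag = L
            start = int(rng.integers(0, L - frag + 1))
            c1, p1, s1 = tr.map_pos(start)
            c2, p2, s2 = tr.map_pos(start + frag - 1)
            rows.append((f"r{pid}", c1, p1 + 1, s1, c2, p2 + 1, s2,
                         read_len, tr.name))
            pid += 1
    df = pd.DataFrame(rows, columns=["id", "chrom1", "pos1", "strand1",
                                     "chrom2", "pos2", "strand2",
                                     "read_len", "source"])
    return df


# ---------------------------------------------------------------------------
# junction reads for the resolver
# ---------------------------------------------------------------------------

def simulate_junction_inventory(inventory, seed: int = 0,
                                chrom_length: int = 130_000,
                                base_freqs=None, flank: int = 150):
    """Plant an explicit inventory of junction structures and patterns.

    Each inventory entry describes one rearrangement placed on its own
    chromosome::

        {"sample": "S1", "chromothripsis": False,
         "structure": "simple" | "shard" | "templated" | "templated3",
         "pattern": ("microhomology", m) | ("blunt",) | ("insertion", n),
         "fragment_mh": (m1, m2)}        # fragment structures only

    ``simple`` plants a single deletion junction with the given pattern;
    ``shard`` / ``templated`` insert a mapped fragment (distant / nearby) at
    the junction, yielding two junction calls; ``templated3`` adds a second
    plain junction with the given pattern, yielding three calls.  Returns
    ``(planted_genome, truth_calls, reads)`` where ``reads`` is a list of
    ``(rearrangement_id, sequence, truth_calls)`` covering every junction,
    and all calls are labelled with sample / rearrangement / chromothripsis.
    """
    rng = np.random.default_rng(seed)
    n = len(inventory)
    names = [f"chr{i + 1}" for i in range(n)] + ["chrDonor"]
    genome = simulate_genome(n + 1, [chrom_length] * n + [80_000],
                             base_freqs=base_freqs, seed=seed, names=names)

    def _spec(pattern):
        if pattern[0] == "microhomology":
            return JunctionSpec("microhomology", mh_len=int(pattern[1]))
        if pattern[0] == "insertion":
            length = int(pattern[1])
            return JunctionSpec("insertion",
                                insertion_seq=random_dna(rng, length))
        return JunctionSpec()

    plans = []
    donor_off = 1_000
    for i, entry in enumerate(inventory):
        chrom = names[i]
        structure = entry.get("structure", "simple")
        name = f"{entry['sample']}:rr{i + 1}"
        if structure == "simple":
            plan = make_deletion_plan(genome, chrom, [(40_000, 70_000)],
                                      specs=[_spec(entry["pattern"])],
                                      name=name)
        elif structure in ("shard", "templated"):
            if structure == "shard":
                frag = Segment("chrDonor", donor_off, donor_off + 200)
                donor_off += 400
            else:
                frag = Segment(chrom, 70_600, 70_800,
                               "-" if rng.random() < 0.5 else "+")
            spec = JunctionSpec(structure, fragment=frag,
                                fragment_mh=tuple(entry.get("fragment_mh",
                                                            (0, 0))))
            plan = make_deletion_plan(genome, chrom, [(40_000, 70_000)],
                                      name=name)
            plan.junctions = [spec]
        elif structure == "templated3":
            plan = make_deletion_plan(genome, chrom,
                                      [(30_000, 52_000), (52_800, 75_000)],
                                      name=name)
            frag = Segment(chrom, 31_000, 31_200,
                           "-" if rng.random() < 0.5 else "+")
            plan.junctions = [
                JunctionSpec("templated", fragment=frag,
                             fragment_mh=tuple(entry.get("fragment_mh",
                                                         (0, 0)))),
                _spec(entry["pattern"])]
        else:
            raise ValueError(f"unknown structure {structure!r}")
        plan.chromothripsis = bool(entry.get("chromothripsis", False))
        plans.append(plan)

    truth, reads = [], []
    g = genome
    for entry, plan in zip(inventory, plans):
        res = render_derived_genome(g, plan, sample=entry["sample"])
        g = res.genome
        for rid, read, calls in junction_reads(res, flank=flank):
            reads.append((plan.name, read, calls))
        for c in res.truth:
            c.rearrangement = plan.name
        truth.extend(res.truth)
    return g, truth, reads


def junction_reads(result: RenderResult, flank: int = 150):
    """Sanger-style reads crossing each rearrangement of a rendered plan.

    Returns a list of (rearrangement_id, read, truth_calls); calls sharing a
    rearrangement (shard / templated fragments) are covered by one read.
    """
    if result.derived.sequence is None:
        raise ValueError("render with materialize_sequence=True first")
    seq = result.derived.sequence
    groups = {}
    for call in result.truth:
        groups.setdefault(call.rearrangement, []).append(call)
    out = []
    for rid, calls in groups.items():
        lo = min(c.derived_pos for c in calls) - flank
        hi = max(c.derived_pos for c in calls) + flank
        lo, hi = max(lo, 0), min(hi, len(seq))
        out.append((rid, seq[lo:hi], calls))
    return out
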