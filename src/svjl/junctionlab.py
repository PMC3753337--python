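"""Base-pair resolution of rearrangement junctions.

Junction reads (Sanger-style sequences crossing one or more breakpoints) are
aligned back to the reference by greedy maximal exact-match anchoring from
both read ends.  The overlap of the two anchor alignments on the read is the
junction microhomology; a gap between them is a candidate inserted sequence,
which is re-mapped to distinguish untemplated insertions from genomic shards
(mappable, distant donor) and templated insertions of nearby sequence.

Conventions
-----------
* Reported positions are 1-based; the microhomology bases are assigned to the
  upstream segment (segA), and the slide interval is recorded as ``mh_len``.
* A junction class is exactly one of ``microhomology``, ``blunt``,
  ``insertion``, ``shard`` or ``templated``; microhomology and insertion are
  mutually exclusive outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq import revcomp

#: Distance separating "templated insertion of nearby sequence" from a
#: genomic shard copied from a distant locus.
SHARD_MIN = 10_000

#: Gaps shorter than this are always called untemplated insertions.
MIN_TEMPLATED_LEN = 15

JUNCTION_CLASSES = ("microhomology", "blunt", "insertion", "shard", "templated")


class JunctionError(ValueError):
    """Base class for junction-resolution failures."""


class UnmappableReadError(JunctionError):
    """No exact anchor of at least ``min_anchor`` bases at a read end."""


class AmbiguousAnchorError(JunctionError):
    """A read-end anchor extends maximally at more than one locus."""


@dataclass
class JunctionCall:
    """A base-pair resolved junction between two donor segments."""

    junction_id: str
    chromA: str
    posA: int          # 1-based last base of segA (microhomology included)
    strandA: str
    chromB: str
    posB: int          # 1-based first base of segB after the junction
    strandB: str
    mh_len: int = 0
    insertion_seq: str = ""
    kind: str = "blunt"
    shard_or_template: tuple | None = None  # (chrom, start, end, strand, distance)
    rearrangement: str = ""
    sample: str = ""
    derived_pos: int | None = None  # 0-based junction point in the derived sequence
    chromothripsis: bool = False

    def __post_init__(self):
        if self.kind not in JUNCTION_CLASSES:
            raise ValueError(f"unknown junction class {self.kind!r}")
        if self.kind == "microhomology" and (self.mh_len < 1 or self.insertion_seq):
            raise ValueError("microhomology class requires mh_len >= 1 and no insertion")
        if self.kind == "blunt" and (self.mh_len != 0 or self.insertion_seq):
            raise ValueError("blunt class requires mh_len == 0 and no insertion")
        if self.kind == "insertion" and not self.insertion_seq:
            raise ValueError("insertion class requires a non-empty insertion_seq")


@dataclass
class _Anchor:
    """An ungapped exact alignment of a read interval to the reference."""

    chrom: str
    strand: str
    read_start: int
    read_end: int
    ref_start: int  # 0-based reference position of read_start

    def ref_at(self, r: int) -> int:
        if self.strand == "+":
            return self.ref_start + (r - self.read_start)
        return self.ref_start - (r - self.read_start)

    def ref_interval(self):
        """0-based half-open reference interval covered by the alignment."""
        a = self.ref_at(self.read_start)
        b = self.ref_at(self.read_end - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        return lo, hi + 1


def _find_all(seq: str, pattern: str):
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def _seed_hits(chromosomes: dict, kmer: str, read_offset: int):
    """All exact placements of ``kmer`` (either strand) as anchors."""
    k = len(kmer)
    hits = []
    rc = revcomp(kmer)
    for chrom, seq in chromosomes.items():
        for p in _find_all(seq, kmer):
            hits.append(_Anchor(chrom, "+", read_offset, read_offset + k, p))
        for p in _find_all(seq, rc):
            # read base at read_offset aligns to the 3' end of the ref match
            hits.append(_Anchor(chrom, "-", read_offset, read_offset + k, p + k - 1))
    return hits


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _extend(anchor: _Anchor, read: str, seq: str) -> _Anchor:
    """Extend an anchor without mismatch in both directions along the read."""
    n = len(read)
    # rightward
    r = anchor.read_end
    while r < n:
        p = anchor.ref_at(r)
        if p < 0 or p >= len(seq):
            break
        want = read[r] if anchor.strand == "+" else _COMP[read[r]]
        if seq[p] != want:
            break
        r += 1
    anchor.read_end = r
    # leftward
    r = anchor.read_start - 1
    while r >= 0:
        p = anchor.ref_at(r)
        if p < 0 or p >= len(seq):
            break
        want = read[r] if anchor.strand == "+" else _COMP[read[r]]
        if seq[p] != want:
            break
        r -= 1
    shift = anchor.read_start - (r + 1)
    if shift:
        anchor.ref_start = anchor.ref_at(r + 1)
        anchor.read_start = r + 1
    return anchor


def _best_anchor(chromosomes: dict, read: str, offset: int, k: int,
                 direction: str) -> _Anchor:
    """Maximal unique extension of the seed at ``offset``; direction is
    'prefix' (maximise read_end) or 'suffix' (minimise read_start)."""
    hits = _seed_hits(chromosomes, read[offset:offset + k], offset)
    if not hits:
        raise UnmappableReadError(
            f"no exact {k}-mer anchor at read offset {offset}")
    for h in hits:
        _extend(h, read, chromosomes[h.chrom])
    if direction == "prefix":
        best = max(h.read_end for h in hits)
        top = [h for h in hits if h.read_end == best]
    else:
        best = min(h.read_start for h in hits)
        top = [h for h in hits if h.read_start == best]
    placements = {(h.chrom, h.strand, h.ref_at(h.read_start)) for h in top}
    if len(placements) > 1:
        raise AmbiguousAnchorError(
            f"{len(placements)} maximal placements for the {direction} anchor")
    return top[0]


def _map_gap(chromosomes: dict, read: str, gap_start: int, gap_end: int,
             min_anchor: int):
    """Try to map the inter-anchor gap as a genomic fragment."""
    k2 = max(min_anchor // 2, 8)
    if gap_end - gap_start < k2:
        return None
    mid = gap_start + (gap_end - gap_start - k2) // 2
    try:
        anchor = _best_anchor(chromosomes, read, mid, k2, "prefix")
    except JunctionError:
        return None
    return anchor


def _pair_call(read, left: _Anchor, right: _Anchor, jid: str) -> JunctionCall:
    """Build the call for two adjacent anchored segments of one read."""
    e, s = left.read_end, right.read_start
    mh = max(0, e - s)
    ins = read[e:s] if s > e else ""
    pos_a = left.ref_at(e - 1) + 1
    pos_b = right.ref_at(max(e, s)) + 1
    kind = "microhomology" if mh else ("insertion" if ins else "blunt")
    return JunctionCall(jid, left.chrom, pos_a, left.strand,
                        right.chrom, pos_b, right.strand,
                        mh_len=mh, insertion_seq=ins, kind=kind)


def _fragment_distance(frag: _Anchor, bp_a, bp_b) -> float:
    lo, hi = frag.ref_interval()
    dist = float("inf")
    for chrom, pos in (bp_a, bp_b):
        if chrom != frag.chrom:
            continue
        p0 = pos - 1
        if lo <= p0 < hi:
            dist = 0.0
        else:
            dist = min(dist, float(lo - p0 if p0 < lo else p0 - hi + 1))
    return dist


def resolve_junction(read: str, reference, min_anchor: int = 20,
                     junction_id: str = "j", shard_min: int = SHARD_MIN):
    """Resolve a junction read against the reference.

    Parameters
    ----------
    read : str
        Junction sequence (ACGT), at least ``2 * min_anchor`` long.
    reference : Genome or mapping of chromosome name to sequence.
    min_anchor : int
        Exact seed length used for end anchoring; half of it is used when
        re-mapping the inter-anchor gap.

    Returns
    -------
    list of JunctionCall
        One call for a simple junction; two calls when the read resolves to
        three segments (a mappable fragment inserted at the junction, i.e. a
        genomic shard or a templated insertion of nearby sequence).  An empty
        list when the read maps contiguously (no junction).
    """
    chromosomes = getattr(reference, "chromosomes", reference)
    if len(read) < 2 * min_anchor:
        raise ValueError("read shorter than 2 * min_anchor")
    left = _best_anchor(chromosomes, read, 0, min_anchor, "prefix")
    right = _best_anchor(chromosomes, read, len(read) - min_anchor,
                         min_anchor, "suffix")
    same_locus = (left.chrom == right.chrom and left.strand == right.strand
                  and left.ref_at(0) == right.ref_at(0))
    if same_locus:
        return []

    e, s = left.read_end, right.read_start
    gap = read[e:s] if s > e else ""
    if len(gap) >= MIN_TEMPLATED_LEN:
        frag = _map_gap(chromosomes, read, e, s, min_anchor)
        if frag is not None and frag.read_start <= e and frag.read_end >= s:
            # three segments: A | fragment | B
            call1 = _pair_call(read, left, frag, f"{junction_id}.1")
            call2 = _pair_call(read, frag, right, f"{junction_id}.2")
            lo, hi = frag.ref_interval()
            dist = _fragment_distance(frag, (call1.chromA, call1.posA),
                                      (call2.chromB, call2.posB))
            # the fragment class overrides the local pattern label; any
            # measured microhomology at the join is kept on the call
            call1.kind = "templated" if dist <= shard_min else "shard"
            call1.shard_or_template = (frag.chrom, lo + 1, hi, frag.strand, dist)
            return [call1, call2]
    return [_pair_call(read, left, right, junction_id)]


def measure_microhomology(flankA: str, flankB: str, junction_point: int) -> int:
    """Microhomology length at a junction from the two donor contexts.

    ``flankA`` and ``flankB`` are donor-A and donor-B sequences written in the
    derived-genome orientation, each covering the breakpoint with
    ``junction_point`` bases before it.  The microhomology is ``u + v`` where
    ``u`` is the longest common suffix of the two left-of-junction sequences
    and ``v`` the longest common prefix of the two right-of-junction
    sequences — equivalently the length of the interval over which the
    breakpoint can slide without changing the derived sequence.
    """
    j = junction_point
    u = 0
    while u < j and flankA[j - 1 - u] == flankB[j - 1 - u]:
        u += 1
    v = 0
    n = min(len(flankA), len(flankB)) - j
    while v < n and flankA[j + v] == flankB[j + v]:
        v += 1
    return u + v


def count_rearrangement_complexity(calls) -> pd.DataFrame:
    """Per-rearrangement junction counts and a simple/complex label.

    A rearrangement resolving to two or more junctions is complex.
    """
    rows = []
    for c in calls:
        if not c.rearrangement:
            raise ValueError(f"call {c.junction_id} lacks a rearrangement key")
        rows.append((c.sample, c.rearrangement))
    df = pd.DataFrame(rows, columns=["sample", "rearrangement"])
    out = (df.groupby(["sample", "rearrangement"], sort=True)
             .size().rename("n_junctions").reset_index())
    out["label"] = out["n_junctions"].map(lambda n: "complex" if n >= 2 else "simple")
    return out


def calls_to_table(calls) -> pd.DataFrame:
    """Flatten junction calls into a report table (1-based coordinates)."""
    rows = []
    for c in calls:
        st = c.shard_or_template
        rows.append({
            "junction_id": c.junction_id, "sample": c.sample,
            "rearrangement": c.rearrangement,
            "chromA": c.chromA, "posA": c.posA, "strandA": c.strandA,
            "chromB": c.chromB, "posB": c.posB, "strandB": c.strandB,
            "class": c.kind, "mh_len": c.mh_len,
            "insertion_seq": c.insertion_seq,
            "template_chrom": st[0] if st else "",
            "template_start": st[1] if st else "",
            "template_end": st[2] if st else "",
            "template_distance": st[4] if st else "",
            "chromothripsis": c.chromothripsis,
        })
    return pd.DataFrame(rows)
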