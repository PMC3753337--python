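"""Paired-end mapping (PEM) signature detection of structural variants.

Mate pairs are classified as concordant ("normal": same chromosome, outward
orientation, insert size inside a robust window around the library mode) or
abnormal; abnormal pairs are clustered by single linkage into SV links, and
each link is assigned one of the eight PEM-signature types derived from the
orientation/spacing logic of the cluster:

========================  =====================================================
DELETION                  outward pairs with stretched insert
INS_FRAGMT                outward pairs with shrunk insert (short known fragment)
INV_INS_FRAGMT            same-strand pairs with short span (inverted fragment)
INV_FRAGMENT              same-strand pairs with a reciprocal cluster (both
                          inversion ends supported)
INVERSION                 same-strand pairs, single cluster (one end supported)
LARGE_DUPLICATION         order-swapped (inward) pairs spanning more than the
                          mean insert
TRANSLOCATION             inter-chromosomal, orientation compatible with a
                          simple derivative chromosome
INTER                     other inter-chromosomal signatures
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEM_TYPES = ("DELETION", "INS_FRAGMT", "INV_INS_FRAGMT", "INV_FRAGMENT",
             "INVERSION", "LARGE_DUPLICATION", "TRANSLOCATION", "INTER",
             "UNDEFINED")

#: Span above which an intra-chromosomal link counts as "large".
LARGE_SV_SPAN = 50_000


class InsertModelError(ValueError):
    pass


@dataclass
class InsertModel:
    """Robust insert-size model of a mate-pair library."""

    mu: float
    sigma: float
    k_sigma: float = 4.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise InsertModelError("sigma must be positive")

    @property
    def lower(self) -> float:
        return self.mu - self.k_sigma * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.k_sigma * self.sigma


def _insert_size(pairs: pd.DataFrame) -> pd.Series:
    """Outer distance spanned by a pair (leftmost start to rightmost end)."""
    return pairs["pos2"] + pairs["read_len"] - pairs["pos1"]


def fit_insert_model(pairs: pd.DataFrame, k_sigma: float = 4.0,
                     min_pairs: int = 100) -> InsertModel:
    """Fit mu/sigma from concordant-candidate pairs.

    Uses the median and the MAD scaled to a normal sigma (1.4826 * MAD),
    then trims inserts outside the provisional concordant window and refits,
    so the estimate tolerates up to ~10% contamination with abnormal pairs
    without the systematic median shift a one-pass fit would show.
    """
    cand = pairs[(pairs["chrom1"] == pairs["chrom2"])
                 & (pairs["strand1"] == "-") & (pairs["strand2"] == "+")]
    if len(cand) < min_pairs:
        raise InsertModelError(
            f"only {len(cand)} outward same-chromosome pairs (< {min_pairs})")
    ins = _insert_size(cand).to_numpy(dtype=float)
    mu, sigma = 0.0, 0.0
    for _ in range(2):
        mu = float(np.median(ins))
        sigma = 1.4826 * float(np.median(np.abs(ins - mu)))
        if sigma <= 0:
            raise InsertModelError("degenerate insert distribution (sigma = 0)")
        ins = ins[np.abs(ins - mu) <= k_sigma * sigma]
        if len(ins) < min_pairs:
            break
    return InsertModel(mu, sigma, k_sigma)


def classify_pairs(pairs: pd.DataFrame, model: InsertModel) -> pd.Series:
    """Vectorised signature per pair.

    Returns one of ``normal``, ``inter``, ``stretched``, ``shrunk``,
    ``same_strand`` or ``swapped`` for every input pair (a total function:
    counts of normal plus abnormal equal the input size).
    """
    inter = pairs["chrom1"] != pairs["chrom2"]
    s1, s2 = pairs["strand1"], pairs["strand2"]
    outward = (s1 == "-") & (s2 == "+")
    inward = (s1 == "+") & (s2 == "-")
    ins = _insert_size(pairs)
    sig = np.full(len(pairs), "same_strand", dtype=object)
    sig[np.asarray(inward)] = "swapped"
    sig[np.asarray(outward & (ins > model.upper))] = "stretched"
    sig[np.asarray(outward & (ins < model.lower))] = "shrunk"
    sig[np.asarray(outward & (ins >= model.lower) & (ins <= model.upper))] = "normal"
    sig[np.asarray(inter)] = "inter"
    return pd.Series(sig, index=pairs.index, name="signature")


def classify_pair(pair, model: InsertModel) -> str:
    """Classify a single pair; 'normal' or 'abnormal:<signature>'."""
    sig = classify_pairs(pd.DataFrame([dict(pair)]), model).iloc[0]
    return "normal" if sig == "normal" else f"abnormal:{sig}"


def dedup_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: identical (pos1, strand1, pos2, strand2)."""
    return pairs.drop_duplicates(
        subset=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"])


@dataclass
class SVLink:
    """A clustered abnormal-pair signature supporting one SV."""

    id: str
    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str
    n_pairs: int
    signature: str
    pem_type: str | None = None
    span: float | None = None   # bp for intra links, None for inter
    bp1: int | None = None      # breakpoint estimates (1-based)
    bp2: int | None = None
    pair_ids: list = field(default_factory=list)

    @property
    def is_inter(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def is_large(self) -> bool:
        return self.span is not None and self.span > LARGE_SV_SPAN


def cluster_links(pairs: pd.DataFrame, model: InsertModel,
                  min_support: int = 2, window: float | None = None,
                  signatures: pd.Series | None = None):
    """Single-linkage clustering of abnormal pairs into SV links.

    Two pairs join a cluster when they share the orientation signature and
    both their ends lie within ``window`` (default mu + k_sigma * sigma) of
    each other.  Clusters below ``min_support`` distinct pairs are dropped.
    Deterministic: pairs are sorted on (chrom1, pos1, chrom2, pos2, id).
    """
    if window is None:
        window = model.upper
    pairs = dedup_pairs(pairs)
    if signatures is None:
        signatures = classify_pairs(pairs, model)
    else:
        signatures = signatures.loc[pairs.index]
    ab = pairs[signatures != "normal"].copy()
    ab["signature"] = signatures[signatures != "normal"]
    ab = ab.sort_values(["chrom1", "pos1", "chrom2", "pos2", "id"],
                        kind="mergesort").reset_index(drop=True)
    links = []
    group_cols = ["chrom1", "chrom2", "strand1", "strand2", "signature"]
    for key, grp in ab.groupby(group_cols, sort=True):
        idx = grp.index.to_numpy()
        p1 = grp["pos1"].to_numpy()
        p2 = grp["pos2"].to_numpy()
        n = len(grp)
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            j = i + 1
            while j < n and p1[j] - p1[i] <= window:
                if abs(p2[j] - p2[i]) <= window:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                j += 1
        roots = np.array([find(i) for i in range(n)])
        for r in np.unique(roots):
            members = grp.iloc[np.flatnonzero(roots == r)]
            if len(members) < min_support:
                continue
            links.append(_make_link(members, key))
    links.sort(key=lambda l: (l.chrom1, l.start1, l.chrom2, l.start2))
    for i, link in enumerate(links):
        link.id = f"link{i + 1}"
    return links


def _make_link(members: pd.DataFrame, key) -> SVLink:
    chrom1, chrom2, s1, s2, sig = key
    read_len = int(members["read_len"].max())
    lo1, hi1 = int(members["pos1"].min()), int(members["pos1"].max())
    lo2, hi2 = int(members["pos2"].min()), int(members["pos2"].max())
    # breakpoint estimate: a '-' end retains the left flank, so the junction
    # sits just right of the rightmost read; a '+' end retains the right flank
    bp1 = hi1 + read_len - 1 if s1 == "-" else lo1
    bp2 = hi2 + read_len - 1 if s2 == "-" else lo2
    span = abs(bp2 - bp1) if chrom1 == chrom2 else None
    return SVLink(id="", chrom1=chrom1, start1=lo1, end1=hi1 + read_len - 1,
                  strand1=s1, chrom2=chrom2, start2=lo2,
                  end2=hi2 + read_len - 1, strand2=s2,
                  n_pairs=len(members), signature=sig, span=span,
                  bp1=bp1, bp2=bp2, pair_ids=list(members["id"]))


def _has_reciprocal(link: SVLink, links, window: float) -> bool:
    want = {"-": "+", "+": "-"}[link.strand1]
    for other in links:
        if other is link or other.is_inter or other.chrom1 != link.chrom1:
            continue
        if other.signature != "same_strand" or other.strand1 != want:
            continue
        gap1 = max(link.start1 - other.end1, other.start1 - link.end1, 0)
        gap2 = max(link.start2 - other.end2, other.start2 - link.end2, 0)
        if gap1 <= window and gap2 <= window:
            return True
    return False


def assign_pem_type(link: SVLink, model: InsertModel,
                    links=None, window: float | None = None) -> SVLink:
    """Assign the PEM-signature type to a clustered link (in place).

    ``links`` (the full link set) enables reciprocal-cluster detection for
    distinguishing INV_FRAGMENT from INVERSION.
    """
    if window is None:
        window = model.upper
    if link.is_inter:
        opposite = link.strand1 != link.strand2
        link.pem_type = "TRANSLOCATION" if opposite else "INTER"
        return link
    sig = link.signature
    if sig == "stretched":
        link.pem_type = "DELETION"
    elif sig == "shrunk":
        link.pem_type = "INS_FRAGMT"
    elif sig == "same_strand":
        if links is not None and _has_reciprocal(link, links, window):
            link.pem_type = "INV_FRAGMENT"
        elif link.span is not None and link.span <= model.upper:
            link.pem_type = "INV_INS_FRAGMT"
        else:
            link.pem_type = "INVERSION"
    elif sig == "swapped":
        link.pem_type = ("LARGE_DUPLICATION" if link.span is not None
                         and link.span > model.mu else "UNDEFINED")
    else:
        link.pem_type = "UNDEFINED"
    return link


def assign_pem_types(links, model: InsertModel,
                     window: float | None = None):
    for link in links:
        assign_pem_type(link, model, links=links, window=window)
    return links


def detect_svs(pairs: pd.DataFrame, min_support: int = 2,
               model: InsertModel | None = None, k_sigma: float = 4.0,
               window: float | None = None):
    """Full detection pass: fit insert model, classify, cluster, type.

    Returns (links, model).
    """
    if model is None:
        model = fit_insert_model(pairs, k_sigma=k_sigma)
    links = cluster_links(pairs, model, min_support=min_support, window=window)
    assign_pem_types(links, model, window=window)
    return links, model


def effective_coverage(n_normal_pairs: float, insert_mean: float,
                       genome_size: float) -> float:
    """Effective (clone) coverage: pairs x insert size / genome size.

    This is the fraction of the genome physically spanned by clones, not by
    sequenced bases; e.g. 20e6 pairs of ~3 kb inserts over a 6 Gbp diploid
    genome give 10-fold effective coverage.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_normal_pairs < 0 or insert_mean <= 0:
        raise ValueError("pair count must be >= 0 and insert size positive")
    return n_normal_pairs * insert_mean / genome_size


def links_to_bedpe(links) -> pd.DataFrame:
    """Links as a BEDPE-dialect table (0-based half-open intervals)."""
    rows = []
    for l in links:
        rows.append({
            "chrom1": l.chrom1, "start1": l.start1 - 1, "end1": l.end1,
            "chrom2": l.chrom2, "start2": l.start2 - 1, "end2": l.end2,
            "name": l.id, "score": l.n_pairs,
            "strand1": l.strand1, "strand2": l.strand2,
            "pem_type": l.pem_type or "", "n_pairs": l.n_pairs,
            "span": "" if l.span is None else int(l.span),
        })
    return pd.DataFrame(rows)


def circos_links(links) -> pd.DataFrame:
    """Circos-compatible link file columns."""
    rows = [{"chrom1": l.chrom1, "start1": l.start1 - 1, "end1": l.end1,
             "chrom2": l.chrom2, "start2": l.start2 - 1, "end2": l.end2,
             "options": f"type={l.pem_type},pairs={l.n_pairs}"}
            for l in links]
    return pd.DataFrame(rows)
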