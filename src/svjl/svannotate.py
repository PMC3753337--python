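"""Functional-impact annotation of SV links against gene models.

Each link end is located relative to the gene models (gene body between TSS
and transcription end, promoter within 2 kb upstream of the TSS, else
intergenic) and the link as a whole receives exactly one impact category:

* ``Intergenic`` / ``Promoter`` — no gene body hit;
* ``Truncated`` — a genic end fused away from its gene (or an
  orientation-incompatible fusion of two genes);
* ``Possible chimera`` — the 5' part of one gene joined to the 3' part of
  another in compatible transcriptional orientation;
* ``May change function`` — an intragenic event removing, inverting or
  duplicating at least one exon;
* ``Does not change function`` — an intragenic event confined to introns;
* ``May not change function`` — e.g. a tandem duplication spanning the whole
  gene, leaving an intact copy.

The damaging rollup comprises Truncated, Possible chimera and May change
function.  The full decision table is a documented reconstruction: the
published material specifies the gene/promoter location rules but not the
category logic, which is reproduced here from the category inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_BP = 2_000

CATEGORIES = ("Intergenic", "Promoter", "Truncated", "Possible chimera",
              "Does not change function", "May change function",
              "May not change function")

DAMAGING = frozenset({"Truncated", "Possible chimera", "May change function"})

#: most-damaging-first precedence used when several genes overlap an end
_PRECEDENCE = ("Possible chimera", "Truncated", "May change function",
               "May not change function", "Does not change function",
               "Promoter", "Intergenic")


@dataclass
class EndContext:
    label: str                 # intergenic | promoter | intron | exon
    genes: list = field(default_factory=list)

    def __str__(self):
        if self.label in ("intergenic", "promoter") or not self.genes:
            return self.label
        ids = ",".join(g.gene_id for g in self.genes)
        return f"{self.label}({ids})"


@dataclass
class ImpactAnnotation:
    link_id: str
    end1_context: str
    end2_context: str
    category: str
    damaging: bool
    genes_hit: list


class GeneIndex:
    """Interval lookup of gene bodies and promoters per chromosome."""

    def __init__(self, genes, promoter_bp: int = PROMOTER_BP):
        self.genes = list(genes)
        self.promoter_bp = promoter_bp
        self.body = {}
        self.promoter = {}
        for g in self.genes:
            lo, hi = g.span
            self.body.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g)
            if g.strand == "+":
                p_lo, p_hi = max(1, g.tss - promoter_bp), g.tss - 1
            else:
                p_lo, p_hi = g.tss + 1, g.tss + promoter_bp
            if p_lo <= p_hi:
                self.promoter.setdefault(g.chrom, IntervalTree()).addi(
                    p_lo, p_hi + 1, g)

    def genes_at(self, chrom, start, end):
        tree = self.body.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda g: g.gene_id)

    def promoters_at(self, chrom, start, end):
        tree = self.promoter.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)),
                      key=lambda g: g.gene_id)


def locate_end(chrom: str, start: int, end: int, index: GeneIndex,
               known_chroms=None) -> EndContext:
    """Context of a breakpoint interval (1-based closed coordinates).

    Genic if the interval overlaps any [TSS, transcription end]; promoter if
    it lies within 2 kb upstream of a TSS without touching any gene body;
    otherwise intergenic.  All overlapping genes are reported.
    """
    if known_chroms is not None and chrom not in known_chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    genes = index.genes_at(chrom, start, end)
    if genes:
        exonic = any(s <= end and e >= start
                     for g in genes for s, e in g.exons)
        return EndContext("exon" if exonic else "intron", genes)
    promoters = index.promoters_at(chrom, start, end)
    if promoters:
        return EndContext("promoter", promoters)
    return EndContext("intergenic")


def _retains_five_prime(gene, end_strand: str) -> bool:
    """Does this link end keep the 5' part of the gene?

    A '-' cluster strand means the retained flank is left of the breakpoint;
    the left flank is the 5' part of a plus-strand gene.
    """
    retained_left = end_strand == "-"
    return retained_left == (gene.strand == "+")


def _exon_in_span(gene, lo: int, hi: int) -> bool:
    return any(s <= hi and e >= lo for s, e in gene.exons)


def _gene_within(gene, lo: int, hi: int) -> bool:
    g_lo, g_hi = gene.span
    return lo <= g_lo and g_hi <= hi


def _intragenic_category(link, gene) -> str:
    lo, hi = sorted((link.bp1, link.bp2))
    if link.pem_type == "LARGE_DUPLICATION":
        if _gene_within(gene, lo, hi):
            return "May not change function"
        return ("May change function" if _exon_in_span(gene, lo, hi)
                else "Does not change function")
    return ("May change function" if _exon_in_span(gene, lo, hi)
            else "Does not change function")


def categorize_link(link, index: GeneIndex) -> ImpactAnnotation:
    """One impact category per link (decision table; see module docstring)."""
    ctx1 = locate_end(link.chrom1, link.start1, link.end1, index)
    ctx2 = locate_end(link.chrom2, link.start2, link.end2, index)
    genes1 = ctx1.genes if ctx1.label in ("exon", "intron") else []
    genes2 = ctx2.genes if ctx2.label in ("exon", "intron") else []

    candidates = []
    spanned = []
    # a tandem duplication spanning a whole gene leaves one intact copy
    if not link.is_inter and link.pem_type == "LARGE_DUPLICATION":
        lo, hi = sorted((link.bp1, link.bp2))
        spanned = [g for g in index.genes_at(link.chrom1, lo, hi)
                   if _gene_within(g, lo, hi)]
        if spanned:
            candidates.append("May not change function")
    if not genes1 and not genes2:
        if not candidates:
            if "promoter" in (ctx1.label, ctx2.label):
                candidates.append("Promoter")
            else:
                candidates.append("Intergenic")
    else:
        ids1 = {g.gene_id for g in genes1}
        shared = [g for g in genes1 if g.gene_id in {x.gene_id for x in genes2}]
        if not link.is_inter:
            for g in shared:
                candidates.append(_intragenic_category(link, g))
        for g1 in genes1:
            for g2 in genes2:
                if g1.gene_id == g2.gene_id:
                    continue
                p1 = _retains_five_prime(g1, link.strand1)
                p2 = _retains_five_prime(g2, link.strand2)
                candidates.append("Possible chimera" if p1 != p2
                                  else "Truncated")
        if genes1 and not genes2 or genes2 and not genes1:
            candidates.append("Truncated")
        if not candidates:  # inter link, same gene id impossible; defensive
            candidates.append("Truncated")

    category = next(c for c in _PRECEDENCE if c in candidates)
    genes_hit = sorted({g.gene_id for g in genes1 + genes2 + spanned})
    return ImpactAnnotation(link.id, str(ctx1), str(ctx2), category,
                            category in DAMAGING, genes_hit)


def annotate_links(links, gene_models, promoter_bp: int = PROMOTER_BP):
    """Annotate every link; returns a list of ImpactAnnotation."""
    index = GeneIndex(gene_models, promoter_bp)
    return [categorize_link(link, index) for link in links]


def annotation_table(links, annotations) -> pd.DataFrame:
    rows = []
    for link, ann in zip(links, annotations):
        rows.append({"link_id": link.id, "pem_type": link.pem_type,
                     "chrom1": link.chrom1, "bp1": link.bp1,
                     "chrom2": link.chrom2, "bp2": link.bp2,
                     "end1_context": ann.end1_context,
                     "end2_context": ann.end2_context,
                     "category": ann.category, "damaging": ann.damaging,
                     "genes": ",".join(ann.genes_hit)})
    return pd.DataFrame(rows)


def category_summary(links, annotations) -> pd.DataFrame:
    """Category counts split into inter-chromosomal and large intra links."""
    rows = {cat: {"inter": 0, "intra_large": 0, "intra_short": 0}
            for cat in CATEGORIES}
    for link, ann in zip(links, annotations):
        if link.is_inter:
            kind = "inter"
        elif link.is_large:
            kind = "intra_large"
        else:
            kind = "intra_short"
        rows[ann.category][kind] += 1
    df = pd.DataFrame(rows).T
    df.index.name = "category"
    return df.reset_index()
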