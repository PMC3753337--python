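"""Expressed-SV testing from RNA-seq read pairs.

An SV annotated as "Possible chimera" or "May change function" is eligible;
it is called expressed when at least two RNA-seq read pairs span the SV
junction.  A pair spans the junction when one end maps within the upstream
gene on the retained (5') side of its breakpoint — in an exon, or in the
intron containing the breakpoint — and the other end maps within the
downstream gene on its retained (3') side under the same rule, with both
ends sense to their genes (anti-sense pairs are not support).

Per-pair exon/intron contexts are rolled up into a transcript pattern in the
style "5'X -> 3'Y (n pairs); 5'X -> intron Y (m pairs)"; an intragenic exon
deletion is labelled "exon-deletion X".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ELIGIBLE_CATEGORIES = frozenset({"Possible chimera", "May change function"})
MIN_SUPPORT_PAIRS = 2


class NotEligibleError(ValueError):
    pass


@dataclass
class EligibleSV:
    """A predicted SV eligible for RNA support testing.

    ``gene5``/``bp5`` name the upstream partner and its (1-based) breakpoint;
    ``gene3``/``bp3`` the downstream partner.  For an intragenic exon
    deletion the two genes coincide.
    """

    sv_id: str
    gene5: object
    bp5: int
    gene3: object
    bp3: int
    category: str = "Possible chimera"


@dataclass
class TranscriptEvidence:
    sv_id: str
    n_support_pairs: int
    expressed: bool
    pattern: str
    genes: tuple = ()
    pattern_counts: dict = field(default_factory=dict)


def _five_prime_intervals(gene, bp: int):
    """(exon intervals, breakpoint intron) on the 5' side of ``bp``,
    1-based closed."""
    exons, intron = [], None
    prev = None
    ordered = gene.exons if gene.strand == "+" else tuple(reversed(gene.exons))
    for s, e in ordered:
        if gene.strand == "+":
            if e < bp:
                exons.append((s, e))
            elif s <= bp:
                exons.append((s, bp))
            elif prev is not None and prev < bp < s:
                intron = (prev + 1, s - 1)
            prev = e if e < bp else prev
        else:
            if s > bp:
                exons.append((s, e))
            elif e >= bp:
                exons.append((bp, e))
            elif prev is not None and s < bp < prev:
                intron = (s + 1, prev - 1)
            prev = s if s > bp else prev
    # breakpoint intron: locate the intron containing bp explicitly
    intron = _intron_containing(gene, bp) or intron
    return exons, intron


def _three_prime_intervals(gene, bp: int):
    exons = []
    for s, e in gene.exons:
        if gene.strand == "+":
            if s > bp:
                exons.append((s, e))
            elif e >= bp:
                exons.append((bp, e))
        else:
            if e < bp:
                exons.append((s, e))
            elif s <= bp:
                exons.append((s, bp))
    intron = _intron_containing(gene, bp)
    return exons, intron


def _intron_containing(gene, bp: int):
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 < bp < s2:
            return (e1 + 1, s2 - 1)
    return None


def _end_context(chrom, pos, strand, gene, exons, intron):
    """'exon' / 'intron' when the read end qualifies, else None."""
    if chrom != gene.chrom or strand != gene.strand:
        return None
    if any(s <= pos <= e for s, e in exons):
        return "exon"
    if intron and intron[0] <= pos <= intron[1]:
        return "intron"
    return None


def support_pairs(sv: EligibleSV, rna_pairs: pd.DataFrame) -> pd.DataFrame:
    """RNA pairs supporting the SV junction, with per-end contexts.

    Raises :class:`NotEligibleError` for SVs outside the eligible
    annotation categories.
    """
    if sv.category not in ELIGIBLE_CATEGORIES:
        raise NotEligibleError(
            f"SV {sv.sv_id} has category {sv.category!r}; only "
            f"{sorted(ELIGIBLE_CATEGORIES)} are tested for expression")
    ex5, in5 = _five_prime_intervals(sv.gene5, sv.bp5)
    ex3, in3 = _three_prime_intervals(sv.gene3, sv.bp3)
    rows = []
    for r in rna_pairs.itertuples(index=False):
        for a, b in (((r.chrom1, r.pos1, r.strand1),
                      (r.chrom2, r.pos2, r.strand2)),
                     ((r.chrom2, r.pos2, r.strand2),
                      (r.chrom1, r.pos1, r.strand1))):
            c5 = _end_context(*a, sv.gene5, ex5, in5)
            c3 = _end_context(*b, sv.gene3, ex3, in3)
            if c5 and c3:
                rows.append({"id": r.id, "context5": c5, "context3": c3})
                break
    return pd.DataFrame(rows, columns=["id", "context5", "context3"])


def _pattern_label(sv: EligibleSV, c5: str, c3: str) -> str:
    x, y = sv.gene5.gene_id, sv.gene3.gene_id
    if x == y and c5 == "exon" and c3 == "exon":
        return f"exon-deletion {x}"
    left = f"5'{x}" if c5 == "exon" else f"intron {x}"
    right = f"3'{y}" if c3 == "exon" else f"intron {y}"
    return f"{left} -> {right}"


def evidence_for(sv: EligibleSV, rna_pairs: pd.DataFrame,
                 min_support: int = MIN_SUPPORT_PAIRS) -> TranscriptEvidence:
    """Expression call and transcript pattern for one eligible SV."""
    sup = support_pairs(sv, rna_pairs)
    n = len(sup)
    counts = {}
    if n:
        for (c5, c3), grp in sup.groupby(["context5", "context3"]):
            counts[_pattern_label(sv, c5, c3)] = len(grp)
    if not counts:
        pattern = ""
    elif len(counts) == 1:
        pattern = next(iter(counts))
    else:
        pattern = "; ".join(f"{k} ({v} pairs)"
                            for k, v in sorted(counts.items(),
                                               key=lambda kv: -kv[1]))
    return TranscriptEvidence(sv.sv_id, n, n >= min_support, pattern,
                              (sv.gene5.gene_id, sv.gene3.gene_id), counts)


def _gene_expressed(gene, rna_pairs: pd.DataFrame) -> bool:
    lo, hi = gene.span
    for side in ("1", "2"):
        hit = ((rna_pairs[f"chrom{side}"] == gene.chrom)
               & (rna_pairs[f"pos{side}"] >= lo)
               & (rna_pairs[f"pos{side}"] <= hi))
        if hit.any():
            return True
    return False


def expression_summary(svs, rna_pairs: pd.DataFrame,
                       min_support: int = MIN_SUPPORT_PAIRS):
    """Three-way partition of eligible SVs.

    Returns (evidence list, summary dict) where the summary counts
    ``expressed`` SVs (>= 2 spanning pairs), ``silent_genes`` (no RNA pair
    over either partner gene) and ``unsupported`` (partner genes expressed
    but the junction is not).
    """
    evidence = [evidence_for(sv, rna_pairs, min_support) for sv in svs]
    summary = {"eligible": len(list(svs)), "expressed": 0,
               "silent_genes": 0, "unsupported": 0}
    for sv, ev in zip(svs, evidence):
        if ev.expressed:
            summary["expressed"] += 1
        elif not (_gene_expressed(sv.gene5, rna_pairs)
                  or _gene_expressed(sv.gene3, rna_pairs)):
            summary["silent_genes"] += 1
        else:
            summary["unsupported"] += 1
    return evidence, summary


def evidence_table(evidence) -> pd.DataFrame:
    """Table-4-style report: genes, type, read pairs, pattern comment."""
    rows = []
    for ev in evidence:
        rows.append({"genes": "///".join(dict.fromkeys(ev.genes)),
                     "n_read_pairs": ev.n_support_pairs,
                     "expressed": ev.expressed,
                     "comment": ev.pattern})
    return pd.DataFrame(rows)
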