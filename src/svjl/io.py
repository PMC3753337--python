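"""Readers and writers for the package's external file formats.

All external files use the field's plain-text conventions: FASTA for
sequences, BED12 for gene models, a BEDPE dialect for read pairs and links
(``chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2``,
0-based half-open), and TSV for junction tables.  In-memory coordinates are
1-based where the domain objects say so; conversion happens here only.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junctionlab import JunctionCall
from .simgenome import GeneModel, Genome

PAIR_COLUMNS = ["id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                "strand2", "read_len", "source"]


def write_fasta(sequences: dict, path):
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Genome:
    chroms = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(path), "fasta")}
    return Genome(chroms)


def write_bed12(genes, path):
    """Gene models as BED12 (0-based half-open; thick region = gene body)."""
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.span
            start0, end0 = lo - 1, hi
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            starts = ",".join(str(s - lo) for s, _ in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, start0, end0, g.gene_id, 0, g.strand,
                start0, end0, "0,0,0", len(g.exons), sizes, starts])) + "\n")


def read_bed12(path):
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start0, end0, name, _, strand = f[:6]
            start0, end0 = int(start0), int(end0)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start0 + o + 1, start0 + o + sz)
                          for o, sz in zip(offs, sizes))
            if strand == "+":
                g = GeneModel(name, chrom, "+", start0 + 1, end0, exons)
            else:
                g = GeneModel(name, chrom, "-", end0, start0 + 1, exons)
            genes.append(g)
    return genes


def write_pairs_bedpe(pairs: pd.DataFrame, path):
    """Read pairs in the BEDPE dialect (score is a placeholder 1)."""
    rl = pairs["read_len"]
    out = pd.DataFrame({
        "chrom1": pairs["chrom1"], "start1": pairs["pos1"] - 1,
        "end1": pairs["pos1"] - 1 + rl,
        "chrom2": pairs["chrom2"], "start2": pairs["pos2"] - 1,
        "end2": pairs["pos2"] - 1 + rl,
        "name": pairs["id"], "score": 1,
        "strand1": pairs["strand1"], "strand2": pairs["strand2"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_pairs_bedpe(path) -> pd.DataFrame:
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
             "name", "score", "strand1", "strand2"]
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     dtype={"chrom1": str, "chrom2": str})
    return pd.DataFrame({
        "id": df["name"], "chrom1": df["chrom1"],
        "pos1": df["start1"] + 1, "strand1": df["strand1"],
        "chrom2": df["chrom2"], "pos2": df["start2"] + 1,
        "strand2": df["strand2"],
        "read_len": df["end1"] - df["start1"], "source": "",
    })


def pairs_from_sam(path, min_mapq: int = 0) -> pd.DataFrame:
    """Extract mate-pair coordinates from a SAM/BAM file via pysam."""
    import pysam

    rows = {}
    with pysam.AlignmentFile(str(path)) as af:
        for rec in af:
            if (rec.is_unmapped or rec.mate_is_unmapped
                    or rec.is_secondary or rec.is_supplementary
                    or rec.mapping_quality < min_mapq):
                continue
            rows.setdefault(rec.query_name, []).append(rec)
    out = []
    for name, recs in rows.items():
        if len(recs) != 2:
            continue
        a, b = recs
        out.append({
            "id": name,
            "chrom1": a.reference_name, "pos1": a.reference_start + 1,
            "strand1": "-" if a.is_reverse else "+",
            "chrom2": b.reference_name, "pos2": b.reference_start + 1,
            "strand2": "-" if b.is_reverse else "+",
            "read_len": a.query_length or 50, "source": "",
        })
    from .simgenome import canonicalize_pairs
    return canonicalize_pairs(pd.DataFrame(out, columns=PAIR_COLUMNS))


TRUTH_COLUMNS = ["junction_id", "chromA", "posA", "strandA", "chromB",
                 "posB", "strandB", "class", "mh_len", "insertion_seq"]


def write_truth_junctions(truth, path):
    rows = [{"junction_id": c.junction_id, "chromA": c.chromA,
             "posA": c.posA, "strandA": c.strandA, "chromB": c.chromB,
             "posB": c.posB, "strandB": c.strandB, "class": c.kind,
             "mh_len": c.mh_len, "insertion_seq": c.insertion_seq,
             "rearrangement": c.rearrangement, "sample": c.sample,
             "chromothripsis": c.chromothripsis}
            for c in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_junctions(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    calls = []
    for r in df.to_dict("records"):
        calls.append(JunctionCall(
            r["junction_id"], r["chromA"], int(r["posA"]), r["strandA"],
            r["chromB"], int(r["posB"]), r["strandB"],
            mh_len=int(r["mh_len"]), insertion_seq=r["insertion_seq"],
            kind=r["class"], rearrangement=r.get("rearrangement", ""),
            sample=str(r.get("sample", "")),
            chromothripsis=bool(r.get("chromothripsis", False))))
    return calls


def write_junction_fasta(reads, path):
    """Junction-region reads as FASTA; ``reads`` is (name, seq, ...) tuples."""
    records = [SeqRecord(Seq(seq), id=str(name), description="")
               for name, seq, *_ in reads]
    SeqIO.write(records, str(path), "fasta")


def alignment_block(call: JunctionCall, reference, flank: int = 30) -> str:
    """A boxed text alignment of a junction, mirroring the style of
    published per-junction figures: donor A context, the junction read
    layout, and donor B context with the microhomology marked."""
    chroms = getattr(reference, "chromosomes", reference)
    a = chroms[call.chromA]
    b = chroms[call.chromB]
    pa, pb = call.posA - 1, call.posB - 1
    ctx_a = a[max(0, pa - flank + 1):pa + 1]
    ctx_b = b[pb:pb + flank]
    mh = f" microhomology={call.mh_len}" if call.mh_len else ""
    ins = f" insertion={call.insertion_seq}" if call.insertion_seq else ""
    lines = [
        f"# junction {call.junction_id} class={call.kind}{mh}{ins}",
        f"segA {call.chromA}:{call.posA}({call.strandA}) ...{ctx_a}|",
        f"segB {call.chromB}:{call.posB}({call.strandB})    |{ctx_b}...",
    ]
    return "\n".join(lines)
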