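"""Gene-impact annotation: end contexts and the category decision table."""

import numpy as np
import pytest

from svjl import svannotate as sa
from svjl.pemdetect import SVLink
from svjl.simgenome import GeneModel


def _gene(gene_id="GX", chrom="chr1", strand="+", start=100_000,
          end=130_000, exons=None):
    if exons is None:
        exons = ((start, start + 200), (start + 10_000, start + 10_300),
                 (end - 200, end))
    if strand == "+":
        return GeneModel(gene_id, chrom, "+", start, end, exons)
    return GeneModel(gene_id, chrom, "-", end, start, exons)


def _link(chrom1, bp1, s1, chrom2, bp2, s2, pem_type, link_id="l1"):
    return SVLink(id=link_id, chrom1=chrom1, start1=bp1 - 100, end1=bp1,
                  strand1=s1, chrom2=chrom2, start2=bp2, end2=bp2 + 100,
                  strand2=s2, n_pairs=5, signature="", pem_type=pem_type,
                  span=None if chrom1 != chrom2 else abs(bp2 - bp1),
                  bp1=bp1, bp2=bp2)


GX = _gene("GX", strand="+")
GY = _gene("GY", chrom="chr2", strand="+", start=400_000, end=430_000)
GYm = _gene("GYm", chrom="chr2", strand="-", start=400_000, end=430_000)
INDEX = sa.GeneIndex([GX, GY, GYm])


class TestLocateEnd:
    def test_promoter_within_2kb_upstream(self):
        ctx = sa.locate_end("chr1", 98_400, 98_600, INDEX)
        assert ctx.label == "promoter"

    def test_boundary_just_outside_promoter(self):
        ctx = sa.locate_end("chr1", 97_900, 97_999, INDEX)
        assert ctx.label == "intergenic"

    def test_intron_and_exon(self):
        assert sa.locate_end("chr1", 105_000, 105_100, INDEX).label == "intron"
        assert sa.locate_end("chr1", 100_100, 100_150, INDEX).label == "exon"

    def test_minus_strand_promoter_downstream_coordinates(self):
        # GYm TSS is at its genomic end; the promoter lies to the right
        ctx = sa.locate_end("chr2", 430_500, 430_900, INDEX)
        assert ctx.label == "promoter"
        assert ctx.genes[0].gene_id == "GYm"

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sa.locate_end("chrZ", 1, 10, INDEX, known_chroms={"chr1"})

    def test_shrinking_interval_never_gains_genes(self):
        for start, end in [(95_000, 140_000), (99_000, 131_000)]:
            big = {g.gene_id for g in INDEX.genes_at("chr1", start, end)}
            small = {g.gene_id
                     for g in INDEX.genes_at("chr1", start + 2_000,
                                             end - 2_000)}
            assert small <= big


class TestCategorize:
    def test_truncating_translocation(self):
        # one end in GX intron 1, the other intergenic
        link = _link("chr1", 105_000, "-", "chr2", 10_000, "+",
                     "TRANSLOCATION")
        ann = sa.categorize_link(link, INDEX)
        assert ann.category == "Truncated"
        assert ann.damaging

    def test_possible_chimera_5to3(self):
        # 5' of GX (plus strand, left flank retained) joined to 3' of GY
        link = _link("chr1", 105_000, "-", "chr2", 415_000, "+",
                     "TRANSLOCATION")
        ann = sa.categorize_link(link, sa.GeneIndex([GX, GY]))
        assert ann.category == "Possible chimera"

    def test_antisense_fusion_is_truncated(self):
        # both ends keep 5' parts: orientation-incompatible fusion
        link = _link("chr1", 105_000, "-", "chr2", 415_000, "-",
                     "TRANSLOCATION")
        ann = sa.categorize_link(link, sa.GeneIndex([GX, GY]))
        assert ann.category == "Truncated"

    def test_chimera_with_minus_strand_partner(self):
        # GYm on '-': its 3' part is the left flank, so a same-strand join
        # of GX-5' to GYm-3' is transcription-compatible
        link = _link("chr1", 105_000, "-", "chr2", 415_000, "-",
                     "TRANSLOCATION")
        ann = sa.categorize_link(link, sa.GeneIndex([GX, GYm]))
        assert ann.category == "Possible chimera"

    def test_intronic_deletion_does_not_change_function(self):
        link = _link("chr1", 101_000, "-", "chr1", 105_000, "+", "DELETION")
        ann = sa.categorize_link(link, INDEX)
        assert ann.category == "Does not change function"
        assert not ann.damaging

    def test_exon_deletion_may_change_function(self):
        link = _link("chr1", 105_000, "-", "chr1", 125_000, "+", "DELETION")
        ann = sa.categorize_link(link, INDEX)
        assert ann.category == "May change function"

    def test_whole_gene_duplication_may_not_change_function(self):
        link = _link("chr1", 95_000, "+", "chr1", 135_000, "-",
                     "LARGE_DUPLICATION")
        # both breakpoint intervals are outside the gene -> intergenic ends;
        # place ends inside flanking introns of a wider gene instead
        wide = _gene("GW", strand="+", start=90_000, end=140_000,
                     exons=((90_000, 90_100), (100_000, 130_000),
                            (139_900, 140_000)))
        inner = _gene("GI", strand="+", start=105_000, end=120_000,
                      exons=((105_000, 105_100), (119_900, 120_000)))
        link = _link("chr1", 101_000, "+", "chr1", 135_000, "-",
                     "LARGE_DUPLICATION")
        ann = sa.categorize_link(link, sa.GeneIndex([inner]))
        assert ann.category == "May not change function"

    def test_intergenic_and_promoter(self):
        link = _link("chr1", 50_000, "-", "chr1", 180_000, "+", "DELETION")
        assert sa.categorize_link(link, INDEX).category == "Intergenic"
        link = _link("chr1", 98_500, "-", "chr1", 180_000, "+", "DELETION")
        assert sa.categorize_link(link, INDEX).category == "Promoter"

    def test_damaging_rollup_definition(self):
        for cat in sa.CATEGORIES:
            assert (cat in sa.DAMAGING) == (cat in {
                "Truncated", "Possible chimera", "May change function"})


class TestPartition:
    def test_every_link_gets_exactly_one_category(self, genome_with_genes):
        genome, genes = genome_with_genes
        rng = np.random.default_rng(12)
        chroms = list(genome.chromosomes)
        links = []
        for i in range(60):
            c1, c2 = rng.choice(chroms, 2)
            p1 = int(rng.integers(5_000, len(genome.chromosomes[c1]) - 5_000))
            p2 = int(rng.integers(5_000, len(genome.chromosomes[c2]) - 5_000))
            links.append(_link(c1, p1, rng.choice(["+", "-"]),
                               c2, p2, rng.choice(["+", "-"]),
                               rng.choice(["DELETION", "TRANSLOCATION",
                                           "INVERSION",
                                           "LARGE_DUPLICATION"]),
                               link_id=f"l{i}"))
        anns = sa.annotate_links(links, genes)
        assert len(anns) == len(links)
        assert all(a.category in sa.CATEGORIES for a in anns)
        summary = sa.category_summary(links, anns)
        totals = summary[["inter", "intra_large", "intra_short"]].sum().sum()
        assert totals == len(links)
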