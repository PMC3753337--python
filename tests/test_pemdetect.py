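"""PEM-signature classification, clustering and typing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from svjl import pemdetect as pdet
from conftest import concordant_background, make_pairs


class TestInsertModel:
    def test_monte_carlo_fit(self):
        pairs = concordant_background(n=10_000, mu=3000, sd=300, seed=2)
        model = pdet.fit_insert_model(pairs)
        assert abs(model.mu - 3000) <= 10
        assert abs(model.sigma - 300) <= 15

    def test_robust_to_contamination(self):
        good = concordant_background(n=9_500, seed=3)
        bad = concordant_background(n=500, mu=80_000, sd=300, seed=4,
                                    span=10_000_000)
        model = pdet.fit_insert_model(pd.concat([good, bad],
                                                ignore_index=True))
        assert abs(model.mu - 3000) <= 15

    def test_degenerate_sigma_rejected(self):
        pairs = make_pairs([("chr1", 1000 + i * 10, "-",
                             "chr1", 1000 + i * 10 + 2950, "+")
                            for i in range(200)])
        with pytest.raises(pdet.InsertModelError, match="sigma"):
            pdet.fit_insert_model(pairs)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(pdet.InsertModelError, match="<"):
            pdet.fit_insert_model(concordant_background(n=50))


class TestClassify:
    model = pdet.InsertModel(3000, 300, 4)

    @pytest.mark.parametrize("row,expected", [
        (("chr1", 1000, "-", "chr1", 3950, "+"), "normal"),
        (("chr1", 1000, "-", "chr2", 3950, "+"), "inter"),
        (("chr1", 1000, "-", "chr1", 80_950, "+"), "stretched"),
        (("chr1", 1000, "-", "chr1", 1500, "+"), "shrunk"),
        (("chr1", 1000, "+", "chr1", 3950, "-"), "swapped"),
        (("chr1", 1000, "-", "chr1", 3950, "-"), "same_strand"),
        (("chr1", 1000, "+", "chr1", 3950, "+"), "same_strand"),
    ])
    def test_signatures(self, row, expected):
        sig = pdet.classify_pairs(make_pairs([row]), self.model).iloc[0]
        assert sig == expected
        label = pdet.classify_pair(make_pairs([row]).iloc[0], self.model)
        assert label == ("normal" if expected == "normal"
                         else f"abnormal:{expected}")

    @given(st.integers(0, 10_000))
    def test_partition_is_total(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(20):
            c1, c2 = rng.choice(["chr1", "chr2"], 2)
            rows.append((c1, int(rng.integers(1, 10_000)),
                         rng.choice(["+", "-"]),
                         c2, int(rng.integers(1, 10_000)),
                         rng.choice(["+", "-"])))
        sigs = pdet.classify_pairs(make_pairs(rows), self.model)
        assert len(sigs) == 20
        n_normal = (sigs == "normal").sum()
        n_abnormal = (sigs != "normal").sum()
        assert n_normal + n_abnormal == 20


class TestCluster:
    model = pdet.InsertModel(3000, 300, 4)

    def _translocation_pairs(self, n, bp1=500_000, bp2=700_000, seed=0):
        rng = np.random.default_rng(seed)
        return make_pairs([
            ("chr1", int(bp1 - rng.integers(100, 2900)), "-",
             "chr2", int(bp2 + rng.integers(50, 2800)), "+")
            for _ in range(n)])

    def test_single_translocation_link(self):
        links = pdet.cluster_links(self._translocation_pairs(8), self.model)
        assert len(links) == 1
        assert links[0].n_pairs == 8

    def test_min_support_threshold(self):
        links = pdet.cluster_links(self._translocation_pairs(1), self.model,
                                   min_support=2)
        assert links == []

    def test_distant_deletions_never_merged(self):
        rng = np.random.default_rng(1)
        rows = []
        for bp1, bp2 in [(1_000_000, 1_100_000), (11_000_000, 11_100_000)]:
            for _ in range(5):
                rows.append(("chr1", int(bp1 - rng.integers(100, 2900)), "-",
                             "chr1", int(bp2 + rng.integers(50, 2800)), "+"))
        links = pdet.cluster_links(make_pairs(rows), self.model)
        assert len(links) == 2
        assert all(l.n_pairs == 5 for l in links)

    def test_pcr_duplicates_collapsed(self):
        pairs = self._translocation_pairs(4)
        doubled = pd.concat([pairs, pairs], ignore_index=True)
        doubled["id"] = [f"q{i}" for i in range(len(doubled))]
        links = pdet.cluster_links(doubled, self.model)
        assert len(links) == 1 and links[0].n_pairs == 4

    def test_end_swap_symmetry(self):
        from svjl.simgenome import canonicalize_pairs

        pairs = self._translocation_pairs(6)
        swapped = pairs.copy()
        cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
        swapped[cols] = swapped[["chrom2", "pos2", "strand2",
                                 "chrom1", "pos1", "strand1"]].to_numpy()
        swapped = canonicalize_pairs(swapped)
        a = pdet.cluster_links(pairs, self.model)
        b = pdet.cluster_links(swapped, self.model)
        assert [(l.chrom1, l.start1, l.chrom2, l.start2, l.n_pairs)
                for l in a] == \
               [(l.chrom1, l.start1, l.chrom2, l.start2, l.n_pairs)
                for l in b]


class TestAssignPemType:
    model = pdet.InsertModel(3000, 300, 4)

    def _link(self, s1, s2, sig, span=None, inter=False):
        return pdet.SVLink(
            id="l", chrom1="chr1", start1=100_000, end1=103_000, strand1=s1,
            chrom2="chr2" if inter else "chr1",
            start2=100_000 + (span or 0), end2=103_000 + (span or 0),
            strand2=s2, n_pairs=5, signature=sig, span=span,
            bp1=103_000, bp2=100_000 + (span or 0))

    def test_decision_table(self):
        cases = [
            (self._link("-", "+", "stretched", span=80_000), "DELETION"),
            (self._link("-", "+", "shrunk", span=1_000), "INS_FRAGMT"),
            (self._link("-", "-", "same_strand", span=2_000),
             "INV_INS_FRAGMT"),
            (self._link("-", "-", "same_strand", span=90_000), "INVERSION"),
            (self._link("+", "-", "swapped", span=90_000),
             "LARGE_DUPLICATION"),
            (self._link("-", "+", "inter", inter=True), "TRANSLOCATION"),
            (self._link("-", "-", "inter", inter=True), "INTER"),
        ]
        for link, expected in cases:
            assert pdet.assign_pem_type(link, self.model).pem_type == expected

    def test_reciprocal_clusters_give_inv_fragment(self):
        a = self._link("-", "-", "same_strand", span=90_000)
        b = self._link("+", "+", "same_strand", span=90_000)
        b.start1, b.end1 = a.start1 + 500, a.end1 + 500
        b.start2, b.end2 = a.start2 + 500, a.end2 + 500
        pdet.assign_pem_types([a, b], self.model)
        assert a.pem_type == b.pem_type == "INV_FRAGMENT"


class TestEffectiveCoverage:
    @pytest.mark.parametrize("n,expected", [
        (20e6, 10.0), (16e6, 8.0), (0, 0.0),
    ])
    def test_values(self, n, expected):
        assert pdet.effective_coverage(n, 3000, 6e9) == pytest.approx(expected)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            pdet.effective_coverage(1e6, 3000, 0)
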