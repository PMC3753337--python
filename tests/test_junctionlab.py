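"""Junction resolution: round trips, microhomology measurement, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from svjl import junctionlab as jl, simgenome as sg
from svjl.seq import random_dna, revcomp


def _call_key(c):
    return (c.chromA, c.posA, c.strandA, c.chromB, c.posB, c.strandB,
            c.mh_len, c.kind, c.insertion_seq)


class TestResolveRoundTrip:
    @pytest.mark.parametrize("m", [0, 1, 4, 9, 17, 28])
    def test_planted_microhomology_recovered_exactly(self, m):
        g = sg.simulate_genome(1, [120_000], seed=100 + m)
        spec = (sg.JunctionSpec("microhomology", mh_len=m) if m
                else sg.JunctionSpec())
        plan = sg.make_deletion_plan(g, "chr1", [(40_000, 70_000)],
                                     specs=[spec])
        res = sg.render_derived_genome(g, plan)
        _, read, tcalls = sg.junction_reads(res)[0]
        out = jl.resolve_junction(read, res.genome)
        assert len(out) == 1
        assert _call_key(out[0]) == _call_key(tcalls[0])

    @pytest.mark.parametrize("n", [1, 8, 17])
    def test_planted_insertion_recovered(self, n):
        rng = np.random.default_rng(n)
        g = sg.simulate_genome(1, [120_000], seed=n)
        spec = sg.JunctionSpec("insertion",
                               insertion_seq=random_dna(rng, n))
        plan = sg.make_deletion_plan(g, "chr1", [(40_000, 70_000)],
                                     specs=[spec])
        res = sg.render_derived_genome(g, plan)
        _, read, tcalls = sg.junction_reads(res)[0]
        out = jl.resolve_junction(read, res.genome)
        assert out[0].kind == "insertion"
        assert out[0].insertion_seq == tcalls[0].insertion_seq
        assert len(out[0].insertion_seq) == n
        assert out[0].mh_len == 0  # mutually exclusive outputs

    def test_three_segment_templated_read(self):
        g = sg.simulate_genome(1, [200_000], seed=6)
        frag = sg.Segment("chr1", 71_000, 71_200, "-")
        plan = sg.make_fragment_insertion_plan(g, "chr1", 40_000, 70_000,
                                               frag, "templated")
        res = sg.render_derived_genome(g, plan)
        _, read, _ = sg.junction_reads(res)[0]
        out = jl.resolve_junction(read, res.genome)
        assert len(out) == 2
        assert out[0].kind == "templated"
        assert out[0].shard_or_template[0] == "chr1"
        assert out[0].shard_or_template[4] <= jl.SHARD_MIN

    def test_shard_distant_fragment(self):
        g = sg.simulate_genome(2, [150_000, 60_000], seed=6)
        frag = sg.Segment("chr2", 10_000, 10_200)
        plan = sg.make_fragment_insertion_plan(g, "chr1", 40_000, 70_000,
                                               frag, "shard")
        res = sg.render_derived_genome(g, plan)
        _, read, _ = sg.junction_reads(res)[0]
        out = jl.resolve_junction(read, res.genome)
        assert out[0].kind == "shard"
        assert out[0].shard_or_template[0] == "chr2"

    def test_reverse_complement_read_consistent(self):
        g = sg.simulate_genome(1, [120_000], seed=21)
        plan = sg.make_deletion_plan(
            g, "chr1", [(40_000, 70_000)],
            specs=[sg.JunctionSpec("microhomology", mh_len=3)])
        res = sg.render_derived_genome(g, plan)
        _, read, _ = sg.junction_reads(res)[0]
        fwd = jl.resolve_junction(read, res.genome)[0]
        rev = jl.resolve_junction(revcomp(read), res.genome)[0]
        # the junction joins the same two loci, seen from the other side
        assert rev.mh_len == fwd.mh_len
        assert {(rev.chromA, rev.strandA), (rev.chromB, rev.strandB)} == \
            {(fwd.chromA, "-"), (fwd.chromB, "-")}

    def test_contiguous_read_has_no_junction(self, small_genome):
        read = small_genome.chromosomes["chr1"][500:900]
        assert jl.resolve_junction(read, small_genome) == []

    def test_unmappable_and_short_reads(self, small_genome):
        rng = np.random.default_rng(0)
        with pytest.raises(jl.UnmappableReadError):
            jl.resolve_junction(random_dna(rng, 200), small_genome)
        with pytest.raises(ValueError, match="min_anchor"):
            jl.resolve_junction("ACGT" * 5, small_genome)

    def test_ambiguous_anchor_detected(self):
        rng = np.random.default_rng(3)
        block = random_dna(rng, 3_000)
        filler = random_dna(rng, 10_000)
        genome = sg.Genome({"chr1": filler + block + random_dna(rng, 5_000)
                            + block + filler[::-1]})
        read = block[100:300] + random_dna(rng, 200)
        with pytest.raises(jl.AmbiguousAnchorError):
            jl.resolve_junction(read, genome)


class TestResolverVsBruteForce:
    def _brute_force_mh(self, read, chrom_seq):
        """Longest mapped prefix + suffix via exhaustive substring search."""
        p = len(read)
        while p > 0 and chrom_seq.find(read[:p]) < 0:
            p -= 1
        s = len(read)
        while s > 0 and chrom_seq.find(read[-s:]) < 0:
            s -= 1
        return p, s

    @pytest.mark.parametrize("m", [0, 2, 7, 15])
    def test_anchoring_matches_exhaustive_search(self, m):
        g = sg.simulate_genome(1, [80_000], seed=40 + m)
        spec = (sg.JunctionSpec("microhomology", mh_len=m) if m
                else sg.JunctionSpec())
        plan = sg.make_deletion_plan(g, "chr1", [(30_000, 55_000)],
                                     specs=[spec])
        res = sg.render_derived_genome(g, plan)
        _, read, _ = sg.junction_reads(res)[0]
        out = jl.resolve_junction(read, res.genome)[0]
        p, s = self._brute_force_mh(read, res.genome.chromosomes["chr1"])
        assert p + s - len(read) == out.mh_len == m


class TestMeasureMicrohomology:
    def _slide_oracle(self, flankA, flankB, j):
        """Number of extra split points producing the same derived word."""
        derived = flankA[:j] + flankB[j:]
        n = min(len(flankA), len(flankB))
        valid = [k for k in range(n + 1)
                 if flankA[:k] + flankB[k:] == derived]
        return max(valid) - min(valid)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_slide_oracle_on_random_flanks(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 40)
        b = random_dna(rng, 40)
        j = int(rng.integers(5, 35))
        assert jl.measure_microhomology(a, b, j) == self._slide_oracle(a, b, j)

    def test_terminal_shared_word(self):
        # flanks agreeing on TTAA around the junction slide by 4
        a = "GGGGGGGGTTAACCCCCCCC"
        b = "AAAAAAAATTAAGGGGGGGG"
        assert jl.measure_microhomology(a, b, 12) == 4

    def test_identical_flanks_full_slide(self):
        a = "ACGTACGTAC"
        assert jl.measure_microhomology(a, a, 5) == 10


class TestComplexity:
    def test_simple_vs_complex_labels(self):
        calls = [jl.JunctionCall("j1", "chr1", 10, "+", "chr1", 20, "+",
                                 rearrangement="r1", sample="S"),
                 jl.JunctionCall("j2", "chr1", 30, "+", "chr1", 40, "+",
                                 rearrangement="r2", sample="S"),
                 jl.JunctionCall("j3", "chr1", 50, "+", "chr1", 60, "+",
                                 rearrangement="r2", sample="S")]
        tab = jl.count_rearrangement_complexity(calls)
        labels = dict(zip(tab["rearrangement"], tab["label"]))
        assert labels == {"r1": "simple", "r2": "complex"}

    def test_missing_group_key_rejected(self):
        call = jl.JunctionCall("j", "chr1", 1, "+", "chr1", 2, "+")
        with pytest.raises(ValueError):
            jl.count_rearrangement_complexity([call])
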