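"""Genome, plan and read simulation: composition, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from svjl import pemdetect, simgenome as sg


class TestSimulateGenome:
    def test_uniform_gc_within_binomial_sd(self):
        g = sg.simulate_genome(1, [100_000], seed=7)
        gc = g.base_frequencies[1] + g.base_frequencies[2]
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_requested_composition_within_binomial_sd(self):
        f = [0.3, 0.2, 0.2, 0.3]
        g = sg.simulate_genome(2, [50_000, 50_000], base_freqs=f, seed=1)
        at = g.base_frequencies[0] + g.base_frequencies[3]
        assert abs(at - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 100_000)

    def test_deterministic_for_fixed_seed(self):
        a = sg.simulate_genome(2, [20_000, 10_000], seed=3)
        b = sg.simulate_genome(2, [20_000, 10_000], seed=3)
        c = sg.simulate_genome(2, [20_000, 10_000], seed=4)
        assert a.chromosomes == b.chromosomes
        assert a.chromosomes != c.chromosomes

    @pytest.mark.parametrize("lengths,freqs", [
        ([0], None), ([-5], None), ([10_000], [0.5, 0.5, 0.1, 0.1]),
    ])
    def test_invalid_arguments(self, lengths, freqs):
        with pytest.raises(ValueError):
            sg.simulate_genome(1, lengths, base_freqs=freqs)

    def test_base_frequencies_recomputable(self):
        g = sg.simulate_genome(1, [30_000], seed=2)
        f = g.base_frequencies
        assert abs(f.sum() - 1) < 1e-12


class TestPlans:
    def test_degenerate_junction_distribution(self):
        dist = sg.JunctionDistribution(p_microhomology=1, p_blunt=0,
                                       p_insertion=0, mh_pmf={5: 1.0})
        g = sg.simulate_genome(1, [400_000], seed=0)
        plan = sg.plan_rearrangements(g, "chromothripsis", 4, seed=1,
                                      junction_dist=dist,
                                      min_segment=20_000)[0]
        assert all(j.mh_len == 5 for j in plan.junctions)

    def test_chromothripsis_states_and_switches(self):
        g = sg.simulate_genome(1, [4_000_000], seed=0)
        plan = sg.plan_rearrangements(g, "chromothripsis", 20, seed=2,
                                      min_segment=80_000)[0]
        states = {s for *_, s in plan.true_states}
        assert states == {1, 2}
        assert len(plan.true_states) >= 40  # >= 2 * n_events fragments
        merged = sg.merged_true_states(plan)
        switches = sum(a[3] != b[3] for a, b in zip(merged, merged[1:]))
        assert switches >= 10

    def test_chromosome_too_short_for_shatter(self):
        g = sg.simulate_genome(1, [100_000], seed=0)
        with pytest.raises(ValueError, match="too short"):
            sg.plan_rearrangements(g, "chromothripsis", 10, seed=0,
                                   min_segment=150_000)

    def test_simple_deletion_plan_shape(self):
        g = sg.simulate_genome(1, [1_000_000], seed=0)
        plan = sg.make_deletion_plan(g, "chr1", [(300_000, 380_000)])
        assert len(plan.segments) == 2 and len(plan.junctions) == 1
        assert all(seg.chrom == "chr1" for seg in plan.segments)

    def test_simple_mode_sizes_exceed_convention(self):
        g = sg.simulate_genome(4, [2_000_000] * 4, seed=0)
        plans = sg.plan_rearrangements(g, "simple", 3, seed=5,
                                      sv_types=["deletion", "inversion",
                                                "duplication"])
        for plan in plans:
            lo = min(s.start for s in plan.segments)
            hi = max(s.end for s in plan.segments)
            inner = sorted({s.start for s in plan.segments} |
                           {s.end for s in plan.segments})
            # the rearranged interval spans more than 50 kb
            assert any(b - a > 50_000 for a, b in zip(inner, inner[1:]))


class TestRender:
    def test_blunt_deletion_concatenates_flanks(self):
        g = sg.simulate_genome(1, [60_000], seed=9)
        plan = sg.make_deletion_plan(g, "chr1", [(20_000, 40_000)])
        res = sg.render_derived_genome(g, plan)
        ref = res.genome.chromosomes["chr1"]
        assert res.derived.sequence == ref[:20_000] + ref[40_000:]
        assert res.truth[0].kind == "blunt"
        assert res.truth[0].mh_len == 0

    def test_untemplated_insertion_verbatim(self):
        ins = "ACGTACGTACGTACGTA"  # 17 bp
        g = sg.simulate_genome(1, [60_000], seed=9)
        plan = sg.make_deletion_plan(
            g, "chr1", [(20_000, 40_000)],
            specs=[sg.JunctionSpec("insertion", insertion_seq=ins)])
        res = sg.render_derived_genome(g, plan)
        t = res.truth[0]
        assert len(t.insertion_seq) == 17
        assert t.insertion_seq in res.derived.sequence

    def test_microhomology_word_shared_by_both_flanks(self):
        g = sg.simulate_genome(1, [60_000], seed=4)
        plan = sg.make_deletion_plan(
            g, "chr1", [(20_000, 40_000)],
            specs=[sg.JunctionSpec("microhomology", mh_len=6)])
        res = sg.render_derived_genome(g, plan)
        ref = res.genome.chromosomes["chr1"]
        assert ref[19_994:20_000] == ref[40_000:40_006]

    def test_templated_fragment_ground_truth(self):
        g = sg.simulate_genome(1, [200_000], seed=4)
        frag = sg.Segment("chr1", 71_000, 71_250, "-")
        plan = sg.make_fragment_insertion_plan(g, "chr1", 40_000, 70_000,
                                               frag, "templated")
        res = sg.render_derived_genome(g, plan)
        assert [c.kind for c in res.truth] == ["templated", "blunt"]
        assert res.truth[0].shard_or_template[4] <= 10_000
        assert len({c.rearrangement for c in res.truth}) == 1

    def test_fragment_overlapping_flank_rejected(self):
        g = sg.simulate_genome(1, [200_000], seed=4)
        frag = sg.Segment("chr1", 69_950, 70_150)
        plan = sg.make_fragment_insertion_plan(g, "chr1", 40_000, 70_000,
                                               frag, "templated")
        with pytest.raises(sg.JunctionConflictError):
            sg.render_derived_genome(g, plan)

    def test_seamless_join_rejected(self):
        g = sg.simulate_genome(1, [60_000], seed=0)
        plan = sg.RearrangementPlan(
            "bad", [sg.Segment("chr1", 0, 20_000),
                    sg.Segment("chr1", 20_000, 60_000)], [sg.JunctionSpec()])
        with pytest.raises(sg.JunctionConflictError):
            sg.render_derived_genome(g, plan)


class TestMatePairs:
    def test_pair_inside_segment_is_concordant(self):
        g = sg.simulate_genome(1, [200_000], seed=1)
        hap = sg.identity_derived(g, "chr1")
        pairs = sg.simulate_mate_pairs([hap], 500, seed=3)
        model = pemdetect.InsertModel(3000, 300)
        sigs = pemdetect.classify_pairs(pairs, model)
        assert (sigs == "normal").mean() > 0.99

    def test_outward_orientation_encoding(self):
        g = sg.simulate_genome(1, [200_000], seed=1)
        pairs = sg.simulate_mate_pairs([sg.identity_derived(g, "chr1")],
                                       200, seed=3)
        normal = pairs[pairs["source"] == "normal"]
        assert (normal["strand1"] == "-").all()
        assert (normal["strand2"] == "+").all()
        assert (normal["pos1"] < normal["pos2"]).all()

    def test_no_junctions_no_abnormal_pairs_beyond_tail(self):
        # with no planted junction the only abnormal pairs are the Gaussian
        # insert tail at the 4-sigma cut: expected 2 * n * Phi(-4) ~ 1.3
        g = sg.simulate_genome(1, [2_000_000], seed=1)
        pairs = sg.simulate_mate_pairs([sg.identity_derived(g, "chr1")],
                                       20_000, seed=8)
        model = pemdetect.fit_insert_model(pairs)
        sigs = pemdetect.classify_pairs(pairs, model)
        assert (sigs != "normal").sum() <= 8

    def test_effective_coverage_round_trip(self):
        g = sg.simulate_genome(1, [1_500_000], seed=1)
        haps = [sg.identity_derived(g, "chr1")]
        n = sg.pairs_for_coverage(haps, 10.0, insert_mean=3000)
        assert pemdetect.effective_coverage(n, 3000, 1_500_000) == \
            pytest.approx(10.0, abs=0.01)

    def test_errors(self):
        g = sg.simulate_genome(1, [30_000], seed=1)
        hap = sg.identity_derived(g, "chr1")
        with pytest.raises(ValueError, match="insert_mean"):
            sg.simulate_mate_pairs([hap], 10, insert_mean=80, read_len=50)
        with pytest.raises(ValueError, match="shorter"):
            sg.simulate_mate_pairs([hap], 10, insert_mean=20_000,
                                   insert_sd=2_000)

    def test_determinism(self):
        g = sg.simulate_genome(1, [200_000], seed=1)
        hap = sg.identity_derived(g, "chr1")
        a = sg.simulate_mate_pairs([hap], 300, seed=5)
        b = sg.simulate_mate_pairs([hap], 300, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestRnaSim:
    def test_zero_weight_yields_no_pairs(self, genome_with_genes):
        _, genes = genome_with_genes
        tr = sg.transcript_from_gene(genes[0])
        pairs = sg.simulate_rnaseq_pairs([tr], [0.0], 100, seed=1)
        assert len(pairs) == 0

    def test_negative_weight_rejected(self, genome_with_genes):
        _, genes = genome_with_genes
        tr = sg.transcript_from_gene(genes[0])
        with pytest.raises(ValueError):
            sg.simulate_rnaseq_pairs([tr], [-1.0], 10)

    def test_transcript_maps_within_exons(self, genome_with_genes):
        _, genes = genome_with_genes
        gene = genes[0]
        tr = sg.transcript_from_gene(gene)
        for t in range(0, tr.length, 37):
            chrom, pos, strand = tr.map_pos(t)
            assert strand == gene.strand
            assert any(s <= pos < e for s, e in gene.exons0)
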