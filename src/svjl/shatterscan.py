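"""Chromothripsis detection and top-level pipeline orchestration.

A chromothriptic chromosome shows (i) many switches between adjacent copy
states, (ii) only two (or very few) distinct states with the two dominant
states covering almost all segments, and (iii) a concentration of the
sample's SV link ends on that chromosome.  Chromosome pairs joined by many
inter-chromosomal links are additionally evaluated as one unit, capturing
two-chromosome shattering.  The thresholds are explicit, configurable and
deliberately conservative; no single published criterion is canonical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .readprofile import CopyNumberProfile


@dataclass
class Thresholds:
    min_state_switches: int = 10
    max_distinct_states: int = 3
    min_two_state_share: float = 0.9
    min_end_fraction: float = 0.5
    joint_min_inter_links: int = 5


@dataclass
class ChromUnitReport:
    unit: tuple                  # chromosome name(s)
    n_state_switches: int
    n_distinct_states: int
    fraction_of_sample_sv_ends: float
    oscillation_fraction: float
    flag: bool


def _unit_metrics(segments_by_chrom, unit, end_counts, total_ends,
                  thresholds: Thresholds) -> ChromUnitReport:
    states, switches = [], 0
    for chrom in unit:
        st = [s.state for s in segments_by_chrom.get(chrom, [])]
        states.extend(st)
        switches += sum(a != b for a, b in zip(st, st[1:]))
    if not states:
        return ChromUnitReport(unit, 0, 0, 0.0, 0.0, False)
    counts = pd.Series(states).value_counts()
    distinct = len(counts)
    two_share = counts.iloc[:2].sum() / len(states)
    ends = sum(end_counts.get(c, 0) for c in unit)
    frac = ends / total_ends if total_ends else 0.0
    flag = (switches >= thresholds.min_state_switches
            and distinct >= 2
            and distinct <= thresholds.max_distinct_states
            and two_share >= thresholds.min_two_state_share
            and frac >= thresholds.min_end_fraction)
    return ChromUnitReport(unit, switches, distinct, frac, two_share, flag)


def chromothripsis_score(profile: CopyNumberProfile, links,
                         thresholds: Thresholds | None = None):
    """Score every chromosome (and inter-linked chromosome pair) for
    chromothripsis; returns a list of :class:`ChromUnitReport`."""
    thresholds = thresholds or Thresholds()
    segments_by_chrom = {}
    for seg in profile.segments:
        segments_by_chrom.setdefault(seg.chrom, []).append(seg)
    profile_chroms = set(segments_by_chrom)
    link_chroms = {l.chrom1 for l in links} | {l.chrom2 for l in links}
    if not link_chroms <= profile_chroms:
        raise ValueError("links mention chromosomes absent from the profile: "
                         f"{sorted(link_chroms - profile_chroms)}")
    end_counts = {}
    inter_counts = {}
    for l in links:
        end_counts[l.chrom1] = end_counts.get(l.chrom1, 0) + 1
        end_counts[l.chrom2] = end_counts.get(l.chrom2, 0) + 1
        if l.chrom1 != l.chrom2:
            key = tuple(sorted((l.chrom1, l.chrom2)))
            inter_counts[key] = inter_counts.get(key, 0) + 1
    total_ends = 2 * len(links)

    units = [(c,) for c in sorted(segments_by_chrom)]
    units += [pair for pair, n in sorted(inter_counts.items())
              if n >= thresholds.joint_min_inter_links]
    return [_unit_metrics(segments_by_chrom, u, end_counts, total_ends,
                          thresholds) for u in units]


def report_table(reports) -> pd.DataFrame:
    return pd.DataFrame([{**asdict(r), "unit": "+".join(r.unit)}
                         for r in reports])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config, outdir=None) -> dict:
    """Run simulate -> detect -> cnv -> annotate -> junction -> mhtest ->
    motifs -> rna -> shatterscan end to end on a seeded simulation.

    ``config`` is a dict or a YAML path; outputs and a manifest are written
    under ``outdir``.  Any stage failure aborts with a stage-labelled error,
    preserving the outputs of earlier stages.
    """
    from . import (io, junctionlab, mhstats, motifscan, pemdetect,
                   readprofile, rnaevidence, simgenome, svannotate)

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir or config.get("outdir", "svjl_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng_seeds = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
    manifest = {"version": __version__, "seed": seed, "config": config,
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": []}

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise PipelineStageError(name, exc) from exc
        manifest["stages"].append(name)
        return out

    sim = config.get("simulate", {})
    mode = sim.get("mode", "chromothripsis")

    def _simulate():
        default_lengths = ([6_000_000, 2_000_000] if mode == "chromothripsis"
                           else [1_500_000] * 5)
        lengths = sim.get("lengths", default_lengths)
        genome = simgenome.simulate_genome(len(lengths), lengths,
                                           seed=int(rng_seeds[0]))
        genes = simgenome.simulate_gene_models(
            genome, sim.get("n_genes", 30), seed=int(rng_seeds[1]))
        plans = simgenome.plan_rearrangements(
            genome, mode,
            sim.get("n_events", 10 if mode == "chromothripsis" else 4),
            seed=int(rng_seeds[2]),
            size_range=tuple(sim.get("size_range", (60_000, 400_000))))
        derived, truth, planted = simgenome.render_sample(
            genome, plans, sample=sim.get("sample", "S1"))
        haps = simgenome.build_haplotypes(planted, plans, derived,
                                          diploid=(mode == "chromothripsis"))
        n_pairs = simgenome.pairs_for_coverage(
            haps, sim.get("coverage", 10.0), sim.get("insert_mean", 3000))
        pairs = simgenome.simulate_mate_pairs(
            haps, n_pairs, insert_mean=sim.get("insert_mean", 3000),
            insert_sd=sim.get("insert_sd", 300),
            read_len=sim.get("read_len", 50), seed=int(rng_seeds[3]))
        io.write_fasta(planted.chromosomes, outdir / "reference.fa")
        io.write_bed12(genes, outdir / "genes.bed")
        io.write_pairs_bedpe(pairs, outdir / "pairs.bedpe")
        io.write_truth_junctions(truth, outdir / "truth_junctions.tsv")
        return genome, genes, plans, derived, truth, planted, pairs

    genome, genes, plans, derived, truth, planted, pairs = stage(
        "simulate", _simulate)

    def _detect():
        links, model = pemdetect.detect_svs(
            pairs, min_support=config.get("detect", {}).get("min_support", 2))
        pemdetect.links_to_bedpe(links).to_csv(
            outdir / "links.bedpe", sep="\t", index=False)
        pemdetect.circos_links(links).to_csv(
            outdir / "circos_links.txt", sep="\t", index=False, header=False)
        return links, model

    links, model = stage("detect", _detect)

    def _cnv():
        lengths = {c: len(s) for c, s in planted.chromosomes.items()}
        prof = readprofile.window_counts(
            pairs, lengths, config.get("cnv", {}).get("window", 30_000))
        prof = readprofile.normalize_and_segment(prof)
        prof.segment_table().to_csv(outdir / "cnv_segments.tsv", sep="\t",
                                    index=False)
        return prof

    profile = stage("cnv", _cnv)

    def _annotate():
        anns = svannotate.annotate_links(links, genes)
        svannotate.annotation_table(links, anns).to_csv(
            outdir / "annotations.tsv", sep="\t", index=False)
        svannotate.category_summary(links, anns).to_csv(
            outdir / "category_summary.tsv", sep="\t", index=False)
        return anns

    annotations = stage("annotate", _annotate)

    def _junction():
        calls = []
        reads = []
        for plan, d in zip(plans, derived):
            res = simgenome.RenderResult(d, [t for t in truth
                                             if t.junction_id.startswith(plan.name + ":")],
                                         planted, plan)
            reads.extend(simgenome.junction_reads(res))
        for rid, read, tcalls in reads:
            resolved = junctionlab.resolve_junction(read, planted,
                                                    junction_id=rid)
            for c in resolved:
                c.rearrangement = rid
                c.sample = tcalls[0].sample
                c.chromothripsis = tcalls[0].chromothripsis
            calls.extend(resolved)
        junctionlab.calls_to_table(calls).to_csv(
            outdir / "junction_calls.tsv", sep="\t", index=False)
        return calls

    calls = stage("junction", _junction)

    def _mhtest():
        null = mhstats.null_pmf(planted.base_frequencies)
        rep = mhstats.stratified_report(calls, null)
        rep.histogram.to_csv(outdir / "mh_histogram.tsv", sep="\t",
                             index=False)
        rep.totals.to_csv(outdir / "mh_totals.tsv", sep="\t", index=False)
        tests = {k: {"chi2": v.chi2, "df": v.df, "p_value": v.p_value}
                 for k, v in rep.tests.items()}
        (outdir / "mh_tests.json").write_text(json.dumps(tests, indent=2))
        return rep

    stage("mhtest", _mhtest)

    def _motifs():
        bps = [(c.chromA, c.posA) for c in calls]
        res = motifscan.enrichment_test(
            bps, planted, n_background=config.get("motifs", {})
            .get("n_background", 200), seed=int(rng_seeds[3]))
        res.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        return res

    stage("motifs", _motifs)

    def _rna():
        svs = _eligible_from_annotations(links, annotations, genes)
        weights = config.get("rna", {}).get("weight", 5.0)
        transcripts, w = [], []
        for sv in svs:
            try:
                transcripts.append(simgenome.fusion_transcript(
                    sv.gene5, sv.bp5, sv.gene3, sv.bp3))
                w.append(weights)
            except ValueError:
                continue
        rna_pairs = simgenome.simulate_rnaseq_pairs(
            transcripts, w, n_pairs=config.get("rna", {}).get("n_pairs", 500),
            seed=int(rng_seeds[2])) if transcripts else pd.DataFrame(
            columns=["id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                     "strand2", "read_len", "source"])
        evidence, summary = rnaevidence.expression_summary(svs, rna_pairs)
        rnaevidence.evidence_table(evidence).to_csv(
            outdir / "rna_evidence.tsv", sep="\t", index=False)
        return summary

    rna_summary = stage("rna", _rna)

    def _shatterscan():
        reports = chromothripsis_score(profile, links)
        report_table(reports).to_csv(outdir / "chromothripsis.tsv", sep="\t",
                                     index=False)
        return reports

    reports = stage("shatterscan", _shatterscan)

    manifest["rna_summary"] = rna_summary
    manifest["flagged_units"] = ["+".join(r.unit) for r in reports if r.flag]
    _write_manifest(outdir, manifest)
    return manifest


def _eligible_from_annotations(links, annotations, genes):
    from .rnaevidence import ELIGIBLE_CATEGORIES, EligibleSV

    by_id = {g.gene_id: g for g in genes}
    svs = []
    for link, ann in zip(links, annotations):
        if ann.category not in ELIGIBLE_CATEGORIES or len(ann.genes_hit) < 1:
            continue
        g1 = next((by_id[g] for g in ann.genes_hit
                   if by_id[g].chrom == link.chrom1), None)
        g2 = next((by_id[g] for g in ann.genes_hit
                   if by_id[g].chrom == link.chrom2), None)
        if g1 is None or g2 is None:
            continue
        svs.append(EligibleSV(link.id, g1, link.bp1, g2, link.bp2,
                              ann.category))
    return svs


def _write_manifest(outdir: Path, manifest: dict):
    (Path(outdir) / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
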