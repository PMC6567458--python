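"""End-to-end orchestration: simulate -> preprocess -> align/call ->
filter -> differential test -> annotate -> origin -> integrate.

Every stage is also runnable standalone from prior stage outputs (see the
CLI); this module wires them together on a fresh simulation and emits a
run manifest whose stage-by-stage record counts reconcile (site
conservation: input = kept + removed-by-coverage + removed-invariant +
removed-SNP).  Identical (config, seed) pairs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .annotate import annotate_sites, attribute_origins, feature_distribution
from .bscall import BisulfiteAligner, call_methylation, conversion_rate
from .config import PipelineConfig
from .diffmeth import (
    call_variants_pileup,
    cluster_samples,
    diff_test,
    drop_invariant,
    exclude_snp_sites,
    significant_sites,
    unite,
)
from .integrate import (
    de_test,
    integration_summary,
    match_sites_to_genes,
    methylation_expression_correlation,
)
from .preprocess import filter_reads
from .simgen import (
    cpg_positions,
    digest,
    inject_variants,
    simulate_annotation,
    simulate_bisulfite_reads,
    simulate_expression,
    simulate_genome,
    simulate_genomic_reads,
    simulate_methylome,
    size_select,
)

__all__ = ["RunManifest", "PipelineResult", "run_pipeline"]

log = logging.getLogger("rrbspipe")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: float
    finished: float = 0.0
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    genome: object
    annotation: object
    methylome: object
    variants: object
    callsets: dict
    conversion_rates: dict
    matrix: object
    screen: object
    comparisons: dict  # (g1, g2) -> list[DiffMethRecord]
    tallies: dict
    annotated: dict
    feature_pcts: dict
    origins: list
    dendrogram: object
    expression: object
    de_results: list
    integration: list
    integration_stats: dict


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    from . import io as fio

    os.makedirs(outdir, exist_ok=True)
    fio.write_fasta(result.genome, os.path.join(outdir, "genome.fa"))
    fio.write_bed12(result.annotation, os.path.join(outdir, "genes.bed"))
    fio.write_vcf(result.variants, os.path.join(outdir, "variants.vcf"))
    for sample, cs in result.callsets.items():
        fio.write_cytosine_report(cs, os.path.join(outdir, f"{sample}.cytosine.tsv"))
    for (g1, g2), records in result.comparisons.items():
        fio.write_diff_results(records, os.path.join(outdir, f"diff_{g1}_vs_{g2}.tsv"))
    if result.dendrogram is not None:
        fio.write_newick(result.dendrogram.to_newick(), os.path.join(outdir, "dendrogram.nwk"))
    if result.expression is not None:
        fio.write_expression(result.expression.values, os.path.join(outdir, "expression.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(result.manifest.to_json())


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run the full synthetic study under one configuration.

    Stage failures propagate with the stage named in the log; outputs
    produced before the failure are retained when ``outdir`` is given.
    """
    config.validate()
    t0 = time.time()
    manifest = RunManifest(config_hash=config.hash(), version=__version__, started=t0)
    counts = manifest.counts
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2**31))

    log.info("stage: simulate")
    genome = simulate_genome(
        config.n_contigs, config.contig_length, config.cpg_enrichment,
        seed=stage_seed(), spikein_length=config.spikein_length,
    )
    annotation = simulate_annotation(genome, genes_per_contig=config.genes_per_contig,
                                     seed=stage_seed())
    group_names = list(config.groups)
    methylome = simulate_methylome(
        genome, group_names, diff_fraction=config.diff_fraction, delta=config.delta,
        seed=stage_seed(),
    )
    all_cpgs = sorted(
        {(c, p) for c in genome.names if c not in genome.spikein_names
         for p, _s in cpg_positions(genome, c)}
    )
    variants = inject_variants(genome, all_cpgs, config.snp_fraction, seed=stage_seed())
    fragments = size_select(digest(genome, config.enzymes),
                            config.min_fragment, config.max_fragment)
    counts["fragments"] = len(fragments)
    counts["variants_injected"] = len(variants)

    samples = config.sample_groups()
    log.info("stage: reads + preprocess (%d samples)", len(samples))
    callsets = {}
    conv = {}
    aligner = BisulfiteAligner(genome, max_mismatch=config.max_mismatch, convert=True)
    qc_counts = {}
    for sample, group in samples.items():
        reads = simulate_bisulfite_reads(
            genome, fragments, methylome, group,
            conversion_rate=config.conversion_rate, read_len=config.read_len,
            depth=config.depth, error_rate=config.error_rate, seed=stage_seed(),
            sample=sample, spikein_mass=config.spikein_mass,
        )
        kept, report = filter_reads(reads, config.min_mean_q, config.min_read_len,
                                    config.adapter)
        qc_counts[sample] = {"in": report.reads_in, "kept": report.reads_kept}
        placements = aligner.align_all(kept)
        callsets[sample] = call_methylation(placements, kept, genome, sample=sample)
        conv[sample] = conversion_rate(callsets[sample], genome.spikein_names)
    counts["qc"] = qc_counts

    log.info("stage: variant screen")
    genomic = simulate_genomic_reads(genome, fragments, variants,
                                     depth=config.genomic_depth,
                                     error_rate=config.error_rate,
                                     read_len=config.read_len, seed=stage_seed())
    gkept, _ = filter_reads(genomic, config.min_mean_q, config.min_read_len, config.adapter)
    galigner = BisulfiteAligner(genome, max_mismatch=config.max_mismatch, convert=False)
    gplacements = galigner.align_all(gkept)
    screen = call_variants_pileup(
        gplacements, gkept, genome, min_cov=config.pileup_min_cov,
        min_alt_frac=config.pileup_min_alt_frac, min_alt_count=config.pileup_min_alt_count,
    )
    counts["variants_flagged"] = len(screen)

    log.info("stage: unite + filter")
    matrix = unite(callsets, samples, min_coverage=config.min_coverage)
    counts["sites_united"] = matrix.n_sites
    matrix2 = drop_invariant(matrix)
    counts["sites_removed_invariant"] = matrix.n_sites - matrix2.n_sites
    matrix3, n_snp = exclude_snp_sites(matrix2, screen)
    counts["sites_removed_snp"] = n_snp
    counts["sites_tested"] = matrix3.n_sites
    assert matrix.n_sites == matrix3.n_sites + counts["sites_removed_invariant"] + n_snp

    log.info("stage: differential testing")
    comparisons = {}
    tallies = {}
    for g1, g2 in itertools.combinations(group_names, 2):
        records = diff_test(matrix3, g1, g2, config.q_threshold, config.diff_threshold)
        comparisons[(g1, g2)] = records
        sig, tally = significant_sites(records, config.q_threshold, config.diff_threshold)
        tallies[(g1, g2)] = {"significant": len(sig), "hyper": tally}
    counts["significant"] = {f"{a}_vs_{b}": t["significant"] for (a, b), t in tallies.items()}

    log.info("stage: annotate")
    annotated = {}
    feature_pcts = {}
    for pair, records in comparisons.items():
        sig = [r.site for r in records if r.significant]
        if sig:
            ann = annotate_sites(sig, annotation, promoter_bp=config.promoter_bp)
            annotated[pair] = ann
            feature_pcts[pair] = feature_distribution(ann)

    origins = []
    oc = config.origin or {}
    if oc and set(oc.get("pietrain", [])) | {oc.get("f2"), oc.get("duroc")} <= set(group_names) | {None}:
        f2, duroc = oc.get("f2"), oc.get("duroc")
        pietrain = list(oc.get("pietrain", []))
        if f2 in group_names and duroc in group_names and len(pietrain) == 2:
            log.info("stage: origin attribution")

            def sig_set(a, b):
                recs = comparisons.get((a, b)) or comparisons.get((b, a)) or []
                return {r.site for r in recs if r.significant}

            origins = attribute_origins(
                sig_set(f2, duroc), sig_set(f2, pietrain[0]), sig_set(f2, pietrain[1]),
                [s for s in matrix3.sites],
            )
            counts["origin"] = {
                lab: sum(1 for o in origins if o.label == lab)
                for lab in ("Duroc_origin", "Pietrain_origin", "unassigned")
            }

    dendrogram = None
    if len(samples) >= 3 and matrix3.n_sites >= 2:
        log.info("stage: clustering")
        dendrogram = cluster_samples(matrix3)

    log.info("stage: integrate")
    eg = list(config.expression_groups)
    expr_samples = {}
    for g in eg:
        for i in range(config.expression_samples_per_group):
            expr_samples[f"{g}_{i + 1}"] = g
    expression = simulate_expression(
        annotation, expr_samples, de_fraction=config.de_fraction,
        effect_size=config.effect_size, link_to_methylome=methylome,
        link_fraction=config.link_fraction, link_window=config.integration_window,
        noise_sd=config.noise_sd, seed=stage_seed(),
    )
    de_results = de_test(expression, eg[0], eg[1])
    pair = (eg[0], eg[1]) if (eg[0], eg[1]) in comparisons else (eg[1], eg[0])
    dm_records = comparisons.get(pair, [])
    pairs = match_sites_to_genes(dm_records, annotation, window_bp=config.integration_window)
    # correlation needs methylation and expression on shared samples; the
    # expression stand-in simulates the same individuals, so reuse the
    # methylation samples of the two groups where names coincide
    integration = []
    istats = {"n_pairs": float(len(pairs)), "n_de_significant": 0.0,
              "n_negative": 0.0, "fraction_negative": float("nan")}
    shared = [s for s in matrix3.samples if s in expression.values.columns]
    if len(shared) >= 3 and pairs:
        integration = methylation_expression_correlation(pairs, matrix3, expression, de_results)
        istats = integration_summary(integration)
    counts["integration"] = {k: (None if v != v else v) for k, v in istats.items()}

    manifest.finished = time.time()
    result = PipelineResult(
        manifest=manifest, genome=genome, annotation=annotation, methylome=methylome,
        variants=variants, callsets=callsets, conversion_rates=conv, matrix=matrix3,
        screen=screen, comparisons=comparisons, tallies=tallies, annotated=annotated,
        feature_pcts=feature_pcts, origins=origins, dendrogram=dendrogram,
        expression=expression, de_results=de_results, integration=integration,
        integration_stats=istats,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result
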