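"""Stage functions wiring the library into an end-to-end pipeline.

Each stage reads its predecessors' outputs from disk under
``config.output_dir`` and writes its own, so stages can be run separately
or chained with ``run_all``. Every output table is plain TSV/JSON; a config
hash is logged per stage for provenance.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import cdr3 as cdr3_mod
from . import linkage as linkage_mod
from . import network as network_mod
from .annotation import LocusAnnotation, read_track_bed
from .config import PipelineConfig
from .genotypes import GenotypeTable
from .ld import blocks_overlap_genes, blocks_to_frame, collapse_perfect_ld, gabriel_blocks
from .repertoire import (
    collapse_paralogs,
    filter_samples,
    partition_by_mutation,
    restrict_to_germline,
    write_airr,
)
from .scan import run_scan, summarize_leads
from .simulate import demo_cohort, read_fixture_bundle, write_fixture_bundle
from .usage import UsageMatrix, compute_usage, mask_undisambiguated, retain_genes

log = logging.getLogger("guqtl")

STAGES = ["simulate", "prep", "usage", "ld", "guqtl", "network", "cdr3", "linkage", "enrich"]


def _out(cfg: PipelineConfig, *parts: str) -> str:
    path = os.path.join(cfg.output_dir, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def _log_stage(cfg: PipelineConfig, stage: str, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s config=%s seed=%d %s", stage, cfg.config_hash(), cfg.seed, info)


def _load_inputs(cfg: PipelineConfig):
    """Genotypes / repertoire / germline sets / annotation from config paths
    (defaulting to the simulate stage's fixture directory)."""
    fixture = os.path.join(cfg.output_dir, "fixture")
    if cfg.vcf is None and os.path.isdir(fixture):
        return read_fixture_bundle(fixture)
    for key in ("vcf", "airr_dir", "germline_fasta", "germline_alleles", "annotation_bed"):
        if getattr(cfg, key) is None:
            raise FileNotFoundError(f"config key '{key}' is required (no fixture found)")
    bundle_dir = os.path.dirname(os.path.abspath(cfg.vcf))
    return read_fixture_bundle(bundle_dir)


def stage_simulate(cfg: PipelineConfig):
    """Generate a synthetic cohort with planted effects and write it out."""
    genotypes, truth, annotation, out = demo_cohort(cfg.seed, cfg.n_individuals)
    fixture_dir = os.path.join(cfg.output_dir, "fixture")
    os.makedirs(fixture_dir, exist_ok=True)
    paths = write_fixture_bundle(
        fixture_dir,
        genotypes,
        out.repertoire,
        out.germline_sets,
        annotation,
        truth,
    )
    out.sample_log.to_csv(_out(cfg, "fixture", "sample_log.tsv"), sep="\t", index=False)
    _log_stage(cfg, "simulate", individuals=genotypes.n_individuals,
               variants=genotypes.n_variants, sequences=len(out.repertoire))
    return paths


def stage_prep(cfg: PipelineConfig):
    """Paralog collapsing, germline restriction, mutation partition, filters."""
    genotypes, repertoire, germline_sets, annotation = _load_inputs(cfg)
    paralog_pairs = [tuple(p) for p in cfg.paralog_pairs]
    # restrict against the personalized set first: germline lookups use the
    # original gene names, collapsing rewrites them to ambi labels after
    restricted, dropped = restrict_to_germline(repertoire, germline_sets)
    collapsed, status = collapse_paralogs(restricted, germline_sets, cfg.ambi_map, paralog_pairs)
    unmutated, mutated = partition_by_mutation(collapsed)
    unmutated, log_u = filter_samples(unmutated, cfg.min_unique)
    mutated, log_m = filter_samples(mutated, cfg.min_unique)
    write_airr(unmutated, _out(cfg, "prepared", "unmutated.tsv"))
    write_airr(mutated, _out(cfg, "prepared", "mutated.tsv"))
    status.to_csv(_out(cfg, "prepared", "disambiguation.tsv"), sep="\t", index=False)
    pd.concat([log_u.assign(partition="unmutated"), log_m.assign(partition="mutated")]).to_csv(
        _out(cfg, "prepared", "dropped_samples.tsv"), sep="\t", index=False
    )
    dropped.to_csv(_out(cfg, "prepared", "dropped_records.tsv"), sep="\t", index=False)
    _log_stage(cfg, "prep", records_in=len(repertoire), unmutated=len(unmutated),
               mutated=len(mutated))
    return unmutated, mutated


def _read_prepared(cfg: PipelineConfig, partition: str) -> pd.DataFrame:
    return pd.read_csv(_out(cfg, "prepared", f"{partition}.tsv"), sep="\t",
                       dtype={"sequence_id": str, "sample_id": str})


def stage_usage(cfg: PipelineConfig, partition: str = "unmutated") -> UsageMatrix:
    rep = _read_prepared(cfg, partition)
    usage = retain_genes(compute_usage(rep, "V"), cfg.min_count)
    usage.to_tsv(
        _out(cfg, "usage", f"{partition}_freq.tsv"),
        _out(cfg, "usage", f"{partition}_counts.tsv"),
    )
    _log_stage(cfg, "usage", partition=partition, genes=len(usage.genes),
               samples=len(usage.samples))
    return usage


def stage_ld(cfg: PipelineConfig):
    genotypes, _, _, annotation = _load_inputs(cfg)
    common = genotypes.filter_maf(cfg.min_maf)
    blocks = gabriel_blocks(common, cfg.gabriel)
    overlap = blocks_overlap_genes(blocks, annotation)
    blocks_to_frame(blocks).to_csv(_out(cfg, "ld", "blocks.tsv"), sep="\t", index=False)
    overlap.to_csv(_out(cfg, "ld", "block_genes.tsv"), sep="\t", index=False)
    groups = collapse_perfect_ld(common)
    with open(_out(cfg, "ld", "perfect_ld_groups.json"), "w") as fh:
        json.dump(sorted(sorted(g) for g in groups), fh, indent=1)
    _log_stage(cfg, "ld", variants=common.n_variants, blocks=len(blocks),
               effective_tests=len(groups))
    return blocks, groups


def stage_guqtl(cfg: PipelineConfig, partition: str = "unmutated"):
    genotypes, _, _, annotation = _load_inputs(cfg)
    usage = stage_usage(cfg, partition)
    status_path = _out(cfg, "prepared", "disambiguation.tsv")
    if os.path.exists(status_path):
        status = pd.read_csv(status_path, sep="\t", dtype={"individual": str})
        usage = mask_undisambiguated(usage, status)
    scan = run_scan(usage, genotypes, alpha=cfg.alpha, min_maf=cfg.min_maf,
                    partition=partition, transform=cfg.usage_transform)
    leads = summarize_leads(scan, usage, genotypes, annotation)
    scan.results.to_csv(_out(cfg, "guqtl", f"{partition}_results.tsv"), sep="\t", index=False)
    leads.to_csv(_out(cfg, "guqtl", f"{partition}_leads.tsv"), sep="\t", index=False)
    with open(_out(cfg, "guqtl", f"{partition}_threshold.json"), "w") as fh:
        json.dump({"threshold": scan.threshold, "n_effective_tests": scan.n_effective_tests}, fh)
    _log_stage(cfg, "guqtl", partition=partition, threshold=scan.threshold,
               significant=int(scan.results["significant"].sum()))
    return scan, leads


def stage_network(cfg: PipelineConfig, partition: str = "unmutated"):
    results = pd.read_csv(_out(cfg, "guqtl", f"{partition}_results.tsv"), sep="\t")
    sig = results[results["significant"]]
    sets = {g: set(grp["variant_id"]) for g, grp in sig.groupby("gene")}
    graph = network_mod.build_graph(sets)
    network_mod.edges_table(graph).to_csv(_out(cfg, "network", "edges.tsv"), sep="\t", index=False)
    cliques = network_mod.maximal_cliques(graph)
    comps = network_mod.connected_components(graph)
    with open(_out(cfg, "network", "cliques.json"), "w") as fh:
        json.dump(
            {
                "maximal_cliques": [sorted(c) for c in cliques],
                "connected_components": [sorted(c) for c in comps],
            },
            fh,
            indent=1,
        )
    _log_stage(cfg, "network", nodes=graph.number_of_nodes(), edges=graph.number_of_edges(),
               cliques=len(cliques))
    return graph, cliques


def stage_cdr3(cfg: PipelineConfig, partition: str = "unmutated"):
    genotypes, _, _, _ = _load_inputs(cfg)
    rep = _read_prepared(cfg, partition)
    means = cdr3_mod.sample_mean_properties(rep, ph=cfg.ph)
    results = pd.read_csv(_out(cfg, "guqtl", f"{partition}_results.tsv"), sep="\t")
    sig = results[results["significant"]]
    guqtl_sets = {g: set(grp["variant_id"]) for g, grp in sig.groupby("gene")}
    scan, prop_leads = cdr3_mod.property_qtl_scan(
        means, genotypes, alpha=cfg.alpha, min_maf=cfg.min_maf, guqtl_sets=guqtl_sets
    )
    means.to_csv(_out(cfg, "cdr3", f"{partition}_sample_means.tsv"), sep="\t")
    scan.results.to_csv(_out(cfg, "cdr3", f"{partition}_property_qtl.tsv"), sep="\t", index=False)
    prop_leads.to_csv(_out(cfg, "cdr3", f"{partition}_property_leads.tsv"), sep="\t", index=False)
    _log_stage(cfg, "cdr3", partition=partition,
               significant=int(scan.results["significant"].sum()))
    return scan, prop_leads


def stage_linkage(cfg: PipelineConfig, partition: str = "unmutated"):
    genotypes, _, germline_sets, _ = _load_inputs(cfg)
    leads = pd.read_csv(_out(cfg, "guqtl", f"{partition}_leads.tsv"), sep="\t")
    out = linkage_mod.allele_linkage_scan(germline_sets, leads, genotypes,
                                          alpha=cfg.alpha, seed=cfg.seed)
    out.to_csv(_out(cfg, "linkage", f"{partition}_allele_linkage.tsv"), sep="\t", index=False)
    _log_stage(cfg, "linkage", genes=len(out))
    return out


def stage_enrich(cfg: PipelineConfig, partition: str = "unmutated"):
    if cfg.tfbs_bed is None or not os.path.exists(cfg.tfbs_bed):
        log.warning("no TFBS track configured; skipping enrichment")
        return None
    genotypes, _, _, _ = _load_inputs(cfg)
    common = genotypes.filter_maf(cfg.min_maf)
    results = pd.read_csv(_out(cfg, "guqtl", f"{partition}_results.tsv"), sep="\t")
    sig = set(results[results["significant"]]["variant_id"])
    track = read_track_bed(cfg.tfbs_bed)
    res = linkage_mod.tfbs_enrichment(sig, common, track)
    if res is not None:
        pd.DataFrame(
            [{"track": res.label, "p": res.p, "odds_ratio": res.odds_ratio,
              "method": res.method, "a": res.table[0, 0], "b": res.table[0, 1],
              "c": res.table[1, 0], "d": res.table[1, 1]}]
        ).to_csv(_out(cfg, "enrich", f"{partition}_tfbs.tsv"), sep="\t", index=False)
        _log_stage(cfg, "enrich", p=res.p)
    return res


def run_all(cfg: PipelineConfig, partition: str = "unmutated"):
    """Run every stage in order on (or after simulating) a cohort."""
    cfg.validate()
    stage_simulate(cfg)
    stage_prep(cfg)
    stage_ld(cfg)
    stage_guqtl(cfg, partition)
    stage_network(cfg, partition)
    stage_cdr3(cfg, partition)
    stage_linkage(cfg, partition)
    stage_enrich(cfg, partition)
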