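"""End-to-end orchestration of the analysis stages.

A run directory is populated stage by stage in dependency order
(filter -> summaries -> enrichment / pathogen -> clustering -> AAI ->
k-mer), every table is written as TSV, and a machine-readable
``summary.json`` plus a plain-text log record seeds, thresholds and
stage outcomes.  All randomness flows from the single master seed via
named substreams, so a rerun with the same config and inputs reproduces
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import pandas as pd
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .catalog import (
    filter_predictions,
    per_genome_counts,
    length_distribution,
    load_catalog,
    summarize_catalog,
    write_prophage_table,
)
from .clustering import greedy_cluster, host_range_report, membership_table
from .enrichment import (
    bootstrap_enrichment,
    bootstrap_table,
    enrichment_table,
    rank_enrichment,
    size_abundance,
)
from .aai import build_network, fraction_by_rank
from .kmer import cocluster_profiles, kmer_bias, merge_profiles, profile_matrix
from .pathogen import (
    cap_per_genus,
    group_enrichment,
    label_hosts,
    loo_contribution,
    shared_genus_comparison,
)
from .seqcompare import find_orfs
from .synthetic import SimulationConfig, simulate_catalog

__all__ = ["RunConfig", "StageError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("filter", "summarize", "enrich", "bootstrap", "pathogen",
              "cluster", "aai", "kmer")

log = logging.getLogger("prophagekit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    outdir: str = "run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either explicit tables or a simulation block
    host_table: Optional[str] = None
    prophage_table: Optional[str] = None
    fasta: Optional[str] = None
    simulate: Optional[dict] = None
    # filtering
    min_replicon_bp: int = 10_000
    keep_categories: tuple[int, ...] = (1, 2)
    drop_plasmid: bool = True
    # enrichment
    enrich_rank: str = "genus"
    min_genomes: int = 5
    cap_trigger: Optional[int] = 50
    cap_sample: int = 10
    bootstrap_n_genomes: int = 10
    bootstrap_n_iter: int = 100
    bootstrap_min_genus: int = 50
    # pathogen
    pathogen_cap: int = 100
    # clustering / AAI
    id_threshold: float = 0.90
    cov_threshold: float = 0.80
    aai_threshold: float = 80.0
    min_orf_aa: int = 33
    # k-mer
    kmer_ks: tuple[int, ...] = (2, 3)

    def __post_init__(self):
        if not 0 < self.id_threshold <= 1 or not 0 < self.cov_threshold <= 1:
            raise ValueError("identity/coverage thresholds must lie in (0, 1]")
        if not 0 <= self.aai_threshold <= 100:
            raise ValueError("aai_threshold must lie in [0, 100]")
        if self.min_replicon_bp < 0 or self.bootstrap_n_iter < 1:
            raise ValueError("min_replicon_bp >= 0 and bootstrap_n_iter >= 1 required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for k in self.kmer_ks:
            if not 1 <= k <= 4:
                raise ValueError("kmer_ks entries must lie in 1..4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "keep_categories", "kmer_ks"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; returns (and writes) the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": _sanitize(dataclasses.asdict(config)),
        "stages": {},
    }
    try:
        log.info("prophagekit %s, seed %d", __version__, config.seed)
        sequences: dict[str, str] = {}
        if config.simulate is not None:
            sim_conf = SimulationConfig(**{"seed": config.seed, **config.simulate})
            cat = simulate_catalog(sim_conf)
            paths = cat.write(outdir / "inputs")
            hosts, records = load_catalog(
                paths["prophages"], paths["hosts"],
                paths["fasta"] if cat.sequences else None)
            sequences = dict(cat.sequences)
            log.info("simulated %d hosts, %d prophages", len(hosts), len(records))
        else:
            if not (config.host_table and config.prophage_table):
                raise ValueError("either input tables or a simulate block is required")
            hosts, records = load_catalog(config.prophage_table,
                                          config.host_table, config.fasta)
            for rec in records:
                if rec.sequence:
                    sequences[rec.prophage_id] = rec.sequence
            log.info("loaded %d hosts, %d prophages", len(hosts), len(records))

        filtered = records
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            try:
                if stage == "filter":
                    filtered = filter_predictions(
                        records, hosts, config.min_replicon_bp,
                        config.keep_categories, config.drop_plasmid)
                    write_prophage_table(filtered, outdir / "filtered_prophages.tsv")
                    summary["stages"]["filter"] = {
                        "n_input": len(records), "n_retained": len(filtered)}
                elif stage == "summarize":
                    s = summarize_catalog(hosts, filtered)
                    out = _sanitize(dataclasses.asdict(s))
                    if filtered:
                        dist = length_distribution(filtered)
                        out["mean_length"] = dist["mean_length"]
                        out["modal_bins_bp"] = dist["modal_bins"]
                        sa = size_abundance(hosts, filtered)
                        sa["bins"].to_csv(outdir / "size_abundance.tsv",
                                          sep="\t", index=False)
                        out["spearman_rho"] = _sanitize(sa["spearman_rho"])
                    summary["stages"]["summarize"] = out
                elif stage == "enrich":
                    res = rank_enrichment(
                        hosts, filtered, rank=config.enrich_rank,
                        min_genomes=config.min_genomes,
                        cap_trigger=config.cap_trigger,
                        cap_sample=config.cap_sample, seed=config.seed)
                    enrichment_table(res).to_csv(
                        outdir / "enrichment.tsv", sep="\t", index=False)
                    summary["stages"]["enrich"] = {
                        "n_taxa_tested": len(res),
                        "significant": [r.taxon for r in res if r.p_adjusted < 0.05],
                    }
                elif stage == "bootstrap":
                    boot, skipped = bootstrap_enrichment(
                        hosts, filtered, config.bootstrap_n_genomes,
                        config.bootstrap_n_iter, config.bootstrap_min_genus,
                        seed=config.seed)
                    bootstrap_table(boot).to_csv(outdir / "bootstrap_p.tsv", sep="\t")
                    summary["stages"]["bootstrap"] = {
                        "genera": [b.genus for b in boot], "skipped": skipped,
                        "median_p": {b.genus: float(b.quantiles()[0.5])
                                     for b in boot},
                    }
                elif stage == "pathogen":
                    capped = cap_per_genus(hosts, config.pathogen_cap, config.seed)
                    labels = label_hosts(capped)
                    counts = per_genome_counts(capped, [
                        r for r in filtered
                        if r.genome_id in {h.genome_id for h in capped}])
                    lab = {l.genome_id: l.label for l in labels}
                    pat = [counts[g] for g in counts.index if lab[g] == "pathogen"]
                    una = [counts[g] for g in counts.index if lab[g] == "unassigned"]
                    stage_out: dict = {"n_pathogen": len(pat),
                                       "n_unassigned": len(una)}
                    if pat and una:
                        stage_out.update(_sanitize(group_enrichment(pat, una)))
                        loo = loo_contribution(labels, capped, filtered)
                        pd_rows = [{"left_out_genus": r.left_out_genus,
                                    "p_value": r.p_value,
                                    "delta_vs_full": r.delta_vs_full}
                                   for r in loo]
                        pd.DataFrame(pd_rows).to_csv(
                            outdir / "loo.tsv", sep="\t", index=False)
                        try:
                            shared = shared_genus_comparison(labels, capped, filtered)
                            shared.to_csv(outdir / "shared_genus.tsv",
                                          sep="\t", index=False)
                        except ValueError:
                            pass
                    summary["stages"]["pathogen"] = stage_out
                elif stage == "cluster":
                    with_seq = [r for r in filtered if r.sequence]
                    if not with_seq:
                        summary["stages"]["cluster"] = {"skipped": "no sequences"}
                        continue
                    vcs = greedy_cluster(with_seq, hosts,
                                         config.id_threshold, config.cov_threshold)
                    membership_table(vcs).to_csv(
                        outdir / "clusters.tsv", sep="\t", index=False)
                    report = host_range_report(vcs)
                    report["multi_host_table"].to_csv(
                        outdir / "multi_host_vcs.tsv", sep="\t", index=False)
                    summary["stages"]["cluster"] = _sanitize({
                        k: v for k, v in report.items()
                        if k != "multi_host_table"})
                    summary["_vcs"] = vcs
                elif stage == "aai":
                    with_seq = [r for r in filtered if r.sequence]
                    vcs = summary.pop("_vcs", None)
                    if vcs is None or len(with_seq) < 2:
                        summary["stages"]["aai"] = {"skipped": "needs cluster stage"}
                        continue
                    reps = {vc.representative for vc in vcs}
                    seq_map = {r.prophage_id: r.sequence for r in with_seq
                               if r.prophage_id in reps}
                    lineage_map = {}
                    host_index = {h.genome_id: h for h in hosts}
                    for r in with_seq:
                        if r.prophage_id in reps:
                            lineage_map[r.prophage_id] = \
                                host_index[r.genome_id].lineage
                    orfsets = {pid: find_orfs(seq, config.min_orf_aa,
                                              parent_id=pid)
                               for pid, seq in seq_map.items()}
                    net = build_network(orfsets, lineage_map,
                                        config.aai_threshold)
                    net.edge_table().to_csv(outdir / "aai_edges.tsv",
                                            sep="\t", index=False)
                    stage_out = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
                    if net.n_edges:
                        fr = fraction_by_rank(net)
                        fr.to_csv(outdir / "aai_rank_fractions.tsv",
                                  sep="\t", index=False)
                        stage_out["fraction_different"] = dict(
                            zip(fr["rank"], fr["fraction_different"]))
                    summary["stages"]["aai"] = _sanitize(stage_out)
                elif stage == "kmer":
                    with_seq = [r for r in filtered if r.sequence]
                    host_seqs = {h.genome_id: sequences[h.genome_id]
                                 for h in hosts if h.genome_id in sequences}
                    if not with_seq or not host_seqs:
                        summary["stages"]["kmer"] = {
                            "skipped": "needs prophage and host sequences"}
                        continue
                    profiles = {}
                    for sid, seq in {**host_seqs,
                                     **{r.prophage_id: r.sequence
                                        for r in with_seq}}.items():
                        parts = [kmer_bias(seq, k, sequence_id=sid)
                                 for k in config.kmer_ks]
                        profiles[sid] = (parts[0] if len(parts) == 1
                                         else merge_profiles(*parts))
                    profile_matrix(profiles).to_csv(
                        outdir / "kmer_log_bias.tsv", sep="\t")
                    cc = cocluster_profiles(profiles, host_ids=list(host_seqs))
                    summary["stages"]["kmer"] = {
                        "n_profiles": len(profiles),
                        "nearest_host": {p: (hs[0] if hs else None)
                                         for p, hs in cc["nearest_hosts"].items()},
                    }
            except Exception as exc:  # noqa: BLE001 - named stage failure
                (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
                raise StageError(stage, exc) from exc
        summary.pop("_vcs", None)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_sanitize(summary), fh, indent=2, default=str)
        log.info("completed stages: %s", ", ".join(summary["stages"]))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
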