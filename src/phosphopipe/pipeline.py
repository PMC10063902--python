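"""End-to-end orchestration: simulate/load → process → differential per
contrast → enrichment → reversal screen per treatment → PPI subnetworks.

A single :class:`RunConfig` (YAML-loadable) drives the run; outputs are
TSVs plus a machine-readable JSON run report.  Identical config + seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats
from .differential import DifferentialParams, compute_contrast, summarize_contrasts, volcano_table
from .enrichment import fisher_enrichment, foreground_proteins, top_pathways
from .network import filter_edges, induced_subgraph
from .reversal import classify_proteins, find_reversed_sites, restrict_to_pathways
from .site_processing import ProcessingParams, run_processing
from .synthetic import SimulationParams, generate_study
from .tables import ConfigError, GeneSetCollection

log = logging.getLogger("phosphopipe")

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass
class RunConfig:
    outdir: str = "phosphopipe_out"
    seed: int = 0
    #: simulation parameter overrides; used when no input paths are given
    simulate: dict = field(default_factory=dict)
    #: input paths: sites, design, gene_sets (GMT), edges; all-or-none with simulate
    inputs: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    disease_contrast: str | None = None
    treatment_contrasts: list[str] | None = None
    #: which enrichment run feeds the top-20 pathway restriction:
    #: union (default), disease, or treatment
    top20_source: str = "union"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def config_hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        cfg = dataclasses.asdict(self)
        cfg.pop("outdir")
        blob = json.dumps(cfg, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    summary: dict
    contrast_counts: list[dict]
    top_pathways: dict
    reversal_counts: dict
    subnetworks: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_inputs(cfg: RunConfig):
    if cfg.inputs:
        required = {"sites", "design", "gene_sets"}
        missing = required - set(cfg.inputs)
        if missing:
            raise ConfigError(f"inputs missing keys: {sorted(missing)}")
        table = io_formats.read_phosphosite_table(cfg.inputs["sites"])
        design = io_formats.read_design(cfg.inputs["design"])
        gene_sets = io_formats.read_gene_sets(cfg.inputs["gene_sets"], "KEGG")
        edges = io_formats.read_ppi_edges(cfg.inputs["edges"], score_scale="unit") \
            if "edges" in cfg.inputs else None
        return table, design, gene_sets, edges, None
    params = SimulationParams(**{**cfg.simulate, "seed": cfg.seed})
    study = generate_study(params)
    return study.site_table, study.design, study.gene_sets, study.edges, study.truth


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage, writing outputs under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"pipeline": "phosphopipe", "config": cfg.config_hash(), "seed": cfg.seed}

    log.info("loading inputs")
    table, design, gene_sets, edges, _truth = _load_inputs(cfg)
    # validate contrasts before any computation (fail fast)
    contrast_names = {c.name for c in design.contrasts}
    disease_name = cfg.disease_contrast or design.contrasts[0].name
    if disease_name not in contrast_names:
        raise ConfigError(f"unknown disease contrast {disease_name!r}")
    disease_contrast = design.contrast(disease_name)
    if cfg.treatment_contrasts is None:
        treatment_names = [c.name for c in design.contrasts
                           if c.name != disease_name
                           and c.denominator == disease_contrast.numerator]
    else:
        treatment_names = list(cfg.treatment_contrasts)
    for name in treatment_names:
        if name not in contrast_names:
            raise ConfigError(f"unknown treatment contrast {name!r}")

    log.info("processing %d records", len(table))
    proc = run_processing(table, design, ProcessingParams(**cfg.processing))
    io_formats.write_site_table(proc.table, outdir / "processed_sites.tsv", header_meta=meta)
    io_formats.write_table(proc.summary_before.to_frame(), outdir / "summary_before.tsv", meta=meta)
    io_formats.write_table(proc.summary_after.to_frame(), outdir / "summary_after.tsv", meta=meta)

    diff_params = DifferentialParams(**cfg.differential)
    diff_tables = {}
    for c in design.contrasts:
        log.info("differential testing %s", c.name)
        dt = compute_contrast(proc.table, design, c, diff_params)
        diff_tables[c.name] = dt
        safe = c.name.replace("/", "_")
        io_formats.write_table(dt.data, outdir / f"diff_{safe}.tsv", meta=meta)
        io_formats.write_table(volcano_table(dt), outdir / f"volcano_{safe}.tsv", meta=meta)
    counts = summarize_contrasts(list(diff_tables.values()))
    io_formats.write_table(counts, outdir / "contrast_counts.tsv", meta=meta)

    background = set(proc.table.data["gene_name"].str.upper())
    enrich_cfg = dict(cfg.enrichment)
    top_n = int(enrich_cfg.pop("top_n", 20))
    category = enrich_cfg.pop("category", "KEGG")
    enrich_results, top_sets = {}, {}
    for name, dt in diff_tables.items():
        fg = foreground_proteins(dt)
        if not fg:
            log.warning("no significant proteins in %s; skipping enrichment", name)
            continue
        res = fisher_enrichment(fg, background, gene_sets, category=category, **enrich_cfg)
        enrich_results[name] = res
        top_sets[name] = top_pathways(res, n=top_n, category=category)
        safe = name.replace("/", "_")
        io_formats.write_table(res, outdir / f"enrich_{safe}.tsv", meta=meta)

    min_conf = float(cfg.network.get("min_confidence", 0.7))
    kept_edges = filter_edges(edges, min_conf) if edges is not None else None

    reversal_counts, subnet_summaries = {}, {}
    for t_name in treatment_names:
        log.info("reversal screen %s vs %s", disease_name, t_name)
        pairs = find_reversed_sites(diff_tables[disease_name], diff_tables[t_name])
        hits = classify_proteins(pairs)
        source_ids = []
        if cfg.top20_source in ("disease", "union") and disease_name in top_sets:
            source_ids += list(top_sets[disease_name]["set_id"])
        if cfg.top20_source in ("treatment", "union") and t_name in top_sets:
            source_ids += list(top_sets[t_name]["set_id"])
        restricted_coll = GeneSetCollection(
            {sid: gene_sets.sets[sid] for sid in dict.fromkeys(source_ids)
             if sid in gene_sets.sets})
        final = restrict_to_pathways(hits, restricted_coll) if len(restricted_coll) \
            else hits.iloc[0:0].assign(pathways="")
        safe = t_name.replace("/", "_")
        io_formats.write_table(final, outdir / f"reversed_{safe}.tsv", meta=meta)
        reversal_counts[t_name] = {
            "n_candidate_proteins": int(len(hits)),
            "n_hits_in_pathways": int(len(final)),
            "by_class": final["class"].value_counts().to_dict() if len(final) else {},
        }
        if kept_edges is not None and len(final):
            subnet = induced_subgraph(final["gene_name"], kept_edges,
                                      dict(zip(final["gene_name"], final["class"])))
            io_formats.write_table(subnet.edge_table(), outdir / f"subnet_edges_{safe}.tsv", meta=meta)
            io_formats.write_table(subnet.degree_table(), outdir / f"subnet_degrees_{safe}.tsv", meta=meta)
            subnet_summaries[t_name] = subnet.summary()

    report = RunReport(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        summary={
            "n_records_in": proc.summary_before.n_records,
            "n_records_processed": proc.summary_after.n_records,
            "n_proteins_processed": proc.summary_after.n_proteins,
            "residue_fractions": proc.summary_before.residue_fractions,
        },
        contrast_counts=counts.to_dict("records"),
        top_pathways={k: list(v["set_id"]) for k, v in top_sets.items()},
        reversal_counts=reversal_counts,
        subnetworks=subnet_summaries,
    )
    (outdir / "run_report.json").write_text(report.to_json())
    return report
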