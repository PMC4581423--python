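"""End-to-end orchestration: one config, one seed, one output bundle.

Stages run in dependency order — diversity, differential screening of
genes and species, per-group co-abundance networks with permutation
significance, per-group co-expression networks, relation acceptance and
correlation validation with a random-pair baseline, merged typed networks
and their topology reports, and functional enrichment — and every output
file is listed with its checksum in a manifest, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    coexpression,
    community,
    data_io,
    differential,
    diversity,
    enrichment,
    relations,
    topology,
)

logger = logging.getLogger(__name__)

GROUPS = ("BF", "FF")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and counts driving one pipeline run."""

    abundance_path: str
    expression_path: str
    counts_path: str
    group_map: dict[str, str]
    out_dir: str
    gmt_path: str | None = None
    alpha: float = 0.05
    lfc: float = 2.0
    pseudocount: float = 0.01
    corr_cutoff: float = 0.8
    corr_mode: str = "positive"
    filter_k: float = 2.0
    n_permutations: int = 1000
    n_boot: int = 200
    n_random_pairs: int = 1000
    permutation_statistic: str = "clustering"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.corr_cutoff <= 1:
            raise ValueError("corr_cutoff must lie in (0, 1]")
        if self.lfc < 0 or self.filter_k < 0:
            raise ValueError("lfc and filter_k must be nonnegative")
        if min(self.n_permutations, self.n_boot, self.n_random_pairs) < 1:
            raise ValueError("permutation/bootstrap counts must be >=1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        # hash the scientific parameters, not where the outputs land
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _child_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    config: PipelineConfig
    diversity: pd.DataFrame
    de_genes: pd.DataFrame
    da_species: pd.DataFrame
    community_nets: dict
    permutation: dict
    coexpr_nets: dict
    relations: pd.DataFrame
    validation: pd.DataFrame
    baseline: dict
    merged: dict
    topology: dict
    enrichment: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _header(cfg: PipelineConfig) -> str:
    return f"# feednet config={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _write_json(obj, path: Path, cfg: PipelineConfig) -> None:
    payload = {"config": cfg.config_hash(), "seed": cfg.seed, "result": obj}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the output bundle plus manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for p in (config.abundance_path, config.expression_path, config.counts_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    if config.gmt_path and not Path(config.gmt_path).exists():
        raise FileNotFoundError(f"input file not found: {config.gmt_path}")

    stage = "load"
    try:
        abundance = data_io.read_abundance(config.abundance_path, config.group_map)
        expression = data_io.read_expression(config.expression_path, config.group_map)
        counts = data_io.read_cooccurrence_counts(config.counts_path)
        gene_sets = data_io.read_gmt(config.gmt_path) if config.gmt_path else None

        stage = "diversity"
        div = diversity.diversity_report(abundance)
        _write_tsv(div, out / "diversity.tsv", config)
        logger.info("stage=diversity samples=%d", len(div))

        stage = "differential_expression"
        de = differential.differential_expression(
            expression, alpha=config.alpha, fc_min=config.lfc
        )
        _write_tsv(de, out / "de_genes.tsv", config)
        de_set = set(de.loc[de["selected"], "feature"])
        logger.info("stage=differential_expression tested=%d selected=%d", len(de), len(de_set))

        stage = "differential_abundance"
        da = differential.differential_abundance(
            abundance, alpha=config.alpha, fc_min=config.lfc, pseudocount=config.pseudocount
        )
        _write_tsv(da, out / "da_species.tsv", config)
        da_set = set(da.loc[da["selected"], "feature"])
        logger.info("stage=differential_abundance tested=%d selected=%d", len(da), len(da_set))

        stage = "community_network"
        community_nets, perm = {}, {}
        for g in GROUPS:
            net = community.community_network(
                abundance, g, k=config.filter_k, n_boot=config.n_boot,
                seed=_child_seed(config.seed, f"conet:{g}"),
            )
            community_nets[g] = net
            data_io.write_sif(net, out / f"community_{g}.sif", out / f"community_{g}.nodes.tsv")
            perm[g] = community.network_permutation_test(
                net,
                statistic=config.permutation_statistic,
                n_permutations=config.n_permutations,
                seed=_child_seed(config.seed, f"perm:{g}"),
            )
            logger.info("stage=community_network group=%s edges=%d p_emp=%.4g",
                        g, net.number_of_edges(), perm[g].p_empirical)
        _write_json({g: perm[g].to_jsonable() for g in GROUPS},
                    out / "community_permutation.json", config)

        stage = "coexpression_network"
        coexpr_nets = {}
        for g in GROUPS:
            net = coexpression.coexpression_network(
                expression, g, cutoff=config.corr_cutoff, mode=config.corr_mode
            )
            coexpr_nets[g] = net
            data_io.write_sif(net, out / f"coexpr_{g}.sif", out / f"coexpr_{g}.nodes.tsv")
            logger.info("stage=coexpression_network group=%s edges=%d", g, net.number_of_edges())
        dens = {g: coexpression.density(coexpr_nets[g]) for g in GROUPS}
        dens["ratio_BF_over_FF"] = coexpression.density_ratio(coexpr_nets["BF"], coexpr_nets["FF"])
        _write_json(dens, out / "coexpr_density.json", config)

        stage = "relations"
        accepted = relations.accept_relations(counts, alpha=config.alpha, de_genes=de_set)
        _write_tsv(accepted, out / "relations.tsv", config)
        rel_edges = relations.relation_edges(accepted)
        logger.info("stage=relations tested=%d accepted=%d", len(accepted), len(rel_edges))

        stage = "validation"
        frames = []
        for g in GROUPS:
            frames.append(relations.validate_relations(rel_edges, abundance, expression, group=g))
        validation = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        _write_tsv(validation, out / "validation.tsv", config)
        baseline = relations.random_pair_baseline(
            abundance, expression,
            n_pairs=config.n_random_pairs,
            seed=_child_seed(config.seed, "baseline"),
            exclude={(s, g_) for s, g_, _ in rel_edges},
        )
        _write_json(baseline, out / "baseline.json", config)

        stage = "merge_topology"
        merged, topo = {}, {}
        for g in GROUPS:
            merged[g] = topology.merge_layers(coexpr_nets[g], community_nets[g], rel_edges, de_set)
            data_io.write_sif(merged[g], out / f"merged_{g}.sif", out / f"merged_{g}.nodes.tsv")
            topo[g] = topology.topology_report(merged[g])
            hist = pd.DataFrame(
                sorted(topo[g].path_length_histogram.items()), columns=["length", "count"]
            )
            _write_tsv(hist, out / f"path_lengths_{g}.tsv", config)
        _write_json({g: topo[g].to_jsonable() for g in GROUPS}, out / "topology.json", config)

        stage = "enrichment"
        enr = None
        if gene_sets is not None and len(gene_sets) and de_set:
            universe = set(expression.gene_ids)
            enr = enrichment.hypergeom_enrich(de_set & universe, gene_sets, universe)
            _write_tsv(enr, out / "enrichment.tsv", config)

        stage = "manifest"
        manifest = {}
        for f in sorted(out.iterdir()):
            if f.name == "manifest.json" or not f.is_file():
                continue
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"config": config.config_hash(), "seed": config.seed,
                       "files": manifest}, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        diversity=div,
        de_genes=de,
        da_species=da,
        community_nets=community_nets,
        permutation=perm,
        coexpr_nets=coexpr_nets,
        relations=accepted,
        validation=validation,
        baseline=baseline,
        merged=merged,
        topology=topo,
        enrichment=enr,
        manifest=manifest,
    )
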