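"""End-to-end orchestration: simulate -> normalize -> bridge -> diff -> enrich -> network,
with the synergy track run independently on a dose-response grid.

Every stage is a pure function of its declared inputs plus the config, so a
rerun with the same config and seed is byte-identical.  All output TSVs carry a
one-line provenance header recording the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .differential import ContrastSpec, DifferentialResults, run_differential
from .enrichment import run_enrichment
from .network import prioritize
from .normalize import bridge_multiplexes, collapse_replicates, normalize_multiplex
from .simulate import (
    DoseSimConfig,
    NetSimConfig,
    TmtSimConfig,
    simulate_dose_response,
    simulate_network,
    simulate_tmt,
)
from .synergy import evaluate_grid

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one place; defaults mirror the analysed study.

    Cutoffs: phosphosites |log2 ratio| > 1, proteins > 0.585, p < 0.05; Bliss
    class threshold 0.05; STRING edge threshold 0.15 (low confidence).
    """

    outdir: str = "combiphos_out"
    seed: int = 0
    n_features: int = 2000
    normalization_mode: str = "curve"
    contrasts: list[dict] = field(
        default_factory=lambda: [
            {"name": "drugA_vs_vehicle", "numerator": "drugA", "denominator": "DMSO"},
            {"name": "drugB_vs_vehicle", "numerator": "drugB", "denominator": "DMSO"},
            {"name": "combo_vs_vehicle", "numerator": "comboAB", "denominator": "DMSO"},
        ]
    )
    priority_contrast: str = "combo_vs_vehicle"
    min_edge_score: float = 0.15
    bliss_threshold: float = 0.05
    interaction_eps: float = 0.15
    n_gene_sets: int = 20
    gene_set_size: int = 40

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: PipelineConfig, stage: str) -> str:
    return f"combiphos {stage} | config={config.hash()} seed={config.seed}"


def make_gene_sets(
    truth_responsive: pd.Series,
    gene_of: dict[str, str],
    n_sets: int,
    set_size: int,
    seed: int,
    planted_fraction: float = 0.6,
) -> tuple[cio.GeneSetCollection, str]:
    """Gene sets over the quantified universe, one enriched for responsive genes.

    The planted set draws ``planted_fraction`` of its members from responsive
    features and the rest from the background; the remaining sets are uniform
    draws.  Returns the collection and the planted set's name.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([gene_of[f] for f in truth_responsive.index])
    responsive_genes = genes[truth_responsive.to_numpy()]
    null_genes = genes[~truth_responsive.to_numpy()]
    sets: dict[str, list[str]] = {}
    n_resp = min(int(round(planted_fraction * set_size)), responsive_genes.size)
    planted = list(rng.choice(responsive_genes, size=n_resp, replace=False)) + list(
        rng.choice(null_genes, size=set_size - n_resp, replace=False)
    )
    planted_name = "PLANTED_RESPONSIVE"
    sets[planted_name] = planted
    for i in range(n_sets - 1):
        sets[f"RANDOM_SET_{i:03d}"] = list(
            rng.choice(genes, size=set_size, replace=False)
        )
    return cio.GeneSetCollection(sets=sets), planted_name


@dataclass
class PipelineReport:
    """Everything run_all computed, for inspection and truth-recovery checks."""

    differential: dict[str, DifferentialResults]
    truth: object
    design: object
    annotations: list
    bliss: object
    dose_truth: object
    priority: object
    net_truth: object
    enrichment: object
    planted_set: str
    outputs: dict[str, str]


def run_all(config: PipelineConfig, outdir: Optional[str] = None) -> PipelineReport:
    """Run the full pipeline on synthetic inputs and write all artifacts."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame, stage: str, index: bool = False) -> None:
        path = out / name
        cio.write_table(path, df, _provenance(config, stage), index=index)
        outputs[stage if stage not in outputs else name] = str(path)

    contrasts = [ContrastSpec(**c) for c in config.contrasts]

    # --- phosphosite track: 2 injection runs ---
    psty_cfg = TmtSimConfig(
        n_features=config.n_features, n_injection_runs=2, kind="phosphosite",
        run_prefix="psty_run", seed=config.seed,
    )
    matrices, design, annotations, truth = simulate_tmt(psty_cfg)
    cio.write_reporter_table(
        out / "psty_reporter.tsv", {m.run_id: m for m in matrices}, annotations,
        provenance=_provenance(config, "simulate"),
    )
    cio.write_design(out / "design.tsv", design, provenance=_provenance(config, "simulate"))
    outputs["simulate"] = str(out / "psty_reporter.tsv")

    normalized = [normalize_multiplex(m, mode=config.normalization_mode) for m in matrices]
    for nm in normalized:
        logger.info("run %s normalized against reference channel %s", nm.run_id, nm.reference_channel)
    bridged = bridge_multiplexes(normalized, mode=config.normalization_mode)
    abundance = collapse_replicates(bridged, design)
    save("psty_abundance.tsv", abundance.log2_abundance, "bridge", index=True)

    diff_psty = run_differential(abundance, design, contrasts, dataset_kind="phosphosite")
    save("psty_differential.tsv", diff_psty.table, "diff")

    # --- protein-expression track: 1 injection run, same latent truth structure ---
    expr_cfg = TmtSimConfig(
        n_features=max(200, config.n_features // 3), n_injection_runs=1, kind="protein",
        run_prefix="total_run", seed=config.seed + 1,
    )
    e_matrices, e_design, e_annotations, e_truth = simulate_tmt(expr_cfg)
    e_norm = [normalize_multiplex(m, mode=config.normalization_mode) for m in e_matrices]
    e_bridged = bridge_multiplexes(e_norm, mode=config.normalization_mode)
    e_abund = collapse_replicates(e_bridged, e_design)
    diff_expr = run_differential(e_abund, e_design, contrasts, dataset_kind="protein")
    save("expression_differential.tsv", diff_expr.table, "diff_expression")

    # --- enrichment on the phosphosite selection ---
    gene_of = {a.feature_id: a.gene_symbol for a in annotations}
    sets, planted_name = make_gene_sets(
        truth.responsive, gene_of, config.n_gene_sets, config.gene_set_size,
        seed=config.seed + 2,
    )
    cio.write_gmt(out / "gene_sets.gmt", sets)
    selected = {
        gene_of[f] for f in diff_psty.passing(config.priority_contrast)["feature_id"]
    }
    background = set(gene_of.values())
    enr = run_enrichment(selected, background, sets)
    save("enrichment.tsv", enr.table, "enrich")

    # --- network prioritization over significant genes ---
    sig_genes = sorted(selected)
    net_cfg = NetSimConfig(
        n_nodes=max(10, len(sig_genes)), seed=config.seed + 3,
    )
    edges, net_truth = simulate_network(net_cfg)
    # relabel simulated nodes onto the significant genes so the graph is an
    # induced subgraph over real selection symbols
    mapping = {f"GENE{i:04d}": g for i, g in enumerate(sig_genes)}
    relabeled = edges.table.copy()
    relabeled["node_a"] = relabeled["node_a"].map(lambda x: mapping.get(x, x))
    relabeled["node_b"] = relabeled["node_b"].map(lambda x: mapping.get(x, x))
    edges = cio.EdgeList(relabeled)
    net_truth.hub = mapping.get(net_truth.hub, net_truth.hub)
    net_truth.modules = {mapping.get(k, k): v for k, v in net_truth.modules.items()}
    cio.write_edges(out / "edges.tsv", edges, provenance=_provenance(config, "simulate_network"))
    priority = prioritize(
        edges,
        {"phosphosite": diff_psty.table, "protein": diff_expr.table},
        annotations + e_annotations,
        config.priority_contrast,
        min_score=config.min_edge_score,
        nodes_of_interest=sig_genes if sig_genes else None,
    )
    save("priority.tsv", priority.table, "network")

    # --- independent synergy track ---
    dose_cfg = DoseSimConfig(interaction_eps=config.interaction_eps, seed=config.seed + 4)
    grid, dose_truth = simulate_dose_response(dose_cfg)
    cio.write_table(out / "dose_grid.tsv", grid, _provenance(config, "simulate_dose"))
    bliss = evaluate_grid(grid, threshold=config.bliss_threshold)
    save("bliss.tsv", bliss.grid, "synergy")

    return PipelineReport(
        differential={"phosphosite": diff_psty, "protein": diff_expr},
        truth=truth,
        design=design,
        annotations=annotations,
        bliss=bliss,
        dose_truth=dose_truth,
        priority=priority,
        net_truth=net_truth,
        enrichment=enr,
        planted_set=planted_name,
        outputs=outputs,
    )
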