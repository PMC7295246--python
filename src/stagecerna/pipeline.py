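"""End-to-end orchestration: DE -> matching -> correlation filtering ->
per-stage networks -> CCEN/UCEN partition -> enrichment -> survival screen.

Every intermediate table is written to the output directory in the
documented plain-text formats, together with a ``manifest.json`` recording
the configuration, package versions, seed and per-step counts, so a run is
fully reproducible and auditable from its output bundle alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from . import io as scio
from .constants import STAGES
from .diffexpr import DEConfig, differential_genes_all_classes
from .enrichment import compare_efficiency, enrich
from .network import NetworkConfig, build_stage_network, match_targets, validate_doubly_bipartite
from .partition import PartitionResult, mirna_linked_mrnas, partition_networks
from .survival import survival_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and output settings for one pipeline run."""

    expression_paths: dict[str, str]  # rna class -> TSV path
    sample_path: str
    interaction_path: str
    annotation_path: str
    out_dir: str
    de: DEConfig = field(default_factory=DEConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    eta_norm: str = "query_size"
    ccen_mode: str = "union_edges"
    survival_alpha: float = 0.05
    survival_split: str = "median"
    stages: Sequence[str] = STAGES
    seed: int = 0
    write_graphml: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["de"] = DEConfig(**raw.get("de", {}))
        raw["network"] = NetworkConfig(**raw.get("network", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_json(self) -> dict:
        obj = dataclasses.asdict(self)
        obj["stages"] = list(self.stages)
        return obj


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    de_tables: dict[str, pd.DataFrame]
    networks: dict[str, nx.Graph]
    partition: PartitionResult
    enrichment_tables: dict[str, pd.DataFrame]
    efficiency: pd.DataFrame
    mean_eta: pd.Series
    screen: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full stage-resolved ceRNA workflow and write the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expression = scio.read_expression_set(
        {cls: Path(p) for cls, p in config.expression_paths.items()}
    )
    samples = scio.read_samples(Path(config.sample_path))
    interactions = scio.read_interactions(Path(config.interaction_path))
    annotation = scio.read_gmt(Path(config.annotation_path))

    config_echo = config.to_json()
    config_echo.pop("out_dir")  # the bundle's own location; keeps bundles comparable
    manifest: dict = {
        "package": "stagecerna",
        "version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "counts": {},
    }

    # ---- DE + matching + networks per stage -------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    networks: dict[str, nx.Graph] = {}
    for stage in config.stages:
        de = differential_genes_all_classes(expression, samples, stage, config.de)
        de_tables[stage] = de
        scio.write_tsv(de, out / f"de_{stage}.tsv")
        n_de_mirnas = int(((de["rna_class"] == "miRNA") & de["is_de"]).sum())
        if n_de_mirnas == 0:
            logger.warning("stage %s: no DE miRNAs; downstream outputs will be empty", stage)
        candidates = match_targets(de, interactions)
        G = build_stage_network(
            candidates, expression, samples, stage, config.network,
            pseudocount=config.de.pseudocount,
        )
        report = validate_doubly_bipartite(G)
        if not report.passed:
            raise AssertionError(f"stage {stage}: constructed network failed validation")
        networks[stage] = G
        scio.write_network(G, out / f"network_{stage}.tsv")
        if config.write_graphml:
            scio.write_graphml(G, out / f"network_{stage}.graphml")
        manifest["counts"][f"stage_{stage}"] = {
            "de_genes": {
                cls: int(((de["rna_class"] == cls) & de["is_de"]).sum())
                for cls in expression
            },
            "candidate_pairs": int(len(candidates)),
            "edges": G.number_of_edges(),
            "nodes": G.number_of_nodes(),
        }

    # ---- partition --------------------------------------------------------
    part = partition_networks(networks, ccen_mode=config.ccen_mode, stages=config.stages)
    scio.write_network(part.ccen, out / "ccen.tsv")
    for s, g in part.ucen.items():
        scio.write_network(g, out / f"ucen_{s}.tsv")
    scio.write_tsv(part.membership, out / "membership.tsv")
    manifest["counts"]["partition"] = part.counts()

    # ---- enrichment -------------------------------------------------------
    def mrnas(g: nx.Graph) -> set[str]:
        return {n for n, d in g.nodes(data=True) if d.get("rna_class") == "mRNA"}

    background = {g for term in annotation for g in term.genes}
    ucen_union = set().union(*(mrnas(g) for g in part.ucen.values())) if part.ucen else set()
    all_net = set().union(*(mrnas(g) for g in networks.values())) if networks else set()
    ucen_linked = (
        set().union(*(mirna_linked_mrnas(g) for g in part.ucen.values()))
        if part.ucen
        else set()
    )
    gene_lists = {
        "ccen_mrnas": mrnas(part.ccen),
        "ucen_mrnas": ucen_union,
        "cerna_mrnas": all_net,
        "ucen_mirna_linked_mrnas": ucen_linked,
    }
    manifest["counts"]["gene_lists"] = {k: len(v) for k, v in gene_lists.items()}

    enrichment_tables: dict[str, pd.DataFrame] = {}
    for name, genes in gene_lists.items():
        if genes & background:
            tab = enrich(genes, annotation, background, eta_norm=config.eta_norm)
        else:
            tab = enrich(background, annotation, background).iloc[0:0]
        enrichment_tables[name] = tab
        scio.write_tsv(tab, out / f"enrichment_{name}.tsv")

    comparable = {k: v for k, v in gene_lists.items() if v & background}
    if len(comparable) >= 2:
        efficiency, mean_eta = compare_efficiency(
            comparable, annotation, background, eta_norm=config.eta_norm
        )
    else:
        logger.warning("fewer than two gene lists overlap the annotation background")
        efficiency = pd.DataFrame()
        mean_eta = pd.Series(dtype=float, name="mean_eta")
    scio.write_tsv(efficiency, out / "enrichment_efficiency.tsv")
    scio.write_tsv(mean_eta.rename_axis("list_name").reset_index(), out / "mean_eta.tsv")
    manifest["counts"]["mean_eta"] = {k: float(v) for k, v in mean_eta.items()}

    # ---- survival screen on CCEN miRNAs -----------------------------------
    mirna_expr = expression.get("miRNA")
    screen_ids = sorted(m for m in part.common if mirna_expr is not None and m in mirna_expr.index)
    if screen_ids:
        screen = survival_screen(
            screen_ids,
            mirna_expr,
            samples,
            alpha=config.survival_alpha,
            split_rule=config.survival_split,
        )
    else:
        screen = pd.DataFrame(columns=["mirna_id", "stage", "n_low", "n_high",
                                       "chi_square", "p", "evaluable", "classification"])
    scio.write_tsv(screen, out / "survival_screen.tsv")
    manifest["counts"]["screened_mirnas"] = len(screen_ids)

    scio.write_json(manifest, out / "manifest.json")
    return PipelineResult(
        de_tables=de_tables,
        networks=networks,
        partition=part,
        enrichment_tables=enrichment_tables,
        efficiency=efficiency,
        mean_eta=mean_eta,
        screen=screen,
        manifest=manifest,
    )
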