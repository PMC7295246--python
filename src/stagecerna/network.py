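"""Per-stage ceRNA network construction.

A stage network is built in three steps that mirror the ceRNA hypothesis:

1. *match*: keep the curated miRNA-target interactions whose miRNA and
   target are both differentially expressed in that stage;
2. *correlate*: compute the Pearson correlation of the two genes' log2
   expression over the stage's tumor samples (optionally tumor + normal);
3. *filter*: retain only pairs with correlation strictly below a negative
   threshold (default -0.1) — a miRNA sponging its target should move
   opposite to it.

The result is doubly bipartite: edges exist only between miRNAs and
lncRNAs or miRNAs and mRNAs, so any lncRNA-mRNA relation is mediated by a
shared miRNA, and within each half the miRNAs and their targets again form
a bipartite graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .constants import NORMAL, TARGET_CLASSES
from .diffexpr import log_transform

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "mirna_id",
    "target_id",
    "target_class",
    "source",
    "mirna_direction",
    "target_direction",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Correlation-filter settings for network construction."""

    correlation_threshold: float = -0.1
    correlation_sample_scope: str = "stage_tumor"  # or "tumor_plus_normal"
    min_samples: int = 3

    def __post_init__(self) -> None:
        if self.correlation_threshold >= 0:
            raise ValueError("correlation_threshold must be negative")
        if self.correlation_sample_scope not in ("stage_tumor", "tumor_plus_normal"):
            raise ValueError(f"unknown sample scope {self.correlation_sample_scope!r}")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


def match_targets(de_table: pd.DataFrame, interactions: pd.DataFrame) -> pd.DataFrame:
    """Interaction rows whose miRNA and target are both DE.

    ``de_table`` is a combined per-stage DE table covering all three RNA
    classes (columns gene_id, rna_class, direction, is_de).  Interaction
    rows whose target's annotated class disagrees with the expression
    data's class are skipped with a warning.

    Returns the candidate pair table annotated with both genes' DE
    directions.
    """
    required = {"gene_id", "rna_class", "direction", "is_de"}
    if not required <= set(de_table.columns):
        raise ValueError(f"de_table missing columns {sorted(required - set(de_table.columns))}")
    de = de_table.set_index("gene_id")
    de_mirnas = de[(de["rna_class"] == "miRNA") & de["is_de"]]
    known_class = de["rna_class"].to_dict()

    mismatched = 0
    rows = []
    for row in interactions.itertuples(index=False):
        if row.target_id in known_class and known_class[row.target_id] != row.target_class:
            mismatched += 1
            continue
        if row.mirna_id not in de_mirnas.index:
            continue
        target = de.index.get_indexer([row.target_id])
        if target[0] < 0 or not bool(de["is_de"].iloc[target[0]]):
            continue
        rows.append(
            {
                "mirna_id": row.mirna_id,
                "target_id": row.target_id,
                "target_class": row.target_class,
                "source": row.source,
                "mirna_direction": de_mirnas.loc[row.mirna_id, "direction"],
                "target_direction": de["direction"].iloc[target[0]],
            }
        )
    if mismatched:
        logger.warning("%d interaction rows with inconsistent target class skipped", mismatched)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def pairwise_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between paired rows of two matrices; NaN where undefined."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r


def build_stage_network(
    candidates: pd.DataFrame,
    expression: Mapping[str, pd.DataFrame],
    sample_table: pd.DataFrame,
    stage: str,
    config: NetworkConfig = NetworkConfig(),
    pseudocount: float = 1.0,
) -> nx.Graph:
    """Filter candidate pairs by negative correlation into a stage network.

    Correlations are computed on log2(value + pseudocount) over the
    configured sample scope, with per-pair intersection of the sample
    columns shared by the miRNA and target matrices.  Pairs with a
    missing gene, too few shared samples, or a constant expression vector
    are excluded (counted in the graph's ``skipped`` attribute).

    Returns a :class:`networkx.Graph` whose nodes carry ``rna_class`` and
    whose edges carry ``pearson_r``; only edge endpoints become nodes.
    """
    groups = sample_table.set_index("sample_id")["group"]
    scope_groups = {stage} if config.correlation_sample_scope == "stage_tumor" else {stage, NORMAL}
    scope_ids = [s for s in groups.index if groups[s] in scope_groups]

    G = nx.Graph(stage=stage, config=repr(config))
    skipped = {"missing_gene": 0, "too_few_samples": 0, "constant_vector": 0}

    logm = {cls: log_transform(m, pseudocount) for cls, m in expression.items()}
    if "miRNA" not in logm:
        raise ValueError("expression matrices must include the miRNA class")

    for cls in TARGET_CLASSES:
        sub = candidates[candidates["target_class"] == cls]
        if sub.empty or cls not in logm:
            skipped["missing_gene"] += int(len(sub)) if cls not in logm else 0
            continue
        mi_m, tg_m = logm["miRNA"], logm[cls]
        shared = [s for s in scope_ids if s in mi_m.columns and s in tg_m.columns]
        if len(shared) < config.min_samples:
            if len(sub):
                raise ValueError(
                    f"only {len(shared)} samples in scope for stage {stage!r}; "
                    f"need >= {config.min_samples}"
                )
            continue
        present = sub["mirna_id"].isin(mi_m.index) & sub["target_id"].isin(tg_m.index)
        skipped["missing_gene"] += int((~present).sum())
        sub = sub[present]
        if sub.empty:
            continue
        a = mi_m.loc[sub["mirna_id"], shared].to_numpy()
        b = tg_m.loc[sub["target_id"], shared].to_numpy()
        r = _row_correlations(a, b)
        skipped["constant_vector"] += int(np.isnan(r).sum())
        keep = ~np.isnan(r) & (r < config.correlation_threshold)
        for (row, r_val) in zip(sub[keep].itertuples(index=False), r[keep]):
            G.add_node(row.mirna_id, rna_class="miRNA")
            G.add_node(row.target_id, rna_class=cls)
            G.add_edge(row.mirna_id, row.target_id, pearson_r=float(r_val))
    if any(skipped.values()):
        logger.warning("stage %s: pairs skipped: %s", stage, skipped)
    G.graph["skipped"] = skipped
    return G


@dataclass
class ValidationReport:
    """Outcome of the doubly-bipartite structure check."""

    passed: bool
    forbidden_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    isolated_nodes: list[str] = field(default_factory=list)
    untyped_nodes: list[str] = field(default_factory=list)


def validate_doubly_bipartite(network: nx.Graph) -> ValidationReport:
    """Check that a network has the doubly bipartite ceRNA structure.

    Fails if any edge joins two nodes of the same class or a lncRNA to an
    mRNA, if any node lacks an RNA class, or if any node is isolated
    (nodes exist only as edge endpoints).
    """
    forbidden: dict[str, list[tuple[str, str]]] = {}
    untyped = [n for n, d in network.nodes(data=True) if d.get("rna_class") is None]
    for u, v in network.edges():
        cu = network.nodes[u].get("rna_class")
        cv = network.nodes[v].get("rna_class")
        classes = {cu, cv}
        if "miRNA" in classes and len(classes) == 2:
            continue
        key = "-".join(sorted(str(c) for c in (cu, cv)))
        forbidden.setdefault(key, []).append((u, v))
    isolated = [n for n in network.nodes() if network.degree(n) == 0]
    return ValidationReport(
        passed=not forbidden and not isolated and not untyped,
        forbidden_edges=forbidden,
        isolated_nodes=isolated,
        untyped_nodes=untyped,
    )
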