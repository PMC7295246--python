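"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
expression TSV   first column ``gene_id``, remaining columns one per sample.
sample TSV       columns sample_id, group, time, event.
interaction TSV  columns mirna_id, target_id, target_class, source; duplicate
                 (mirna_id, target_id) rows are collapsed with sources merged.
GMT              one annotation term per line: id, description, member genes,
                 tab-separated.
edge-list TSV    columns stage, mirna_id, target_id, target_class, pearson_r.

All writes are atomic (temp file + rename) so a crashed run never leaves a
half-written table behind.  Schema violations raise :class:`SchemaError`
naming the file and, where possible, the line.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .constants import NORMAL, RNA_CLASSES, STAGES, TARGET_CLASSES
from .enrichment import AnnotationTable, GeneSet

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "group", "time", "event"]
INTERACTION_COLUMNS = ["mirna_id", "target_id", "target_class", "source"]
EDGE_COLUMNS = ["stage", "mirna_id", "target_id", "target_class", "pearson_r"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: Path, *, index: bool = False) -> None:
    """Atomically write a DataFrame as TSV (full float precision)."""
    _atomic_write_text(Path(path), df.to_csv(sep="\t", index=index))


# ---------------------------------------------------------------- expression


def read_expression(path: Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix; index is gene_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: no data rows")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no sample columns")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric sample columns {non_numeric[:5]}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene id {dup!r}")
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene_id"
    return df


def write_expression(matrix: pd.DataFrame, path: Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    write_tsv(out, path, index=True)


# ------------------------------------------------------------------- samples


def read_samples(path: Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, group, time, event)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: no data rows")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample id {dup!r}")
    valid_groups = set(STAGES) | {NORMAL}
    bad = ~df["group"].isin(valid_groups)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise SchemaError(
            f"{path}: line {line}: group {df.loc[bad, 'group'].iloc[0]!r} "
            f"not in {sorted(valid_groups)}"
        )
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    if (df["time"].dropna() < 0).any():
        raise SchemaError(f"{path}: negative survival time")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise SchemaError(f"{path}: event flag must be 0/1")
    return df[SAMPLE_COLUMNS]


def write_samples(samples: pd.DataFrame, path: Path) -> None:
    write_tsv(samples[SAMPLE_COLUMNS], path)


# -------------------------------------------------------------- interactions


def read_interactions(path: Path) -> pd.DataFrame:
    """Read a miRNA-target edge list, collapsing duplicate pairs.

    Duplicate (mirna_id, target_id) rows — e.g. the same interaction
    curated by several databases — are merged into one row whose source
    field concatenates the distinct sources with ';'.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: no data rows")
    bad = ~df["target_class"].isin(TARGET_CLASSES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(
            f"{path}: line {line}: target_class "
            f"{df.loc[bad, 'target_class'].iloc[0]!r} not in {TARGET_CLASSES}"
        )
    for col in ("mirna_id", "target_id"):
        df[col] = df[col].astype(str).str.strip()
    n_dup = int(df.duplicated(subset=["mirna_id", "target_id"]).sum())
    if n_dup:
        logger.warning("%s: %d duplicate interaction rows collapsed", path, n_dup)
    merged = (
        df.groupby(["mirna_id", "target_id"], sort=True)
        .agg(
            target_class=("target_class", "first"),
            source=("source", lambda s: ";".join(sorted(set(map(str, s))))),
        )
        .reset_index()
    )
    return merged[INTERACTION_COLUMNS]


def write_interactions(interactions: pd.DataFrame, path: Path) -> None:
    write_tsv(interactions[INTERACTION_COLUMNS], path)


# ----------------------------------------------------------------------- GMT


def read_gmt(path: Path) -> list[GeneSet]:
    """Read annotation gene sets from a GMT file.

    Each line: term id TAB description TAB gene TAB gene ...  Terms with
    no member genes are skipped with a warning.
    """
    path = Path(path)
    terms: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(f"{path}: line {lineno}: expected >= 2 tab-separated fields")
            term_id, name, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if term_id in seen:
                raise SchemaError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            if not genes:
                logger.warning("%s: line %d: term %r has no genes, skipped", path, lineno, term_id)
                continue
            terms.append(GeneSet(term_id, name, frozenset(genes)))
    return terms


def write_gmt(annotation: AnnotationTable, path: Path) -> None:
    lines = [
        "\t".join([t.term_id, t.name, *sorted(t.genes)]) for t in annotation
    ]
    _atomic_write_text(Path(path), "".join(line + "\n" for line in lines))


# ----------------------------------------------------------------- networks


def network_to_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Flatten a ceRNA network into the edge-list TSV schema."""
    stage = network.graph.get("stage", "")
    rows = []
    for u, v, data in network.edges(data=True):
        if network.nodes[u].get("rna_class") == "miRNA":
            mirna, target = u, v
        else:
            mirna, target = v, u
        rows.append(
            {
                "stage": stage,
                "mirna_id": mirna,
                "target_id": target,
                "target_class": network.nodes[target].get("rna_class"),
                "pearson_r": data["pearson_r"],
            }
        )
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values(["mirna_id", "target_id"], kind="mergesort").reset_index(drop=True)


def write_network(network: nx.Graph, path: Path) -> None:
    write_tsv(network_to_edge_table(network), path)


def read_network(path: Path) -> nx.Graph:
    """Rebuild a ceRNA network from an edge-list TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    G = nx.Graph()
    stages = df["stage"].unique()
    if len(stages) == 1:
        G.graph["stage"] = str(stages[0])
    for row in df.itertuples(index=False):
        if row.target_class not in TARGET_CLASSES:
            raise SchemaError(f"{path}: bad target_class {row.target_class!r}")
        G.add_node(row.mirna_id, rna_class="miRNA")
        G.add_node(row.target_id, rna_class=row.target_class)
        G.add_edge(row.mirna_id, row.target_id, pearson_r=float(row.pearson_r))
    return G


def write_graphml(network: nx.Graph, path: Path) -> None:
    """GraphML export for external viewers (e.g. Cytoscape)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(network, path)


# ---------------------------------------------------------------------- JSON


def write_json(obj, path: Path) -> None:
    _atomic_write_text(Path(path), json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def read_expression_set(paths: Mapping[str, Path]) -> dict[str, pd.DataFrame]:
    """Read one expression matrix per RNA class given a class -> path map."""
    out = {}
    for cls, p in paths.items():
        if cls not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {cls!r}")
        out[cls] = read_expression(p)
    return out
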