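"""Partition of stage networks into common (CCEN) and unique (UCEN) parts.

Across the four per-stage ceRNA networks, miRNAs fall into three classes:

* **common** — present in every stage network; these miRNAs, with the
  lncRNAs and mRNAs they connect, form the common competing endogenous
  network (CCEN);
* **unique** — present in exactly one stage network; per stage they induce
  that stage's unique competing endogenous network (UCEN);
* **shared** — present in some but not all stages; they belong to neither
  compartment and are reported as such in the membership table.

CCEN edges default to the union over stages of edges incident to common
miRNAs (the CCEN is stage-agnostic); an intersection mode keeps only edges
present in every stage network.  UCEN edges come from their one stage only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .constants import STAGES


def _mirna_set(network: nx.Graph) -> set[str]:
    return {n for n, d in network.nodes(data=True) if d.get("rna_class") == "miRNA"}


def common_mirnas(networks: Sequence[nx.Graph]) -> set[str]:
    """miRNAs present in every one of the given networks."""
    if not networks:
        raise ValueError("empty network list")
    return reduce(set.__and__, (_mirna_set(g) for g in networks))


def unique_mirnas(networks: Mapping[str, nx.Graph], stage: str) -> set[str]:
    """miRNAs present in the given stage's network and in no other."""
    if stage not in networks:
        raise ValueError(f"unknown stage {stage!r}; have {sorted(networks)}")
    others: set[str] = set()
    for s, g in networks.items():
        if s != stage:
            others |= _mirna_set(g)
    return _mirna_set(networks[stage]) - others


def extract_subnetwork(
    networks: Mapping[str, nx.Graph],
    mirna_set: Iterable[str],
    mode: str = "union_edges",
) -> nx.Graph:
    """Subnetwork induced by a miRNA set's incident edges.

    ``mode="union_edges"`` takes edges from every stage network (CCEN
    extraction; an edge appearing in several stages keeps the correlation
    from the earliest stage).  ``mode="single_stage:<stage>"`` restricts
    to the named stage's network (UCEN extraction).
    ``mode="intersection_edges"`` keeps only edges present in every
    stage network.
    """
    mirna_set = set(mirna_set)
    if mode == "union_edges" or mode == "intersection_edges":
        sources = [networks[s] for s in networks]
    elif mode.startswith("single_stage:"):
        stage = mode.split(":", 1)[1]
        if stage not in networks:
            raise ValueError(f"unknown stage {stage!r}")
        sources = [networks[stage]]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = nx.Graph()
    for g in sources:
        for u, v, data in g.edges(data=True):
            mirna = u if g.nodes[u].get("rna_class") == "miRNA" else v
            target = v if mirna == u else u
            if mirna not in mirna_set:
                continue
            if mode == "intersection_edges" and not all(
                h.has_edge(u, v) for h in sources
            ):
                continue
            if not out.has_edge(mirna, target):
                out.add_node(mirna, rna_class="miRNA")
                out.add_node(target, rna_class=g.nodes[target].get("rna_class"))
                out.add_edge(mirna, target, pearson_r=data.get("pearson_r"))
    return out


def mirna_linked_mrnas(network: nx.Graph) -> set[str]:
    """mRNA nodes adjacent to at least one miRNA node."""
    out = set()
    for n, d in network.nodes(data=True):
        if d.get("rna_class") != "mRNA":
            continue
        if any(network.nodes[m].get("rna_class") == "miRNA" for m in network.neighbors(n)):
            out.add(n)
    return out


@dataclass
class PartitionResult:
    """CCEN, per-stage UCENs, and the miRNA membership classification."""

    ccen: nx.Graph
    ucen: dict[str, nx.Graph]
    common: set[str]
    unique: dict[str, set[str]]
    shared: set[str]
    membership: pd.DataFrame  # gene_id, rna_class, compartments

    def counts(self) -> dict:
        """Per-compartment node counts by RNA class (summary-JSON payload)."""

        def by_class(g: nx.Graph) -> dict[str, int]:
            out = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
            for _, d in g.nodes(data=True):
                cls = d.get("rna_class")
                if cls in out:
                    out[cls] += 1
            return out

        return {
            "CCEN": by_class(self.ccen),
            **{f"UCEN-{s}": by_class(g) for s, g in self.ucen.items()},
            "shared_mirnas": len(self.shared),
        }


def partition_networks(
    networks: Mapping[str, nx.Graph],
    ccen_mode: str = "union_edges",
    stages: Sequence[str] = STAGES,
) -> PartitionResult:
    """Decompose stage networks into the CCEN and one UCEN per stage."""
    nets = {s: networks[s] for s in stages if s in networks}
    if len(nets) < 2:
        raise ValueError("need at least two stage networks to partition")

    common = common_mirnas(list(nets.values()))
    unique = {s: unique_mirnas(nets, s) for s in nets}
    all_mirnas = set().union(*(_mirna_set(g) for g in nets.values()))
    shared = all_mirnas - common - set().union(*unique.values())

    ccen = extract_subnetwork(nets, common, mode=ccen_mode)
    ccen.graph["stage"] = "common"
    ucen = {}
    for s in nets:
        g = extract_subnetwork(nets, unique[s], mode=f"single_stage:{s}")
        g.graph["stage"] = s
        ucen[s] = g

    rows = []
    gene_class: dict[str, str] = {}
    gene_compartments: dict[str, list[str]] = {}
    for s, g in [("CCEN", ccen)] + [(f"UCEN-{s}", u) for s, u in ucen.items()]:
        for n, d in g.nodes(data=True):
            gene_class[n] = d.get("rna_class")
            gene_compartments.setdefault(n, []).append(s)
    for g in nets.values():
        for n, d in g.nodes(data=True):
            gene_class.setdefault(n, d.get("rna_class"))
            gene_compartments.setdefault(n, [])
    for gene in sorted(gene_class):
        comps = gene_compartments[gene]
        if gene_class[gene] == "miRNA" and gene in shared:
            label = "shared"
        elif comps:
            label = ";".join(comps)
        else:
            label = "neither"
        rows.append({"gene_id": gene, "rna_class": gene_class[gene], "compartments": label})
    membership = pd.DataFrame(rows, columns=["gene_id", "rna_class", "compartments"])

    return PartitionResult(ccen, ucen, common, unique, shared, membership)
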