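"""Hypergeometric over-representation analysis and enrichment efficiency.

For a query gene list of size ``n`` drawn from a background of ``N``
annotated genes, a term annotating ``M`` background genes and ``k`` query
genes is scored with the upper-tail hypergeometric probability

    p = P(X >= k) = 1 - sum_{i=0}^{k-1} C(M, i) C(N-M, n-i) / C(N, n),

i.e. the chance of seeing at least ``k`` annotated genes in the query by
chance alone.  The enrichment efficiency normalises the evidence by the
size of the gene list being tested,

    eta = -log10(p) / list_size,

so that lists of very different sizes can be compared on evidence *per
gene*.  By default the normalising list size is the query size; a mode is
provided to normalise by the background size instead.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_TINY = 5e-324  # smallest positive subnormal float; keeps p in (0, 1]


class GeneSet(NamedTuple):
    """A named annotation term with its member genes."""

    term_id: str
    name: str
    genes: frozenset[str]


#: An annotation collection is an ordered sequence of unique GeneSets.
AnnotationTable = Sequence[GeneSet]


def hypergeom_p(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Parameters
    ----------
    N : background size.
    M : annotated genes in the background.
    n : query-list size.
    k : annotated genes in the query list.

    Returns
    -------
    float in (0, 1]; the survival function is evaluated in a numerically
    stable way and clamped away from exact 0.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N; got N={N}, M={M}, n={n}")
    if not (0 <= k <= min(M, n)):
        raise ValueError(f"require 0 <= k <= min(M, n); got k={k}, M={M}, n={n}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, M, n))
    return min(max(p, _TINY), 1.0)


def enrichment_efficiency(p: float, list_size: int) -> float:
    """Evidence per gene: eta = -log10(p) / list_size."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if list_size < 1:
        raise ValueError(f"list_size must be >= 1, got {list_size}")
    return -math.log10(p) / list_size


def enrich(
    query_genes: Iterable[str],
    annotation: AnnotationTable,
    background: Iterable[str],
    *,
    eta_norm: str = "query_size",
) -> pd.DataFrame:
    """Score every annotation term against a query gene list.

    Genes outside the background are dropped (with a warning).  Terms with
    no overlap (k = 0) are omitted: their upper-tail p is identically 1.
    Rows are sorted by p ascending, ties broken by term id for
    deterministic output.

    Parameters
    ----------
    eta_norm : ``"query_size"`` (default) divides -log10 p by the query
        list size; ``"background_size"`` divides by the background size.

    Returns
    -------
    DataFrame with columns term_id, term_name, N, M, n, k, p,
    neg_log10_p, eta, p_bh (Benjamini-Hochberg adjusted p, reported for
    convenience and never used in the scoring itself).
    """
    if eta_norm not in ("query_size", "background_size"):
        raise ValueError(f"unknown eta_norm {eta_norm!r}")
    bg = set(background)
    if not bg:
        raise ValueError("background gene set is empty")
    query = set(query_genes)
    outside = query - bg
    if outside:
        logger.warning("%d query genes outside the background were dropped", len(outside))
        query &= bg

    N = len(bg)
    n = len(query)
    rows = []
    for term in annotation:
        members = term.genes & bg
        M = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = hypergeom_p(N, M, n, k)
        denom = n if eta_norm == "query_size" else N
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.name,
                "N": N,
                "M": M,
                "n": n,
                "k": k,
                "p": p,
                "neg_log10_p": -math.log10(p),
                "eta": enrichment_efficiency(p, denom),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "N", "M", "n", "k", "p", "neg_log10_p", "eta"],
    )
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out


def compare_efficiency(
    gene_lists: Mapping[str, Iterable[str]],
    annotation: AnnotationTable,
    background: Iterable[str],
    *,
    terms_of_interest: Iterable[str] | None = None,
    eta_norm: str = "query_size",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-list, per-term p and eta, plus per-list mean eta.

    Reproduces the "which gene list yields the most enrichment evidence
    per gene" comparison on arbitrary named lists.

    Parameters
    ----------
    terms_of_interest : term ids over which the per-list mean eta is
        taken; defaults to every term that scored in at least one list.

    Returns
    -------
    (table, mean_eta) where ``table`` is the long-format per-list
    enrichment table with a ``list_name`` column, and ``mean_eta`` is a
    Series indexed by list name, sorted descending.  Terms a list does
    not overlap contribute eta = 0 to its mean.
    """
    if len(gene_lists) < 2:
        raise ValueError("need at least two gene lists to compare")
    frames = []
    for name, genes in gene_lists.items():
        genes = set(genes)
        if not genes:
            raise ValueError(f"gene list {name!r} is empty")
        tab = enrich(genes, annotation, background, eta_norm=eta_norm)
        tab.insert(0, "list_name", name)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)

    if terms_of_interest is None:
        terms = list(dict.fromkeys(table["term_id"]))
    else:
        terms = list(terms_of_interest)
    mean_eta = {}
    for name in gene_lists:
        sub = table[(table["list_name"] == name) & table["term_id"].isin(terms)]
        etas = sub.set_index("term_id")["eta"].reindex(terms).fillna(0.0)
        mean_eta[name] = float(etas.mean()) if terms else float("nan")
    series = pd.Series(mean_eta, name="mean_eta").sort_values(ascending=False)
    series.index.name = "list_name"
    return table, series


def efficiency_matrix(table: pd.DataFrame, value: str = "neg_log10_p") -> pd.DataFrame:
    """Pivot a compare_efficiency table into a terms x lists heat-map matrix."""
    return table.pivot_table(index="term_id", columns="list_name", values=value, fill_value=0.0)
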