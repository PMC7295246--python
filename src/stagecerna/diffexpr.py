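"""Differential expression: dual fold-change / p-value filtering.

Each tumor stage is compared against the normal group gene by gene on the
log2 scale.  A gene is called differentially expressed (DE) when both

* |log2FC| >= log2fc_threshold  (default 1; ties at the threshold kept), and
* Welch two-sample t-test p < p_threshold  (default 0.05, strict),

where log2FC is the difference of group means of log2(value + pseudocount).
Up-regulated means log2FC > 0, down-regulated log2FC < 0.  No
multiple-testing correction is applied in this filter; that is a documented
property of the screening design, not an oversight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import NORMAL

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "rna_class", "log2fc", "p_value", "direction", "is_de"]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for the dual DE filter."""

    log2fc_threshold: float = 1.0
    p_threshold: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Replace every value by log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=matrix.index, columns=matrix.columns
    )


def compute_log2fc(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Difference of group means on already log2-transformed values."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(case.mean() - control.mean())


def two_sample_test(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on log2 values.

    Degenerate inputs — a group of fewer than two values, or both groups
    constant — yield p = 1 with a warning: such a gene can never be called
    DE, but it is never silently dropped.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        warnings.warn("group with fewer than 2 values; p set to 1", stacklevel=2)
        return 1.0
    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        warnings.warn("both groups constant; p set to 1", stacklevel=2)
        return 1.0
    return float(stats.ttest_ind(case, control, equal_var=False).pvalue)


def _welch_pvalues(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorised Welch test over genes (rows); degenerate rows get p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (case.var(axis=1, ddof=1) == 0) & (control.var(axis=1, ddof=1) == 0)
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def differential_genes(
    matrix: pd.DataFrame,
    sample_table: pd.DataFrame,
    stage: str,
    config: DEConfig = DEConfig(),
    rna_class: str = "",
) -> pd.DataFrame:
    """Per-gene DE table for one stage-versus-normal comparison.

    Parameters
    ----------
    matrix : raw (non-negative) expression, genes x samples.
    sample_table : sample metadata with ``sample_id`` and ``group``.
    stage : tumor-stage label to compare against the normal group.
    rna_class : annotation carried into the output table.

    Returns
    -------
    DataFrame with columns gene_id, rna_class, log2fc, p_value, direction,
    is_de.  Every input gene appears exactly once.
    """
    groups = sample_table.set_index("sample_id")["group"]
    known_stages = set(groups.unique()) - {NORMAL}
    if stage not in known_stages:
        raise ValueError(f"unknown stage {stage!r}; sample table has {sorted(known_stages)}")
    case_ids = [s for s in matrix.columns if groups.get(s) == stage]
    ctrl_ids = [s for s in matrix.columns if groups.get(s) == NORMAL]
    if len(ctrl_ids) < 2:
        raise ValueError("need at least 2 normal samples")
    if len(case_ids) < 2:
        raise ValueError(f"need at least 2 samples in stage {stage!r}")

    logm = log_transform(matrix, config.pseudocount)
    case = logm[case_ids].to_numpy()
    control = logm[ctrl_ids].to_numpy()

    log2fc = case.mean(axis=1) - control.mean(axis=1)
    p = _welch_pvalues(case, control)

    is_de = (np.abs(log2fc) >= config.log2fc_threshold) & (p < config.p_threshold)
    direction = np.where(is_de & (log2fc > 0), "up", np.where(is_de & (log2fc < 0), "down", "none"))

    return pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "rna_class": rna_class,
            "log2fc": log2fc,
            "p_value": p,
            "direction": direction,
            "is_de": is_de,
        }
    ).reset_index(drop=True)


def differential_genes_all_classes(
    matrices: dict[str, pd.DataFrame],
    sample_table: pd.DataFrame,
    stage: str,
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Concatenate per-class DE tables for one stage into a single table."""
    parts = [
        differential_genes(m, sample_table, stage, config, rna_class=cls)
        for cls, m in matrices.items()
    ]
    return pd.concat(parts, ignore_index=True)
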