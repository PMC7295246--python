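"""Kaplan-Meier estimation, log-rank comparison, and the miRNA survival screen.

The survival probability is estimated by the product-limit formula

    S(t_i) = S(t_{i-1}) * (1 - d_i / n_i),

where ``n_i`` is the number of patients still at risk just before event
time ``t_i`` and ``d_i`` the number of deaths at ``t_i``; censored times
reduce the risk set without a step.  Groups are compared with the
unweighted log-rank test (chi-square, 1 degree of freedom).

The screen dichotomises patients per stage into high/low expression of a
miRNA (median split by default, ties to low), runs the log-rank test in
every stage (and pooled over stages), and classifies the miRNA as
"pan-stage" when significant in every stage or "stage-specific for s"
when significant in stage s only.  The full p-value matrix is always
reported; the classification at a given alpha is derived from it and is
advisory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

from .constants import NORMAL, STAGES

SCREEN_COLUMNS = [
    "mirna_id",
    "stage",
    "n_low",
    "n_high",
    "chi_square",
    "p",
    "evaluable",
    "classification",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct death times."""

    times: np.ndarray  # distinct event (death) times, ascending
    at_risk: np.ndarray  # n_i just before each death time
    deaths: np.ndarray  # d_i at each death time
    survival: np.ndarray  # S(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first death."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int
    df: int = 1


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate from right-censored data.

    ``events`` is 1 where death was observed, 0 where censored.  At tied
    times, deaths are processed before censorings (both still count in the
    risk set of that time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    death_times = np.unique(t[e == 1])
    at_risk = np.empty(death_times.size, dtype=int)
    deaths = np.empty(death_times.size, dtype=int)
    surv = np.empty(death_times.size, dtype=float)
    s = 1.0
    for i, ti in enumerate(death_times):
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i], deaths[i], surv[i] = n_i, d_i, s
    return KMCurve(death_times, at_risk, deaths, surv)


def split_by_expression(
    values: pd.Series,
    clinical: pd.DataFrame,
    rule: str = "median",
    q: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Dichotomise samples into (low, high) expression groups.

    ``values`` is expression indexed by sample id; only samples present in
    both ``values`` and ``clinical`` are used.  Ties at the cut point go
    to the low group.  ``rule`` is "median", "mean" or "quantile" (with
    ``q``).
    """
    ids = [s for s in clinical["sample_id"] if s in values.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 samples with expression and clinical data")
    v = values.loc[ids].astype(float)
    if v.nunique() == 1:
        raise ValueError("degenerate split: all expression values identical")
    if rule == "median":
        cut = float(v.median())
    elif rule == "mean":
        cut = float(v.mean())
    elif rule == "quantile":
        cut = float(v.quantile(q))
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    low = [s for s in ids if v[s] <= cut]
    high = [s for s in ids if v[s] > cut]
    if not high:  # cut at the maximum: move strict maxima is impossible, resplit strictly
        low = [s for s in ids if v[s] < cut]
        high = [s for s in ids if v[s] >= cut]
    return low, high


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> LogRankResult:
    """Unweighted two-group log-rank test (chi-square with 1 df)."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        n_a=int(ta.size),
        n_b=int(tb.size),
    )


def classify(p_by_stage: dict[str, float | None], alpha: float) -> str:
    """Deterministic classification from the per-stage p-value row.

    ``None`` marks a not-evaluable stage (excluded).  "pan-stage" needs
    p <= alpha in every evaluable stage (and at least two evaluable);
    "stage-specific:<s>" needs p <= alpha in stage s and in no other
    evaluable stage.
    """
    evaluable = {s: p for s, p in p_by_stage.items() if p is not None}
    if not evaluable:
        return "not-evaluable"
    significant = [s for s, p in evaluable.items() if p <= alpha]
    if len(significant) == len(evaluable) and len(evaluable) >= 2:
        return "pan-stage"
    if len(significant) == 1:
        return f"stage-specific:{significant[0]}"
    return "none"


def survival_screen(
    mirna_ids: Iterable[str],
    mirna_expression: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    split_rule: str = "median",
    min_subjects: int = 4,
) -> pd.DataFrame:
    """Per-miRNA, per-stage log-rank screen with pan/stage-specific calls.

    Parameters
    ----------
    mirna_ids : miRNAs to screen (must be rows of ``mirna_expression``).
    mirna_expression : miRNA expression, genes x samples (any monotone
        scale; only the ordering enters the split).
    clinical : sample table with sample_id, group, time, event; normal
        samples are ignored.
    min_subjects : stages with fewer subjects are reported not-evaluable
        and excluded from classification.

    Returns
    -------
    Long-format DataFrame, one row per miRNA x (stage or "pooled"), with
    group sizes, chi-square, p, evaluability and the per-miRNA
    classification (repeated on each of its rows).
    """
    tumor = clinical[clinical["group"] != NORMAL]
    stages = [s for s in STAGES if s in set(tumor["group"])]
    rows = []
    for mirna in mirna_ids:
        if mirna not in mirna_expression.index:
            raise ValueError(f"miRNA {mirna!r} not in the expression matrix")
        values = mirna_expression.loc[mirna]
        p_by_stage: dict[str, float | None] = {}
        mirna_rows = []
        for scope in [*stages, "pooled"]:
            sub = tumor if scope == "pooled" else tumor[tumor["group"] == scope]
            sub = sub[sub["sample_id"].isin(values.index)]
            entry = {
                "mirna_id": mirna,
                "stage": scope,
                "n_low": 0,
                "n_high": 0,
                "chi_square": np.nan,
                "p": np.nan,
                "evaluable": False,
            }
            if len(sub) >= min_subjects:
                try:
                    low, high = split_by_expression(values, sub, rule=split_rule)
                except ValueError:
                    low, high = [], []
                if low and high:
                    surv = sub.set_index("sample_id")
                    res = logrank_test(
                        (surv.loc[low, "time"], surv.loc[low, "event"]),
                        (surv.loc[high, "time"], surv.loc[high, "event"]),
                    )
                    entry.update(
                        n_low=len(low),
                        n_high=len(high),
                        chi_square=res.chi_square,
                        p=res.p_value,
                        evaluable=True,
                    )
            if scope != "pooled":
                p_by_stage[scope] = entry["p"] if entry["evaluable"] else None
            mirna_rows.append(entry)
        label = classify(p_by_stage, alpha)
        for entry in mirna_rows:
            entry["classification"] = label
        rows.extend(mirna_rows)
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)
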