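"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a stage-annotated tumor expression study: per-class
expression matrices (lncRNA / miRNA / mRNA) over normal samples and four
tumor stages, a curated miRNA-target interaction table, annotation gene
sets, and right-censored survival times.  Every planted signal is recorded
in a :class:`PlantedTruth` ledger so recovery can be scored exactly.

Model
-----
Expression is log-normal: a per-gene baseline on the log2 scale plus
Gaussian noise, mapped through ``2**x - 1`` (clipped at 0) so that the
downstream ``log2(value + 1)`` transform recovers the Gaussian exactly.

A planted ceRNA triple (lncRNA, miRNA, mRNA) is active in a set of stages:
the miRNA is shifted up by ``planted_log2fc`` and both targets down by the
same amount in those stages' tumor samples, and the targets' log2 noise
contains a ``-slope * miRNA-noise`` component with ``slope =
|r| / sqrt(1 - r**2)`` so the population miRNA-target Pearson correlation
equals ``planted_correlation``.  Triples are either pan-stage (active in
all four stages, the material of the common network) or stage-specific
(active in exactly one, the material of the unique networks).  Decoy
interaction-table pairs are drawn exclusively from genes carrying no
planted effect: they are true negative controls, so the fraction of decoys
surviving the pipeline estimates its false-positive rate.

Survival is exponential: each tumor sample's hazard is
``baseline_hazard * exp(sum_j beta * z_j)`` where ``z_j`` is the within-
stage standardised log2 expression of planted prognostic miRNA ``j``
(pan-stage markers act in every stage, stage-specific ones only in
theirs).  Censoring times are uniform on (0, u) with ``u`` solved so the
expected censored fraction under the baseline hazard equals
``censoring_rate``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from . import io as scio
from .constants import NORMAL, RNA_CLASSES, STAGES
from .enrichment import GeneSet

GROUPS: tuple[str, ...] = (NORMAL, *STAGES)

# log2-scale class baselines: miRNA/mRNA libraries sit higher than lncRNA
_CLASS_BASELINE = {"lncRNA": 7.0, "miRNA": 9.0, "mRNA": 10.0}
_BASELINE_SD = 1.0  # per-gene spread of baselines around the class mean
_DB_SOURCES = ("tarbase", "mirtarbase", "mirecords")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``n_samples_per_stage`` may be a single integer (applied to the normal
    group and every stage) or a mapping group -> count.
    """

    n_lncRNA: int = 120
    n_miRNA: int = 60
    n_mRNA: int = 200
    n_samples_per_stage: int | Mapping[str, int] = 60
    n_planted_triples: int = 30
    frac_stage_specific: float = 0.5
    planted_log2fc: float = 2.0
    planted_correlation: float = -0.6
    noise_sd: float = 1.0
    db_true_fraction: float | None = None
    db_decoy_pairs: int = 300
    n_terms: int = 20
    term_size: int = 15
    n_enriched_terms: int = 3
    hazard_coefficient: float = 0.8
    n_prognostic_pan: int = 1
    n_prognostic_stage: int = 1
    baseline_hazard: float = 1.0 / 1000.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncRNA", "n_miRNA", "n_mRNA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_planted_triples", "db_decoy_pairs", "n_terms", "term_size",
                     "n_enriched_terms", "n_prognostic_pan", "n_prognostic_stage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, n in self.samples_per_group().items():
            if n <= 0:
                raise ValueError(f"sample count for group {g!r} must be positive")
        if self.n_planted_triples > min(self.n_lncRNA, self.n_miRNA, self.n_mRNA):
            raise ValueError("n_planted_triples exceeds a gene-class count")
        if not -1.0 <= self.planted_correlation < 0.0:
            raise ValueError("planted_correlation must lie in [-1, 0)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.frac_stage_specific <= 1.0:
            raise ValueError("frac_stage_specific must lie in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.db_true_fraction is not None and not 0.0 < self.db_true_fraction <= 1.0:
            raise ValueError("db_true_fraction must lie in (0, 1]")
        total_prognostic = self.n_prognostic_pan + self.n_prognostic_stage
        if total_prognostic > self.n_planted_triples:
            raise ValueError("prognostic miRNAs exceed the number of planted triples")

    def samples_per_group(self) -> dict[str, int]:
        if isinstance(self.n_samples_per_stage, Mapping):
            missing = set(GROUPS) - set(self.n_samples_per_stage)
            if missing:
                raise ValueError(f"n_samples_per_stage missing groups {sorted(missing)}")
            return {g: int(self.n_samples_per_stage[g]) for g in GROUPS}
        return {g: int(self.n_samples_per_stage) for g in GROUPS}

    def n_decoys(self) -> int:
        if self.db_true_fraction is None:
            return self.db_decoy_pairs
        n_true = 2 * self.n_planted_triples
        if n_true == 0:
            return self.db_decoy_pairs
        return int(round(n_true * (1.0 - self.db_true_fraction) / self.db_true_fraction))


@dataclass(frozen=True)
class PlantedTriple:
    lncRNA: str
    miRNA: str
    mRNA: str
    stages: tuple[str, ...]  # stages in which the triple is active


@dataclass
class PlantedTruth:
    """Ground-truth ledger for recovery scoring."""

    triples: list[PlantedTriple] = field(default_factory=list)
    de_genes: dict[str, list[str]] = field(default_factory=dict)  # stage -> gene ids
    enriched_terms: list[str] = field(default_factory=list)
    prognostic: list[tuple[str, str]] = field(default_factory=list)  # (mirna, "pan"|stage)

    def pairs(self) -> list[tuple[str, str, str, tuple[str, ...]]]:
        """All planted (mirna, target, target_class, active stages) pairs."""
        out = []
        for t in self.triples:
            out.append((t.miRNA, t.lncRNA, "lncRNA", t.stages))
            out.append((t.miRNA, t.mRNA, "mRNA", t.stages))
        return out

    def to_json(self) -> dict:
        return {
            "triples": [dataclasses.asdict(t) | {"stages": list(t.stages)} for t in self.triples],
            "de_genes": self.de_genes,
            "enriched_terms": self.enriched_terms,
            "prognostic": [list(p) for p in self.prognostic],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PlantedTruth":
        return cls(
            triples=[
                PlantedTriple(t["lncRNA"], t["miRNA"], t["mRNA"], tuple(t["stages"]))
                for t in obj["triples"]
            ],
            de_genes={k: list(v) for k, v in obj["de_genes"].items()},
            enriched_terms=list(obj["enriched_terms"]),
            prognostic=[(m, s) for m, s in obj["prognostic"]],
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    expression: dict[str, pd.DataFrame]  # rna class -> genes x samples (raw scale)
    samples: pd.DataFrame  # sample_id, group, time, event
    interactions: pd.DataFrame  # mirna_id, target_id, target_class, source
    annotation: list[GeneSet]
    truth: PlantedTruth


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i:04d}" for i in range(1, n + 1)]


def _sample_ids(counts: Mapping[str, int]) -> dict[str, list[str]]:
    tag = {NORMAL: "N", "I": "S1", "II": "S2", "III": "S3", "IV": "S4"}
    return {g: [f"{tag[g]}-{i:03d}" for i in range(1, counts[g] + 1)] for g in GROUPS}


def _censoring_horizon(baseline_hazard: float, censoring_rate: float) -> float:
    """Solve (1 - exp(-l*u)) / (l*u) = censoring_rate for u (uniform censoring)."""
    if censoring_rate == 0:
        return math.inf
    l = baseline_hazard

    def frac_censored(u: float) -> float:
        return (1.0 - math.exp(-l * u)) / (l * u) - censoring_rate

    # frac -> 1 as u -> 0 and -> 0 as u -> inf; bracket and bisect
    lo, hi = 1e-9 / l, 1e9 / l
    return float(optimize.brentq(frac_censored, lo, hi, xtol=1e-12 / l))


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one complete synthetic dataset (deterministic given config)."""
    rng = np.random.default_rng(config.seed)
    counts = config.samples_per_group()
    sample_ids = _sample_ids(counts)
    all_samples = [s for g in GROUPS for s in sample_ids[g]]
    n_total = len(all_samples)
    col_of = {s: j for j, s in enumerate(all_samples)}
    stage_cols = {
        g: np.array([col_of[s] for s in sample_ids[g]], dtype=int) for g in GROUPS
    }

    genes = {
        "lncRNA": _gene_ids("lnc", config.n_lncRNA),
        "miRNA": _gene_ids("mir", config.n_miRNA),
        "mRNA": _gene_ids("mrna", config.n_mRNA),
    }
    row_of = {cls: {g: i for i, g in enumerate(ids)} for cls, ids in genes.items()}

    # --- plant triples -----------------------------------------------------
    T = config.n_planted_triples
    n_specific = int(round(T * config.frac_stage_specific))
    triples: list[PlantedTriple] = []
    for i in range(T):
        if i < T - n_specific:
            active: tuple[str, ...] = STAGES
        else:
            active = (STAGES[(i - (T - n_specific)) % len(STAGES)],)
        triples.append(
            PlantedTriple(genes["lncRNA"][i], genes["miRNA"][i], genes["mRNA"][i], active)
        )

    # --- log2-scale expression --------------------------------------------
    baselines = {
        cls: rng.normal(_CLASS_BASELINE[cls], _BASELINE_SD, size=len(genes[cls]))
        for cls in RNA_CLASSES
    }
    noise = {
        cls: rng.normal(0.0, config.noise_sd, size=(len(genes[cls]), n_total))
        for cls in RNA_CLASSES
    }
    logx = {cls: baselines[cls][:, None] + noise[cls] for cls in RNA_CLASSES}

    r = config.planted_correlation
    slope = abs(r) / math.sqrt(1.0 - r * r) if r > -1.0 else 1e9
    fc = config.planted_log2fc
    for t in triples:
        mi = row_of["miRNA"][t.miRNA]
        for stage in t.stages:
            cols = stage_cols[stage]
            logx["miRNA"][mi, cols] += fc
            mi_noise = noise["miRNA"][mi, cols]
            for cls, gene in (("lncRNA", t.lncRNA), ("mRNA", t.mRNA)):
                gi = row_of[cls][gene]
                logx[cls][gi, cols] += -fc - slope * mi_noise

    expression = {
        cls: pd.DataFrame(
            np.clip(np.exp2(logx[cls]) - 1.0, 0.0, None),
            index=pd.Index(genes[cls], name="gene_id"),
            columns=all_samples,
        )
        for cls in RNA_CLASSES
    }

    # --- interaction table -------------------------------------------------
    rows = []
    planted_pairs = set()
    for t in triples:
        for target, cls in ((t.lncRNA, "lncRNA"), (t.mRNA, "mRNA")):
            rows.append((t.miRNA, target, cls, _DB_SOURCES[rng.integers(len(_DB_SOURCES))]))
            planted_pairs.add((t.miRNA, target))
    # decoys are negative controls: drawn only from genes carrying no
    # planted effect, so a decoy passing the pipeline is a false positive
    n_decoys = config.n_decoys()
    free = {cls: genes[cls][T:] for cls in RNA_CLASSES}
    if n_decoys > 0 and (not free["miRNA"] or not (free["lncRNA"] or free["mRNA"])):
        raise ValueError("decoy pairs need at least one unplanted miRNA and target")
    seen = set(planted_pairs)
    attempts = 0
    while len(rows) < 2 * T + n_decoys and attempts < 200 * (n_decoys + 1):
        attempts += 1
        mir = free["miRNA"][rng.integers(len(free["miRNA"]))]
        if free["lncRNA"] and (not free["mRNA"] or rng.random() < 0.5):
            cls = "lncRNA"
        else:
            cls = "mRNA"
        target = free[cls][rng.integers(len(free[cls]))]
        if (mir, target) in seen:
            continue
        seen.add((mir, target))
        rows.append((mir, target, cls, _DB_SOURCES[rng.integers(len(_DB_SOURCES))]))
    interactions = (
        pd.DataFrame(rows, columns=scio.INTERACTION_COLUMNS)
        .sort_values(["mirna_id", "target_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- annotation --------------------------------------------------------
    planted_mrnas = [t.mRNA for t in triples]
    annotation: list[GeneSet] = []
    enriched_terms: list[str] = []
    n_enriched = min(config.n_enriched_terms, config.n_terms)
    for i in range(config.n_terms):
        term_id = f"TERM-{i + 1:04d}"
        if i < n_enriched and planted_mrnas:
            k_planted = min(config.term_size, len(planted_mrnas))
            members = list(rng.choice(planted_mrnas, size=k_planted, replace=False))
            if config.term_size > k_planted:
                rest = [g for g in genes["mRNA"] if g not in members]
                members += list(
                    rng.choice(rest, size=min(config.term_size - k_planted, len(rest)),
                               replace=False)
                )
            enriched_terms.append(term_id)
            name = "planted enriched term"
        else:
            members = list(
                rng.choice(genes["mRNA"], size=min(config.term_size, config.n_mRNA),
                           replace=False)
            )
            name = "background term"
        if members:
            annotation.append(GeneSet(term_id, name, frozenset(members)))

    # --- prognostic markers ------------------------------------------------
    pan_triples = [t for t in triples if t.stages == STAGES]
    specific_triples = [t for t in triples if len(t.stages) == 1]
    prognostic: list[tuple[str, str]] = []
    for t in pan_triples[: config.n_prognostic_pan]:
        prognostic.append((t.miRNA, "pan"))
    picked = 0
    for want_stage in (STAGES * config.n_prognostic_stage)[: config.n_prognostic_stage]:
        match = next(
            (t for t in specific_triples
             if t.stages == (want_stage,) and (t.miRNA, want_stage) not in prognostic),
            None,
        )
        if match is not None:
            prognostic.append((match.miRNA, want_stage))
            specific_triples.remove(match)
            picked += 1
    if picked < config.n_prognostic_stage:
        for t in specific_triples[: config.n_prognostic_stage - picked]:
            prognostic.append((t.miRNA, t.stages[0]))

    # --- survival ----------------------------------------------------------
    lp = np.zeros(n_total)
    for mirna, scope in prognostic:
        mi = row_of["miRNA"][mirna]
        scopes = STAGES if scope == "pan" else (scope,)
        for stage in scopes:
            cols = stage_cols[stage]
            x = logx["miRNA"][mi, cols]
            sd = x.std(ddof=0)
            if sd > 0:
                lp[cols] += config.hazard_coefficient * (x - x.mean()) / sd
    hazard = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    horizon = _censoring_horizon(config.baseline_hazard, config.censoring_rate)
    if math.isinf(horizon):
        censor_time = np.full(n_total, np.inf)
    else:
        censor_time = rng.uniform(0.0, horizon, size=n_total)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    samples = pd.DataFrame(
        {
            "sample_id": all_samples,
            "group": [g for g in GROUPS for _ in sample_ids[g]],
            "time": time,
            "event": event,
        }
    )

    truth = PlantedTruth(
        triples=triples,
        de_genes={
            stage: sorted(
                {g for t in triples if stage in t.stages for g in (t.lncRNA, t.miRNA, t.mRNA)}
            )
            for stage in STAGES
        },
        enriched_terms=enriched_terms,
        prognostic=prognostic,
    )
    return SimulatedDataset(config, expression, samples, interactions, annotation, truth)


# ------------------------------------------------------------------ fixtures


FIXTURE_FILES = {
    "lncRNA": "expression_lncRNA.tsv",
    "miRNA": "expression_miRNA.tsv",
    "mRNA": "expression_mRNA.tsv",
}


def write_fixture(dataset: SimulatedDataset, directory: Path) -> dict[str, Path]:
    """Write a dataset as the TSV/GMT/JSON file set the pipeline consumes.

    Returns the mapping of logical names to paths.  A read with
    :func:`read_fixture` reproduces the in-memory dataset exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls, fname in FIXTURE_FILES.items():
        paths[cls] = directory / fname
        scio.write_expression(dataset.expression[cls], paths[cls])
    paths["samples"] = directory / "samples.tsv"
    scio.write_samples(dataset.samples, paths["samples"])
    paths["interactions"] = directory / "interactions.tsv"
    scio.write_interactions(dataset.interactions, paths["interactions"])
    paths["annotation"] = directory / "annotation.gmt"
    scio.write_gmt(dataset.annotation, paths["annotation"])
    paths["truth"] = directory / "truth.json"
    scio.write_json(
        {"config": _config_to_json(dataset.config), "truth": dataset.truth.to_json()},
        paths["truth"],
    )
    return paths


def read_fixture(directory: Path) -> SimulatedDataset:
    """Read a fixture directory back into a :class:`SimulatedDataset`."""
    directory = Path(directory)
    expression = {
        cls: scio.read_expression(directory / fname) for cls, fname in FIXTURE_FILES.items()
    }
    samples = scio.read_samples(directory / "samples.tsv")
    interactions = scio.read_interactions(directory / "interactions.tsv")
    annotation = scio.read_gmt(directory / "annotation.gmt")
    meta = scio.read_json(directory / "truth.json")
    config = _config_from_json(meta["config"])
    truth = PlantedTruth.from_json(meta["truth"])
    return SimulatedDataset(config, expression, samples, interactions, annotation, truth)


def _config_to_json(config: SimConfig) -> dict:
    obj = dataclasses.asdict(config)
    if isinstance(obj["n_samples_per_stage"], Mapping):
        obj["n_samples_per_stage"] = dict(obj["n_samples_per_stage"])
    return obj


def _config_from_json(obj: dict) -> SimConfig:
    return SimConfig(**obj)
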