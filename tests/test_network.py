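"""Network construction: matching, correlation filter, bipartite validation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagecerna import (
    NetworkConfig,
    SimConfig,
    build_stage_network,
    generate_dataset,
    match_targets,
    pairwise_correlation,
    validate_doubly_bipartite,
)
from stagecerna.diffexpr import differential_genes_all_classes, log_transform


def _de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "rna_class", "log2fc", "p_value",
                                       "direction", "is_de"])


def _interactions(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class", "source"])


class TestMatchTargets:
    def setup_method(self):
        self.de = _de_table([
            ("m1", "miRNA", 2.0, 0.001, "up", True),
            ("m2", "miRNA", 0.1, 0.8, "none", False),
            ("t1", "mRNA", -2.0, 0.001, "down", True),
            ("t2", "mRNA", 0.0, 0.9, "none", False),
            ("l1", "lncRNA", -1.5, 0.01, "down", True),
        ])

    def test_both_de_pair_is_candidate(self):
        cand = match_targets(self.de, _interactions([("m1", "t1", "mRNA", "db")]))
        assert len(cand) == 1
        assert cand.iloc[0]["mirna_direction"] == "up"
        assert cand.iloc[0]["target_direction"] == "down"

    def test_non_de_member_excludes_pair(self):
        cand = match_targets(self.de, _interactions([
            ("m1", "t2", "mRNA", "db"),   # target not DE
            ("m2", "t1", "mRNA", "db"),   # miRNA not DE
        ]))
        assert len(cand) == 0

    def test_pair_absent_from_db_is_not_invented(self):
        cand = match_targets(self.de, _interactions([("m1", "l1", "lncRNA", "db")]))
        assert set(zip(cand["mirna_id"], cand["target_id"])) == {("m1", "l1")}

    def test_class_mismatch_skipped(self):
        # l1 is a lncRNA in the DE table but annotated mRNA in the database
        cand = match_targets(self.de, _interactions([("m1", "l1", "mRNA", "db")]))
        assert len(cand) == 0


class TestPairwiseCorrelation:
    def test_exact_cases(self):
        x = [1.0, 2.0, 3.0]
        assert pairwise_correlation(x, [-1.0, -2.0, -3.0]) == pytest.approx(-1.0)
        assert pairwise_correlation(x, [6.0, 4.0, 2.0]) == pytest.approx(-1.0)
        assert pairwise_correlation(x, [2.0, 4.0, 6.0]) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            x, y = rng.normal(size=100), rng.normal(size=100)
            if abs(pairwise_correlation(x, y)) < 0.2:
                hits += 1
        assert hits >= 45

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _brute_force_edges(dataset, stage, config, de_table):
    """Triple loop oracle: DB pairs x DE check x per-pair Pearson check."""
    de = de_table.set_index("gene_id")
    cols = list(dataset.samples.loc[dataset.samples["group"] == stage, "sample_id"])
    logm = {cls: log_transform(m) for cls, m in dataset.expression.items()}
    edges = set()
    for row in dataset.interactions.itertuples(index=False):
        if row.mirna_id not in de.index or row.target_id not in de.index:
            continue
        if not (de.loc[row.mirna_id, "is_de"] and de.loc[row.target_id, "is_de"]):
            continue
        x = logm["miRNA"].loc[row.mirna_id, cols].to_numpy()
        y = logm[row.target_class].loc[row.target_id, cols].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = stats.pearsonr(x, y).statistic
        if r < config.correlation_threshold:
            edges.add((row.mirna_id, row.target_id))
    return edges


class TestBuildStageNetwork:
    def test_edge_set_matches_brute_force_oracle(self, small_dataset):
        ds = small_dataset
        config = NetworkConfig()
        for stage in ("I", "III"):
            de = differential_genes_all_classes(ds.expression, ds.samples, stage)
            cand = match_targets(de, ds.interactions)
            G = build_stage_network(cand, ds.expression, ds.samples, stage, config)
            got = {frozenset(e) for e in G.edges()}
            expected = {frozenset(e) for e in _brute_force_edges(ds, stage, config, de)}
            assert got == expected

    def test_edge_correlations_below_threshold(self, small_dataset):
        ds = small_dataset
        de = differential_genes_all_classes(ds.expression, ds.samples, "II")
        cand = match_targets(de, ds.interactions)
        G = build_stage_network(cand, ds.expression, ds.samples, "II")
        assert G.number_of_edges() > 0
        for _, _, data in G.edges(data=True):
            assert data["pearson_r"] < -0.1

    def test_more_negative_threshold_never_adds_edges(self, small_dataset):
        ds = small_dataset
        de = differential_genes_all_classes(ds.expression, ds.samples, "I")
        cand = match_targets(de, ds.interactions)
        previous = None
        for thr in (-0.05, -0.3, -0.6, -0.9):
            G = build_stage_network(cand, ds.expression, ds.samples, "I",
                                    NetworkConfig(correlation_threshold=thr))
            edges = {frozenset(e) for e in G.edges()}
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_no_candidates_gives_empty_network(self, small_dataset):
        ds = small_dataset
        empty = ds.interactions.iloc[0:0]
        de = differential_genes_all_classes(ds.expression, ds.samples, "I")
        G = build_stage_network(match_targets(de, empty), ds.expression, ds.samples, "I")
        assert G.number_of_nodes() == 0 and G.number_of_edges() == 0
        assert validate_doubly_bipartite(G).passed


class TestValidation:
    def test_built_networks_pass(self, small_dataset):
        ds = small_dataset
        for stage in ("I", "II", "III", "IV"):
            de = differential_genes_all_classes(ds.expression, ds.samples, stage)
            G = build_stage_network(match_targets(de, ds.interactions),
                                    ds.expression, ds.samples, stage)
            assert validate_doubly_bipartite(G).passed

    def test_lncrna_mrna_edge_fails_with_edge_listed(self):
        G = nx.Graph()
        G.add_node("l1", rna_class="lncRNA")
        G.add_node("t1", rna_class="mRNA")
        G.add_edge("l1", "t1", pearson_r=-0.5)
        report = validate_doubly_bipartite(G)
        assert not report.passed
        assert ("l1", "t1") in report.forbidden_edges["lncRNA-mRNA"]

    def test_same_class_edge_and_isolated_node_fail(self):
        G = nx.Graph()
        G.add_node("m1", rna_class="miRNA")
        G.add_node("m2", rna_class="miRNA")
        G.add_edge("m1", "m2", pearson_r=-0.5)
        G.add_node("orphan", rna_class="mRNA")
        report = validate_doubly_bipartite(G)
        assert not report.passed
        assert "miRNA-miRNA" in report.forbidden_edges
        assert report.isolated_nodes == ["orphan"]


def test_construction_validation_agreement_fuzzed():
    """Every network built from random small configs passes validation."""
    rng = np.random.default_rng(99)
    for _ in range(15):
        config = SimConfig(
            n_lncRNA=int(rng.integers(6, 15)),
            n_miRNA=int(rng.integers(4, 10)),
            n_mRNA=int(rng.integers(8, 20)),
            n_samples_per_stage=int(rng.integers(8, 15)),
            n_planted_triples=int(rng.integers(0, 4)),
            db_decoy_pairs=int(rng.integers(5, 25)),
            n_prognostic_pan=0, n_prognostic_stage=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ds = generate_dataset(config)
        stage = ["I", "II", "III", "IV"][int(rng.integers(4))]
        de = differential_genes_all_classes(ds.expression, ds.samples, stage)
        G = build_stage_network(match_targets(de, ds.interactions),
                                ds.expression, ds.samples, stage)
        assert validate_doubly_bipartite(G).passed
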