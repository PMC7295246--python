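"""Survival: product-limit estimator, log-rank test, and the miRNA screen."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats

from stagecerna import (
    SimConfig,
    classify,
    generate_dataset,
    km_curve,
    logrank_test,
    split_by_expression,
    survival_screen,
)


def logrank_oracle(ta, ea, tb, eb):
    """Observed-minus-expected log-rank chi-square, coded from the textbook
    formula independently of any survival library."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_a = E_a = V = 0.0
    for t in times:
        n_a = (ta >= t).sum()
        n_b = (tb >= t).sum()
        d_a = ((ta == t) & (ea == 1)).sum()
        d_b = ((tb == t) & (eb == 1)).sum()
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        O_a += d_a
        E_a += d * n_a / n
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    chi2 = (O_a - E_a) ** 2 / V if V > 0 else 0.0
    return chi2, stats.chi2.sf(chi2, 1)


class TestKMCurve:
    def test_two_subjects_two_deaths(self):
        km = km_curve([1.0, 2.0], [1, 1])
        assert km.survival_at(1.0) == pytest.approx(0.5)
        assert km.survival_at(2.0) == pytest.approx(0.0)
        assert km.survival_at(0.5) == 1.0

    def test_all_censored_flat_at_one(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_one_death_three_censored_after(self):
        km = km_curve([5.0, 6.0, 7.0, 8.0], [1, 0, 0, 0])
        assert km.survival_at(5.0) == pytest.approx(0.75)

    def test_matches_lifelines_on_random_datasets(self):
        """Independent product-limit oracle: lifelines' fitter."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(3, 31))
            times = np.round(rng.exponential(10, n), 1)  # rounding forces ties
            events = rng.integers(0, 2, n)
            km = km_curve(times, events)
            kmf = KaplanMeierFitter().fit(times, events)
            for t, s in zip(km.times, km.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
                )

    def test_no_censoring_equals_empirical_fraction(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5, 40)
        km = km_curve(times, np.ones_like(times, dtype=int))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(float((times > t).mean()), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestSplit:
    def test_even_median_split(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        clinical = pd.DataFrame({"sample_id": list("abcd"), "group": "I",
                                 "time": 1.0, "event": 0})
        low, high = split_by_expression(values, clinical)
        assert set(low) == {"a", "b"} and set(high) == {"c", "d"}

    def test_odd_count_tie_to_low(self):
        values = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        clinical = pd.DataFrame({"sample_id": list("abc"), "group": "I",
                                 "time": 1.0, "event": 0})
        low, high = split_by_expression(values, clinical)
        assert set(low) == {"a", "b"} and set(high) == {"c"}

    def test_constant_values_rejected(self):
        values = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        clinical = pd.DataFrame({"sample_id": list("abc"), "group": "I",
                                 "time": 1.0, "event": 0})
        with pytest.raises(ValueError, match="degenerate"):
            split_by_expression(values, clinical)


class TestLogRank:
    def test_identical_groups_chi_square_zero(self):
        t, e = [1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1]
        res = logrank_test((t, e), (t, e))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_observed_minus_expected_oracle(self):
        cases = [
            ([1, 3, 5, 7, 9], [1, 1, 0, 1, 1], [2, 4, 6, 8, 10], [1, 0, 1, 1, 0]),
            ([1, 1, 2, 3], [1, 1, 1, 0], [4, 5, 6, 7], [1, 1, 0, 1]),
        ]
        for ta, ea, tb, eb in cases:
            res = logrank_test((ta, ea), (tb, eb))
            chi2, p = logrank_oracle(ta, ea, tb, eb)
            assert res.chi_square == pytest.approx(chi2, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            na, nb = int(rng.integers(5, 25)), int(rng.integers(5, 25))
            ta = np.round(rng.exponential(10, na), 1)
            tb = np.round(rng.exponential(14, nb), 1)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            res = logrank_test((ta, ea), (tb, eb))
            chi2, _ = logrank_oracle(ta, ea, tb, eb)
            assert res.chi_square == pytest.approx(chi2, abs=1e-8)

    def test_permutation_null_uniform(self):
        """Permuting group labels yields approximately uniform p-values."""
        rng = np.random.default_rng(21)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        pvals = []
        for _ in range(200):
            idx = rng.permutation(60)
            a, b = idx[:30], idx[30:]
            pvals.append(logrank_test((times[a], events[a]), (times[b], events[b])).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([], []), ([1.0], [1]))


class TestClassify:
    def test_deterministic_rules(self):
        assert classify({"I": 0.01, "II": 0.02, "III": 0.03, "IV": 0.04}, 0.05) == "pan-stage"
        assert classify({"I": 0.5, "II": 0.01, "III": 0.5, "IV": 0.5}, 0.05) == (
            "stage-specific:II"
        )
        assert classify({"I": 0.01, "II": 0.01, "III": 0.5, "IV": 0.5}, 0.05) == "none"
        assert classify({"I": None, "II": None, "III": None, "IV": None}, 0.05) == (
            "not-evaluable"
        )
        # a not-evaluable stage is excluded, the rest decide
        assert classify({"I": 0.01, "II": 0.02, "III": None, "IV": 0.03}, 0.05) == "pan-stage"


class TestScreen:
    @pytest.fixture(scope="class")
    def powered_dataset(self):
        return generate_dataset(
            SimConfig(n_lncRNA=12, n_miRNA=12, n_mRNA=12, n_samples_per_stage=150,
                      n_planted_triples=8, frac_stage_specific=0.5,
                      hazard_coefficient=0.8, n_prognostic_pan=1, n_prognostic_stage=1,
                      db_decoy_pairs=0, seed=77)
        )

    def test_pan_and_stage_specific_recovery(self, powered_dataset):
        ds = powered_dataset
        planted = dict(ds.truth.prognostic)
        screen = survival_screen(list(planted), ds.expression["miRNA"], ds.samples)
        labels = screen.drop_duplicates("mirna_id").set_index("mirna_id")["classification"]
        for mirna, scope in planted.items():
            if scope == "pan":
                assert labels[mirna] == "pan-stage"
            else:
                # the planted stage must at least be among the significant ones
                stage_p = screen[
                    (screen["mirna_id"] == mirna) & (screen["stage"] == scope)
                ]["p"].iloc[0]
                assert stage_p <= 0.05

    def test_null_mirna_not_classified(self, null_dataset):
        ds = null_dataset
        screen = survival_screen(["mir-0002"], ds.expression["miRNA"], ds.samples)
        label = screen["classification"].iloc[0]
        assert label in ("none", "stage-specific:I", "stage-specific:II",
                         "stage-specific:III", "stage-specific:IV")
        assert label != "pan-stage"

    def test_unknown_mirna_rejected(self, null_dataset):
        with pytest.raises(ValueError):
            survival_screen(["nope"], null_dataset.expression["miRNA"], null_dataset.samples)

    def test_small_stage_not_evaluable(self, null_dataset):
        ds = null_dataset
        clinical = ds.samples[ds.samples["group"].isin(["normal", "I"])].copy()
        tiny = pd.concat(
            [clinical, pd.DataFrame({"sample_id": ["x1", "x2"], "group": "II",
                                     "time": [5.0, 6.0], "event": [1, 0]})],
            ignore_index=True,
        )
        screen = survival_screen(["mir-0001"], ds.expression["miRNA"], tiny)
        row = screen[(screen["stage"] == "II")].iloc[0]
        assert not row["evaluable"]
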