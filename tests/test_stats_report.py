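"""Hypothesis tests against enumeration/permutation oracles, and the
report bundle's structure and determinism."""
import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtoburden.stats_report import (build_report, chi_square_test, median_iqr,
                                    rank_sum_test, trend_test)


def exact_rank_sum_p(a, b):
    """Oracle: full enumeration of group assignments; two-sided p as the
    probability of a rank sum at least as extreme as observed."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {}
    from scipy.stats import rankdata
    r = rankdata(pooled)
    obs = sum(r[:n_a])
    mean = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        s = sum(r[i] for i in comb)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestMedianIqr:
    def test_small_sample(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_generator_private_medical_target(self, large_survey_records):
        vals = [r.costs.medical_oop / 100.0 for r in large_survey_records
                if r.stratum == "private"]
        med, q1, q3 = median_iqr(vals)
        assert med == pytest.approx(300, rel=0.10)


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_match_enumeration(self):
        a, b = [1, 2, 3, 4], [10, 11, 12, 13]
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=0.02)

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=10, unique=True),
           st.integers(2, 8))
    @settings(max_examples=40)
    def test_matches_enumeration_small_untied_n(self, pooled, split):
        split = min(split, len(pooled) - 2)
        a, b = pooled[:split], pooled[split:]
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20),
           st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    @settings(max_examples=30)
    def test_symmetric_in_groups(self, a, b):
        assert rank_sum_test(a, b).p_value == pytest.approx(
            rank_sum_test(b, a).p_value, rel=1e-9)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestChiSquare:
    def test_printed_finance_table(self):
        res = chi_square_test([[199, 145], [266, 205]])
        assert res.p_value == pytest.approx(0.70, abs=0.01)

    def test_proportional_table_statistic_zero(self):
        res = chi_square_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_computed(self):
        res = chi_square_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_zero_expected_count_error(self):
        with pytest.raises(ValueError, match="merge"):
            chi_square_test([[0, 0], [5, 5]])


class TestTrend:
    def test_increasing_trend_detected(self):
        values = np.arange(25, dtype=float)
        labels = np.repeat(list("abcde"), 5)
        res = trend_test(values, labels, order=list("abcde"))
        assert res.p_value < 0.01

    def test_permutation_oracle(self):
        # oracle: null distribution of the score-weighted rank sum under
        # 10 000 label shuffles, computed independently with numpy
        from scipy.stats import rankdata
        rng = np.random.default_rng(0)
        values = rng.normal(size=60) + np.repeat([0.0, 0.25, 0.5], 20)
        labels = np.repeat([1, 2, 3], 20)
        obs = trend_test(values, labels, order=[1, 2, 3])
        ranks = rankdata(values)
        scores = labels.astype(float)
        t_obs = float(scores @ ranks)
        e_t = scores.sum() * (len(values) + 1) / 2
        t_null = np.array([rng.permutation(scores) @ ranks for _ in range(10_000)])
        p_perm = np.mean(np.abs(t_null - e_t) >= abs(t_obs - e_t) - 1e-9)
        assert obs.p_value == pytest.approx(p_perm, abs=0.02)

    def test_two_groups_signs_agree_with_rank_sum(self):
        a = [1.0, 3.0, 4.0, 2.0]
        b = [6.0, 8.0, 5.0, 9.0]
        res = trend_test(a + b, ["g1"] * 4 + ["g2"] * 4, order=["g1", "g2"])
        assert res.statistic > 0  # values increase along the group order
        res_rev = trend_test(a + b, ["g1"] * 4 + ["g2"] * 4, order=["g2", "g1"])
        assert res_rev.statistic < 0

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            trend_test([1, 2], ["a", "a"])


class TestBuildReport:
    def test_bundle_contents(self, survey_records, tmp_path):
        summary = build_report(survey_records, tmp_path, seed=5,
                               bootstrap_replicates=100)
        expected = {"table_demographics.csv", "table_disease_profile.csv",
                    "costs_per_traveler.csv", "table_cost_shares.csv",
                    "table_catastrophic.csv", "table_extrapolation.csv",
                    "summary.json", "run_metadata.json"}
        assert expected <= {p.name for p in tmp_path.iterdir()}
        assert summary["n_records"] == 815
        assert summary["disease_profile_omitted"] > 0

    def test_rerun_byte_identical_summary(self, survey_records, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_report(survey_records, d1, seed=5, bootstrap_replicates=100)
        build_report(survey_records, d2, seed=5, bootstrap_replicates=100)
        assert (d1 / "summary.json").read_bytes() == (d2 / "summary.json").read_bytes()

    def test_disease_table_excludes_ineligible(self, survey_records, tmp_path):
        import pandas as pd
        build_report(survey_records, tmp_path, seed=5, bootstrap_replicates=100)
        disease = pd.read_csv(tmp_path / "table_disease_profile.csv")
        assert not disease["label"].str.contains("Factors influencing").any()
        assert not (disease["label"] == "missing").any()
        summary = json.loads((tmp_path / "summary.json").read_text())
        n_z_or_missing = sum((r.icd_code or "").startswith("Z") or r.icd_code is None
                             for r in survey_records)
        assert summary["disease_profile_omitted"] == n_z_or_missing
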