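"""Detection filter, Fisher's combined test, permutation p and q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bxdnet.datatypes import ConfigurationError, DataError
from bxdnet.responsome import (ResponsomeTest, detection_filter,
                               detection_proxy, empirical_pvalues,
                               fisher_combine, qvalues)


class TestDetectionFilter:
    def test_fully_absent_excluded(self):
        detect = pd.DataFrame(False, index=["a"], columns=range(20))
        assert detection_filter(detect) == []

    def test_exactly_95_percent_absent_excluded(self):
        calls = np.zeros((1, 100), dtype=bool)
        calls[0, :5] = True  # absent in exactly 95 of 100
        assert detection_filter(pd.DataFrame(calls, index=["a"])) == []

    def test_present_everywhere_retained(self):
        detect = pd.DataFrame(True, index=["a"], columns=range(20))
        assert detection_filter(detect) == ["a"]

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            detection_filter(pd.DataFrame())

    def test_proxy_thresholds_log2_expression(self):
        expr = pd.DataFrame([[5.0, 7.0]], index=["a"], columns=["s1", "s2"])
        present = detection_proxy(expr, floor=6.0)
        assert present.values.tolist() == [[False, True]]


class TestFisherCombine:
    def test_all_ones_gives_zero_statistic(self):
        X, p = fisher_combine(np.ones((3, 5)))
        np.testing.assert_array_equal(X, 0.0)
        np.testing.assert_array_equal(p, 1.0)

    def test_two_pvalues_closed_form(self):
        # df = 4: survival function has the closed form e^{-x/2}(1 + x/2)
        X, p = fisher_combine(np.array([0.05, 0.05]))
        x_expected = -2 * 2 * np.log(0.05)
        assert X == pytest.approx(x_expected, abs=1e-3)
        assert X == pytest.approx(11.983, abs=1e-3)
        p_oracle = np.exp(-X / 2) * (1 + X / 2)
        assert p == pytest.approx(p_oracle, rel=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_null_combined_p_is_uniform(self):
        rng = np.random.default_rng(0)
        _, p = fisher_combine(rng.uniform(size=(2000, 27)))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_statistic_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, size=(50, 9))
        X, _ = fisher_combine(p)
        np.testing.assert_allclose(X, (-2 * np.log(p)).sum(axis=1),
                                   rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            fisher_combine(np.array([0.5, 1.5]))


class TestEmpiricalPvalues:
    def test_constant_matrix_gives_all_ones(self):
        S = pd.DataFrame(np.full((30, 6), 1.3))
        emp = empirical_pvalues(S, n_perm=100, seed=0)
        np.testing.assert_array_equal(emp.values, 1.0)

    def test_extreme_row_gets_minimum_pvalue(self):
        rng = np.random.default_rng(2)
        S = pd.DataFrame(rng.normal(size=(200, 10)))
        S.iloc[0] = 30.0
        emp = empirical_pvalues(S, n_perm=100, seed=0)
        assert emp.iloc[0] == pytest.approx(1 / 101)

    def test_null_empirical_p_uniform(self):
        rng = np.random.default_rng(3)
        S = pd.DataFrame(rng.normal(size=(1500, 20)))
        emp = empirical_pvalues(S, n_perm=300, seed=1)
        assert stats.kstest(emp, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        S = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(ConfigurationError):
            empirical_pvalues(S, n_perm=50)


class TestQvalues:
    def test_all_equal_pvalues_give_equal_q(self):
        q = qvalues(np.full(200, 0.3))
        assert len(set(np.round(q, 12))) == 1

    def test_q_nondecreasing_in_p_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_uniform_null_yields_no_discoveries(self):
        rng = np.random.default_rng(5)
        q = qvalues(rng.uniform(size=2000))
        assert (q <= 0.05).mean() < 0.005

    def test_small_input_falls_back_to_bh(self):
        p = np.array([0.01, 0.02, 0.5])
        q = qvalues(p)  # pi0 = 1 -> plain BH
        np.testing.assert_allclose(q, [0.03, 0.03, 0.5])


class TestResponsomeTest:
    def test_planted_responders_called_with_power(self, dataset):
        from bxdnet.sscore import SScoreTransformer
        S = SScoreTransformer().fit(dataset.probes).transform(dataset.probes)
        rt = ResponsomeTest(n_permutations=300, random_state=0).fit(S)
        truth = set(dataset.truth.response_effects)
        called = set(rt.responsive_)
        power = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(len(called), 1)
        assert power > 0.8
        assert fdr < 0.1

    def test_null_matrix_yields_no_calls(self):
        rng = np.random.default_rng(6)
        S = pd.DataFrame(rng.normal(size=(1000, 27)))
        rt = ResponsomeTest(n_permutations=200, random_state=1).fit(S)
        assert len(rt.responsive_) / 1000 < 0.01

    def test_responsive_flag_consistent_with_q(self, dataset):
        rng = np.random.default_rng(7)
        S = pd.DataFrame(rng.normal(size=(300, 8)))
        rt = ResponsomeTest(n_permutations=150, random_state=2).fit(S)
        r = rt.results_
        assert (r["responsive"] == (r["q_value"] <= 0.05)).all()
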