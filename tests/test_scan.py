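import math

import numpy as np
import pandas as pd
import pytest

from panselect.coalescent import NullDistribution
from panselect.neutrality import NEUTRALITY_TESTS
from panselect.scan import (
    call_selection,
    corroborate,
    empirical_percentiles,
    summarize_calls,
)


def stat_table(values_by_test, population="AFR"):
    """Build a scan input table; values_by_test maps test -> list."""
    n = len(next(iter(values_by_test.values())))
    df = pd.DataFrame({"gene": [f"g{i:03d}" for i in range(n)], "population": population,
                       "tested": True})
    for t in NEUTRALITY_TESTS:
        df[t] = values_by_test.get(t, list(np.zeros(n)))
    return df


def background(rng, n=100, planted=(0,)):
    """Random statistics with the planted genes pinned at the panel median,
    so only explicitly planted extremes can support a call."""
    base = {t: list(rng.normal(size=n)) for t in NEUTRALITY_TESTS}
    for t in NEUTRALITY_TESTS:
        for g in planted:
            base[t][g] = 0.0
    return base


class TestPercentiles:
    def test_minimum_of_hundred(self):
        vals = pd.Series(np.arange(100, dtype=float))
        pct = empirical_percentiles(vals)
        assert pct.iloc[0] == pytest.approx(0.01)
        assert pct.iloc[-1] == pytest.approx(1.0)

    def test_tied_minima_mean_rank(self):
        vals = pd.Series(np.concatenate([[0.0, 0.0], np.arange(1, 99, dtype=float)]))
        pct = empirical_percentiles(vals)
        assert pct.iloc[0] == pct.iloc[1] == pytest.approx(0.015)

    def test_nan_values_excluded_from_pool(self):
        vals = pd.Series([1.0, 2.0, np.nan, 3.0] + list(np.arange(4.0, 24.0)))
        pct = empirical_percentiles(vals)
        assert math.isnan(pct.iloc[2])
        assert pct.iloc[0] == pytest.approx(1 / 23)

    def test_uniform_calibration(self, rng):
        vals = pd.Series(rng.normal(size=500))
        pct = empirical_percentiles(vals)
        from scipy import stats as sps
        # percentile of rank k is k/n: compare against uniform grid
        assert sps.kstest(pct, "uniform").pvalue > 0.01

    def test_small_panel_warns(self):
        with pytest.warns(UserWarning):
            empirical_percentiles(pd.Series([1.0, 2.0, 3.0]))


class TestCallSelection:
    def test_two_lower_tests_positive_call(self, rng):
        base = background(rng)
        base["tajima_d"][0] = -50.0
        base["fuli_f_star"][0] = -50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "positive"
        assert {t for t, _, _ in calls[0].supporting_tests} >= {"tajima_d", "fuli_f_star"}

    def test_one_test_is_not_enough(self, rng):
        base = background(rng)
        base["tajima_d"][0] = -50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "none"

    def test_two_upper_tests_balancing_call(self, rng):
        base = background(rng)
        base["fuli_d"][0] = 50.0
        base["fuli_f"][0] = 50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "balancing"

    def test_h_never_supports_balancing(self, rng):
        base = background(rng)
        base["faywu_h_norm"][0] = 50.0
        base["fuli_d"][0] = 50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "none"

    def test_h_flags_unequivocal_positive(self, rng):
        base = background(rng)
        base["faywu_h_norm"][0] = -50.0
        base["tajima_d"][0] = -50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "positive" and calls[0].unequivocal_positive

    def test_mixed_tails_tie_is_ambiguous(self, rng):
        base = background(rng)
        base["tajima_d"][0] = -50.0
        base["fuli_d_star"][0] = -50.0
        base["fuli_d"][0] = 50.0
        base["fuli_f"][0] = 50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "none" and calls[0].ambiguous

    def test_mixed_tails_majority_wins(self, rng):
        base = background(rng)
        for t in ("tajima_d", "fuli_d_star", "fuli_f_star"):
            base[t][0] = -50.0
        base["fuli_d"][0] = 50.0
        base["fuli_f"][0] = 50.0
        calls = call_selection(stat_table(base))
        assert calls[0].direction == "positive"

    def test_untested_gene_reported_with_reason(self, rng):
        base = background(rng, n=30)
        df = stat_table(base)
        df.loc[0, "tested"] = False
        calls = call_selection(df)
        assert calls[0].direction == "none" and calls[0].reason == "untested_low_S"

    def test_invariant_to_gene_order_and_monotone_rescaling(self, rng):
        base = background(rng, n=60, planted=(5,))
        base["tajima_d"][5] = -50.0
        base["fuli_f"][5] = -50.0
        df = stat_table(base)
        calls1 = {c.gene_id: c.direction for c in call_selection(df)}
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        calls2 = {c.gene_id: c.direction for c in call_selection(shuffled)}
        assert calls1 == calls2
        rescaled = df.copy()
        rescaled["tajima_d"] = np.exp(rescaled["tajima_d"] / 25.0)  # monotone
        calls3 = {c.gene_id: c.direction for c in call_selection(rescaled)}
        assert calls1 == calls3

    def test_every_call_has_consistent_support(self, rng):
        base = {t: list(rng.standard_t(3, size=200)) for t in NEUTRALITY_TESTS}
        for c in call_selection(stat_table(base)):
            if c.direction != "none":
                assert len(c.supporting_tests) >= 2
                tails = {tail for _, _, tail in c.supporting_tests}
                assert tails == {"lower"} if c.direction == "positive" else tails == {"upper"}


class TestCorroborate:
    def _calls_with_support(self, rng):
        base = background(rng, n=50)
        base["tajima_d"][0] = -50.0
        base["fuli_f_star"][0] = -50.0
        df = stat_table(base)
        return df, call_selection(df)

    def test_median_observation_not_corroborated(self, rng):
        df, calls = self._calls_with_support(rng)
        df.loc[0, "tajima_d"] = 0.0  # at the null median
        df.loc[0, "fuli_f_star"] = 0.0
        null = {t: NullDistribution(t, np.linspace(-3, 3, 1001)) for t in NEUTRALITY_TESTS}
        out = corroborate(calls, df, {"g000": null})
        assert out[0].sim_pvalues["tajima_d"] == pytest.approx(0.5, abs=0.01)
        assert out[0].corroborated is False

    def test_extreme_observation_corroborated(self, rng):
        df, calls = self._calls_with_support(rng)
        null = {t: NullDistribution(t, np.linspace(-3, 3, 1001)) for t in NEUTRALITY_TESTS}
        out = corroborate(calls, df, {"g000": null})
        assert out[0].corroborated is True
        assert all(p == pytest.approx(1 / 1002) for p in out[0].sim_pvalues.values())

    def test_missing_distribution_left_undecided(self, rng):
        _, calls = self._calls_with_support(rng)
        df, _ = self._calls_with_support(rng)
        out = corroborate(calls, df, {})
        assert out[0].corroborated is None


class TestSummarize:
    def test_empty_call_set_all_zero(self):
        class_map = pd.Series(["Receptors", "Adaptors"], index=["g1", "g2"])
        table = summarize_calls({"AFR": []}, class_map)
        assert (table[[c for c in table.columns if c.endswith("_n")]].to_numpy() == 0).all()

    def test_counts_match_calls(self, rng):
        base = background(rng, n=40, planted=(3,))
        base["tajima_d"][3] = -50.0
        base["fuli_f"][3] = -50.0
        calls = call_selection(stat_table(base))
        class_map = pd.Series(["Receptors"] * 20 + ["Cytokines"] * 20,
                              index=[f"g{i:03d}" for i in range(40)])
        table = summarize_calls({"AFR": calls}, class_map).set_index("class")
        assert table.loc["Receptors", "positive_AFR_n"] == 1
        assert "g003" in table.loc["Receptors", "positive_AFR_genes"]
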