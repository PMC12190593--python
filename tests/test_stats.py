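"""Signed-rank exactness, comparison procedures, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from pacnet import compare_groups, compare_states, group_summary, wilcoxon_signed_rank
from pacnet.core_io import FEATURE_COLUMNS
from pacnet.stats import benjamini_hochberg, results_to_dataframe


def enumeration_p(d):
    """Independent exact two-sided p by full sign-pattern enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    w_plus = np.array(
        [sum(r for s, r in zip(signs, ranks) if s)
         for signs in itertools.product([0, 1], repeat=len(d))]
    )
    return min(1.0, 2 * min((w_plus <= obs).mean(), (w_plus >= obs).mean()))


def feature_rows(values, feature="mi", band="delta-gamma"):
    """values: dict (subject, group, state, channel) -> value."""
    rows = [
        (s, g, st, ch, feature, band, v) for (s, g, st, ch), v in values.items()
    ]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        with pytest.warns(UserWarning, match="zero"):
            w, p = wilcoxon_signed_rank(a, a)
        assert p == 1.0

    def test_five_positive_differences_exact(self):
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(0.0625, abs=1e-12)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(20):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            _, p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(enumeration_p(a - b), abs=1e-12)

    def test_large_n_uses_valid_approximation(self, rng):
        a = rng.standard_normal(60)
        b = a + 0.5 + rng.standard_normal(60) * 0.1
        _, p = wilcoxon_signed_rank(a, b)
        assert p < 1e-6  # strong systematic shift detected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestCompareStates:
    @staticmethod
    def _table(n_subjects=12, channels=("C1", "C2"), effect=2.0, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        values = {}
        for s in range(n_subjects):
            base = rng.normal(1.0, noise)
            for ch in channels:
                values[(f"s{s:02d}", "wm", "pre_rest", ch)] = base + rng.normal(0, noise)
                values[(f"s{s:02d}", "wm", "task", ch)] = (
                    base * effect + rng.normal(0, noise)
                )
        return feature_rows(values)

    def test_known_effect_detected_with_direction(self):
        res = compare_states(self._table(), "mi", "delta-gamma", ("pre_rest", "task"))
        whole = [r for r in res if r.level == "whole_brain_mean"][0]
        assert whole.significant
        assert whole.mean_b > whole.mean_a
        assert whole.n_pairs == 12
        per = [r for r in res if r.level == "per_channel"]
        assert len(per) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="two subjects"):
            compare_states(
                self._table(n_subjects=1), "mi", "delta-gamma", ("pre_rest", "task")
            )

    def test_subject_missing_state_excluded_with_warning(self):
        t = self._table()
        t = t[~((t.subject_id == "s00") & (t.state == "task"))]
        with pytest.warns(UserWarning, match="s00"):
            res = compare_states(t, "mi", "delta-gamma", ("pre_rest", "task"))
        assert res[-1].n_pairs == 11

    def test_summary_string_reproduces_arithmetic(self):
        res = compare_states(self._table(), "mi", "delta-gamma", ("pre_rest", "task"))
        whole = [r for r in res if r.level == "whole_brain_mean"][0]
        s = whole.summary()
        assert f"{whole.mean_a:.4g}" in s and f"{whole.sd_a:.4g}" in s
        # sd is the n-1 sample standard deviation of the subject means
        t = self._table()
        pre = t[t.state == "pre_rest"].groupby("subject_id")["value"].mean()
        assert whole.sd_a == pytest.approx(np.std(pre.to_numpy(), ddof=1))


class TestCompareGroups:
    @staticmethod
    def _table(shift=0.0, channels=tuple(f"C{i}" for i in range(12)), seed=1):
        rng = np.random.default_rng(seed)
        values = {}
        for g, delta in (("sham", 0.0), ("tdcs", shift)):
            for s in range(12):
                for ch in channels:
                    values[(f"{g}{s:02d}", g, "task", ch)] = rng.normal(1.0 + delta, 0.1)
        return feature_rows(values, feature="band_power_db", band="gamma")

    def test_known_group_effect_detected(self):
        res = compare_groups(
            self._table(shift=1.0), "band_power_db", "gamma", ("sham", "tdcs")
        )
        whole = [r for r in res if r.level == "whole_brain_mean"][0]
        assert whole.significant
        assert whole.mean_b > whole.mean_a
        assert whole.test_name == "wilcoxon_signed_rank_over_channels"
        per = [r for r in res if r.level == "per_channel"]
        assert all(r.test_name == "rank_sum" for r in per)

    def test_disjoint_channel_sets_rejected(self):
        t = self._table()
        t.loc[t.group == "tdcs", "channel"] = t.loc[t.group == "tdcs", "channel"] + "x"
        with pytest.raises(ValueError, match="channel sets"):
            compare_groups(t, "band_power_db", "gamma", ("sham", "tdcs"))

    def test_missing_group_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="no rows"):
            compare_groups(
                t[t.group == "sham"], "band_power_db", "gamma", ("sham", "tdcs")
            )


class TestSummariesAndCorrections:
    def test_group_summary_matches_arithmetic(self):
        t = TestCompareGroups._table(shift=0.5)
        out = group_summary(t, "band_power_db", "gamma", by=("group",))
        sham = t[t.group == "sham"]["value"].to_numpy()
        row = out[out.group == "sham"].iloc[0]
        assert row["mean"] == pytest.approx(sham.mean())
        assert row["sd"] == pytest.approx(np.std(sham, ddof=1))
        assert row["n"] == len(sham)

    def test_benjamini_hochberg_bounds_naive_rejection(self):
        p = np.array([0.001, 0.011, 0.021, 0.2, 0.9])
        mask = benjamini_hochberg(p, alpha=0.05)
        assert mask[0] and not mask[-1]
        assert mask.sum() <= (p < 0.05).sum()

    def test_results_dataframe_round_trip(self):
        res = compare_groups(
            TestCompareGroups._table(shift=1.0), "band_power_db", "gamma",
            ("sham", "tdcs"),
        )
        df = results_to_dataframe(res)
        assert len(df) == len(res)
        assert (df["significant"] == (df["p_value"] < 0.05)).all()
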