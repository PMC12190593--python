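"""Paired nonparametric comparisons and group summaries.

The study's reporting structure is reproduced: per-channel Wilcoxon
signed-rank comparisons (pairs = subjects) plus a whole-brain-mean
comparison, each summarised as "mean ± sd" per condition with a two-sided
p-value and a significance flag at the configured alpha.

Between-group contrasts mirror the published procedure, which applied a
signed-rank (paired) test to two independent groups: the whole-brain
contrast pairs per-channel group means across channels; subject-level
per-channel contrasts are additionally reported with an unpaired rank-sum
test, labelled as such in the output.

No multiple-comparison correction is applied by default (raw p < alpha per
node, as reported); Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .network import NETWORK_MEAN_CHANNEL

__all__ = [
    "ComparisonResult",
    "wilcoxon_signed_rank",
    "rank_sum",
    "compare_states",
    "compare_groups",
    "group_summary",
    "results_to_dataframe",
    "benjamini_hochberg",
]


@dataclass
class ComparisonResult:
    feature_name: str
    band: str
    level: str  # per_channel | whole_brain_mean
    channel: str  # "" for whole-brain rows
    condition_a: str
    condition_b: str
    n_pairs: int
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    significant: bool
    test_name: str = "wilcoxon_signed_rank"

    def summary(self) -> str:
        """Report line in the conventional '(a: x ± s; b: x ± s; p = …)' form."""
        return (
            f"({self.condition_a}: {self.mean_a:.4g} ± {self.sd_a:.4g}; "
            f"{self.condition_b}: {self.mean_b:.4g} ± {self.sd_b:.4g}; "
            f"p = {self.p_value:.3g})"
        )


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 without tied |differences|; otherwise the normal approximation
    with tie correction. Returns (W, p) with W = min of the signed rank
    sums. All differences zero gives p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sst.wilcoxon(d, method=method, correction=False)
    return float(res.statistic), float(res.pvalue)


def rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) for unpaired samples."""
    res = sst.mannwhitneyu(sample_a, sample_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator); 0 for a single value."""
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _pivot(
    table: pd.DataFrame, feature: str, band: str, exclude_network_rows: bool = True
) -> pd.DataFrame:
    sel = table[(table["feature_name"] == feature) & (table["band"] == band)]
    if exclude_network_rows:
        sel = sel[sel["channel"] != NETWORK_MEAN_CHANNEL]
    if sel.empty:
        raise ValueError(f"no rows for feature {feature!r}, band {band!r}")
    return sel


def compare_states(
    table: pd.DataFrame,
    feature: str,
    band: str,
    states: tuple[str, str],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Paired state comparison: per-channel tests plus a whole-brain test.

    Pairs are subjects; subjects missing either state are excluded with a
    warning. The whole-brain test compares each subject's mean over
    channels. Requires at least two complete subjects.
    """
    state_a, state_b = states
    sel = _pivot(table, feature, band)
    sel = sel[sel["state"].isin(states)]
    wide = sel.pivot_table(
        index="subject_id", columns=["state", "channel"], values="value"
    )
    have_a = wide.get(state_a)
    have_b = wide.get(state_b)
    if have_a is None or have_b is None:
        raise ValueError(f"one of the states {states} has no rows")
    complete = wide.dropna().index
    dropped = set(wide.index) - set(complete)
    if dropped:
        warnings.warn(
            f"excluding subject(s) missing a state: {sorted(dropped)}", stacklevel=2
        )
    if len(complete) < 2:
        raise ValueError("need at least two subjects with both states")
    mat_a = wide.loc[complete, state_a]
    mat_b = wide.loc[complete, state_b]
    channels = [c for c in mat_a.columns if c in mat_b.columns]

    results = []
    for ch in channels:
        va, vb = mat_a[ch].to_numpy(), mat_b[ch].to_numpy()
        w, p = wilcoxon_signed_rank(va, vb)
        results.append(
            ComparisonResult(
                feature, band, "per_channel", str(ch), state_a, state_b,
                len(va), w, p,
                float(va.mean()), _sd(va), float(vb.mean()), _sd(vb),
                p < alpha,
            )
        )
    ma = mat_a[channels].mean(axis=1).to_numpy()
    mb = mat_b[channels].mean(axis=1).to_numpy()
    w, p = wilcoxon_signed_rank(ma, mb)
    results.append(
        ComparisonResult(
            feature, band, "whole_brain_mean", "", state_a, state_b,
            len(ma), w, p,
            float(ma.mean()), _sd(ma), float(mb.mean()), _sd(mb),
            p < alpha,
        )
    )
    return results


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    band: str,
    groups: tuple[str, str],
    state: str = "task",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Between-group contrast in one state.

    Whole-brain level: per-channel group means paired across channels,
    signed-rank over the channel pairs (the published procedure; n_pairs =
    number of channels). Per-channel level: subject values compared with an
    unpaired rank-sum test, labelled ``rank_sum``.
    """
    group_a, group_b = groups
    sel = _pivot(table, feature, band)
    sel = sel[(sel["state"] == state) & (sel["group"].isin(groups))]
    if sel.empty:
        raise ValueError(f"no rows for groups {groups} in state {state!r}")
    wide = sel.pivot_table(
        index=["group", "subject_id"], columns="channel", values="value"
    )
    try:
        mat_a = wide.loc[group_a].dropna(axis=1)
        mat_b = wide.loc[group_b].dropna(axis=1)
    except KeyError as exc:
        raise ValueError(f"group {exc} has no rows in state {state!r}") from exc
    if list(mat_a.columns) != list(mat_b.columns):
        raise ValueError(
            f"channel sets differ between groups: "
            f"{sorted(set(mat_a.columns) ^ set(mat_b.columns))}"
        )
    channels = list(mat_a.columns)

    results = []
    for ch in channels:
        va, vb = mat_a[ch].to_numpy(), mat_b[ch].to_numpy()
        u, p = rank_sum(va, vb)
        results.append(
            ComparisonResult(
                feature, band, "per_channel", str(ch), group_a, group_b,
                min(len(va), len(vb)), u, p,
                float(va.mean()), _sd(va), float(vb.mean()), _sd(vb),
                p < alpha, test_name="rank_sum",
            )
        )
    chan_means_a = mat_a.mean(axis=0).to_numpy()
    chan_means_b = mat_b.mean(axis=0).to_numpy()
    w, p = wilcoxon_signed_rank(chan_means_a, chan_means_b)
    results.append(
        ComparisonResult(
            feature, band, "whole_brain_mean", "", group_a, group_b,
            len(channels), w, p,
            float(chan_means_a.mean()), _sd(chan_means_a),
            float(chan_means_b.mean()), _sd(chan_means_b),
            p < alpha,
            test_name="wilcoxon_signed_rank_over_channels",
        )
    )
    return results


def group_summary(
    table: pd.DataFrame, feature: str, band: str, by: tuple[str, ...] = ("group", "state")
) -> pd.DataFrame:
    """Mean ± sd of a feature by grouping columns (generic summary op)."""
    sel = _pivot(table, feature, band)
    agg = sel.groupby(list(by))["value"].agg(["count", "mean", lambda v: _sd(v.to_numpy())])
    agg.columns = ["n", "mean", "sd"]
    return agg.reset_index()


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up procedure; returns a boolean rejection mask."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        mask[order[: np.max(np.nonzero(passed)[0]) + 1]] = True
    return mask


def results_to_dataframe(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclass_as_row(r) for r in results])


def dataclass_as_row(r: ComparisonResult) -> dict:
    return {
        "feature_name": r.feature_name,
        "band": r.band,
        "level": r.level,
        "channel": r.channel,
        "condition_a": r.condition_a,
        "condition_b": r.condition_b,
        "n_pairs": r.n_pairs,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "mean_a": r.mean_a,
        "sd_a": r.sd_a,
        "mean_b": r.mean_b,
        "sd_b": r.sd_b,
        "significant": r.significant,
        "test_name": r.test_name,
    }
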