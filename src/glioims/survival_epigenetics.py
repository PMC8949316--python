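"""Survival and epigenetic comparisons: Kaplan-Meier curves, two-group
log-rank tests on expression-defined groups, and one-way ANOVA with Tukey HSD
across molecular subtypes for expression and methylation values.

Estimation is delegated to lifelines (product-limit estimator, log-rank) and
scipy (ANOVA F, studentized-range Tukey HSD); this module adds the
expression-median grouping, tidy result containers and TSV-friendly tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "LogrankResult",
    "SubtypeComparison",
    "km_estimate",
    "survival_at",
    "logrank_two_groups",
    "median_split",
    "subtype_anova_tukey",
]


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``records`` needs ``time`` (days > 0) and ``event`` (True = death
    observed) columns. Returns a step function table with S(0) = 1 and drops
    only at event times.
    """
    records = _validate_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"].astype(bool))
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a km_estimate table at time t (right-continuous)."""
    eligible = km[km["time"] <= t]
    return float(eligible["survival"].iloc[-1]) if len(eligible) else 1.0


def median_split(values: pd.Series) -> pd.Series:
    """High/low grouping at the median; ties go to the low group."""
    return pd.Series(
        np.where(values > values.median(), "high", "low"),
        index=values.index,
        name="group",
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    groups: pd.Series
    km_curves: dict[str, pd.DataFrame]

    @property
    def n_per_group(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()


def logrank_two_groups(
    records: pd.DataFrame,
    split_values: pd.Series,
    event_col: str = "event",
) -> LogrankResult:
    """Two-group log-rank test with groups defined by a median split of
    ``split_values`` (typically one gene's expression across samples).

    Standard log-rank: at each event time the observed events per group are
    compared with their hypergeometric expectation; the statistic is
    chi-square on 1 df. With no events at all, p = 1 by convention.
    """
    records = _validate_records(records)
    common = records.index.intersection(split_values.index)
    if len(common) < len(records):
        records = records.loc[common]
    groups = median_split(split_values.loc[records.index])
    if groups.nunique() < 2:
        raise ValueError("median split produced a single group")

    time = records["time"]
    event = records[event_col].astype(bool)
    high, low = groups == "high", groups == "low"
    curves = {
        name: km_estimate(records[mask.values].assign(event=event[mask.values]))
        for name, mask in (("high", high), ("low", low))
    }
    if not event.any():
        return LogrankResult(chi2=0.0, p=1.0, groups=groups, km_curves=curves)

    res = logrank_test(
        time[high.values], time[low.values],
        event_observed_A=event[high.values],
        event_observed_B=event[low.values],
    )
    return LogrankResult(
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        groups=groups,
        km_curves=curves,
    )


@dataclass
class SubtypeComparison:
    """One-way ANOVA + Tukey HSD of one variable across subtypes."""

    means: pd.DataFrame       # subtype -> mean, sd, n
    f_stat: float
    p: float
    tukey_p: pd.DataFrame     # symmetric pairwise adjusted p matrix

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        pairs = []
        cols = list(self.tukey_p.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if self.tukey_p.loc[a, b] < alpha:
                    pairs.append((a, b))
        return pairs


def subtype_anova_tukey(
    values: pd.Series, subtypes: pd.Series
) -> SubtypeComparison:
    """Ordinary one-way ANOVA with post-hoc Tukey HSD across subtypes.

    Applied identically to expression values and methylation betas. Requires
    at least two groups with at least two values each.
    """
    common = values.index.intersection(subtypes.index)
    values, subtypes = values.loc[common], subtypes.loc[common]
    levels = sorted(subtypes.unique())
    if len(levels) < 2:
        raise ValueError("need at least two subtypes")
    groups = [values[subtypes == s].to_numpy(float) for s in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two values per subtype")

    f_stat, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    tukey_p = pd.DataFrame(tukey.pvalue, index=levels, columns=levels)

    means = pd.DataFrame(
        {
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) for g in groups],
            "n": [len(g) for g in groups],
        },
        index=levels,
    )
    return SubtypeComparison(
        means=means, f_stat=float(f_stat), p=float(p), tukey_p=tukey_p
    )
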