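"""Kaplan-Meier estimation and log-rank comparison of sorted subpopulations.

The decile-sorted subpopulations are followed after sorting; deaths are
recorded daily and individuals that escape or burst are censored.
Estimation is delegated to lifelines; this module adds the table contract
(death/censor records per individual and group), median extraction from the
product-limit curve, and the percent median-lifespan difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class SurvivalCurve:
    label: str
    times: np.ndarray          # event/censor times, ascending (0 included)
    survival: np.ndarray       # S(t), starts at 1
    at_risk: np.ndarray
    n_events: int


def _group_arrays(table: pd.DataFrame, group: str):
    sub = table.loc[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present in survival table")
    durations = sub["day"].to_numpy(dtype=float)
    observed = (sub["event"] == "death").to_numpy()
    return durations, observed


def km_curve(table: pd.DataFrame, group: str) -> SurvivalCurve:
    """Product-limit survival curve for one group.

    Censored individuals leave the risk set at their censor time; at tied
    days, deaths are processed before censorings (standard convention).
    Raises if the group has no death events.
    """
    durations, observed = _group_arrays(table, group)
    if not observed.any():
        raise ValueError(f"group {group!r} has no death events")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed, label=group)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf[group].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(label=group, times=times, survival=surv,
                         at_risk=at_risk, n_events=int(observed.sum()))


def logrank(table: pd.DataFrame, group_a: str, group_b: str):
    """Mantel-Cox log-rank test between two groups: (chi2, p)."""
    if group_a == group_b:
        raise ValueError("log-rank requires two distinct groups")
    da, oa = _group_arrays(table, group_a)
    db, ob = _group_arrays(table, group_b)
    if not oa.any() or not ob.any():
        raise ValueError("both groups need at least one death event")
    res = logrank_test(da, db, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


def median_survival(curve: SurvivalCurve) -> float:
    """First time at which S(t) <= 0.5; error if the curve never reaches it."""
    below = curve.survival <= 0.5
    if not below.any():
        raise ValueError(f"median undefined: S never reaches 0.5 for {curve.label!r}")
    return float(curve.times[np.argmax(below)])


def median_diff(curve_a: SurvivalCurve, curve_b: SurvivalCurve) -> float:
    """Percent difference in median lifespan, 100*(medA - medB)/medB."""
    ma, mb = median_survival(curve_a), median_survival(curve_b)
    return 100.0 * (ma - mb) / mb


def compare_groups(table: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """KM medians, log-rank chi2/p, and percent median difference (A vs B)."""
    ca, cb = km_curve(table, group_a), km_curve(table, group_b)
    chi2, p = logrank(table, group_a, group_b)
    ma, mb = median_survival(ca), median_survival(cb)
    return {
        "group_a": group_a, "group_b": group_b,
        "median_a": ma, "median_b": mb,
        "median_pct_diff": 100.0 * (ma - mb) / mb,
        "chi2": chi2, "p": p,
        "n_a": int(len(table.loc[table["group"] == group_a])),
        "n_b": int(len(table.loc[table["group"] == group_b])),
    }
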