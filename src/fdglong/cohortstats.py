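"""Cohort-level categorical and time-to-event statistics.

Baseline group comparisons and the conversion analysis use a Pearson
chi-square on 2x2 count tables *without* continuity correction (the
convention that reproduces the printed p-values of the emulated study
from its printed counts).  Conversion to dementia is analysed as a
survival problem: Kaplan-Meier curves per group and a Fleming-Harrington
weighted log-rank test with weights S(t-)^p (1 - S(t-))^q.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .phantom import SubjectRecord

__all__ = [
    "chi2_2x2",
    "survival_records",
    "kaplan_meier",
    "fleming_harrington_test",
]


def chi2_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    tail: str = "two",
    direction: str = "greater",
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df=1) on [[a,b],[c,d]].

    ``tail='one'`` halves the two-sided p when the observed effect lies
    in the tested direction (``direction='greater'``: row-1 event
    proportion above row-2's), and reports ``1 - p/2`` otherwise.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    if tail not in ("one", "two"):
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")

    chi2, p_two, _, _ = stats.chi2_contingency(counts, correction=False)
    if tail == "two":
        return float(chi2), float(p_two)
    observed = a / (a + b) - c / (c + d)
    tested_sign = 1.0 if direction == "greater" else -1.0
    if observed * tested_sign >= 0:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return float(chi2), float(p_one)


def survival_records(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Conversion outcomes as a survival table (group, time, event)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": ["carrier" if s.carrier else "non-carrier" for s in subjects],
            "time_months": [s.event_or_censor_month for s in subjects],
            "event": [s.converted for s in subjects],
        }
    )


def kaplan_meier(records: pd.DataFrame, group: str) -> KaplanMeierFitter:
    """Product-limit survival estimate for one group with Greenwood-based CI.

    Survival is "not yet converted"; censored subjects exit the risk set
    at their censoring time and the curve starts at 1.0.
    """
    sub = records[records["group"] == group]
    if sub.empty:
        raise ValueError(f"no records in group {group!r}")
    kmf = KaplanMeierFitter(label=group)
    kmf.fit(sub["time_months"], event_observed=sub["event"])
    return kmf


def fleming_harrington_test(
    records: pd.DataFrame,
    weight_p: float = 1.0,
    weight_q: float = 0.0,
) -> tuple[float, float]:
    """Weighted log-rank test between the two groups.

    Weights are S(t-)^p (1 - S(t-))^q with S the pooled Kaplan-Meier
    left limit; ``p = q = 0`` reduces to the standard log-rank test.
    Returns (chi-square statistic, df=1 p-value).
    """
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if int(records["event"].sum()) == 0:
        raise ValueError("no events observed; weighted log-rank test undefined")
    g1 = records[records["group"] == groups[0]]
    g2 = records[records["group"] == groups[1]]
    res = logrank_test(
        g1["time_months"],
        g2["time_months"],
        event_observed_A=g1["event"].astype(bool),
        event_observed_B=g2["event"].astype(bool),
        weightings="fleming-harrington",
        p=weight_p,
        q=weight_q,
    )
    return float(res.test_statistic), float(res.p_value)
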