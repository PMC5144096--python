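"""Kaplan-Meier estimation, two-group log-rank test and O/E hazard ratio.

The hazard ratio is the Mantel-Haenszel-type observed/expected estimate
HR = (O1/E1)/(O2/E2) with 95% CI exp(ln HR +/- 1.96*sqrt(1/E1 + 1/E2));
a closed-form approximation to the Cox partial-likelihood estimate that is
standard in survival screening tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

__all__ = [
    "LogRankResult",
    "read_survival",
    "dichotomize_by_median",
    "km_curve",
    "logrank",
]

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float
    hr: float           # (O_low/E_low) / (O_high/E_high)
    ci95: tuple[float, float]
    o1: float
    e1: float
    o2: float
    e2: float


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 (censored) or 1 (event)")
    return df


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Split samples at the median: values <= median are 'low', above 'high'.

    Ties at the median go to the low group, so an odd-sized sample puts its
    median observation in 'low'.  All-equal input yields a single group,
    which downstream two-group tests reject.
    """
    med = float(values.median())
    return pd.Series(
        np.where(values.to_numpy(dtype=float) <= med, LOW, HIGH),
        index=values.index,
        name="group",
    )


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Returns one row per distinct event time (time, n_at_risk, n_events,
    survival); the curve is right-continuous and non-increasing with
    S(0) = 1.  With no censoring it reduces to the empirical survival
    function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) != len(e):
        raise ValueError("times and events must have equal length")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n_at_risk = len(t)
    i = 0
    while i < len(t):
        ti = t[i]
        j = i
        d = 0
        while j < len(t) and t[j] == ti:
            d += e[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            rows.append((ti, n_at_risk, d, s))
        n_at_risk -= j - i
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> LogRankResult:
    """Two-group log-rank test with tied event times pooled per time point.

    Group 1 is 'low', group 2 'high'.  At each distinct event time with d
    pooled events and n at risk (n_g per group), E_g accrues d*n_g/n and
    the hypergeometric variance term d*(n1/n)*(n2/n)*(n-d)/(n-1) is summed.
    Raises when a group is empty, no events are observed, or an expected
    count is zero.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (len(t) == len(e) == len(g)):
        raise ValueError("times, events, groups must have equal length")
    labels = set(g.tolist())
    if labels != {LOW, HIGH}:
        raise ValueError(
            f"need both groups {{'low', 'high'}} non-empty, got labels {sorted(labels)}"
        )
    if e.sum() == 0:
        raise ValueError("no events observed in either group")

    o1 = e2 = o2 = e1 = 0.0
    var = 0.0
    event_times = np.unique(t[e == 1])
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == LOW)).sum())
        n2 = n - n1
        at_ti = (t == ti) & (e == 1)
        d = int(at_ti.sum())
        d1 = int((at_ti & (g == LOW)).sum())
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if e1 == 0 or e2 == 0:
        raise ValueError("expected event count is zero in one group")
    if var == 0:
        raise ValueError("log-rank variance is zero (degenerate risk sets)")
    chi2 = (o1 - e1) ** 2 / var
    p = float(_chi2.sf(chi2, df=1))
    if o1 == 0 or o2 == 0:
        hr = float("inf") if o2 == 0 else 0.0
        ci = (float("nan"), float("nan"))
    else:
        hr = (o1 / e1) / (o2 / e2)
        half = 1.96 * np.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    return LogRankResult(float(chi2), p, float(hr), ci, o1, e1, o2, e2)
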