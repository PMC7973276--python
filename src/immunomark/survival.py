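"""Kaplan-Meier estimation, log-rank testing, and quartile stratification.

The hazard ratio is the observed/expected (Mantel-Haenszel) log-rank
estimator, HR = (O_a / E_a) / (O_b / E_b), with the 95% interval
exp(ln HR +/- 1.96 sqrt(1/E_a + 1/E_b)); no proportional-hazards model
is fit. Kaplan-Meier curves come from the product-limit estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import Cohort

__all__ = [
    "SurvRecord",
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_hr",
    "quartile_groups",
    "parse_survival_records",
    "days_to_months",
]


@dataclass(frozen=True)
class SurvRecord:
    time: float   # months; 0 allowed but flagged with a warning
    event: bool   # True = death/progression observed
    arm: str | None = None


def days_to_months(days: float) -> float:
    """Convert follow-up days to months (x 12 / 365.25)."""
    return days * 12.0 / 365.25


def _check_times(records: Sequence[SurvRecord]) -> None:
    if not records:
        raise ValueError("no survival records")
    for r in records:
        if r.time < 0:
            raise ValueError(f"negative survival time: {r.time}")
        if r.time == 0:
            warnings.warn("survival record with time 0 retained", stacklevel=3)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: S steps down only at event times."""

    times: np.ndarray      # ascending event times
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # number at risk just before each event time

    def s_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over the records."""
    _check_times(records)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    hr: float | None
    ci95: tuple[float, float] | None


def logrank_hr(arm_a: Sequence[SurvRecord],
               arm_b: Sequence[SurvRecord]) -> LogRankResult:
    """Mantel-Haenszel log-rank test with the O/E hazard ratio.

    At each distinct event time a 2x2 table contributes the expected
    events and hypergeometric variance; chi2 = (O_a - E_a)^2 / V on one
    degree of freedom. An arm with no expected events leaves the hazard
    ratio undefined (``None``) while the test p-value is still reported
    when the variance permits.
    """
    _check_times(arm_a)
    _check_times(arm_b)
    t_a = np.array([r.time for r in arm_a], dtype=float)
    e_a_obs = np.array([r.event for r in arm_a], dtype=bool)
    t_b = np.array([r.time for r in arm_b], dtype=float)
    e_b_obs = np.array([r.event for r in arm_b], dtype=bool)

    event_times = np.unique(np.concatenate([t_a[e_a_obs], t_b[e_b_obs]]))
    O_a = float(e_a_obs.sum())
    O_b = float(e_b_obs.sum())
    E_a = E_b = V = 0.0
    for t in event_times:
        n_a = float((t_a >= t).sum())
        n_b = float((t_b >= t).sum())
        d_a = float(((t_a == t) & e_a_obs).sum())
        d_b = float(((t_b == t) & e_b_obs).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n <= 0:
            continue
        E_a += d * n_a / n
        E_b += d * n_b / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if V > 0:
        chi2 = (O_a - E_a) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if E_a > 0 and E_b > 0 and O_a > 0 and O_b > 0:
        hr = (O_a / E_a) / (O_b / E_b)
        half = 1.96 * np.sqrt(1.0 / E_a + 1.0 / E_b)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    else:
        hr, ci = None, None
    return LogRankResult(chi2=float(chi2), p=p, o_a=O_a, e_a=E_a,
                         o_b=O_b, e_b=E_b, hr=hr, ci95=ci)


def quartile_groups(expression: Sequence[float],
                    ids: Sequence | None = None,
                    n_per_group: int | None = None) -> tuple[tuple, tuple]:
    """Bottom/top expression quartile sample ids.

    Group size defaults to round-half-up(n / 4) (378 samples -> 95 per
    group). Ties at the boundary are resolved by stable input order.
    """
    v = np.asarray(expression, dtype=float)
    n = v.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for quartile groups")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids, dtype=object)
    size = n_per_group if n_per_group is not None else int(np.floor(n / 4.0 + 0.5))
    if size > n // 2:
        raise ValueError(f"group size {size} exceeds half the cohort ({n})")
    order = np.argsort(v, kind="stable")
    low = tuple(ids[order[:size]])
    high = tuple(ids[order[n - size:]])
    return low, high


def parse_survival_records(cohort: Cohort, endpoint: str = "pfs",
                           use_alt_months: bool = False) -> list[SurvRecord]:
    """Cohort metadata as survival records: event = not censored."""
    if endpoint not in ("pfs", "os"):
        raise ValueError(f"endpoint must be 'pfs' or 'os', got {endpoint!r}")
    records = []
    for rec in cohort.records:
        sv = rec.pfs if endpoint == "pfs" else rec.os
        months = sv.months
        if use_alt_months and sv.alt_months is not None:
            months = sv.alt_months
        records.append(SurvRecord(time=months, event=not sv.censored,
                                  arm=rec.group))
    return records
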