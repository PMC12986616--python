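"""Cohort survival: Kaplan-Meier curves, log-rank comparison, hazard ratio.

Only knockout cohorts enter the survival analysis: every KO animal dies
prematurely (all records are events, no censoring), while wild-type
littermates are euthanized on their paired KO's death day and are excluded.
With no censoring, the Kaplan-Meier mean equals the arithmetic mean of the
death ages, which is asserted rather than assumed.

Kaplan-Meier estimation and the log-rank (Mantel-Cox) test are delegated to
lifelines; the Mantel-Haenszel hazard ratio — the ratio of
observed/expected event ratios from the pooled log-rank table, with a
log-scale confidence interval — is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


class UndefinedHazardError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time_days: float
    event: bool = True

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError(f"survival time must be positive, got {self.time_days}")


@dataclass
class KmResult:
    survival: pd.DataFrame  # columns: time, S
    mean: float
    median: float


def _times_events(records: Sequence[SurvivalRecord] | np.ndarray):
    if len(records) == 0:
        raise ValueError("survival analysis needs >= 1 record")
    if isinstance(records[0], SurvivalRecord):
        t = np.array([r.time_days for r in records], dtype=float)
        e = np.array([r.event for r in records], dtype=bool)
    else:
        t = np.asarray(records, dtype=float)
        e = np.ones(len(t), dtype=bool)
    return t, e


def km_curve(records: Sequence[SurvivalRecord] | np.ndarray) -> KmResult:
    """Product-limit survival curve with mean and median survival.

    The mean is the area under the step function restricted to the last
    observed time; with no censoring this equals the arithmetic mean of the
    death ages exactly.
    """
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "S"]
    # restricted mean: integral of S(t) dt up to the last time
    times = sf["time"].to_numpy()
    s_vals = sf["S"].to_numpy()
    mean = float(np.sum(s_vals[:-1] * np.diff(times))) if len(times) > 1 else float(times[-1])
    # S(0)=1 row is included by lifelines; if not starting at 0, prepend
    if times[0] != 0:
        mean += float(times[0])
    return KmResult(survival=sf, mean=mean, median=float(kmf.median_survival_time_))


def logrank(
    group_a: Sequence[SurvivalRecord] | np.ndarray,
    group_b: Sequence[SurvivalRecord] | np.ndarray,
) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) chi-square statistic and p-value."""
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def logrank_table(
    ta: np.ndarray, ea: np.ndarray, tb: np.ndarray, eb: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Observed/expected/variance accumulation over pooled event times.

    Returns (O_A, E_A, O_B, E_B, V) from the standard 2x2 table at each
    distinct pooled event time (hypergeometric expectation and variance).
    """
    o_a = e_a = o_b = e_b = v = 0.0
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    is_a = np.r_[np.ones(len(ta), bool), np.zeros(len(tb), bool)]
    for t in np.unique(all_t[all_e]):
        at_risk = all_t >= t
        n = at_risk.sum()
        n_a = (at_risk & is_a).sum()
        d = (all_e & (all_t == t)).sum()
        d_a = (all_e & (all_t == t) & is_a).sum()
        o_a += d_a
        o_b += d - d_a
        e_a += d * n_a / n
        e_b += d * (n - n_a) / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_a, e_a, o_b, e_b, v


def hazard_ratio_mh(
    group_a: Sequence[SurvivalRecord] | np.ndarray,
    group_b: Sequence[SurvivalRecord] | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel hazard ratio (O_A/E_A)/(O_B/E_B) with log-scale CI.

    The CI uses the standard error sqrt(1/E_A + 1/E_B) on the log scale.
    Satisfies HR(A, B) = 1 / HR(B, A). Raises when a group has zero
    expected events.
    """
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    o_a, e_a, o_b, e_b, _ = logrank_table(ta, ea, tb, eb)
    if e_a <= 0 or e_b <= 0:
        raise UndefinedHazardError("zero expected events in a group; HR undefined")
    if o_a == 0 or o_b == 0:
        raise UndefinedHazardError("zero observed events in a group; HR undefined")
    hr = (o_a / e_a) / (o_b / e_b)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1.0 / e_a + 1.0 / e_b)
    ci = (float(hr * np.exp(-z * se)), float(hr * np.exp(z * se)))
    return float(hr), ci
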