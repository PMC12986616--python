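"""The study's statistical battery for binned endpoints.

Two-way ANOVA (Type III sums of squares, classical eta-squared) with Sidak
post hoc adjustment, Welch's unequal-variance t-test, Pearson chi-square on
count tables, and Kruskal-Wallis with Dunn's post hoc comparisons. A
Shapiro-Wilk normality gate routes an endpoint to the rank-based battery
when normality is rejected.

The ANOVA is computed directly from sum-coded design matrices via least
squares: Type III SS for an effect is the residual-SS increase when that
effect's columns are dropped from the full model. Classical eta-squared is
SS_effect / SS_total. Mortality makes the designs unbalanced, which is why
Type III (rather than sequential) sums of squares are used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Two-way ANOVA, Type III, classical eta^2


def _sum_code(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    cols = []
    ref = levels[-1]
    for lev in levels[:-1]:
        c = np.where(values == lev, 1.0, 0.0) - np.where(values == ref, 1.0, 0.0)
        cols.append(c)
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class AnovaEffect:
    ss: float
    df: int
    F: float
    p: float
    eta_sq: float


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> dict[str, AnovaEffect]:
    """Type III two-way ANOVA with classical eta-squared per effect.

    Returns effects keyed 'A', 'B', 'A:B', and 'residual' (F and p are NaN
    for the residual row). Unbalanced designs are supported; every factor
    needs at least two levels and every occupied cell at least one
    observation.
    """
    y = data[value].to_numpy(dtype=float)
    a = data[factor_a].to_numpy()
    b = data[factor_b].to_numpy()
    if not np.isfinite(y).all():
        raise DegenerateDataError("values must be finite")
    lev_a, lev_b = np.unique(a), np.unique(b)
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise DesignError(
            f"each factor needs >= 2 levels (got {len(lev_a)} x {len(lev_b)})"
        )
    Xa = _sum_code(lev_a, a)
    Xb = _sum_code(lev_b, b)
    Xab = np.column_stack(
        [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    )
    ones = np.ones((len(y), 1))
    full = np.column_stack([ones, Xa, Xb, Xab])
    n, p_full = full.shape
    if n <= p_full:
        raise DesignError(f"not enough observations ({n}) for the design ({p_full})")
    rss_full = _rss(full, y)
    df_resid = n - np.linalg.matrix_rank(full)
    ms_resid = rss_full / df_resid
    ss_total = float(((y - y.mean()) ** 2).sum())

    blocks = {
        "A": (Xa, np.column_stack([ones, Xb, Xab])),
        "B": (Xb, np.column_stack([ones, Xa, Xab])),
        "A:B": (Xab, np.column_stack([ones, Xa, Xb])),
    }
    out: dict[str, AnovaEffect] = {}
    for name, (block, reduced) in blocks.items():
        ss = _rss(reduced, y) - rss_full
        df = block.shape[1]
        F = (ss / df) / ms_resid if ms_resid > 0 else np.inf
        p = float(stats.f.sf(F, df, df_resid)) if np.isfinite(F) else 0.0
        out[name] = AnovaEffect(
            ss=float(ss), df=df, F=float(F), p=p,
            eta_sq=float(ss / ss_total) if ss_total > 0 else 0.0,
        )
    out["residual"] = AnovaEffect(
        ss=rss_full, df=int(df_resid), F=float("nan"), p=float("nan"),
        eta_sq=float(rss_full / ss_total) if ss_total > 0 else 0.0,
    )
    return out


# ---------------------------------------------------------------------------
# Post hoc adjustments and pairwise tests


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = 1.0 - (1.0 - p_arr) ** m
    adj = np.clip(adj, 0.0, 1.0)
    return float(adj) if np.isscalar(p) else adj


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unpaired two-tailed t-test: (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise DegenerateDataError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero marginal in the contingency table")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn's post hoc


@dataclass
class DunnComparison:
    group_i: str
    group_j: str
    z: float
    p_raw: float
    p_adj: float


def kruskal_dunn(
    groups: dict[str, np.ndarray], adjust: str = "sidak"
) -> tuple[float, float, list[DunnComparison]]:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise comparisons.

    Dunn's z for groups i, j uses pooled mid-ranks:
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), with the
    tie term T = sum(t^3 - t) / (12 (N - 1)). Pairwise p-values are
    two-sided normal and family-wise adjusted (Sidak by default,
    'bonferroni' or 'none' available).
    """
    names = list(groups)
    if len(names) < 2:
        raise DesignError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(a) < 1 for a in arrays):
        raise DesignError("every group needs >= 1 value")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    ranks = stats.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    idx = np.cumsum([0] + sizes)
    mean_ranks = {
        names[i]: ranks[idx[i]: idx[i + 1]].mean() for i in range(len(names))
    }
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(names)), 2))
    comparisons = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se if se > 0 else 0.0
        p_raw = float(2 * stats.norm.sf(abs(z)))
        if adjust == "sidak":
            p_adj = float(sidak_adjust(p_raw, len(pairs)))
        elif adjust == "bonferroni":
            p_adj = float(min(1.0, p_raw * len(pairs)))
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        comparisons.append(
            DunnComparison(names[i], names[j], float(z), p_raw, p_adj)
        )
    return float(h), float(p), comparisons


def normality_gate(samples: list[np.ndarray], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk screen: True when every group is consistent with normality.

    Groups smaller than 3 cannot be tested and pass by default; endpoints
    failing the gate are routed to the rank-based battery.
    """
    for s in samples:
        s = np.asarray(s, dtype=float)
        if len(s) < 3 or np.ptp(s) == 0:
            continue
        if stats.shapiro(s).pvalue < alpha:
            return False
    return True
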