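"""Disease-free survival comparison and categorical association tests.

Kaplan-Meier product-limit curves, the multi-group log-rank test, and
Pearson's chi-squared test with a simulated p-value (tables drawn
uniformly at fixed margins, Patefield-style) are implemented from their
definitions; they back the subtype-level clinical comparisons (relapse
risk, tumor-size association).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def km_estimate(times, events, group=None) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate, optionally per group.

    Ties are handled by simultaneous events: at each distinct event
    time t with d events among n at risk, the survival estimate is
    multiplied by (1 - d/n). Censoring at t removes subjects from the
    risk set after t. Returns long-format rows (group, time, at_risk,
    events, censored, survival).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if group is None:
        group = np.full(times.size, "all")
    group = np.asarray(group)
    rows = []
    for g in pd.unique(group):
        sel = group == g
        t, e = times[sel], events[sel].astype(int)
        if t.size == 0:
            raise ValueError(f"empty group {g!r}")
        surv = 1.0
        for tt in np.unique(t):
            at_risk = int((t >= tt).sum())
            d = int(((t == tt) & (e == 1)).sum())
            c = int(((t == tt) & (e == 0)).sum())
            if d > 0:
                surv *= 1.0 - d / at_risk
            rows.append(
                {"group": g, "time": float(tt), "at_risk": at_risk,
                 "events": d, "censored": c, "survival": surv}
            )
    return pd.DataFrame(rows)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test.

    At each distinct event time, the observed events per group are
    compared to the expectation under the hypergeometric null given the
    risk sets; the quadratic form of (O - E) over the summed covariance
    (first g-1 groups) is chi-squared with g-1 degrees of freedom.

    Returns (chi_square, df, p_value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least two groups")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    event_times = np.unique(times[events == 1])
    oe = np.zeros(g)
    cov = np.zeros((g, g))
    for tt in event_times:
        at_risk = times >= tt
        n = int(at_risk.sum())
        d = int(((times == tt) & (events == 1)).sum())
        if n <= 1:
            continue
        nj = np.array([int((at_risk & (groups == lv)).sum()) for lv in levels],
                      dtype=float)
        dj = np.array(
            [int(((times == tt) & (events == 1) & (groups == lv)).sum())
             for lv in levels], dtype=float)
        ej = d * nj / n
        oe += dj - ej
        factor = d * (n - d) / (n - 1) if n > 1 else 0.0
        cov += factor * (np.diag(nj / n) - np.outer(nj / n, nj / n))
    sub = cov[: g - 1, : g - 1]
    vec = oe[: g - 1]
    try:
        stat = float(vec @ np.linalg.solve(sub, vec))
    except np.linalg.LinAlgError:
        stat = float(vec @ np.linalg.pinv(sub) @ vec)
    df = g - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def chisq_simulated(table, n_sim: int = 2000, seed: int = 0):
    """Pearson chi-squared with Monte-Carlo p at fixed margins.

    ``p = (1 + #{simulated X^2 >= observed}) / (1 + n_sim)`` with tables
    drawn uniformly given both margins (Patefield's algorithm via
    scipy.stats.random_table). Zero-margin rows/columns are dropped with
    a warning. Returns (statistic, p_simulated).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (tab < 0).any() or not np.array_equal(tab, np.round(tab)):
        raise ValueError("table must hold non-negative integer counts")
    row_ok = tab.sum(axis=1) > 0
    col_ok = tab.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns")
        tab = tab[row_ok][:, col_ok]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("table needs >=2 non-empty rows and columns")
    rows, cols = tab.sum(axis=1), tab.sum(axis=0)
    total = tab.sum()
    expected = np.outer(rows, cols) / total
    stat = float(((tab - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    dist = stats.random_table(rows.astype(int), cols.astype(int))
    sims = dist.rvs(n_sim, method="patefield", random_state=rng)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (1 + int((sim_stats >= stat - 1e-12).sum())) / (1 + n_sim)
    return stat, float(p)


def dichotomize_size(size_cm, threshold: float = 2.5, boundary_larger: bool = True):
    """Split tumor sizes at a threshold (default 2.5 cm).

    The exact boundary value is assigned to the "larger" class by
    default (``boundary_larger``); missing sizes give missing labels.
    """
    s = pd.Series(size_cm, dtype=float)
    labels = pd.Series(pd.NA, index=s.index, dtype="object")
    if boundary_larger:
        labels[s >= threshold] = f">={threshold}cm"
        labels[s < threshold] = f"<{threshold}cm"
    else:
        labels[s > threshold] = f">{threshold}cm"
        labels[s <= threshold] = f"<={threshold}cm"
    return labels
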