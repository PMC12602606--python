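"""Shared statistical primitives used across the pipeline.

The Benjamini-Hochberg adjustment and the one-sided Fisher
over-representation test are implemented once here and reused by every
stage (differential methylation, differential expression, integration,
enrichment) so that all reported adjusted p-values share one routine.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    Built from the definition: sort ascending, multiply p_(i) by m/i,
    take the running minimum from the largest rank down, clip at 1.
    NaN entries are excluded from the family (m) and returned as NaN.

    Parameters
    ----------
    pvalues : array-like of float
        Raw p-values in [0, 1]; NaN allowed.

    Returns
    -------
    numpy.ndarray
        Adjusted p-values, same order and length as the input.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def fisher_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test on a 2x2 table.

    Table layout::

        in category      not in category
        a (selected)     b (selected)
        c (background)   d (background)

    The p-value is the hypergeometric upper tail P(X >= a) where X counts
    selected items falling in the category, conditioning on all margins.
    The odds ratio is the sample odds ratio (a*d)/(b*c); when any cell is
    zero a 0.5 continuity correction is added to every cell.

    Returns
    -------
    (odds_ratio, p_value)
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table cells must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    # X ~ Hypergeom(M=n, n=a+b draws, K=a+c in category)
    p = float(stats.hypergeom.sf(a - 1, n, a + c, a + b))
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), min(p, 1.0)


def overrepresentation_table(
    selected: set, universe_categories: "pd.Series"
) -> pd.DataFrame:
    """Per-category one-sided Fisher over-representation analysis.

    Parameters
    ----------
    selected : set
        Identifiers of the selected items (e.g. DMP probe ids, DEG gene
        ids); must be a subset of the universe index.
    universe_categories : pandas.Series
        Index = item id for the whole tested universe, values = category
        label (chromatin state, gene-set name after expansion, ...).

    Returns
    -------
    pandas.DataFrame
        One row per category with columns ``n_selected``, ``n_universe``,
        ``odds_ratio``, ``p_value``, ``p_adjusted`` (BH across
        categories), sorted by p-value.
    """
    universe = set(universe_categories.index)
    extra = set(selected) - universe
    if not universe:
        raise ValueError("empty universe")
    if extra:
        raise ValueError(
            f"{len(extra)} selected items missing from universe, e.g. "
            f"{sorted(extra)[:3]}"
        )
    n_sel = int(universe_categories.index.isin(selected).sum())
    n_tot = len(universe_categories)
    rows = []
    for state, members in universe_categories.groupby(universe_categories).groups.items():
        k_state = len(members)
        a = int(pd.Index(members).isin(selected).sum())
        b = n_sel - a
        c = k_state - a
        d = n_tot - k_state - b
        orr, p = fisher_one_sided(a, b, c, d)
        rows.append(
            {
                "category": state,
                "n_selected": a,
                "n_universe": k_state,
                "odds_ratio": orr,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
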