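"""Promoter methylation <-> expression anti-correlation screen.

For each significant DEG and each probe annotated to an active or weak
promoter of that gene, the Spearman correlation between the probe's
M-values and the gene's variance-stabilized expression is computed
across the shared samples. Pairs with rho < -0.6 and BH-adjusted
p < 0.05 are flagged as candidate epigenetically regulated genes.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import PROMOTER_STATES

DEFAULT_RHO = -0.6
DEFAULT_P_ADJ = 0.05
EXACT_P_MAX_N = 9


def promoter_probe_pairs(manifest: pd.DataFrame, deg_table: pd.DataFrame) -> list:
    """(gene, probe) pairs for significant DEGs with promoter probes.

    A pair is emitted when the gene is flagged ``significant`` in
    ``deg_table`` and the probe's chromatin state is an active or weak
    promoter linked to that gene; a gene with several promoter probes
    yields several pairs.
    """
    degs = set(deg_table.index[deg_table["significant"]])
    if not degs:
        warnings.warn("no significant DEGs; promoter pair list is empty")
        return []
    prom = manifest[
        manifest["state"].isin(PROMOTER_STATES) & manifest["gene"].notna()
    ]
    pairs = [
        (gene, probe)
        for gene, probe in zip(prom["gene"], prom["probe_id"])
        if gene in degs
    ]
    return sorted(pairs)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return np.nan
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho uses mid-ranks for ties. For n <= 9 complete pairs the p-value
    is exact: the proportion of all n! permutations of y whose |rho|
    reaches |rho_observed| (ties included, so the null distribution is
    conditioned on both tie patterns). For larger n the usual
    t-approximation t = rho * sqrt((n-2) / (1-rho^2)) is used.

    Pairs with a missing value in either vector are removed first;
    at least 4 complete pairs are required. A constant vector makes rho
    undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >=4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rho = _spearman_rho(x, y)
    if n <= EXACT_P_MAX_N:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        rx_c = rx - rx.mean()
        denom_x = float(rx_c @ rx_c)
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        ry_c_mean = ry.mean()
        denom_y = float(((ry - ry_c_mean) ** 2).sum())
        norm = math.sqrt(denom_x * denom_y)
        for perm in permutations(ry):
            r = (rx_c @ (np.asarray(perm) - ry_c_mean)) / norm
            total += 1
            if abs(r) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def anticorrelation_screen(
    m_matrix: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    pairs: list,
    deg_table: pd.DataFrame | None = None,
    rho_threshold: float = DEFAULT_RHO,
    p_adj_threshold: float = DEFAULT_P_ADJ,
) -> pd.DataFrame:
    """Spearman screen over (gene, probe) pairs with pooled BH adjustment.

    ``m_matrix`` (probes x samples) and ``expr_matrix`` (genes x
    samples) must be sample-aligned (same columns, same order; use
    ``align_omics``). A pair ``passes`` iff rho < ``rho_threshold``
    (strict) and BH-adjusted p < ``p_adj_threshold``; the BH family is
    all tested pairs pooled. The ``direction`` column carries the
    gene's DE direction when ``deg_table`` is given.

    Returns the association table plus a ``summary`` attr with the
    number of distinct up- and down-regulated genes having at least one
    passing probe.
    """
    if list(m_matrix.columns) != list(expr_matrix.columns):
        raise ValueError("matrices are not sample-aligned; use align_omics")
    rows = []
    skipped = []
    for gene, probe in pairs:
        if probe not in m_matrix.index or gene not in expr_matrix.index:
            skipped.append((gene, probe, "missing feature"))
            continue
        try:
            rho, p = spearman(m_matrix.loc[probe].to_numpy(),
                              expr_matrix.loc[gene].to_numpy())
        except ValueError as exc:
            skipped.append((gene, probe, str(exc)))
            continue
        rows.append({"gene_id": gene, "probe_id": probe, "rho": rho,
                     "p_value": p})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} pairs: {skipped[:3]}")
    table = pd.DataFrame(rows, columns=["gene_id", "probe_id", "rho", "p_value"])
    if table.empty:
        table["p_adjusted"] = []
        table["direction"] = []
        table["passes"] = []
        table.attrs["summary"] = {"up": 0, "down": 0}
        return table
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    if deg_table is not None:
        lfc = deg_table["log2_fold_change"].reindex(table["gene_id"]).to_numpy()
        table["direction"] = np.where(lfc >= 0, "up", "down")
    else:
        table["direction"] = "na"
    table["passes"] = (table["rho"] < rho_threshold) & (
        table["p_adjusted"] < p_adj_threshold
    )
    passing = table[table["passes"]]
    table.attrs["summary"] = {
        "up": int(passing.loc[passing["direction"] == "up", "gene_id"].nunique()),
        "down": int(passing.loc[passing["direction"] == "down", "gene_id"].nunique()),
    }
    return table
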