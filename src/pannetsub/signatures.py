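"""Rank-sum signature scoring and gene-set enrichment.

The signature score (used for MLP1-style metastasis signatures) ranks
samples per gene (ascending, mid-ranks for ties) and sums those ranks
over the signature genes, so a high score means coordinately high
expression of the signature. Preranked GSEA follows the weighted
Kolmogorov-Smirnov running-sum statistic with gene-label permutation
p-values; over-representation of DEG lists in gene sets reuses the
shared one-sided Fisher routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, fisher_one_sided
from .io import GeneSetCollection


def signature_score(expr: pd.DataFrame, genes, name: str = "signature") -> pd.DataFrame:
    """Per-sample sum of gene-wise across-sample ranks.

    For each signature gene present in ``expr`` (genes x samples),
    samples are ranked ascending with mid-ranks for ties; a sample's
    score is the sum of its ranks over the signature genes, so for g
    genes and n samples the score lies in [g, g*n].
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.index]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent: {missing[:5]}")
    values = expr.loc[present].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    scores = ranks.sum(axis=0)
    return pd.DataFrame(
        {"sample_id": expr.columns, "signature": name, "score": scores}
    )


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_value: float
    p_adjusted: float
    size: int
    leading_edge: tuple


def _es_from_mask(w: np.ndarray, hit: np.ndarray) -> tuple[float, int]:
    """ES and argmax position from a sorted weight vector and hit mask."""
    n, g = hit.size, int(hit.sum())
    if g == 0 or g == n:
        raise ValueError("gene set empty or covering the whole ranking")
    hit_total = w[hit].sum()
    if hit_total == 0:
        raise ValueError("all hit statistics are zero; ES undefined")
    steps = np.where(hit, w / hit_total, -1.0 / (n - g))
    running = np.cumsum(steps)
    i_max = int(np.argmax(np.abs(running)))
    return float(running[i_max]), i_max


def enrichment_score(ranked: pd.Series, members: set, weight: float = 1.0):
    """Weighted KS enrichment score of a gene set against a ranking.

    ``ranked`` maps gene -> statistic; genes are walked in decreasing
    statistic order. Hits increment the running sum by
    |stat|^weight / sum(|stat|^weight over hits); misses decrement by
    1/(N - g). The ES is the running-sum value of maximal absolute
    deviation from zero. Returns (es, leading_edge_genes).
    """
    order = ranked.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    hit = np.isin(genes, list(members))
    w = np.abs(order.to_numpy(dtype=float)) ** weight
    es, i_max = _es_from_mask(w, hit)
    if es >= 0:
        leading = tuple(genes[: i_max + 1][hit[: i_max + 1]])
    else:
        leading = tuple(genes[i_max:][hit[i_max:]])
    return es, leading


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    p-values come from gene-label permutation: ``n_perm`` random sets of
    the same size are drawn from the ranking and p is the one-tailed
    frequency (with +1 correction) of permuted ES at least as extreme on
    the same side as the observed ES. NES = ES / mean(|permuted ES|
    restricted to the observed sign). BH adjustment across sets.
    """
    if ranked.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistics must be finite")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    order = ranked.sort_values(ascending=False, kind="stable")
    genes_sorted = order.index.to_numpy()
    w = np.abs(order.to_numpy(dtype=float)) ** weight
    n = len(genes_sorted)
    rows = []
    for name in sorted(sets):
        members = set(sets.members(name)) & set(genes_sorted)
        if len(members) < min_size:
            warnings.warn(f"set {name!r} has <{min_size} genes in ranking; skipped")
            continue
        es, leading = enrichment_score(ranked, members, weight)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=len(members), replace=False)] = True
            perm_es[b], _ = _es_from_mask(w, hit)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        extreme = np.abs(perm_es[same_sign]) >= abs(es) - 1e-12
        p = (1 + int(extreme.sum())) / (1 + n_same) if n_same else 1.0
        denom = np.abs(perm_es[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "set": name, "es": es, "nes": nes, "p_value": p,
                "size": len(members), "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table


def set_ora(deg_genes: set, universe: set, sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher over-representation of a DEG list in gene sets.

    Same 2x2 contract as the chromatin-state ORA: per set, selected vs
    not x in-set vs not over the gene universe; sets disjoint from the
    universe are skipped with a warning. BH across sets.
    """
    deg_genes = set(deg_genes)
    universe = set(universe)
    if not deg_genes <= universe:
        raise ValueError("DEG genes must be a subset of the universe")
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for name in sorted(sets):
        members = set(sets.members(name)) & universe
        if not members:
            warnings.warn(f"set {name!r} disjoint from universe; skipped")
            continue
        a = len(deg_genes & members)
        b = len(deg_genes) - a
        c = len(members) - a
        d = len(universe) - len(members) - b
        orr, p = fisher_one_sided(a, b, c, d)
        rows.append({"set": name, "n_selected": a, "n_set": len(members),
                     "odds_ratio": orr, "p_value": p})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table
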