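"""Resampling-based consensus clustering with CDF/delta-area model selection.

Samples are repeatedly subsampled (a fraction ``p_item`` of columns,
without replacement), hierarchically clustered on the 1 - Pearson
correlation dissimilarity with a Ward-type (ward.D2) inner linkage, and
co-clustering frequencies are accumulated into a per-k consensus
matrix. Final assignments come from average-linkage clustering of
1 - consensus. The number of clusters is assessed by the relative
change in area under the consensus CDF (delta-area).

A caveat worth stating: Ward linkage formally assumes squared Euclidean
distances, and 1 - correlation is not one. The combination is
nevertheless the de-facto standard configuration of consensus
clustering in tumor-subtyping studies and is reproduced here verbatim;
the model-selection statistics do not depend on the linkage being
metrically proper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and model-selection curves."""

    samples: list
    consensus: dict  # k -> (n x n) ndarray, symmetric, diag 1
    assignments: dict  # k -> pd.Series sample -> cluster label (1..k)
    params: dict = field(default_factory=dict)

    def consensus_frame(self, k: int) -> pd.DataFrame:
        return pd.DataFrame(self.consensus[k], index=self.samples,
                            columns=self.samples)


def _pearson_dissimilarity(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns of a features x samples array."""
    corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    # numerical guard: tiny negatives from float error
    return np.clip(d, 0.0, 2.0)


def _renumber_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance along the samples."""
    mapping, out = {}, np.empty_like(labels)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def _drop_constant_features(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    const = np.nanstd(values, axis=1) == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant features "
            "(correlation undefined)"
        )
        matrix = matrix.loc[~const]
    return matrix


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=range(2, 11),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of the columns of a features x samples matrix.

    Each of ``reps`` iterations draws ``ceil(p_item * n)`` samples
    without replacement (and, when ``p_feature < 1``, a feature subset),
    clusters them with ward.D2 linkage on 1 - Pearson dissimilarity, and
    cuts the tree at every k in ``k_range``. The consensus entry
    M_k[i, j] is (#times co-clustered) / (#times co-sampled); pairs
    never co-sampled get 0 with a warning. Deterministic given ``seed``:
    repetition ``r`` uses the RNG substream ``(seed, r)``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n = matrix.shape[1]
    if min(k_range) < 2:
        raise ValueError("k must be >= 2")
    if n < max(k_range) + 1:
        raise ValueError(f"need at least max(k)+1={max(k_range)+1} samples, got {n}")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must lie in (0, 1]")
    matrix = _drop_constant_features(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("need at least two non-constant features")
    values = matrix.to_numpy(dtype=float)
    n_items = math.ceil(p_item * n)
    n_feat = matrix.shape[0] if p_feature >= 1 else max(2, math.ceil(p_feature * matrix.shape[0]))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    for rep in range(reps):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, rep])
        cols = np.sort(rng.choice(n, size=n_items, replace=False))
        sub = values[:, cols]
        if n_feat < matrix.shape[0]:
            rows = np.sort(rng.choice(matrix.shape[0], size=n_feat, replace=False))
            sub = sub[rows]
        d = _pearson_dissimilarity(sub)
        link = linkage(squareform(d, checks=False), method="ward")
        ix = np.ix_(cols, cols)
        co_sampled[ix] += 1.0
        for k in k_range:
            labels = fcluster(link, t=k, criterion="maxclust")
            co_clustered[k][ix] += labels[:, None] == labels[None, :]

    off_diag = ~np.eye(n, dtype=bool)
    never = (co_sampled == 0) & off_diag
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs never co-sampled; "
            "consensus set to 0 (increase reps)"
        )
    consensus, assignments = {}, {}
    samples = list(matrix.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            m = np.where(co_sampled > 0, co_clustered[k] / np.where(co_sampled == 0, 1, co_sampled), 0.0)
            np.fill_diagonal(m, 1.0)
            m = (m + m.T) / 2.0
            consensus[k] = m
            assignments[k] = final_assignments(
                pd.DataFrame(m, index=samples, columns=samples), k
            )
    return ConsensusResult(
        samples=samples,
        consensus=consensus,
        assignments=assignments,
        params={
            "reps": reps, "p_item": p_item, "p_feature": p_feature,
            "distance": "1-pearson", "inner_linkage": "ward.D2",
            "final_linkage": "average", "seed": int(seed),
        },
    )


def final_assignments(consensus: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage tree of 1 - consensus at k clusters.

    Labels are renumbered 1..k by first occurrence along the sample
    order, so labelling is deterministic and order-stable.
    """
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if k == 1:
        return pd.Series(1, index=consensus.index, name="cluster")
    m = consensus.to_numpy(dtype=float)
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(link, t=k, criterion="maxclust")
    labels = _renumber_first_occurrence(labels)
    return pd.Series(labels, index=consensus.index, name="cluster")


def consensus_cdf(consensus: np.ndarray):
    """Empirical CDF of the off-diagonal upper-triangle consensus entries.

    Returns (grid, cdf) where grid spans [0, 1] and cdf[i] is the
    fraction of entries <= grid[i].
    """
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    entries = np.sort(consensus[iu])
    grid = np.unique(np.concatenate([[0.0], entries, [1.0]]))
    cdf = np.searchsorted(entries, grid, side="right") / entries.size
    return grid, cdf


def _cdf_area(consensus: np.ndarray) -> float:
    # exact integral of the step CDF over [0, 1]
    grid, cdf = consensus_cdf(consensus)
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def cdf_and_delta_area(result: ConsensusResult) -> pd.DataFrame:
    """Per-k CDF area and relative delta-area.

    ``delta(2) = A_2`` and ``delta(k) = (A_k - A_{k-1}) / A_{k-1}`` for
    k > 2; the k after which delta flattens indicates cluster number.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        raise ValueError("need at least two values of k")
    areas = {k: _cdf_area(result.consensus[k]) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        if i == 0:
            delta = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta = (areas[k] - prev) / prev if prev > 0 else np.inf
        rows.append({"k": k, "area": areas[k], "delta_area": delta})
    return pd.DataFrame(rows)
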