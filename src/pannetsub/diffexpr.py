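"""Count filtering, normalization and negative-binomial differential expression.

The test is a per-gene NB log-linear Wald test of one subtype against
the rest of the cohort, with median-of-ratios size factors as offsets.
Dispersion per gene is a method-of-moments estimate shrunk 50/50 toward
a fitted mean-dispersion trend (a + b / mean), floored at 1e-8. This is
a deliberately transparent substitute for the full DESeq2 estimator
(Cox-Reid adjusted likelihood, apeglm shrinkage, outlier handling); it
recovers planted effects on NB-simulated data, which is what the test
suite checks, but will not numerically match DESeq2 on real data.

``vst_like`` is a shifted log2 of normalized counts used for
clustering, correlation and signature scoring downstream; those uses
are rank-based or distance-based, where any strictly monotone
variance-stabilizing transform agrees.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import bh_adjust

DEFAULT_LOG2FC = 1.0
DEFAULT_P_ADJ = 0.05
_MIN_DISPERSION = 1e-8


def filter_low_counts(
    counts: pd.DataFrame, min_samples: int = 2, min_reads: int = 5
) -> pd.DataFrame:
    """Keep genes with at least ``min_reads`` reads in >= ``min_samples`` samples."""
    values = counts.to_numpy()
    keep = (values >= min_reads).sum(axis=1) >= min_samples
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each gene with strictly positive counts in every sample, compute
    the ratio of each sample's count to the gene's geometric mean; the
    sample's factor is the median ratio over those genes.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; apply "
            "filter_low_counts or check the matrix"
        )
    logs = np.log(values[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_like(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1); monotone in counts per gene."""
    f = factors.reindex(counts.columns)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive for all samples")
    return np.log2(counts / f + 1.0)


def _moments_dispersion(values: np.ndarray, indicator: np.ndarray,
                        factors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion using within-group residuals.

    Returns (raw dispersion estimates, overall normalized means).
    Normalized counts q = K / s; within each group, Var(q) ~
    mean(1/s) * mu + disp * mu^2, solved for disp and pooled.
    """
    q = values / factors
    mean_inv_s = float(np.mean(1.0 / factors))
    mu = q.mean(axis=1)
    ss = np.zeros(values.shape[0])
    dof = 0
    for v in (0.0, 1.0):
        cols = indicator == v
        sub = q[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    var = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mean_inv_s * mu) / mu**2
    disp = np.where(np.isfinite(disp), disp, 0.0)
    return np.maximum(disp, 0.0), mu


def _fit_trend(disp: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a + b / mu on genes with usable estimates.

    Plain least squares on the genes with positive raw dispersion;
    coefficients floored at 0 (the trend must stay non-negative).
    """
    ok = (disp > 0) & (mu > 0)
    if ok.sum() < 10:
        return float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01, 0.0
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, disp[ok], rcond=None)
    a, b = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    if a == 0.0 and b == 0.0:
        a = float(np.median(disp[ok]))
    return a, b


def estimate_dispersions(
    counts: pd.DataFrame, indicator: np.ndarray, factors: pd.Series
) -> pd.Series:
    """Trend-shrunk per-gene NB dispersions (50/50 gene/trend blend)."""
    values = counts.to_numpy(dtype=float)
    disp_raw, mu = _moments_dispersion(values, indicator,
                                       factors.to_numpy(dtype=float))
    a, b = _fit_trend(disp_raw, mu)
    with np.errstate(divide="ignore"):
        trend = a + b / np.where(mu > 0, mu, np.inf)
    disp = 0.5 * disp_raw + 0.5 * trend
    return pd.Series(np.maximum(disp, _MIN_DISPERSION), index=counts.index,
                     name="dispersion")


def nb_test_one_vs_rest(
    counts: pd.DataFrame,
    subtype_labels: pd.Series,
    target_subtype: str,
    factors: pd.Series | None = None,
    log2fc_threshold: float = DEFAULT_LOG2FC,
    p_adj_threshold: float = DEFAULT_P_ADJ,
) -> pd.DataFrame:
    """NB Wald test of ``target_subtype`` vs the rest of the cohort.

    Per gene, fits ``K ~ NB(mu, dispersion)`` with
    ``log mu = offset(log s) + b0 + b1 * [sample in target]`` and tests
    b1 = 0 (Wald). ``log2_fold_change = b1 / ln 2``. BH adjustment is
    across converged genes; non-converged genes get NaN p-values and are
    excluded from the family.

    Returns a DataFrame indexed by gene with ``base_mean``,
    ``log2_fold_change``, ``wald_statistic``, ``p_value``,
    ``p_adjusted``, ``significant``.
    """
    labels = subtype_labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("subtype label missing for some samples")
    indicator = (labels == target_subtype).to_numpy(dtype=float)
    n_target = int(indicator.sum())
    n_rest = len(indicator) - n_target
    if n_target < 2 or n_rest < 2:
        raise ValueError(
            f"need >=2 samples in target ({n_target}) and rest ({n_rest})"
        )
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    disp = estimate_dispersions(counts, indicator, factors)

    x = np.column_stack([np.ones(len(indicator)), indicator])
    offset = np.log(factors.to_numpy(dtype=float))
    values = counts.to_numpy(dtype=float)
    q = values / factors.to_numpy(dtype=float)

    n_genes = values.shape[0]
    coef = np.full(n_genes, np.nan)
    wald = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    failed = []
    for i in range(n_genes):
        y = values[i]
        if (y[indicator == 1.0].sum() == 0) and (y[indicator == 0.0].sum() == 0):
            continue  # all-zero gene: no information
        fam = sm.families.NegativeBinomial(alpha=float(disp.iloc[i]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(y, x, family=fam, offset=offset)
                res = model.fit(maxiter=100, tol=1e-8)
            if not np.all(np.isfinite(res.bse)) or res.bse[1] == 0:
                raise ValueError("degenerate standard error")
            coef[i] = res.params[1]
            wald[i] = res.params[1] / res.bse[1]
            pval[i] = 2.0 * stats.norm.sf(abs(wald[i]))
        except Exception:
            failed.append(counts.index[i])
    if failed:
        warnings.warn(
            f"{len(failed)} genes failed to converge and were excluded "
            f"from adjustment, e.g. {failed[:3]}"
        )
    table = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2_fold_change": coef / np.log(2.0),
            "wald_statistic": wald,
            "p_value": pval,
            "dispersion": disp.to_numpy(),
        },
        index=counts.index,
    )
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = (
        (table["p_adjusted"] < p_adj_threshold)
        & (table["log2_fold_change"].abs() > log2fc_threshold)
    ).fillna(False)
    table.attrs["contrast"] = {"target": target_subtype, "n_target": n_target,
                               "n_rest": n_rest}
    return table
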