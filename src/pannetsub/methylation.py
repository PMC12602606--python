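"""Core methylation-array transforms and probe filtering.

Beta values are the methylated signal fraction in [0, 1]; M values are
their logit on the base-2 scale, M = log2(beta / (1 - beta)), the
variance-stabilized scale used for correlation and testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_EPSILON = 0.001


def beta_to_m(beta: pd.DataFrame, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Logit2 transform of beta values, clipped to [epsilon, 1 - epsilon].

    Missing values stay missing; the transform is strictly monotone
    increasing on the clipped range, so |M| <= log2((1-eps)/eps).
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    values = np.clip(beta.to_numpy(dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(values / (1.0 - values))
    m[np.isnan(beta.to_numpy(dtype=float))] = np.nan
    out = pd.DataFrame(m, index=beta.index, columns=beta.columns)
    out.attrs["epsilon"] = epsilon
    return out


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` on the open interval (eps, 1-eps)."""
    values = m.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -values))
    return pd.DataFrame(beta, index=m.index, columns=m.columns)


def filter_probes(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    fail_mask: pd.DataFrame | None = None,
    max_fail_fraction: float = 0.10,
    autosomes: set | None = None,
):
    """Drop failed and non-autosomal probes.

    A probe is kept iff its detection-failure fraction is <=
    ``max_fail_fraction`` (probes failing in *more than* 10% of samples
    are excluded; equality keeps) and its chromosome is autosomal.

    Parameters
    ----------
    beta : probes x samples beta matrix.
    manifest : probe manifest with ``probe_id``/``chrom`` columns.
    fail_mask : optional boolean probes x samples frame, True = failed
        detection (e.g. a relaxed out-of-band detection p-value mask
        computed upstream). ``None`` means no probe failed.
    autosomes : set of chromosome names to retain; default chr1..chr22.

    Returns
    -------
    (filtered_beta, report) where ``report`` is a DataFrame listing each
    removed probe and the reason (``failed`` or ``non_autosomal``).
    """
    if autosomes is None:
        autosomes = {f"chr{i}" for i in range(1, 23)}
    chrom = manifest.set_index("probe_id")["chrom"]
    missing = beta.index.difference(chrom.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes absent from manifest")
    chrom = chrom.reindex(beta.index)

    if fail_mask is not None:
        if fail_mask.shape != beta.shape or list(fail_mask.index) != list(beta.index) \
                or list(fail_mask.columns) != list(beta.columns):
            raise ValueError("fail_mask shape/labels do not match beta matrix")
        frac = fail_mask.to_numpy(dtype=bool).mean(axis=1)
    else:
        frac = np.zeros(beta.shape[0])

    failed = frac > max_fail_fraction
    non_auto = ~chrom.isin(autosomes).to_numpy()
    keep = ~(failed | non_auto)
    reasons = np.where(failed, "failed", "non_autosomal")
    report = pd.DataFrame(
        {
            "probe_id": beta.index[~keep],
            "reason": reasons[~keep],
            "fail_fraction": frac[~keep],
        }
    ).reset_index(drop=True)
    return beta.loc[keep], report


def intersect_platforms(matrices: list) -> pd.DataFrame:
    """Combine beta matrices from several array platforms.

    Rows are restricted to the probes present on every platform, then
    sample columns are concatenated (duplicate sample ids rejected).
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise ValueError("no probes shared across all platforms")
    combined = pd.concat([m.loc[common] for m in matrices], axis=1)
    if combined.columns.duplicated().any():
        dup = combined.columns[combined.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id across platforms: {dup!r}")
    return combined


def mad(values: np.ndarray) -> float:
    """Median absolute deviation, median(|x - median(x)|), NaN-excluded.

    The 1.4826 normal-consistency constant is deliberately omitted: MAD
    is used here only to rank features, and a constant factor does not
    change the ranking.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    return float(np.median(np.abs(x - np.median(x))))


def select_top_mad(matrix: pd.DataFrame, n: int = 2000) -> list:
    """Ids of the ``n`` most variable features by MAD.

    Ties are broken by feature id ascending, so the selection is
    deterministic and invariant to sample order.
    """
    if n > matrix.shape[0]:
        raise ValueError(f"requested {n} features but matrix has {matrix.shape[0]}")
    values = matrix.to_numpy(dtype=float)
    med = np.nanmedian(values, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        scores = np.nanmedian(np.abs(values - med), axis=1)
    scores = np.nan_to_num(scores, nan=-np.inf)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], matrix.index[i]))
    return [matrix.index[i] for i in order[:n]]
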