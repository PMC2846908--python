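"""Technical-replicate reproducibility: Spearman correlations with bootstrap
confidence intervals, overall, by intensity stratum, and in a sliding window.

Arrays carrying the same reference RNA should rank probes identically up to
measurement noise; the average pairwise Spearman correlation across arrays is
therefore a direct measure of acquisition reproducibility.  Confidence
intervals come from a percentile bootstrap over probes (the sampling units of
each correlation), Bonferroni-adjusted for the number of acquisition
approaches being compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["CorrelationSummary", "spearman_matrix", "mean_corr_ci",
           "stratified_corr", "sliding_window_corr"]


@dataclass
class CorrelationSummary:
    mean_corr: float
    ci_lower: float
    ci_upper: float
    stratum: str
    n_probes: int
    B: int
    n_methods_compared: int = 1


def _rank(values: np.ndarray) -> np.ndarray:
    return rankdata(np.asarray(values, float), axis=0, method="average")


def _mean_upper(corr: np.ndarray) -> float:
    iu = np.triu_indices_from(corr, k=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(corr[iu]))


def _corr_of(ranks: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(ranks, rowvar=False)


def spearman_matrix(norm) -> np.ndarray:
    """Array x array Spearman correlation matrix (average ranks for ties).

    A constant array yields NaN against every other (correlation undefined).
    """
    values = norm.values if hasattr(norm, "values") else np.asarray(norm)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 arrays")
    return _corr_of(_rank(values))


def mean_corr_ci(norm, B: int = 10000, alpha: float = 0.05,
                 n_methods: int = 1, seed: int | None = None,
                 stratum: str = "overall") -> CorrelationSummary:
    """Average pairwise Spearman correlation with a Bonferroni-adjusted
    percentile bootstrap CI (probes resampled with replacement, B draws)."""
    values = norm.values if hasattr(norm, "values") else np.asarray(norm)
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is too small for stable "
                      "percentile intervals", RuntimeWarning, stacklevel=2)
    ranks = _rank(values)
    point = _mean_upper(_corr_of(ranks))
    n = ranks.shape[0]
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot[b] = _mean_upper(_corr_of(ranks[idx]))
    level = alpha / max(n_methods, 1)
    lo, hi = np.nanquantile(boot, [level / 2.0, 1.0 - level / 2.0])
    return CorrelationSummary(point, float(lo), float(hi), stratum, n,
                              B, n_methods)


def stratified_corr(norm, n_bins: int = 10, B: int = 10000,
                    alpha: float = 0.05, n_methods: int = 1,
                    seed: int | None = None) -> list[CorrelationSummary]:
    """Correlation summaries within quantile bins of the across-array median
    intensity (bin 1 = lowest intensity).  Bin sizes differ by at most one."""
    values = norm.values if hasattr(norm, "values") else np.asarray(norm)
    n = values.shape[0]
    if n < 10 * n_bins:
        raise ValueError(f"need >= {10 * n_bins} probes for {n_bins} bins")
    order = np.argsort(np.median(values, axis=1), kind="stable")
    seeds = np.random.SeedSequence(seed).spawn(n_bins)
    out = []
    for d, idx in enumerate(np.array_split(order, n_bins)):
        out.append(mean_corr_ci(values[idx], B=B, alpha=alpha,
                                n_methods=n_methods,
                                seed=seeds[d],
                                stratum=f"decile {d + 1}" if n_bins == 10
                                else f"bin {d + 1}"))
    return out


def sliding_window_corr(norm, window: int = 2000,
                        stride: int = 100) -> pd.DataFrame:
    """Mean pairwise Spearman correlation in a window sliding from low- to
    high-intensity probes (sorted by across-array median); windows are
    aligned by the percentile of their centre probe."""
    values = norm.values if hasattr(norm, "values") else np.asarray(norm)
    n = values.shape[0]
    if window > n:
        raise ValueError(f"window {window} exceeds probe count {n}")
    if window < 3 or stride < 1:
        raise ValueError("window must be >= 3 and stride >= 1")
    order = np.argsort(np.median(values, axis=1), kind="stable")
    sorted_vals = values[order]
    n_windows = (n - window) // stride + 1
    rows = []
    for w in range(n_windows):
        start = w * stride
        sub = sorted_vals[start:start + window]
        corr = _mean_upper(_corr_of(_rank(sub)))
        centre = start + (window - 1) / 2.0
        pct = 100.0 * centre / (n - 1) if n > 1 else 50.0
        rows.append((pct, corr, start))
    return pd.DataFrame(rows, columns=["percentile", "mean_corr", "start"])
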