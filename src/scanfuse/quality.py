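"""Array quality metrics: negative-control statistics, signal-to-noise
ratio, dynamic range, and paired testing across approaches.

All metrics are computed on the cyclic-lowess normalized log2 scale.  The
SNR of an array is its median normalized intensity minus the mean of its
negative controls; the dynamic range is the proportion of probes above the
background bound and below 10% of detector saturation (for fused multi-scan
data the saturation filter is evaluated on the raw low-scan values, which
set the upper end of the usable range).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["negcontrol_stats", "snr", "dynamic_range", "saturation_bound_log2",
           "paired_bonferroni"]


def _values(norm):
    return norm.values if hasattr(norm, "values") and not isinstance(
        norm, (np.ndarray, pd.DataFrame)) else np.asarray(norm, float)


def negcontrol_stats(norm, negcontrol_mask) -> pd.DataFrame:
    """Per-array mean and coefficient of variation of the negative controls."""
    v = _values(norm)
    neg = v[np.asarray(negcontrol_mask, bool), :]
    if neg.shape[0] == 0:
        raise ValueError("empty negative-control mask")
    mean = neg.mean(axis=0)
    if np.any(mean == 0):
        raise ZeroDivisionError("negative-control mean of 0: CV undefined")
    sd = neg.std(axis=0, ddof=1) if neg.shape[0] > 1 else np.zeros_like(mean)
    return pd.DataFrame({"mean": mean, "cv": sd / mean})


def snr(norm, negctrl_mean) -> np.ndarray:
    """Per-array median normalized log2 intensity minus negative-control mean."""
    v = _values(norm)
    return np.median(v, axis=0) - np.asarray(negctrl_mean, float)


def saturation_bound_log2(ceiling: float = 65535.0,
                          fraction: float = 0.1) -> float:
    """10%-of-saturation bound mapped to the log2 scale."""
    return float(np.log2(fraction * ceiling))


def dynamic_range(norm, background_bound, saturation_bound: float,
                  upper_raw: np.ndarray | None = None,
                  ceiling: float = 65535.0,
                  fraction: float = 0.1) -> np.ndarray:
    """Per-array proportion of probes strictly above the background bound and
    strictly below the saturation bound.

    With ``upper_raw`` (a raw FLU probe x array matrix, e.g. the low scan
    behind a fused estimate), the upper filter is ``upper_raw <
    fraction * ceiling`` instead of the log2 comparison.
    """
    v = _values(norm)
    bg = np.asarray(background_bound, float)
    above = v > bg
    if upper_raw is not None:
        below = np.asarray(upper_raw, float) < fraction * ceiling
    else:
        below = v < saturation_bound
    return (above & below).mean(axis=0)


def paired_bonferroni(per_array: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired t-tests between approaches.

    ``per_array`` is (array x approach).  Two-sided p-values are adjusted by
    the Bonferroni factor C(k, 2); pairs with zero-variance differences are
    flagged not-applicable rather than propagating NaN.
    """
    cols = list(per_array.columns)
    n_comp = len(cols) * (len(cols) - 1) // 2
    rows = []
    for a, b in combinations(cols, 2):
        d = per_array[a].to_numpy(float) - per_array[b].to_numpy(float)
        if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
            rows.append((a, b, float(d.mean()), np.nan, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_rel(per_array[a], per_array[b])
        rows.append((a, b, float(d.mean()), float(t), float(p),
                     min(1.0, float(p) * n_comp), True))
    return pd.DataFrame(rows, columns=["approach_a", "approach_b", "mean_diff",
                                       "t", "p_raw", "p_adjusted",
                                       "applicable"])
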