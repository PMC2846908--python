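"""log2 transform, cyclic lowess normalization and background bound.

Cyclic lowess equalizes intensity-dependent differences between arrays by
iterating over all array pairs: for each pair a loess curve of
``M = x_a - x_b`` on ``A = (x_a + x_b)/2`` is fitted and half of it is
subtracted from one array and added to the other, so the pair mean (and the
grand mean) is preserved.  The background bound is the mean plus three
standard deviations of the negative-control probes on the normalized log2
scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = ["NormalizedMatrix", "log2_transform", "cyclic_lowess",
           "background_bound"]


@dataclass
class NormalizedMatrix:
    """log2, between-array normalized intensities for one approach."""

    values: np.ndarray              # (probe, array)
    span: float
    iterations: int
    approach: str = ""
    background: np.ndarray | None = field(default=None, repr=False)


def log2_transform(raw: np.ndarray) -> np.ndarray:
    """``log2(x + 1)``; the +1 guards zero-FLU counts."""
    return np.log2(np.asarray(raw, float) + 1.0)


def _loess_ma(m: np.ndarray, a: np.ndarray, span: float) -> np.ndarray:
    # delta speeds lowess up by linear interpolation between close x values
    delta = 0.01 * float(np.ptp(a)) if a.size > 200 else 0.0
    fit = sm.nonparametric.lowess(m, a, frac=span, it=3, delta=delta,
                                  return_sorted=False)
    return fit


def cyclic_lowess(matrix: np.ndarray, span: float = 2.0 / 3.0,
                  max_iter: int = 3, approach: str = "") -> NormalizedMatrix:
    """Iterated pairwise MA-loess normalization of a (probe, array) log2
    matrix.  Deterministic; a single-array input is returned unchanged with
    a warning.
    """
    x = np.array(matrix, float)
    if x.ndim != 2:
        raise ValueError("expected a (probe, array) matrix")
    n, k = x.shape
    if k < 2:
        warnings.warn("single array: nothing to normalize", RuntimeWarning,
                      stacklevel=2)
        return NormalizedMatrix(x, span, 0, approach)
    for _ in range(max_iter):
        for i, j in itertools.combinations(range(k), 2):
            m = x[:, i] - x[:, j]
            a = 0.5 * (x[:, i] + x[:, j])
            fit = _loess_ma(m, a, span)
            x[:, i] -= 0.5 * fit
            x[:, j] += 0.5 * fit
    return NormalizedMatrix(x, span, max_iter, approach)


def background_bound(norm: NormalizedMatrix | np.ndarray,
                     negcontrol_mask: np.ndarray) -> np.ndarray:
    """Per-array background upper bound: mean + 3 sd of the negative-control
    probes on the normalized log2 scale."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    mask = np.asarray(negcontrol_mask, bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 negative controls per array")
    neg = values[mask, :]
    bound = neg.mean(axis=0) + 3.0 * neg.std(axis=0, ddof=1)
    if isinstance(norm, NormalizedMatrix):
        norm.background = bound
    return bound
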