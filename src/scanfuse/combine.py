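"""Fusion of multiple PMT scans into one expression estimate per probe.

Three algorithms are implemented, all operating per array on raw FLU:

* **Lyng scaling** — a correction factor ``k`` (mean high/low ratio over a
  mid-intensity window of the high scan) imputes saturated high-scan probes
  from the low scan.
* **CSML** (clipping-saturation maximum likelihood) — a resistant
  (least-trimmed-squares) line ``high = a*low + b`` fitted over unclipped
  probes, then a per-probe latent intensity minimizing a Gaussian objective
  in which clipped high-scan observations enter through the censoring tail.
* **Cauchy functional regression** (Khondoker-style) — a joint
  errors-in-variables fit of any number of scans,
  ``y_ij = clip(beta_j * x_i + eps_ij, ceiling)`` with
  ``eps_ij ~ Cauchy(0, sigma * beta_j)`` and ``beta_1 = 1``; clipped
  observations contribute the Cauchy survival tail.  The proportional-scale
  assumption keeps the likelihood bounded, but with only two scans the fitted
  ``sigma`` can still collapse towards zero (a heavy-tail pathology flagged
  by ``degenerate_scale_flag``).

Fused intensities may exceed the detector ceiling: censored probes are
de-censored by the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .io import ScanSet

__all__ = [
    "LyngFit", "CsmlFit", "KhondokerFit", "CombinedEstimate",
    "lyng_combine", "csml_combine", "khondoker_combine",
    "standardized_residuals", "least_trimmed_squares", "EstimationError",
]

PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed"
PROV_ESTIMATED = "estimated"
PROV_DECENSORED = "decensored"
PROV_FULLY_CENSORED = "fully-censored"


class EstimationError(RuntimeError):
    pass


@dataclass
class LyngFit:
    correction_factor: float
    window: tuple[float, float]
    impute_threshold: float
    n_window_probes: int


@dataclass
class CsmlFit:
    scale_a: float
    intercept_b: float
    sigma_low: float
    sigma_high: float
    clip_threshold: float
    converged: np.ndarray = field(repr=False)


@dataclass
class KhondokerFit:
    betas: np.ndarray
    sigma: float
    x_hat: np.ndarray = field(repr=False)
    loglik: float
    degenerate_scale_flag: bool
    ceiling: float
    n_iter: int = 0
    censored: np.ndarray | None = field(default=None, repr=False)


@dataclass
class CombinedEstimate:
    """Per-probe, per-array fused intensity from one method."""

    method: str
    values: np.ndarray              # (probe, array); FLU, may exceed ceiling
    provenance: np.ndarray          # (probe, array) str codes
    fits: list
    ceiling: float = 65535.0


def _as_columns(arr) -> tuple[np.ndarray, bool]:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        return a[:, None], True
    if a.ndim == 2:
        return a, False
    raise ValueError("expected (probe,) or (probe, array) intensities")


# ---------------------------------------------------------------------------
# Lyng correction-factor scaling

def lyng_combine(low, high, window: tuple[float, float] = (20000.0, 30000.0),
                 impute_threshold: float = 50000.0,
                 ceiling: float = 65535.0) -> CombinedEstimate:
    """Impute saturated high-scan probes from the low scan.

    Probes whose high-scan signal lies inside ``window`` define the high/low
    ratio; its mean ``k`` replaces every high-scan value above
    ``impute_threshold`` by ``k * low``.  All other probes pass through
    unchanged.
    """
    lo2, was_1d = _as_columns(low)
    hi2, _ = _as_columns(high)
    if lo2.shape != hi2.shape:
        raise ValueError("low/high shapes differ")
    values = hi2.copy()
    prov = np.full(hi2.shape, PROV_OBSERVED, dtype=object)
    fits = []
    for a in range(hi2.shape[1]):
        l, h = lo2[:, a], hi2[:, a]
        sel = (h >= window[0]) & (h <= window[1]) & (l > 0)
        if not sel.any():
            raise EstimationError(
                f"no probes in window {window} for array {a}; widen the window"
            )
        k = float(np.mean(h[sel] / l[sel]))
        imput = h > impute_threshold
        values[imput, a] = k * l[imput]
        prov[imput, a] = PROV_IMPUTED
        fits.append(LyngFit(k, tuple(window), impute_threshold, int(sel.sum())))
    return CombinedEstimate("lyng", values, prov.astype(str), fits, ceiling)


# ---------------------------------------------------------------------------
# Least trimmed squares (resistant line)

def least_trimmed_squares(x: np.ndarray, y: np.ndarray, h: int | None = None,
                          n_starts: int = 30, n_csteps: int = 25,
                          seed: int = 0) -> tuple[float, float]:
    """Fit ``y = a*x + b`` minimizing the sum of the ``h`` smallest squared
    residuals (concentration steps from random elemental starts).

    Default coverage ``h = n//2 + 1`` (simple-regression convention); the fit
    resists up to ``n - h`` arbitrarily bad points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise EstimationError("need at least 3 points for a resistant line")
    if h is None:
        h = n // 2 + 1
    h = int(min(max(h, 2), n))
    rng = np.random.default_rng(seed)

    def _ols(xs, ys):
        xm, ym = xs.mean(), ys.mean()
        vx = np.sum((xs - xm) ** 2)
        if vx == 0:
            return None
        a = np.sum((xs - xm) * (ys - ym)) / vx
        return a, ym - a * xm

    def _concentrate(a, b):
        obj_prev = np.inf
        for _ in range(n_csteps):
            r2 = (y - (a * x + b)) ** 2
            idx = np.argpartition(r2, h - 1)[:h]
            fit = _ols(x[idx], y[idx])
            if fit is None:
                break
            a, b = fit
            obj = np.sort((y - (a * x + b)) ** 2)[:h].sum()
            if obj >= obj_prev - 1e-12 * max(obj_prev, 1.0):
                obj_prev = obj
                break
            obj_prev = obj
        return obj_prev, a, b

    best = (np.inf, 1.0, 0.0)
    start = _ols(x, y)
    if start is not None:
        best = min(best, _concentrate(*start), key=lambda t: t[0])
    for _ in range(n_starts):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        a = (y[j] - y[i]) / (x[j] - x[i])
        b = y[i] - a * x[i]
        best = min(best, _concentrate(a, b), key=lambda t: t[0])
    if not np.isfinite(best[0]):
        raise EstimationError("resistant line fit failed (degenerate x)")
    return float(best[1]), float(best[2])


# ---------------------------------------------------------------------------
# CSML

def _solve_clipped(low, a, b, s_l, s_h, ceiling):
    """Vectorized bisection on the derivative of the clipped objective
    (convex: quadratic pull towards the low scan plus a log-concave tail)."""

    def grad(t):
        u = (a * t + b - ceiling) / s_h
        hazard = np.exp(-0.5 * u * u - 0.5 * np.log(2 * np.pi)
                        - special.log_ndtr(u))
        return 2.0 * (t - low) / s_l ** 2 - 2.0 * (a / s_h) * hazard

    lo = np.array(low, float, copy=True)     # grad < 0 at t = low
    step = np.maximum((ceiling - b) / a - low, 10.0 * (s_l + s_h / a)) + 1.0
    hi = low + step
    for _ in range(60):
        need = grad(hi) < 0
        if not need.any():
            break
        hi[need] += step[need]
        step[need] *= 2.0
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        neg = grad(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def csml_combine(low, high, clip_threshold: float = 65535.0,
                 robust_trim: float | None = None,
                 ceiling: float = 65535.0, seed: int = 0) -> CombinedEstimate:
    """Clipping-saturation maximum-likelihood fusion of a low/high scan pair.

    A least-trimmed-squares line ``high = a*low + b`` is fitted over probes
    with ``high < clip_threshold`` (coverage ``robust_trim`` as a fraction of
    those probes; default the LTS half-sample).  Noise scales are taken from
    the robust residual spread, split between the two scans under the
    proportional-noise assumption ``sigma_high = a * sigma_low``.  Each
    probe's latent intensity ``t`` minimizes

        (low - t)^2 / sigma_low^2 + (high - (a t + b))^2 / sigma_high^2

    with the second term replaced by ``-2 log P(a t + b + eps >= ceiling)``
    when the high scan is clipped.  The fused value ``a*t + b`` is reported
    on the high-scan scale, de-censored.
    """
    lo2, _ = _as_columns(low)
    hi2, _ = _as_columns(high)
    if lo2.shape != hi2.shape:
        raise ValueError("low/high shapes differ")
    values = np.empty_like(hi2)
    prov = np.full(hi2.shape, PROV_ESTIMATED, dtype=object)
    fits = []
    for col in range(hi2.shape[1]):
        l, h = lo2[:, col], hi2[:, col]
        unclip = h < clip_threshold
        if unclip.sum() < 3:
            raise EstimationError("too few unclipped probes for the line fit")
        n_fit = int(unclip.sum())
        h_cov = None if robust_trim is None else int(np.ceil(robust_trim * n_fit))
        a, b = least_trimmed_squares(l[unclip], h[unclip], h=h_cov, seed=seed)
        if a <= 0:
            raise EstimationError(f"non-positive scaling estimate a={a:.3g}")
        resid = h[unclip] - (a * l[unclip] + b)
        mad = np.median(np.abs(resid - np.median(resid)))
        sigma_r = max(1.4826 * mad, 1e-9 * max(float(np.median(h)), 1.0))
        # split residual spread assuming noise grows with the gain
        s_h = sigma_r / np.sqrt(2.0)
        s_l = s_h / a

        t = np.empty_like(l)
        # unclipped: quadratic objective, closed-form minimizer
        w = 1.0 / s_l ** 2 + a ** 2 / s_h ** 2
        t[unclip] = (l[unclip] / s_l ** 2
                     + a * (h[unclip] - b) / s_h ** 2)[...] / w
        clip = ~unclip
        if clip.any():
            t[clip] = _solve_clipped(l[clip], a, b, s_l, s_h, ceiling)
            prov[clip, col] = PROV_DECENSORED
        values[:, col] = a * t + b
        fits.append(CsmlFit(a, b, s_l, s_h, clip_threshold,
                            converged=np.ones(l.size, dtype=bool)))
    return CombinedEstimate("csml", values, prov.astype(str), fits, ceiling)


# ---------------------------------------------------------------------------
# Cauchy functional regression over m >= 2 scans

_LOG_PI = np.log(np.pi)


def _cauchy_loglik_rows(Y, cens, beta, sigma, ceiling, x):
    """Row-wise log-likelihood (n,) at per-row latent x (n,)."""
    mu = x[:, None] * beta
    s = sigma * beta
    z = (Y - mu) / s
    ll_unc = -(np.log(s) + _LOG_PI) - np.log1p(z * z)
    sf = 0.5 + np.arctan((mu - ceiling) / s) / np.pi
    ll_cen = np.log(np.maximum(sf, 1e-300))
    return np.where(cens, ll_cen, ll_unc).sum(axis=1)


def _profile_x(Y, cens, beta, sigma, ceiling):
    """Per-probe 1-D maximization of the Cauchy likelihood in x, vectorized.

    The likelihood in x is multimodal, with one mode of width ~``sigma``
    near each unclipped ``y_j / beta_j`` (the residual scale on the x axis
    is ``sigma`` for every scan).  Every candidate mode is refined by a
    bracketed grid plus golden-section search and the best refinement wins.
    """
    n, m = Y.shape

    def ll_at(x):
        return _cauchy_loglik_rows(Y, cens, beta, sigma, ceiling, x)

    def refine(centre):
        """Grid + golden-section maximization in centre +- 5 sigma."""
        delta = 5.0 * sigma + 1e-9 * np.abs(centre)
        lo = np.maximum(centre - delta, 1e-9)
        hi = centre + delta
        gx, gll = centre.copy(), ll_at(centre)
        n_grid = 21
        for frac in np.linspace(0.0, 1.0, n_grid):
            xg = lo + frac * (hi - lo)
            llg = ll_at(xg)
            take = llg > gll
            gx = np.where(take, xg, gx)
            gll = np.where(take, llg, gll)
        span = (hi - lo) / (n_grid - 1.0)
        lo = np.maximum(gx - span, 1e-9)
        hi = gx + span
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc, fd = ll_at(c), ll_at(d)
        for _ in range(55):
            left = fc > fd
            hi = np.where(left, d, hi)
            lo = np.where(left, lo, c)
            c = hi - gr * (hi - lo)
            d = lo + gr * (hi - lo)
            fc, fd = ll_at(c), ll_at(d)
        xh = 0.5 * (lo + hi)
        llh = ll_at(xh)
        worse = gll > llh
        return np.where(worse, gx, xh), np.where(worse, gll, llh)

    cand = np.where(cens, ceiling / beta, Y / beta)
    med = np.where(cens, np.nan, Y / beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmedian(med, axis=1)
    center = np.where(np.isfinite(center), center, ceiling)

    best_x = np.full(n, np.nan)
    best_ll = np.full(n, -np.inf)
    for k in range(m + 1):
        start = center if k == m else cand[:, k]
        xk, llk = refine(start)
        take = llk > best_ll
        best_x = np.where(take, xk, best_x)
        best_ll = np.where(take, llk, best_ll)
    return best_x


def fit_khondoker_array(Y: np.ndarray, ceiling: float = 65535.0,
                        sigma_floor_factor: float = 1e-6,
                        max_outer: int = 8, tol: float = 1e-8) -> KhondokerFit:
    """Fit the Cauchy functional-regression model to one array's scans.

    ``Y`` is (probe, scan) ordered low to high; observations at or above
    ``ceiling`` are treated as censored.  Alternating optimization: profile
    the latent ``x_i`` given ``(beta, sigma)``, then refine ``(beta, sigma)``
    by Nelder-Mead on the log scale.  ``beta_1`` is fixed at 1, so estimates
    live on the lowest-scan scale.  ``sigma`` is floored at
    ``sigma_floor_factor * median(Y)``; a fit ending on the floor sets
    ``degenerate_scale_flag`` (the two-scan pathology) instead of failing.
    """
    from scipy.optimize import minimize

    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a (probe, scan) matrix with at least 2 scans")
    n, m = Y.shape
    cens = Y >= ceiling
    active = ~cens.all(axis=1)
    Ya, ca = Y[active], cens[active]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ca | ca[:, :1] | (Ya[:, :1] <= 0), np.nan,
                         Ya / np.maximum(Ya[:, :1], 1e-12))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmedian(ratio, axis=0)
    beta = np.where(np.isfinite(beta) & (beta > 0), beta, 1.0)
    beta[0] = 1.0

    floor = sigma_floor_factor * max(float(np.median(Y)), 1.0)
    r = np.where(ca, np.nan, Ya / beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x = np.nanmedian(r, axis=1)
        spread = np.nanmedian(np.abs(r - x[:, None]))
    x = np.where(np.isfinite(x), x, ceiling)
    sigma = max(1.4826 * float(np.nan_to_num(spread)), floor)

    def total_ll(beta_v, sigma_v, x_v):
        return float(_cauchy_loglik_rows(Ya, ca, beta_v, sigma_v, ceiling,
                                         x_v).sum())

    ll_prev = total_ll(beta, sigma, x)
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        x = _profile_x(Ya, ca, beta, sigma, ceiling)

        def neg(params):
            b = np.concatenate([[1.0], np.exp(params[:-1])])
            s = max(float(np.exp(params[-1])), floor)
            return -total_ll(b, s, x)

        p0 = np.concatenate([np.log(beta[1:]), [np.log(max(sigma, floor))]])
        # explicit simplex: fixed absolute steps in log space keep the
        # optimization path equivariant under rescaling of the data
        simplex = np.vstack([p0] + [p0 + 0.05 * e
                                    for e in np.eye(p0.size)])
        res = minimize(neg, p0, method="Nelder-Mead",
                       options={"maxiter": 400 * m, "xatol": 1e-8,
                                "fatol": 1e-10,
                                "initial_simplex": simplex})
        p_best = res.x if res.fun <= neg(p0) else p0
        beta = np.concatenate([[1.0], np.exp(p_best[:-1])])
        sigma = max(float(np.exp(p_best[-1])), floor)

        ll = total_ll(beta, sigma, x)
        if abs(ll - ll_prev) <= tol * (1.0 + abs(ll_prev)):
            ll_prev = ll
            break
        ll_prev = ll
    x = _profile_x(Ya, ca, beta, sigma, ceiling)
    ll_prev = total_ll(beta, sigma, x)

    x_full = np.full(n, ceiling)
    x_full[active] = x
    if np.any(np.diff(beta) < 0):
        warnings.warn("fitted gains are not non-decreasing across scans",
                      RuntimeWarning, stacklevel=2)
    return KhondokerFit(
        betas=beta, sigma=sigma, x_hat=x_full, loglik=ll_prev,
        degenerate_scale_flag=bool(sigma <= floor * (1.0 + 1e-9)),
        ceiling=ceiling, n_iter=n_iter, censored=cens,
    )


def khondoker_combine(scanset: ScanSet | np.ndarray, n_scans: int | None = None,
                      scans: tuple[int, ...] | None = None,
                      **fit_options) -> CombinedEstimate:
    """Fit the Cauchy functional-regression model to every array.

    ``n_scans=2`` uses the lowest and highest scans; ``n_scans=3`` (or None)
    all three; an explicit ``scans`` index tuple overrides.  Fused values are
    the latent estimates on the lowest-scan scale.
    """
    if isinstance(scanset, ScanSet):
        cube, ceiling = scanset.intensities, scanset.ceiling
    else:
        cube = np.asarray(scanset, float)
        ceiling = fit_options.pop("ceiling", 65535.0)
    if cube.ndim != 3:
        raise ValueError("expected (probe, array, scan) intensities")
    m_all = cube.shape[2]
    if scans is None:
        k = m_all if n_scans is None else n_scans
        if k < 2:
            raise ValueError("the functional-regression fit needs >= 2 scans")
        if k > m_all:
            raise ValueError(f"requested {k} scans but only {m_all} available")
        scans = (0, m_all - 1) if k == 2 else tuple(range(m_all))
    cube = cube[:, :, list(scans)]
    n, n_arrays, m = cube.shape
    values = np.empty((n, n_arrays))
    prov = np.full((n, n_arrays), PROV_ESTIMATED, dtype=object)
    fits = []
    for a in range(n_arrays):
        fit = fit_khondoker_array(cube[:, a, :], ceiling=ceiling, **fit_options)
        values[:, a] = fit.x_hat
        cens = fit.censored
        prov[cens.all(axis=1), a] = PROV_FULLY_CENSORED
        partially = cens.any(axis=1) & ~cens.all(axis=1)
        prov[partially, a] = PROV_DECENSORED
        fits.append(fit)
    tag = f"khondoker_{m}scan"
    return CombinedEstimate(tag, values, prov.astype(str), fits, ceiling)


def standardized_residuals(fit: KhondokerFit, Y: np.ndarray):
    """Standardized residuals of one array's fit against intensity rank.

    ``r_ij = (y_ij - min(beta_j x_i, ceiling)) / (sigma beta_j)`` for
    unclipped observations; clipped cells are NaN and counted.  Rows are
    ordered by rank of the estimated intensity (low to high).
    """
    Y = np.asarray(Y, float)
    cens = Y >= fit.ceiling
    mu = np.minimum(fit.x_hat[:, None] * fit.betas, fit.ceiling)
    r = (Y - mu) / (fit.sigma * fit.betas)
    r[cens] = np.nan
    order = np.argsort(fit.x_hat, kind="stable")
    return r[order], order, int(cens.sum())
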