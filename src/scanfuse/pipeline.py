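"""End-to-end orchestration: simulate -> combine -> normalize -> metrics ->
correlation, with machine-readable plot data for every summary figure.

Seven acquisition approaches are compared by default: the three individual
scans (low, medium, high) and four multi-scan fusions (Lyng scaling, CSML,
and the Cauchy functional regression with 2 and 3 scans).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import combine as cmb
from . import normalize as nrm
from . import quality as qc
from . import reproducibility as rep
from .io import ScanSet
from .simulate import TruthModel, simulate_scanset

__all__ = ["RunConfig", "ConfigError", "StageFailure", "run_pipeline",
           "ratio_intensity_data", "density_with_corr_overlay",
           "ALL_APPROACHES"]

log = logging.getLogger("scanfuse")

ALL_APPROACHES = ("low", "medium", "high", "lyng", "csml",
                  "khondoker_2scan", "khondoker_3scan")


class ConfigError(ValueError):
    pass


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``simulation`` holds :class:`~scanfuse.simulate.TruthModel` keyword
    overrides; the master ``seed`` drives both simulation and bootstrap.
    """

    simulation: dict = field(default_factory=dict)
    approaches: tuple[str, ...] = ALL_APPROACHES
    span: float = 2.0 / 3.0
    max_iter: int = 3
    saturation_fraction: float = 0.1
    B: int = 10000
    alpha: float = 0.05
    window: int = 2000
    stride: int = 100
    n_bins: int = 10
    compute_deciles: bool = False
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> TruthModel:
        unknown = [a for a in self.approaches if a not in ALL_APPROACHES]
        if unknown:
            raise ConfigError(f"unknown approaches {unknown}")
        try:
            model = TruthModel(seed=self.seed, **self.simulation)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulation parameters: {exc}") from exc
        needs3 = {"medium", "khondoker_3scan"} & set(self.approaches)
        if needs3 and model.n_scans < 3:
            raise ConfigError(
                f"approaches {sorted(needs3)} need 3 scans, simulation has "
                f"{model.n_scans}"
            )
        if model.n_scans < 2 and set(self.approaches) - {"low", "high"}:
            raise ConfigError("multi-scan approaches need >= 2 scans")
        if not 0 < self.span <= 1 or self.max_iter < 1:
            raise ConfigError("span must be in (0, 1], max_iter >= 1")
        if self.window < 3 or self.stride < 1 or self.B < 1:
            raise ConfigError("window/stride/B out of range")
        return model


@dataclass
class ApproachResult:
    name: str
    norm: nrm.NormalizedMatrix
    background: np.ndarray
    negctrl: pd.DataFrame
    snr: np.ndarray
    dynamic_range: np.ndarray
    overall: rep.CorrelationSummary
    window_curve: pd.DataFrame
    deciles: list[rep.CorrelationSummary] | None = None
    combined: cmb.CombinedEstimate | None = None


@dataclass
class PipelineReport:
    config: RunConfig
    scanset: ScanSet
    truth: object
    results: dict[str, ApproachResult]
    pairwise_dr: pd.DataFrame
    artifacts: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append({
                "approach": name,
                "mean_corr": r.overall.mean_corr,
                "ci_lower": r.overall.ci_lower,
                "ci_upper": r.overall.ci_upper,
                "negctrl_mean": float(r.negctrl["mean"].mean()),
                "negctrl_cv": float(r.negctrl["cv"].mean()),
                "snr": float(np.mean(r.snr)),
                "dynamic_range": float(np.mean(r.dynamic_range)),
            })
        return pd.DataFrame(rows).set_index("approach")


def _approach_values(name: str, scanset: ScanSet, seed: int):
    """Raw fused/selected (probe x array) values plus the raw matrix used for
    the 10%-of-saturation upper filter (the low scan for fused data)."""
    low = scanset.scan(0)
    high = scanset.scan(scanset.n_scans - 1)
    if name == "low":
        return low, low, None
    if name == "high":
        return high, high, None
    if name == "medium":
        mid = scanset.scan(scanset.n_scans // 2)
        return mid, mid, None
    if name == "lyng":
        est = cmb.lyng_combine(low, high, ceiling=scanset.ceiling)
        return est.values, low, est
    if name == "csml":
        est = cmb.csml_combine(low, high, clip_threshold=scanset.ceiling,
                               ceiling=scanset.ceiling, seed=seed)
        return est.values, low, est
    if name == "khondoker_2scan":
        est = cmb.khondoker_combine(scanset, n_scans=2)
        return est.values, low, est
    if name == "khondoker_3scan":
        est = cmb.khondoker_combine(scanset, n_scans=3)
        return est.values, low, est
    raise ConfigError(f"unknown approach {name!r}")


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full comparison for every configured approach.

    Deterministic given ``config.seed``.  Any stage failure raises
    :class:`StageFailure` naming the stage; results computed before the
    failure are attached to the exception as ``partial``.
    """
    model = config.validate()
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    scanset, truth = simulate_scanset(model)
    log.info("simulated %d probes x %d arrays x %d scans in %.1fs",
             scanset.n_probes, scanset.n_arrays, scanset.n_scans,
             time.perf_counter() - t0)

    mask = scanset.negcontrol_mask
    sat_log2 = qc.saturation_bound_log2(scanset.ceiling,
                                        config.saturation_fraction)
    boot_seeds = np.random.SeedSequence(config.seed).spawn(
        len(config.approaches))
    results: dict[str, ApproachResult] = {}
    for name, sseq in zip(config.approaches, boot_seeds):
        t1 = time.perf_counter()
        try:
            raw, upper_raw, est = _approach_values(name, scanset, config.seed)
            norm = nrm.cyclic_lowess(nrm.log2_transform(raw),
                                     span=config.span,
                                     max_iter=config.max_iter, approach=name)
            bg = nrm.background_bound(norm, mask)
            neg = qc.negcontrol_stats(norm, mask)
            snr_a = qc.snr(norm, neg["mean"].to_numpy())
            dr = qc.dynamic_range(norm, bg, sat_log2, upper_raw=upper_raw,
                                  ceiling=scanset.ceiling,
                                  fraction=config.saturation_fraction)
            child = sseq.spawn(3)
            overall = rep.mean_corr_ci(norm, B=config.B, alpha=config.alpha,
                                       n_methods=len(config.approaches),
                                       seed=child[0])
            curve = rep.sliding_window_corr(
                norm, window=min(config.window, scanset.n_probes),
                stride=config.stride)
            deciles = None
            if config.compute_deciles:
                deciles = rep.stratified_corr(
                    norm, n_bins=config.n_bins, B=config.B,
                    alpha=config.alpha,
                    n_methods=len(config.approaches), seed=child[1])
            results[name] = ApproachResult(name, norm, bg, neg, snr_a, dr,
                                           overall, curve, deciles, est)
            log.info("approach %-16s done in %.1fs (mean corr %.4f)", name,
                     time.perf_counter() - t1, overall.mean_corr)
        except Exception as exc:                      # noqa: BLE001
            failure = StageFailure(name, exc)
            failure.partial = results
            raise failure from exc

    dr_table = pd.DataFrame({n: r.dynamic_range for n, r in results.items()})
    pairwise = qc.paired_bonferroni(dr_table)

    artifacts = _plot_artifacts(results, config)
    report = PipelineReport(config, scanset, truth, results, pairwise,
                            artifacts)
    if config.outdir:
        _write_report(report, Path(config.outdir))
    return report


def ratio_intensity_data(norm, reference: str = "probe_mean_across_arrays"):
    """(A, M) pairs per array against the probe-wise mean reference.

    ``M = x_ia - ref_i`` and ``A = (x_ia + ref_i) / 2`` on the normalized
    log2 scale; with replicate arrays of one RNA pool the probe-wise mean
    across arrays is the natural reference channel.
    """
    if reference != "probe_mean_across_arrays":
        raise ValueError(f"unknown reference {reference!r}")
    v = norm.values if hasattr(norm, "values") else np.asarray(norm)
    ref = v.mean(axis=1, keepdims=True)
    return (v + ref) / 2.0, v - ref


def density_with_corr_overlay(norm, window_curve: pd.DataFrame,
                              background_bound, grid_size: int = 256) -> dict:
    """Kernel density of across-array mean intensity with the sliding-window
    correlation aligned on the intensity axis and the background bound marked.
    """
    v = norm.values if hasattr(norm, "values") else np.asarray(norm)
    mean_int = np.sort(v.mean(axis=1))
    kde = gaussian_kde(mean_int)
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(mean_int.min() - 4 * h, mean_int.max() + 4 * h,
                       grid_size)
    dens = kde(grid)
    n = mean_int.size
    centre = (window_curve["percentile"].to_numpy() / 100.0 * (n - 1)).astype(int)
    bound = float(np.mean(background_bound))
    return {
        "grid": grid,
        "density": dens,
        "corr_intensity": mean_int[centre],
        "corr": window_curve["mean_corr"].to_numpy(),
        "background_line": bound,
        "fraction_below_background": float((mean_int < bound).mean()),
    }


def _plot_artifacts(results: dict[str, ApproachResult],
                    config: RunConfig) -> dict:
    """Machine-readable data behind each summary figure."""
    arts: dict = {}
    ma = {}
    for name, r in results.items():
        A, M = ratio_intensity_data(r.norm)
        ma[name] = {"A_range": [float(A.min()), float(A.max())],
                    "M_sd": float(M.std())}
    arts["ratio_intensity"] = ma
    arts["negctrl"] = {n: r.negctrl.to_dict("list") for n, r in results.items()}
    arts["snr"] = {n: r.snr.tolist() for n, r in results.items()}
    arts["dynamic_range"] = {n: r.dynamic_range.tolist()
                             for n, r in results.items()}
    arts["window_corr"] = {n: r.window_curve.to_dict("list")
                           for n, r in results.items()}
    for tag in ("khondoker_3scan", "khondoker_2scan"):
        if tag in results and results[tag].combined is not None:
            fit = results[tag].combined.fits[0]
            arts.setdefault("residuals", {})[tag] = {
                "sigma": fit.sigma,
                "betas": fit.betas.tolist(),
                "degenerate": fit.degenerate_scale_flag,
            }
    best = "khondoker_3scan" if "khondoker_3scan" in results else \
        next(iter(results))
    r = results[best]
    overlay = density_with_corr_overlay(r.norm, r.window_curve, r.background)
    arts["density_overlay"] = {
        "approach": best,
        "background_line": overlay["background_line"],
        "fraction_below_background": overlay["fraction_below_background"],
    }
    return arts


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _write_report(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(report.config)
    (outdir / "config.json").write_text(
        json.dumps(_to_jsonable(cfg), indent=2, sort_keys=True))
    report.summary_frame().to_csv(outdir / "summary.tsv", sep="\t")
    report.pairwise_dr.to_csv(outdir / "pairwise_dynamic_range.tsv",
                              sep="\t", index=False)
    (outdir / "artifacts.json").write_text(
        json.dumps(_to_jsonable(report.artifacts), indent=2, sort_keys=True))
    for name, r in report.results.items():
        pd.DataFrame(r.norm.values).to_csv(
            outdir / f"normalized_{name}.tsv", sep="\t", index=False,
            float_format="%.6f")
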