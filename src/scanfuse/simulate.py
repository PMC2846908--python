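"""Synthetic multi-PMT scan sets with known ground truth.

The generator emulates the structure of a technical-replicate microarray
study: one reference RNA hybridized to many arrays, each array scanned at an
ordered ladder of photomultiplier-tube (PMT) sensitivities.  Raw fluorescence
(FLU) for probe *i*, array *a*, scan *j* is

    raw_iaj = clip(round(g_j * x_ia + b_iaj + eps_iaj), 0, ceiling)

where ``g_j`` are the strictly increasing scan gains, ``x_ia`` the latent
true expression (log-normal; identical across arrays because the replicates
share one RNA pool, zero for negative-control probes), ``b`` the background
fluorescence and ``eps`` additive measurement noise whose scale grows in
proportion to the gain.  The 16-bit detector clips at ``ceiling`` (65535).

Background is amplified slightly super-proportionally with gain
(``background_gain_exponent`` > 1): photomultiplier dark signal and glass
autofluorescence grow faster than the specific signal as the tube voltage is
raised, which is what makes high-sensitivity scans background-heavy and
lowers their signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import ScanSet, CONTROL_EXPERIMENTAL, CONTROL_NEGATIVE

__all__ = ["TruthModel", "GroundTruth", "simulate_scanset", "default_study_fixture"]

CEILING_16BIT = 65535.0


class ConfigurationError(ValueError):
    """Raised when a TruthModel violates its invariants."""


@dataclass(frozen=True)
class TruthModel:
    """Parameters of the generative model for a multi-scan study.

    Parameters
    ----------
    n_probes, n_arrays, n_negcontrols
        Array geometry.  Negative controls are carried within ``n_probes``.
    scan_gains
        Strictly increasing PMT gains, one per scan level; the lowest scan
        defines the reference scale (gain 1 by convention, not enforced).
    background_mean, background_sd
        Background fluorescence (FLU) at unit gain.
    background_gain_exponent
        Background at gain g has mean ``background_mean * g**exponent``;
        values above 1 emulate background rising faster than signal with PMT.
    noise_model
        ``gaussian`` or ``cauchy`` additive measurement noise.
    noise_scale_coeff
        Noise scale for scan j is ``coeff * median(expression law) * g_j``,
        i.e. proportional to the gain as in the Cauchy functional-regression
        model, expressed as a fraction of the median true signal.
    expression_meanlog, expression_sdlog
        Natural-log parameters of the log-normal law of true expression.
    ceiling
        Detector saturation bound (16-bit default).
    """

    n_probes: int = 22575
    n_arrays: int = 40
    n_negcontrols: int = 162
    scan_gains: tuple[float, ...] = (1.0, 3.2, 6.2)
    background_mean: float = 400.0
    background_sd: float = 80.0
    background_gain_exponent: float = 1.2
    noise_model: Literal["gaussian", "cauchy"] = "gaussian"
    noise_scale_coeff: float = 0.05
    expression_meanlog: float = 5.86
    expression_sdlog: float = 2.2
    ceiling: float = CEILING_16BIT
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.scan_gains, dtype=float)
        if g.size < 1 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ConfigurationError(
                "scan_gains must be strictly increasing and positive, got "
                f"{self.scan_gains}"
            )
        if self.n_probes <= 0 or self.n_arrays <= 0:
            raise ConfigurationError("n_probes and n_arrays must be positive")
        if not 0 <= self.n_negcontrols < self.n_probes:
            raise ConfigurationError("need 0 <= n_negcontrols < n_probes")
        if self.ceiling <= 0:
            raise ConfigurationError("ceiling must be positive")
        if self.background_sd < 0 or self.noise_scale_coeff < 0:
            raise ConfigurationError("scale parameters must be non-negative")
        if self.expression_sdlog <= 0:
            raise ConfigurationError("expression_sdlog must be positive")

    @property
    def n_scans(self) -> int:
        return len(self.scan_gains)

    @property
    def noise_scales(self) -> np.ndarray:
        """Per-scan additive noise scales sigma_j (FLU), proportional to gain."""
        ref = float(np.exp(self.expression_meanlog))
        return self.noise_scale_coeff * ref * np.asarray(self.scan_gains, float)


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind one simulated ScanSet (oracle for recovery tests)."""

    expression: np.ndarray          # (n_probes,) true x_i, shared by replicates
    gains: np.ndarray               # (n_scans,)
    negcontrol_mask: np.ndarray     # (n_probes,) bool
    model: TruthModel = field(repr=False)

    @property
    def true_expression(self) -> np.ndarray:
        """(probe x array) view; technical replicates share one RNA pool."""
        return np.tile(self.expression[:, None], (1, self.model.n_arrays))


def simulate_scanset(model: TruthModel) -> tuple[ScanSet, GroundTruth]:
    """Draw one multi-scan study from ``model``.

    Returns the observed ScanSet (integer FLU, clipped to ``[0, ceiling]``)
    and the GroundTruth used to generate it.  Identical seeds give
    bit-identical output; per-array noise streams are spawned from the master
    seed so array subsets are reproducible.
    """
    gains = np.asarray(model.scan_gains, dtype=float)
    master = np.random.SeedSequence(model.seed)
    expr_seq, *array_seqs = master.spawn(1 + model.n_arrays)

    rng = np.random.default_rng(expr_seq)
    x = rng.lognormal(model.expression_meanlog, model.expression_sdlog,
                      size=model.n_probes)
    mask = np.zeros(model.n_probes, dtype=bool)
    if model.n_negcontrols:
        # controls are interleaved across the probe list, as on real layouts
        idx = np.linspace(0, model.n_probes - 1, model.n_negcontrols).astype(int)
        mask[idx] = True
    x[mask] = 0.0

    bg_scale = gains ** model.background_gain_exponent     # (m,)
    sigma = model.noise_scales                             # (m,)

    raw = np.empty((model.n_probes, model.n_arrays, model.n_scans))
    for a, seq in enumerate(array_seqs):
        arng = np.random.default_rng(seq)
        b = arng.normal(model.background_mean, model.background_sd,
                        size=(model.n_probes, model.n_scans)) * bg_scale
        if model.noise_model == "cauchy":
            eps = arng.standard_cauchy((model.n_probes, model.n_scans)) * sigma
        else:
            eps = arng.normal(0.0, 1.0, (model.n_probes, model.n_scans)) * sigma
        raw[:, a, :] = gains * x[:, None] + b + eps

    raw = np.clip(np.round(raw), 0.0, model.ceiling)

    probe_ids = np.array([f"P{i:06d}" for i in range(model.n_probes)])
    control = np.where(mask, CONTROL_NEGATIVE, CONTROL_EXPERIMENTAL)
    scanset = ScanSet(
        probe_ids=probe_ids,
        control_type=control,
        intensities=raw,
        scan_labels=tuple(f"scan{j + 1}" for j in range(model.n_scans)),
        ceiling=model.ceiling,
    )
    truth = GroundTruth(expression=x, gains=gains, negcontrol_mask=mask,
                        model=model)
    return scanset, truth


def default_study_fixture(mini: bool = False, seed: int = 2010,
                          **overrides) -> tuple[ScanSet, GroundTruth]:
    """The standard simulated study: 22575 probes x 40 arrays x 3 scans with
    162 negative controls, or a reduced ``mini`` variant (2000 probes x 8
    arrays, 40 controls) small enough for routine test runs.

    Keyword overrides are passed through to :class:`TruthModel`.
    """
    if mini:
        params = dict(n_probes=2000, n_arrays=8, n_negcontrols=40)
    else:
        params = dict(n_probes=22575, n_arrays=40, n_negcontrols=162)
    params["seed"] = seed
    params.update(overrides)
    return simulate_scanset(TruthModel(**params))
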