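# Methods

## Generative model for multi-scan studies

`scanfuse.simulate` draws a technical-replicate study: one reference RNA
pool hybridized to `n_arrays` arrays, each scanned at an ordered ladder of
PMT gains `g_1 < … < g_m`.  Observed fluorescence is

    raw_iaj = clip(round(g_j · x_ia + b_iaj + ε_iaj), 0, ceiling)

with the pieces defined as follows.

* **True expression `x_i`** — log-normal(`expression_meanlog`,
  `expression_sdlog`), identical across arrays because technical replicates
  share one RNA pool; zero for negative-control probes, which therefore
  carry background only.  Defaults (meanlog 5.86, sdlog 2.2) put the median
  true signal near the low-scan background bound, so roughly half of all
  probes sit inside the background on the low scan — the regime in which
  questions about fusing scans are interesting at all.  There is no claim
  that any particular real dataset is log-normal; it is a stand-in with a
  realistic dynamic range (raw intensities span the full 16-bit scale).
* **Background `b`** — Gaussian with mean `background_mean · g_j^γ` and sd
  `background_sd · g_j^γ`, defaults 400 and 80 FLU at unit gain with
  exponent γ = `background_gain_exponent` = 1.2.  Purely proportional
  background (γ = 1) would make the log2 signal-to-noise ratio
  gain-invariant; real scanners show background (dark current, glass
  autofluorescence) growing faster than specific signal as the PMT voltage
  rises, and γ > 1 reproduces exactly that: negative-control means increase
  and SNR decreases with the scan level.
* **Noise `ε`** — Gaussian or Cauchy, scale
  `σ_j = noise_scale_coeff · median(expression law) · g_j`.  The
  coefficient is dimensionless (a fraction of the median true signal);
  multiplying by the gain gives the proportional-scale structure assumed by
  the Cauchy functional-regression model.  Default 0.05.
* **Clipping and rounding** — values are rounded to integer FLU (scanners
  emit counts) and clipped to `[0, 65535]`.  Oracles in the tests account
  for the rounding.

Seeding: one master seed; the expression vector and each array's noise
stream are spawned deterministically from it, so any array subset is
reproducible bit-for-bit.

What the generator does **not** emulate: spatial artefacts, print-tip
effects, dye chemistry, probe-sequence effects, and any dependence between
probes.  Tests passing on these simulations therefore demonstrate
correctness of the algorithms under the stated model, not performance on
any particular real array platform.

## Fusion algorithms — numerical choices

**Correction-factor scaling.**  Window (20000, 30000) FLU and imputation
threshold 50000 FLU, both on the raw scale.  Defined for exactly one
low/high pair; extra scans are ignored.  An empty window raises an error
suggesting a wider window rather than silently extrapolating.

**CSML.**  The resistant line uses least trimmed squares (sum of the `h`
smallest squared residuals, default `h = n/2 + 1`), minimized by
concentration steps from 30 random two-point starts plus the OLS start,
with a fixed internal seed so fits are deterministic.  The residual spread
`σ_r` (1.4826·MAD) mixes both scans' noise; it is split under the same
proportional-noise assumption used elsewhere (`σ_high = a·σ_low`), giving
`σ_high = σ_r/√2`.  Unclipped probes have a closed-form quadratic
minimizer; clipped probes are solved by bisection on the derivative of the
convex censored objective (90 iterations, bracket expanded geometrically
until it straddles the root).  `σ_r` is floored at `1e-9 · median(high)` so
noiseless data do not divide by zero.  The intercept is estimated, not
forced through zero, because background offsets differ between PMT
settings.

**Cauchy functional regression.**  `β_1 ≡ 1`, so estimates live on the
lowest-scan scale.  Alternating optimization: the per-probe profile of `x`
is a vectorized 1-D search — the likelihood has one mode of width ~σ near
each unclipped `y_j/β_j`, so every candidate mode is refined by a σ/2
grid plus golden-section search within ±5σ and the best refinement wins
(the per-probe results match brute-force grid searches; when two modes tie
to ~1e-5 log-likelihood units the chosen location is arbitrary, which is a
property of the likelihood, not of the optimizer).  `(β_2..m, σ)` are then
updated by Nelder–Mead on the log scale with an explicit initial simplex
(fixed absolute steps in log space keep the optimization path equivariant
under rescaling of the data).  Up to 8 outer iterations, stopping when the
log-likelihood changes by < 1e-8 relative.

σ is floored at `1e-6 · median(Y)`.  A fit ending on the floor sets
`degenerate_scale_flag` instead of failing: with two scans, fitting one
scan exactly gains `−log σ` while the Cauchy tail penalizes the other scan
only `+log σ`, so the profile in σ is flat towards zero and the estimate
collapses; with three or more scans the penalty is `2·log σ` and the
collapse disappears.  The flag thus *is* the two-scan pathology, observable
rather than fatal.  Probes censored in every scan carry no information
about `x` beyond a bound and are pinned at the ceiling on the output scale
with provenance `fully-censored`.

## Normalization

Cyclic lowess on log2(x+1): for each array pair, a lowess fit (span 2/3,
three robustifying iterations, the statsmodels `delta` speedup at 1% of the
A-range) of `M = x_a − x_b` on `A = (x_a + x_b)/2` is split half-and-half
between the two arrays, preserving the pair mean and hence the grand mean.
Default 3 sweeps, the convention of the reference implementations.  The
sweep has no exact fixed point: fit magnitudes decay to the lowess noise
floor and then wander slowly, so the procedure is only approximately
idempotent and approximately symmetric in array order (both properties are
tested at the level the iteration actually attains, and the single-sweep
behaviour is cross-checked against limma's `normalizeCyclicLoess`).
Normalization is applied within each acquisition approach across arrays;
single-channel data only.

The background bound is `mean + 3·sd` (sample sd) of the negative-control
probes on the normalized log2 scale, per array.

## Quality metrics

All on the normalized log2 scale.  SNR = per-array median minus
negative-control mean.  Dynamic range counts probes strictly above the
background bound and strictly below 10% of saturation; the upper filter is
evaluated on raw FLU (`raw < 0.1·ceiling`) using each single scan's own
values and, for fused data, the raw low scan — the low scan is what
saturates last, so it governs the usable upper end.  A config switch
(`upper_raw=None`) falls back to comparing normalized values against
`log2(0.1·65535)`.  Paired t-tests are two-sided with Bonferroni factor
C(k,2); zero-variance differences are reported as not-applicable rather
than propagating NaN.

## Reproducibility analysis

Spearman correlations: average ranks for ties, product-moment correlation
of rank vectors; a constant array yields missing (NaN) correlations.  The
summary statistic is the mean of the upper triangle of the array × array
matrix.  Percentile bootstrap over probes (the sampling units of each
correlation), default B = 10000, CI level Bonferroni-adjusted by the number
of acquisition approaches compared (7 in the standard design).  Resampled
rank vectors are correlated without re-ranking — the standard large-n
shortcut; a coverage study in the tests confirms ≥ 90% empirical coverage
of nominal 95% intervals for bivariate-normal data.  Intensity strata are
quantile bins of the across-array median (sizes differing by at most one);
note that conditioning on the median induces a small negative correlation
within extreme bins even for independent noise, which is a property of the
stratification, not a bug.  The sliding window (default 2000 probes,
stride 100 — the stride is a package choice) slides over probes sorted by
the across-array median and is aligned by the percentile of the window
centre.

## Pipeline

`run_pipeline` compares seven approaches by default: low/medium/high single
scans, correction-factor scaling, CSML, and the Cauchy functional
regression with 2 scans (lowest+highest) and 3 scans.  Everything is
deterministic given the master seed (bootstrap streams are spawned from
it).  Each summary figure of the analysis — ratio-intensity (MA) spread,
negative-control boxes, SNR, dynamic range, window correlation curves,
residual diagnostics, and the intensity-density/correlation overlay — has a
machine-readable artifact in the report bundle.  The MA reference is the
probe-wise mean across the replicate arrays (with replicates of one RNA
pool there is no second channel to ratio against); this is recorded as a
config option.

## Problem sizes

The full-scale study (22575 probes × 40 arrays × 3 scans, 162 negative
controls) is available via `default_study_fixture()`.  The test suite and
the acceptance script run the same pipeline at reduced sizes chosen to keep
a full run in the low minutes on one CPU: a 2000 × 8 mini fixture for
qualitative checks, 5000 × 4 with Cauchy noise and >20% high-scan
saturation for the censoring-benefit and scale-collapse analyses, and a
2500 × 8 study with B = 2000 bootstrap replicates for the end-to-end
summary.  All qualitative findings reported by the acceptance script are
size-stable in this range.

## Known limitations

* The Cauchy functional regression is fitted independently per array; no
  information is shared across arrays.
* The CSML noise split (`σ_high = a·σ_low`) is an assumption, not an
  estimate; only the total residual spread is identified by the line fit.
* Near-tied likelihood modes make individual latent estimates
  ill-conditioned at the ~1% level for a small fraction of probes (the
  attained likelihood is still optimal).
* The simulator's independence across probes means decile-level correlation
  structure in real data (shared hybridization artefacts) is not emulated.
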