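# scanfuse

Microarray scanners trade off two failure modes through one dial, the
photomultiplier-tube (PMT) voltage: scan at low sensitivity and weakly
expressed probes drown in background; scan high and strongly expressed
probes saturate at the 16-bit ceiling (65535 FLU).  A family of
*multi-scan* acquisition strategies scans the same array several times at
different PMT settings and fuses the scans into one expression estimate per
probe.  `scanfuse` implements three such fusion algorithms together with the
quality and reproducibility metrics needed to judge whether fusing scans is
worth the extra scanner time — and a synthetic multi-scan generator with
known ground truth so the whole pipeline is testable without any array data.

It is aimed at people working with scanner-level microarray data
(transcriptomics cores, methods developers) and at anyone who needs a
censored-regression treatment of clipped fluorescence intensities.

## The three fusion algorithms

With scans `j = 1..m` of the same array, observed intensity `y_ij` for probe
`i`, and detector ceiling `C`:

* **Correction-factor scaling (Lyng).**  Probes with high-scan signal in a
  mid-intensity window (default 20000–30000 FLU) define a ratio
  `k = mean(high/low)`; high-scan values above an imputation threshold
  (default 50000 FLU) are replaced by `k·low`.  Two scans only.
* **Clipping-saturation maximum likelihood (CSML).**  A resistant
  least-trimmed-squares line `high = a·low + b` is fitted over unclipped
  probes; each probe's latent intensity `t_i` then minimizes
  `(low_i − t_i)²/σ_l² + (high_i − (a·t_i + b))²/σ_h²`, with the second term
  replaced by the Gaussian censoring tail `−2·log P(a·t_i + b + ε ≥ C)` when
  the high scan is clipped.  Fused values are reported de-censored on the
  high-scan scale.  Two scans only.
* **Cauchy functional regression (Khondoker).**  An errors-in-variables
  model over any number of scans:
  `y_ij = clip(β_j·x_i + ε_ij, C)`, `ε_ij ~ Cauchy(0, σ·β_j)`, `β_1 ≡ 1`,
  fitted by alternating profile likelihood (per-probe `x_i`, then `(β, σ)`).
  Clipped observations enter through the Cauchy survival tail.  The
  proportional-scale assumption `σ_j = σ·β_j` keeps the likelihood bounded,
  but with only two scans the fitted `σ` can still collapse towards zero —
  the fit is then flagged (`degenerate_scale_flag`) rather than failed,
  because that pathology is itself a finding.

## Quality and reproducibility metrics

All metrics work on log2, cyclic-lowess-normalized probe × array matrices:
per-array negative-control mean and CV, signal-to-noise ratio (median log2
intensity minus negative-control mean), dynamic range (share of probes above
the background bound `mean + 3·sd` of negative controls and below 10% of
saturation — evaluated on the raw low scan for fused data), paired
t-tests with Bonferroni correction across acquisition approaches, and
technical-replicate Spearman correlations with percentile-bootstrap
confidence intervals (overall, per intensity decile, and in a 2000-probe
sliding window).

## Worked example

```python
from scanfuse import RunConfig, run_pipeline

cfg = RunConfig(simulation=dict(n_probes=2000, n_arrays=8, n_negcontrols=40),
                B=500, window=500, stride=100, seed=1, log_level="WARNING")
report = run_pipeline(cfg)
print(report.summary_frame().round(4).to_string())
```

```
                 mean_corr  ci_lower  ci_upper  negctrl_mean  negctrl_cv     snr  dynamic_range
approach
low                 0.9403    0.9356    0.9450        8.6087      0.0381  0.9547         0.4015
medium              0.9213    0.9146    0.9277       10.6384      0.0300  0.7933         0.2030
high                0.9136    0.9072    0.9196       11.7433      0.0263  0.7716         0.0168
lyng                0.9137    0.9063    0.9199       11.7433      0.0263  0.7716         0.3588
csml                0.9494    0.9453    0.9527       11.7831      0.0152  0.7092         0.4782
khondoker_2scan     0.9279    0.9222    0.9330        8.6930      0.0407  0.9021         0.3627
khondoker_3scan     0.9472    0.9427    0.9515        8.8214      0.0259  0.7987         0.4476
```

Reading the table: background (negctrl_mean) rises and the SNR falls as the
PMT increases, so the low scan has the widest dynamic range of the single
scans; the Lyng fusion inherits the high scan's background; the 3-scan
Cauchy fit is among the most reproducible approaches (mean replicate
Spearman correlation with its Bonferroni-adjusted bootstrap CI), while the
same model restricted to 2 scans loses reproducibility — its scale estimate
collapses.  On this simulated study 46.7% of probes fall below the
background bound, so correlations are driven by the upper half of the
intensity range.

A CLI mirrors the library (`scanfuse simulate | assemble | combine |
normalize | qc | corr | run`); see `scanfuse --help`.

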