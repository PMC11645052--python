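# mferobust

Robustness analysis of **Multiscale Fuzzy Entropy (MFE)** as an EEG
biomarker for Alzheimer's disease, with and without a per-subject
**amplitude transformation (AT)**.

## The problem

Fuzzy entropy measures the regularity of a signal by comparing templates of
`m` consecutive samples under a continuous similarity grading

```
D_ij = exp(-d_ij^n / r),      FE(m, n, r) = -ln(phi_{m+1} / phi_m)
```

where `d_ij` is the Chebyshev distance between baseline-corrected
templates, `r = r_coeff * SD` the tolerance, and `phi_m` the mean
similarity over template pairs. MFE evaluates FE on coarse-grained copies
of the signal (scale factors 1–20). Because `d` carries the raw amplitude
while `r` only scales with one SD, the statistic is biased by inter-subject
and inter-channel amplitude differences — EEG amplitudes vary strongly
across acquisition systems — and it is notoriously sensitive to the choice
of `(m, r)`.

The AT maps each subject's epochs to a common range `[-5, 5]` with a single
affine map (bounds = medians of per-epoch global extrema, pooled over all
channels), exactly cancelling per-subject gain while preserving
inter-channel ratios. This package implements the full two-arm experiment
that quantifies how much that stabilizes MFE:

* **synthetic cohorts** — seeded two-group (HS/AD) 19-channel EEG-like
  signals with a controllable group regularity difference and log-normal
  subject/channel gains (the amplitude heterogeneity that motivates AT);
* **preprocessing** — 0.5–45 Hz FIR filtering (order = one 3 s window),
  causal application with the 3 s transient trimmed, 3 s epochs, AT;
* **entropy** — FE/MFE over the 12-combination grid `m ∈ {2,3,4}`,
  `r ∈ {0.10, 0.15, 0.20, 0.25}`;
* **group statistics** — pooled two-sample t-tests per (channel, scale)
  cell, percentage of significant comparisons (PSC), Cohen's D, Lilliefors
  and Levene assumption checks, central-t power;
* **clustering evaluation** — 2-means on the 60×19 scale-averaged feature
  matrix, scored with V-measure / ARI / AMI.

## Worked example

```python
from mferobust import CohortSpec, ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    cohort=CohortSpec(n_per_group=10, n_channels=10, fs=100.0,
                      duration=27.0, seed=1),
    scales=tuple(range(1, 11)), check_assumptions=False)
bundle = run_experiment(cfg)
for arm in ("raw", "transformed"):
    a = bundle.aggregates[arm]
    print(f"{arm:12s} PSC {a['psc_mean']:5.1f} ± {a['psc_sd']:4.1f} %  "
          f"CD_mean {a['cd_mean']:.2f}")
print(f"power: {bundle.power.power:.2f} %")
```

prints

```
raw          PSC  56.9 ± 12.9 %  CD_mean 1.04
transformed  PSC  70.5 ±  4.8 %  CD_mean 1.56
power: 91.04 %
```

The transformed arm reaches a higher mean PSC with less than half the
spread across the 12 `(m, r)` combinations: after AT, the fraction of
significant (channel, scale) comparisons barely depends on the parameter
choice, which is the robustness property under study. (Power is computed
at this synthetic cohort's own mean effect size, which is large.)

The same experiment is available from a shell:

```bash
mferobust run --seed 1 --out results/run1      # full default experiment
mferobust simulate --seed 1 --out cohort/      # just write a cohort
mferobust report --summary results/run1/summary.json
```

`run` writes `table3.tsv` (t/p ranges, Cohen's D, PSC per combination and
arm), `table4.tsv` (clustering metrics) and `summary.json`.

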