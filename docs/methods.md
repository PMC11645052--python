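# Methods

## Entropy model

Fuzzy entropy is computed from baseline-corrected templates: the template
`X_i^m = (x_i, ..., x_{i+m-1}) - mean` is compared to every other template
by Chebyshev distance `d_ij`, graded with the exponential membership
`D_ij = exp(-d_ij^n / r_abs)`, and `phi_m` is the mean of `D_ij` over
`i != j` with the standard normalization (`N - m` templates for both the
`m` and `m + 1` stages, so both averages run over the same pair count).
`FE = -ln(phi_{m+1} / phi_m)`; natural logarithm throughout.

Choices worth calling out:

* **Membership exponent.** `D = exp(-d^n / r_abs)` (tolerance enters
  linearly, not as `(d/r)^n`). With the default `n = 2` this makes FE
  genuinely amplitude-sensitive even when `r_abs` is proportional to a
  signal SD: scaling the data by `c` scales `d^2/r` by `c`. That
  sensitivity is the phenomenon the amplitude transformation addresses, so
  it is retained deliberately. The exact invariance that does hold — and
  is tested — is `FE(c*x, c^n * r_abs) = FE(x, r_abs)`.
* **Fuzzy power `n`.** Not fixed by the analysis protocol; default 2 (the
  common FuzzyEn convention), configurable.
* **Tolerance reference (`r_mode`).** `r_abs = r_coeff * SD`. Default
  `per_subject_global`: one SD per subject over the full multichannel
  epoch array actually fed to the entropy stage (raw or transformed
  respectively). A shared within-subject reference is what lets
  channel-gain differences bias per-channel FE — the mechanism under
  study. `per_epoch_channel` (SD of each epoch's channel signal) is
  provided for comparison.
* **`r_abs` fixed across scales** (computed once at scale 1, not
  recomputed on coarse-grained series), the standard multiscale
  convention; recomputing would erase the scale-dependent variance decay.
* **Coarse-graining**: non-overlapping means of `s` consecutive samples.
* **Per-scale output.** The scale-resolved FE vector is the primary
  output (20 values per channel after epoch averaging); the across-scale
  mean is used only where a scalar per channel is needed (the clustering
  features).
* **Degenerate inputs.** `phi > 0` always (memberships are strictly
  positive), so the log ratio is defined; constant sequences give exactly
  FE = 0; a zero SD in the tolerance reference is an error. With very
  small `r_abs` the pair sums are dominated by the closest templates and
  the estimate gets noisy — visible in the scaled experiments at `m >= 3`.

## Preprocessing

Band-pass 0.5–45 Hz windowed-sinc FIR (Hamming), order = number of samples
in one 3 s window (600 taps + 1 at 200 Hz). The filter is applied in a
single causal pass and the first 3 s are discarded as the transient;
zero-phase (forward–backward) filtering is deliberately not used, because
the protocol removes a causal transient. Epochs are consecutive,
non-overlapping 3 s windows; a trailing remainder is dropped.

AT bounds: per epoch, the max and min over the pooled channels × samples
block; `x_max` / `x_min` are the medians of those per-epoch extrema; one
affine map `[x_min, x_max] -> [-5, 5]` per subject is applied to all
channels, preserving inter-channel amplitude ratios. Samples outside the
bounds (possible, since medians are not extrema) follow the same affine
rule — no clipping, the map stays strictly increasing. The map is exactly
invariant to a positive rescaling of the whole recording; composed with
the (deterministic) entropy stage this removes per-subject gain exactly.

## Group statistics

Per (channel, scale) cell: pooled-variance two-sample t (two-sided), df =
`N_HS + N_AD - 2`, Cohen's D with the pooled SD. PSC = percentage of cells
with `p < alpha` strictly, no multiple-testing correction (PSC is defined
on raw p-values). The per-combination effect aggregate averages |d| —
signed averaging would cancel opposing channels and cannot produce the
published per-combination means (~0.95 with small SD); the signed mean is
reported alongside. Spreads (d across cells, PSC across combinations) use
the population form (divisor N), which is the form consistent with the
published across-combination SD of the raw PSC column (9.10).

Assumption checks are recorded per cell, never gating: Lilliefors
normality (KS statistic with estimated mean/SD; p-value from a seeded
Monte-Carlo null of 10^4 replicates, cached per sample size — exact at any
n and reproducible) and mean-centered Levene. Power uses the central-t
shift approximation: `beta = T_df(t_crit - d * sqrt(n1 n2 / (n1 + n2)))`.

## Clustering evaluation

Features: per subject, the across-scale mean MFE per channel (60 × 19 at
the default cohort). No standardization by default — AT already brings
subjects to a common scale, and z-scoring would mask exactly the raw-arm
amplitude pathology being measured (a flag enables it). k-means, k = 2,
k-means++ with 10 restarts and a fixed seed. External indices: V-measure,
ARI, and AMI with the arithmetic-mean normalization.

## Synthetic cohorts

Each channel is `g_subj * g_chan * mix(t)` with
`mix = (a * osc + (1 - a) * noise) / sqrt(a^2 + (1-a)^2)`: a unit-variance
sinusoid (9 Hz, random phase per channel) blended with unit-variance noise
and renormalized so the regularity fraction `a` changes only the signal's
*structure* — without the renormalization, `a` would also change the
variance and group membership would leak into amplitude, confounding the
raw-vs-AT comparison. Amplitude heterogeneity comes exclusively from the
log-normal gains (`exp(N(0, sigma^2))`, subject sigma 0.5, channel sigma
0.1 by default): subject gains emulate different acquisition systems,
channel gains electrode-level spread. Defaults `a_HS = 0.2`, `a_AD = 0.5`
encode the reduced EEG complexity reported in Alzheimer's disease (the AD
group is more regular, hence lower entropy).

Noise is pink (1/f-shaped via spectral weighting of white noise) by
default — the realistic EEG choice; with white noise the group effect
becomes strongly m-specific (large at m = 2, weak at m = 3) and the
across-combination comparison degenerates. White noise remains available.

Per-subject seeds are `SeedSequence([cohort_seed, subject_index])`, so any
subject can be regenerated independently of generation order. What the
generator does **not** emulate: eye-blink/EMG artifacts, volume
conduction, electrode montage effects, non-stationarity, and realistic
between-subject spectral variability. Passing tests on these cohorts
demonstrate the pipeline's statistical behavior under controlled
amplitude heterogeneity, not clinical performance on real EEG.

## Scaled study conditions

The full protocol (60 subjects, 200 Hz, 51 s, 19 channels, scales 1–20,
12 combinations × 2 arms) runs in roughly 25 minutes on one core via the
shared-distance-matrix entropy path (`multi_combination_profiles`, which
reuses each template distance matrix across the whole (m, r) grid). The
stochastic test experiments use reduced conditions chosen once:

* 100 Hz sampling, 27 s (8 epochs of 300 samples after trim), scales
  1–10, 10 subjects per group;
* null calibration: 19 channels, one combination (m = 2, r = 0.20), raw
  arm, equal group regularities, homogeneous subject amplitudes
  (subject gain sigma 0), seeds 0–9;
* robustness experiment: 10 channels, all 12 combinations, both arms,
  heterogeneous gains (subject sigma 0.5), seeds 1–10.

The null calibration deliberately switches subject gains off: with heavy
log-normal amplitude gains and 10 subjects per group the t-test becomes
*conservative* (empirical cell-level rejection near 1% at nominal 5%),
a known small-sample effect of strongly skewed data. This is documented
as a limitation of entropy-based group testing on small heterogeneous
cohorts; under exchangeable homogeneous-amplitude nulls the pipeline's
rejection rate is nominal.

## Known limitations

* The exponential membership with `n = 2` makes absolute FE values depend
  on the overall amplitude convention; only AT-processed values are
  comparable across acquisition setups.
* Per-combination published table values derive from access-restricted
  clinical EEG and are not reproducible from synthetic cohorts; only the
  in-table aggregates and the qualitative robustness direction are
  checked.
* Lilliefors p-values are Monte-Carlo estimates (resolution 1/10^4 by
  default).
* k-means restarts make the clustering deterministic given the seed, but
  the chosen partition can still be a local optimum for unfavorable
  feature geometries.
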