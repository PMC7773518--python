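# Methods

## The analysis

The pipeline reproduces a device-validation workflow for the sensory
organization test (SOT): a clinical posturography device (Equitest) reports
a scalar equilibrium index (EI) per trial, while a VR-based alternative
records raw center-of-pressure (COP) trajectories on a force plate. The
question is whether COP-derived scores agree with the clinical score,
separately for each of the six SOT sensory conditions.

### Signal conditioning

Each COP trace (20 s at 50 Hz by convention; any uniform rate is accepted)
is linearly detrended per axis by least squares, then smoothed with a
centered moving average. The filter window defaults to 20 ms, which rounds
to a single sample at 50 Hz and is therefore the identity at the native
rate; the parameter exists for force plates streaming faster. The filter
order is fixed as detrend → smooth. At the trial edges the window shrinks
rather than padding, so no samples are invented and results are exactly
reproducible.

### Estimated equilibrium index

The clinical score models the body as an inverted pendulum swaying about
the ankle within a theoretical anterior-posterior limit of 12.5°. Its
COP-based estimate converts the peak anterior and peak posterior excursions
of the detrended AP channel to angles over an estimated center-of-gravity
height (0.56 × stature):

    theta_ant  = asin(max(AP) / h),   theta_post = asin(|min(AP)| / h)
    eEI        = 100 * (1 - (theta_ant + theta_post) / 12.5deg)

clamped to [0, 100]. Clamping is a deliberate choice: the clinical scale is
bounded (sway at or beyond the limit scores 0), and an unbounded estimate
would leave the two scores on different supports. Excursions at or beyond
the COG height raise a domain error — the geometric model has no answer
there. A trace that never crosses to one side contributes a zero angle for
that side.

### The other COP metrics

* **95% ellipse area** uses the chi-square prediction-ellipse convention:
  area = π · χ²₀.₉₅(2 df) · √det(S), S the 2×2 sample covariance (n−1
  denominator), χ²₀.₉₅(2) ≈ 5.9915. The small-sample F-based correction is
  not applied; the quantile is configurable.
* **Path length** is the sum of per-step Euclidean displacements.
* **DFA α** integrates the mean-removed AP series, removes an order-1
  polynomial in non-overlapping boxes at 12 log-spaced sizes from 4 samples
  to a quarter of the series, and takes the slope of log RMS residual vs
  log box size. All four knobs sit in `DfaConfig`; the defaults follow
  common stabilogram practice. A constant series has zero fluctuation and
  is reported as a missing α (NaN) rather than an error, so one degenerate
  trial does not abort a batch.

### Trial selection and outlier screening

Only the final trial per (participant, condition, device) enters the
analysis; the first trial is familiarization. The primary scores (EI and
eEI) are then screened per device-condition with a *single-pass* 3-SD rule:
mean and SD come from the full unfiltered vector, each flagged entry
removes that participant's whole pair in that condition, and the screen is
not re-run on the filtered data. Single-pass screening is the only reading
consistent with a one-shot removal of individual trials; note it is
conservative — with n participants the largest attainable |z| is
(n−1)/√n, so the rule cannot fire at all for n ≤ 10. Screening is applied
to the primary scores only; cascading it over every COP metric would
multiply removals without a protocol to arbitrate them.

### Agreement statistics

ICCs are two-way single-measure coefficients from the mean-squares
decomposition of the n×2 score table: consistency (ICC(3,1)-type) forgives
a systematic device offset, absolute agreement (ICC(2,1)-type) penalizes
it. Interpretation bands follow the standard poor (<0.5) / moderate
(0.5–0.75) / good (0.75–0.9) / excellent (≥0.9) convention. Pearson r uses
the two-sided t-transform p-value (n−2 df) and is labelled on |r|
(negligible <0.3, weak, moderate, strong, very strong ≥0.9), since an
inverse association is as informative as a direct one here. Bland-Altman
limits are mean(d) ± 1.96·sd(d) with the n−1 SD; the multiplier is
configurable. Conditions with fewer than 3 valid pairs degrade to warnings
and missing statistics rather than aborting the batch.

## The synthetic study generator

No human recordings ship with the package; `sotpipe.synthetic` generates
the full paired design instead: 20 participants (7 male, 13 female;
heights drawn per sex from N(1.79, 0.079²) and N(1.66, 0.072²) m — the
cohort's means with standard errors converted to SDs), six SOT conditions
plus the two VR-only head-tracking conditions, two devices, two 20-s
trials per condition at 50 Hz — 28 trials per participant.

Sway traces are mean-reverting first-order autoregressive processes
(x[k+1] = φx[k] + η, φ = exp(−1/(fs·τ)), τ = 1 s), started from the
stationary distribution, so 20-s trials stay bounded and the inverse sine
always remains defined. Per-condition stationary sway SDs default to
4–12 mm, increasing with task difficulty (millimetres of sway on a stable
surface, roughly a centimetre on foam); they set the condition mean score
through the same inverse-sine geometry the metric uses, so raising a
condition's sway scale strictly lowers its mean eEI.

Scores follow a latent bivariate model per participant × condition: a
stability factor z drives the Equitest score, and the VR latent
w = ρz + √(1−ρ²)z′ is correlated with z at the planted agreement ρ
(default 0.75). Both device scores are the condition mean plus the scaled
latent plus trial noise (SD 3 score units), clamped to [0, 100]. Each VR
trial's AP channel is then rescaled so that the pipeline's eEI reproduces
the drawn VR score *exactly* (the target combined sway angle is solved for
an amplitude factor by bracketed root finding, and the channel is written
pre-detrended so the pipeline's conditioning is a no-op on it). This makes
the generator's statistics available in closed form, ignoring the rare
clamp events: with between-subject SD s, noise SD σ and device offset δ,

    ICC(consistency) = rho * s^2 / (s^2 + sigma^2)
    ICC(absolute)    = 2 rho s^2 / (2(s^2 + sigma^2) + delta^2)
    Pearson r        = rho * s^2 / (s^2 + sigma^2)

These targets are emitted in a truth record (`truth.json`) and anchor the
parameter-recovery tests: over 50 replicate studies at n = 20 the mean
recovered ICC(consistency) sits within ±0.15 of its target per condition,
tightening to ±0.05 at n = 200.

What the generator does *not* emulate: intermittent postural control,
rambling-trembling structure, distinct dynamics for the VR tracking modes,
or realistic cross-metric coupling (ellipse area and path length inherit
only the AR process's scale). Passing tests therefore demonstrate that the
pipeline recovers planted agreement structure from data with the study's
design and noise levels — not that any particular device pair agrees.

## Numerical choices and edge cases

* A target eEI of exactly 100 would require a zero trace (undefined DFA);
  the generator floors the combined sway angle at 0.02° (eEI ≤ 99.84).
* Uniform sampling is enforced at 1 µs per step; trace files round-trip
  through CSV at 12 significant digits (≤ 1e−9 m error).
* Score clamping at the 0/100 boundaries slightly biases recovered
  statistics in easy conditions (~2% of trials clamp at 100 under default
  settings); the recovery tolerances absorb this.
* Determinism: every trial draws from its own integer-keyed substream of
  the study seed, so a single trial can be regenerated in isolation and a
  fixed study + config yields a byte-identical results CSV.
* Problem sizes in the recovery tests (50 replicates at n = 20, 8 at
  n = 200) keep Monte-Carlo error on the mean recovered ICC near 0.02
  while the whole suite stays quick to run.

## Known limitations

* Only two raters/devices are supported; no ICC confidence intervals.
* The eEI clamping decision and the chi-square (rather than F) ellipse
  convention are declared conventions — validated clinically nowhere in
  this package.
* The 3-SD screen's single-pass inclusive SD cannot flag anything in
  cohorts of 10 or fewer.
* Proprietary force-plate formats (C3D, vendor binaries) are out of scope;
  input is the documented CSV/YAML dialect.
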