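# Methods

## Model

Tumor volume `V(t)` (mL, time in days) follows the Itô SDE

    dV = a V log(b/V) dt + c V / (h + sqrt(V)) dW(t).

The drift is the Gompertz law — exponential-like early growth saturating at
the carrying capacity `b` — whose noise-free solution is
`V(t) = b exp(log(v0/b) exp(-a t))`.  The diffusion term models the
between-patient and micro-environmental scatter of the growth *rate*: the
per-volume amplitude `sigma(V) = c/(h + sqrt(V))` decreases with volume,
matching the observation that small tumors show far larger relative
growth-rate variation than large ones.  Assumptions inherited from this
model class: a single well-mixed cell population, no spatial structure, no
explicit dependence on nutrients, vasculature, age or genetics, and growth
dynamics unchanged by resection.

Reference parameter values (fitted to the Trondheim cohort of 94 untreated
glioblastoma patients): `a = 0.009916` 1/day, `b = 121.6` mL, `c = 0.0769`,
`h = 0.2241`.

## Fitting pipeline

1. **Drift (a, b).**  Each record `(V1, dt, V2)` yields a specific growth
   rate `SGR = (ln V2 - ln V1)/dt`.  Since `E[SGR] ~ a ln b - a ln V1`, an
   OLS regression of SGR on `ln V1` gives `a = -slope` and
   `b = exp(intercept/a)`.  Linearised OLS is used rather than a nonlinear
   fit: it is closed-form, deterministic, and exact for the model family.
2. **Noise (c, h).**  First-scan volumes are binned at separators
   10, 20, ..., 60 mL (first bin closed below, last bin open-ended overflow,
   dropped by default as too sparse).  Within each remaining bin the sample
   SD of SGR is computed; `sigma(V) = c/(h + sqrt(V))` is fitted to the
   (mean bin volume, SD) pairs by bounded Levenberg–Marquardt-style least
   squares (`c >= 0`, `h > 0`, default init (0.1, 0.5), perturbed restarts on
   failure, non-identifiability flagged when the SDs carry no variation).
   The dispersion statistic is SGR by default (`v1` selectable): the
   magnitude of the reference `sigma(V)` (~0.02 at 10 mL) is only consistent
   with growth-rate dispersion, not raw-volume dispersion within 10-mL bins.
   Caveat for cohort-level fits: the SD of SGR estimates
   `sigma(V) * E[1/sqrt(dt)]` rather than `sigma(V)` itself when inter-scan
   intervals vary, so cohort-recovered `c` is scale-compressed and `h` weakly
   identified; the parameter-recovery criterion for cohort pipelines is
   therefore (a, b), with (c, h) recovery checked on noiseless fixtures.
3. **Survival surfaces.**  Monte-Carlo waiting-time summaries over the
   39-cell grid (`v0 = 10..60`, `vc = 20..100`, `vc >= v0 + 10`) are fitted
   by unweighted OLS: a plane `{1, v0, vc}` for the mean and the restricted
   quadratic `{1, v0, vc, v0*vc, vc^2}` (no `v0^2` term) for the SD.

## Simulation numerics

- **Scheme.**  Euler–Maruyama on `x = ln V` with the Itô-corrected drift
  `dx = [a ln(b/V) - sigma(V)^2/2] dt + sigma(V) dW`.  Log-space integration
  guarantees positivity for any step; at the fitted noise scale the
  correction is ~1% of the drift.
- **Step.**  Default 0.05 day.  Halving the step moves the (10 to 20 mL)
  mean first-passage time by well under 0.5 day, far below the Monte-Carlo
  standard error of a 500-path ensemble; deterministic-limit paths track the
  closed form to ~5e-5 relative error.
- **First passage.**  A path crosses a threshold at the first *grid* time
  with `V >= vc`; no sub-step interpolation, so the discretisation bias is
  bounded by one step (discrete monitoring biases times slightly upward).
  Paths are capped at `t_max = 5000` days; with thresholds below the
  carrying capacity censoring is practically impossible, but censored paths
  are counted and by default any censoring is an error.  All thresholds
  sharing a starting volume are monitored on the same simulated paths, so a
  full grid costs one integration per starting volume.
- **RNG.**  Every operation takes a seed and builds one
  `numpy.random.Generator`; multi-stage runs expand a single top-level seed
  into independent per-stage child seeds (recorded in the artifacts), so
  results are reproducible and stage order is irrelevant.

## Prediction bands and verification

Paired-scan verification follows the `|V2 - mu| <= 3 sigma` rule: simulate
500 paths from `V1` over `dt`, compute the ensemble mean and SD, and test
the observed `V2`.  On a self-generated cohort this band covers ≥ 99% of
records (by construction); the original study reported ~62% on real data,
which measures model–data mismatch rather than pipeline error.

Two conventions coexist for "99%" bands and both are exposed via `k_sd`:
literal `mean ± 3 SD` (the verification rule; 99.7% under normality) and the
normal 99% quantile `mean ± 2.576 SD`.  Reconstruction of the independently
reported per-patient prediction intervals shows they carry probability 0.99
in the quantile sense: for the 1.592 mL / 13-day record the model's exact
volume SD is 0.426 mL (fine-step oracle), so the 2.576-SD band lands within
~0.05 mL of the reported bounds while a literal 3-SD band is systematically
~0.15 mL wider on each side.  `prediction_interval` defaults to `k_sd = 3`;
the quantile variant is a parameter choice, not a refit.

## Protocol calculus

A staged protocol with K resections partitions the disease course into K+1
growth segments.  Segment waiting times are modelled as jointly normal with
surface means/SDs; total survival has mean equal to the sum of segment means
(independent of correlations) and SD `sqrt(sigma^T R sigma)` — the square
root is applied because the quadratic form is a variance, and the
reconstructed double-resection SDs (e.g. 36 days for the 492-day schedule)
confirm that reading.  Conventions:

- Correlations are scenario parameters, not estimates; `R` must be symmetric
  with unit diagonal and positive semidefinite.  Note that the published
  three-segment scenario triple (0.8, 0, 0.8) is *not* positive semidefinite
  (smallest eigenvalue 1 - 0.8 sqrt(2) < 0) and is rejected; the analysis
  driver uses (0.8, 0.3, 0.8) instead.
- Surface evaluations outside the fitted grid box (`v0` in [10, 60], `vc` in
  [20, 100]) are extrapolations and warn; a negative extrapolated mean (for
  a tiny first segment, e.g. 1 mL to 2 mL) is kept as-is rather than
  clamped, because the published totals require it.
- Zero-length segments (a cut triggered at the volume entering the segment)
  have waiting time identically zero and are skipped.
- The death volume defaults to 100 mL — deliberately below the fitted
  carrying capacity of 121.6 mL so the threshold is reached by drift.

## Synthetic cohort

The real paired-scan cohort is not publicly deposited, so all cohort-level
stages run on synthetic data with its structure: `V1 ~ lognormal(ln 8,
1.05)` (about 95% of draws between 1 and 65 mL, upper tail reaching ~146 mL
in a 94-draw cohort), `dt ~ Uniform(7, 49)` days, and `V2` simulated forward
with the SDE.  Records are redrawn until `V2 > V1` (bounded retries, then a
fresh patient draw), mirroring the original cohort's growth-only selection;
this selection mildly biases fitted `a` upward, which the 25% recovery
tolerance accommodates.  What the synthetic cohort does *not* emulate:
scanner- or method-specific measurement error (the independent re-test
records used ellipsoid estimates), age or genetic covariates, and any
true departure of human glioblastoma growth from the Gompertz-diffusion
law — so passing recovery tests demonstrate pipeline correctness, not
clinical validity.

## Problem sizes

Defaults mirror the study conditions: 94-patient cohorts, 500 simulation
paths per record or grid cell, the 39-cell waiting-time grid, and a 0.05-day
step.  The test suite uses the same sizes for its headline checks (scaling
the grid check to 2000 paths per cell) and smaller ensembles for smoke
tests; each choice is stated where it is used.

## Known limitations

- The waiting-time surfaces are fitted on the 39-cell grid; far outside it
  the plane/quadratic forms are uncontrolled extrapolations (warned, not
  prevented).
- First-passage summaries use sample moments under a normal reading of the
  waiting time; the true distribution is mildly right-skewed for thresholds
  near the carrying capacity.
- Cohort-level noise-strength fitting inherits the SGR/interval confounding
  described above.
- The model is non-spatial and treatment-free by construction; resection is
  an instantaneous volume cut with unchanged post-surgical dynamics.
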