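# Methods

## The model

A participant's waking time splits into sedentary behavior (SB), light
physical activity (LPA), and moderate-to-vigorous physical activity (MVPA).
Dividing each behavior's accelerometer-measured minutes by total wear time
gives a 3-part composition x = (T_SB, T_LPA, T_MVPA) on the simplex. The
analysis model is a linear log-contrast model

    E[y | x, w] = β₀ + a_SB ln T_SB + a_LPA ln T_LPA + a_MVPA ln T_MVPA + γ'w,
    a_SB + a_LPA + a_MVPA = 0,

fitted in pivot isometric log-ratio (ilr) coordinates: for pivot order
(p1, p2, p3), z1 = √(2/3)·ln(p1/√(p2 p3)) and z2 = √(1/2)·ln(p3/p2). The two
coordinates are an orthonormal basis of the log-contrast space, so OLS on
(z1, z2, w) is exactly the model above; refitting with each behavior
pivot-first re-expresses the same fit (identical fitted values, residuals,
predictions) while making that behavior's z1 coefficient the quantity of
interest — its share relative to the geometric mean of the other two. The
identities β_z1(k) = √(3/2)·a_k and Σ_k β_z1(k) = 0 are exact algebra, and
the package verifies them at run time.

Assumptions: linearity in log-shares, homoscedastic Gaussian errors
(classical t inference with n − p degrees of freedom; no robust-SE variant),
and strictly positive parts. The z2 completion for non-MVPA pivots follows
the same √(1/2)·ln(third/second) pattern; any orthonormal completion yields
the same fit, so only z1 reporting depends on it.

## Screening rules and their parameters

* Non-wear: a run of consecutive zero-MET epochs strictly longer than
  60 min (60 epochs of 60 s). The strict inequality follows the "longer
  than" convention; `strict=False` switches to ≥ for groups using that
  variant. No interruption allowance inside a run.
* MET bands: SB ≤ 1.5, MVPA ≥ 3.0, LPA strictly between. The open interval
  (1.5, 1.6) is classified LPA: 1.5 and 3.0 are the operative physiological
  cut-points and the conventional "1.6–2.9" labelling reflects 0.1-MET
  display resolution.
* Valid day ≥ 600 min wear; included participant ≥ 4 valid days. All four
  thresholds are config fields; overrides are recorded in the run log.
* Participant compositions pool minutes across valid days ("total band
  minutes / total wear minutes"); a day-mean variant (mean of daily
  proportion vectors) is available for sensitivity since the two differ
  when wear time varies across days.
* Zero parts (a participant with, say, no MVPA in any valid day) are
  imputed by multiplicative replacement: zero parts set to δ (default
  0.65 × the smallest observed non-zero share of that part), non-zero
  parts scaled by 1 − Σδ. Strategy and δ are configurable; a "fail"
  strategy refuses to impute.

## Nested covariate models

Model 1 is unadjusted; 2 adds sex, age, intracranial volume (ICV); 3 adds
education (≥ 13 y); 4 adds BMI category (< 18.5 and ≥ 25.0 vs 18.5–24.9),
smoking, heavy alcohol use (≥ 60 g ethanol/day); 5 adds medication flags for
hypertension, dyslipidemia, diabetes (11 covariate columns in total).
Missing values are handled by listwise deletion with a logged count. The
ICV-ratio sensitivity outcome divides volume by ICV, drops ICV as a
covariate (10 columns), and reports coefficients × 10⁻⁶. OLS estimation and
t-based intervals are delegated to statsmodels; the test suite cross-checks
them against a hand-written normal-equations solver.

## Reallocation prediction

For base composition x and a shift of δ proportion units into focal
behavior k, the "equal" rule subtracts δ/2 from each remaining part (the
convention used for published reallocation curves); "proportional" subtracts
in proportion to base shares, which keeps the remaining parts' ratio — hence
the second pivot coordinate — fixed. The predicted difference
a·(ln x* − ln x) is computed twice (log-contrast and ilr-difference routes)
and cross-checked to 1e-10 on every call. Predictions are deliberately
asymmetric in ±δ: the log-share of a small part moves further when the part
shrinks than when it grows.

The default base is the arithmetic-mean composition (ratio of mean minutes),
which is what published reallocation numbers at "the cohort mean" are
computed from; the compositional (geometric-mean) center is available via
`realloc_base="geometric"` and both bases are recorded in the run log, since
the two differ noticeably for a skewed part like MVPA (6.0% vs 4.6%).

## Synthetic study generator

The generator emulates a 485-participant community-dwelling older-adult
cohort wearing a waist accelerometer for 7 days:

* **Covariates**: sex ~ Bernoulli(0.47); age ~ N(73.3, 5.5²) y;
  ICV ~ N(1 432 369, 152 092²) mm³; binary education (19.6%), BMI category
  (8.2% under / 17.7% over), smoking (8.5%), alcohol (4.5%), medication
  flags (45.6 / 34.4 / 9.5%). Covariates are sampled independently of the
  composition by default; `age_ilr_slope` adds age→composition confounding
  for stress tests.
* **Compositions**: pivot coordinates drawn from a bivariate normal
  (logistic-normal on the simplex, guaranteeing positive parts — the
  population model is the package's choice). The mean is the ilr image of
  the 50.5/44.9/4.6% compositional center; the covariance
  [[0.607, 0.124], [0.124, 0.130]] is derived in closed form from the
  target variation matrix (SB-LPA 0.26, SB-MVPA 1.19, LPA-MVPA 0.76) via
  the clr-covariance identity, so the simulated log-ratio dispersion
  reproduces that matrix in expectation, including its ordering (MVPA/SB
  most variable).
* **Daily minutes**: per-participant wear ~ N(887.5, 109.4²) min/day,
  clipped and jittered day-to-day, then split into integer minutes by
  largest-remainder rounding with a 1-min/day floor per behavior (extreme
  logistic-normal tails would otherwise fall below the device's 1-min
  resolution and break the positivity contract). The participant's "true"
  composition is recomputed from the realized integers, so the noiseless
  model is exactly recoverable through the full epoch pipeline.
* **Epoch streams**: each day is 1440 one-minute epochs; non-wear is MET 0
  (signal absence; worn epochs are ≥ 0.9 MET) placed as one or two runs
  longer than 60 min framing the worn block; worn minutes are laid down in
  bouts (SB 10–45 min, LPA 10–40, MVPA 3–15) with MET values uniform inside
  each band. Screening the stream recovers the intended minutes exactly —
  the construction is its own oracle.
* **Outcomes**: right volume = intercept + 57.1·z1 − 6.70·z2 + covariate
  effects + N(0, σ²). The z-coefficients re-express reported pivot-first
  coefficients (−22.7, −34.3, 57.1 mm³/ilr); the left hemisphere uses
  (34.9, −52.4, 17.5). Covariate effects are field-typical choices: ICV
  slope 0.002 mm³/mm³ (≈ the hippocampus/ICV volume ratio), age −30 mm³/y
  (≈ 0.8%/y atrophy at this age), male +40, ±10–40 for the binaries. The
  intercept and σ (≈ 233 mm³ right, ≈ 179 left) are solved in closed form
  so the marginal outcome mean and SD hit 3 687.7 (420.3) mm³ right and
  3 522.1 (391.1) left in expectation.

What the generator does **not** emulate: raw tri-axial signals and the
device's MET-estimation algorithm; covariate–activity and covariate–
covariate dependence (only marginals are matched, except the optional
confounding knob); seasonal/weekday structure; measurement error in MRI
volumes. Passing tests therefore demonstrate the correctness of the
screening arithmetic, the compositional algebra, and unbiased recovery of a
known log-contrast effect under realistic dispersion — not robustness to
device artifacts or real-world confounding structure.

## Numerical choices

* ilr inverse exponentiates clr coordinates after subtracting the row max
  (overflow-safe for |z| up to ~700); round-trip error is < 1e-12.
* Sample variances use the n − 1 divisor throughout (variation matrix,
  descriptives).
* Rank deficiency is detected before fitting and reported with the names of
  collinear columns; the pipeline (not the core fitter) drops covariates
  that are constant in the analysis set, with a log line, since small
  cohorts can lack e.g. any heavy drinker.
* Pivot-invariance of fitted values is enforced at 1e-8 relative
  precision — the design contains ICV (~1.4e6 mm³), so absolute agreement
  beyond ~1e-8 mm³ is outside float64 least-squares conditioning.
* Ties in largest-remainder rounding resolve by part order (SB, LPA, MVPA);
  reallocation feasibility uses open intervals (a part may approach but not
  reach 0 or 1).
* Degenerate inputs: all-zero epoch days are valid input (wear 0, invalid
  day); an all-zero composition, n < 2 variation matrices, and infeasible
  reallocation deltas raise with the feasible range.

## Verification scales

Tests and the acceptance script run the epoch-level chain at 24–60
participants × 7 days (the per-epoch layout is the slow stage and its
correctness is scale-free), and run cohort-level statistics at the full
n = 485 with 200-replicate recovery studies; these sizes are the package's
chosen verification scales. The recovery study's 200-replicate mean has a
Monte Carlo SE of ≈ 1.15 mm³ around the true 57.1 (per-replicate SE
≈ 16 mm³ at n = 485 under the calibrated dispersion), so individual study
runs scatter accordingly; the reported coverage is the empirical fraction of
95% t-intervals containing the truth.

## Known limitations

* Only 3-part compositions are supported; no general D-part balances.
* No confidence bands on reallocation predictions (point predictions only),
  and no robust or mixed-model inference.
* Zero imputation is multiplicative replacement only (no Bayesian or
  count-based imputation).
* Partial first/last wear days are processed as ordinary 1440-epoch days
  (missing portions count as signal absence), which is how waist-worn
  protocols are usually scored but can undercount wear on transition days.
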