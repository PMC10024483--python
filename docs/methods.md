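# Methods

## Kinematic model and inverse dynamics

The velocity of a maximal sprint acceleration from a standing start is
modelled as `v(t) = MSS·(1 − e^(−t/τ))`. The model assumes a maximal,
monotonically saturating effort on level ground; it does not represent
sub-maximal pacing, stumbles, or the very first push-off transient (which
the free time-shift parameter absorbs instead).

The mechanical layer treats the athlete as a point mass at the centre of
mass. Net horizontal force is `F_hzt(t) = m·a(t) + k·v(t)²` with drag
constant `k = 0.5·ρ·C_d·A_f`:

* air density `ρ = 1.293·(P/760)·(273/(273+T))` with pressure in Torr and
  temperature in °C (hPa input is converted; the internal canonical unit is
  Torr);
* frontal area `A_f = 0.266·BSA` with Du Bois
  `BSA = 0.2025·h^0.725·m^0.425`;
* `C_d = 0.9`, fixed. Both constants are exposed as arguments of
  `drag_model` for sensitivity analysis only; defaults are never varied by
  the pipeline.
* `g = 9.81 m/s²`, fixed.

The F-v profile is obtained by linearly regressing `F_hzt` on `v` over a
uniform model-time grid of 1000 points from 0.001 s to the modelled time to
cover the trial's sprint distance. With drag disabled the regression is
exact (`r² = 1`) and the closed forms `F0 = m·MSS/τ`, `v0 = MSS`,
`S_FV = −m/τ`, `Pmax = m·MSS²/(4τ)` hold to numerical precision; with drag
enabled the relation is very slightly convex and `r² > 0.999`. Grid density
was chosen so that halving or doubling it moves regression estimates by
well under 0.01%.

Ratio-of-forces variables are evaluated on the fitted model, not on raw
samples: `RF_max = RF(0.3 s)` and `D_RF` is the slope of RF against
velocity over `t ≥ 0.3 s`. The 0.3 s window start excludes the t → 0
region where the point-mass model's RF is not physically meaningful; under
the model RF decreases strictly beyond that point, so `RF_max` is the
window maximum and `D_RF < 0`.

Split times invert `x(t)` by bracketed Brent root finding (position
tolerance < 1e−6 m); segment times are differences of split times.

## Trace trimming and fitting

Radar traces contain a pre-start standing segment and a post-finish
segment. Onset is the first sample opening a run of 3 consecutive samples
above 0.3 m/s (the recording protocol defines no rule; residual onset error
is absorbed by the fitted time shift). The trailing cut keeps samples up to
the first crossing of the trapezoid-integrated distance with the trial's
sprint distance. At least 30 samples must survive.

Fitting minimises squared velocity residuals of
`v(t) = MSS·(1 − e^(−(t−shift)/τ))` (zero before the shift) with scipy's
bounded trust-region-reflective least squares: `MSS ∈ [0.5, 3]·max(v)`,
`τ ∈ [0.01, 10] s`, `shift ∈ [−0.5, 0.5] s`; initialisation
`MSS₀ = max(v)`, `τ₀` = time to first reach 0.632·MSS₀, `shift₀ = 0`;
tolerances 1e−12 on cost, step and gradient. Non-convergence raises an
error carrying the solver diagnostics. Noiseless mono-exponential traces
round-trip to ≤ 1e−6 absolute parameter error.

The three trials of an athlete-session are averaged at the
derived-variable level (each trial is fitted and profiled separately, then
per-variable means are taken). Averaging traces first and refitting gives
systematically different answers because the profile variables are
nonlinear in the trace; the per-variable mean matches the convention of
using the mean of three maximal trials for analysis.

## Reliability statistics

ICC form is ICC(3,1): two-way mixed effects, consistency, single measure —
trials are fixed repeats of one device/protocol, so a consistency
coefficient is appropriate. Confidence intervals come from F-distribution
bounds on `MS_subjects/MS_error`. The implementation is written directly
from the mean squares and is cross-checked in the tests against
`pingouin.intraclass_corr` to machine precision.

SEM is `SD·√(1−ICC)` with SD the standard deviation of all observations in
the trial matrix; MDC at 90% confidence is `1.645·SEM·√2`; MDC% divides by
the grand mean of the pre-test matrix (absolute value for negative-valued
variables such as the F-v slope). The true-change flag uses a strict
inequality: a change exactly equal to the MDC is not called true.
Qualitative ICC bands are poor < 0.50, moderate 0.50–0.74, high 0.75–0.89,
very high 0.90–0.98, extremely high ≥ 0.99, inclusive at the lower edge.

## Group inference

The 2×2 design (session within, group between, groups of unequal size) is
analysed with classical split-plot sums of squares computed directly in
numpy; for two sessions the decomposition is exact for unequal group sizes
and the interaction F provably equals the squared pooled-variance t on
change scores — both identities are asserted in the tests, along with
equality to `pingouin.mixed_anova` and to an explicit brute-force
sums-of-squares oracle. The direct implementation keeps the
2000-replicate type-I-error calibration test fast.

Within-group pre-post change uses a paired t-test (the two-level
repeated-measures ANOVA equivalent) with a within-group d defined as mean
change divided by the pooled SD of pre and post scores. Between-group and
marginal effect sizes are pooled-SD standardized mean differences
(Cohen's d) with normal-approximation 95% limits,
`SE = √((nA+nB)/(nA·nB) + d²/(2(nA+nB)))`. The per-effect ES columns of
the comparison table are standardized mean differences on the matching
marginal contrasts: subject means across sessions (group), pooled post vs
pre scores (time), and change scores between groups (interaction); they
are labelled as such since no other convention is defined for them.
Effect-size bands: trivial < 0.20, small 0.20–<0.60, moderate 0.60–<1.20,
large 1.20–2.00, extremely large > 2.00, on |d|. α = 0.05 throughout with
no multiple-testing correction — a deliberate mirror of the study design
and a known caveat of it. Percent change is computed per subject
(`100·(post−pre)/pre`) and summarised as mean ± SD; a change-of-means mode
exists as an option.

Power for the within-between interaction uses the noncentral F
distribution with `λ = f²·N·m·ε/(1−ρ)`, `df1 = (g−1)(m−1)ε`,
`df2 = (N−g)(m−1)ε`; defaults `ρ = 0.5`, `ε = 1` (exact for m = 2). The
required sample size is the smallest total N whose power reaches the
target. At f = 0.3, α = 0.05, g = m = 2 this gives N = 24 for 80% power
and power 0.7633 at N = 22; both are recomputed by
`scripts/acceptance.py`.

## Synthetic cohort

The generator emulates the reference design: 22 athletes (CST 14, MST 8),
body mass ~ Normal(58.5, 10.0) kg, stature ~ Normal(1.74, 0.08) m,
group-specific pre-test profile distributions (CST: F0_rel 5.18 ± 0.49
N/kg, v0 8.31 ± 0.83 m/s; MST: 5.10 ± 0.51, 7.80 ± 0.43) and intervention
percent changes (CST: F0_rel +11.19 ± 12.52%, v0 −0.25 ± 6.08%; MST:
−0.40 ± 8.47%, +2.60 ± 2.87%) applied multiplicatively per athlete. Draws
are truncated to physical ranges (mass > 30 kg, stature > 1.4 m,
F0_rel > 2 N/kg, v0 > 5 m/s) by resampling. The between-athlete
correlation of F0_rel and v0 defaults to 0 (no published estimate exists
for this cohort) and is configurable.

The latent profile is (F0_rel, v0); in `mono_exp` mode it maps to the
velocity model via the drag-free correspondence `MSS = v0`,
`τ = v0/F0_rel`, keeping ground truth in reported units. `linear_fv_ode`
mode instead treats the linear force-velocity law with drag,
`m·dv/dt = F0(1−v/v0) − k·v²`, as the true dynamics, integrated with
fixed-step RK4 at 1 ms. The mono-exponential fit of an ODE-mode trace has
a small, bounded model mismatch (≈ 1–3% on recovered F0_rel and v0),
which the tests measure explicitly.

Trial-to-trial variability multiplies MSS and τ by independent
Normal(1, 1.5%) draws per trial; measurement noise is Gaussian on velocity
with SD 0.05 m/s at 36.6 Hz; a 0.5 s stationary pre-onset segment
(noise SD 0.02 m/s) exercises onset detection. Group allocation by the
rank-and-pair procedure (rank by pre-test 20 m time, split adjacent pairs
by seeded coin flip) is implemented and tested separately; with unequal
target sizes the surplus pairs go wholly to the larger group and are
spread evenly across the ranking so group means stay balanced. The default
simulate-mode pipeline draws athletes directly from the group-specific
distributions, since those distributions already condition on group.

What the generator does not emulate: distance-dependent radar error
(cosine error, body-sway artefacts), autocorrelated noise, fatigue across
trials, athlete maturation, or assisted (towed) sprinting. Passing
end-to-end tests therefore demonstrates correctness of the estimation and
statistics pipeline under the stated noise model, not robustness to every
artefact of field radar data. Under these defaults the simulated
split-time ICCs come out near the top of the very-high band (≈ 0.92–0.96),
somewhat above typical field reports — real trial-to-trial variability
evidently exceeds a 1.5% CV — which the reliability-band test accepts as
moderate-to-very-high on the ICC scale.

## Problem sizes and runtime choices

The default study (22 athletes × 2 sessions × 3 trials, 36.6 Hz, 20 m)
fits 132 traces in about one second. The test suite uses 200 replicate
fits for noise-recovery percentiles, 2000 null replicates for ANOVA
type-I calibration, 1000 replicates for ICC CI coverage, and 20 replicate
studies for end-to-end effect recovery; these sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* The point-mass model ignores wind, slope, and intra-step force
  fluctuation; `RF_max`/`D_RF` are model-based, not measured from force
  plates.
* The mono-exponential model slightly misfits dynamics in which drag makes
  the true velocity law non-exponential; the resulting profile bias is
  small (tested ≤ 3%) but systematic, and cancels almost entirely in
  pre-post percent changes.
* Normal-approximation confidence limits for d are first-order only;
  a noncentral-t option is not currently implemented.
* SEM/MDC summarise a single session's trials; day-to-day biological
  variation is attributed to the intervention contrast, not separated.
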