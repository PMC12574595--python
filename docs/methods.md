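# Methods

This note documents the statistical model, the algorithms, the synthetic
study conditions, and the numerical and design choices behind `poppk`.

## Structural models

Four linear compartmental models, single dose at t = 0:

| kind          | route    | solution |
|---------------|----------|----------|
| `onecomp`     | IV bolus | `C(t) = (D/V) e^{-(CL/V) t}` |
| `onecomp_abs` | oral     | Bateman: `C(t) = D·Ka / (V (Ka − ke)) (e^{−ke t} − e^{−Ka t})`, `ke = CL/V` |
| `twocomp`     | IV bolus | `C(t) = A e^{−α t} + B e^{−β t}` |
| `twocomp_abs` | oral     | mass-balance ODEs (gut, central, peripheral) |

For the two-compartment models the hybrid constants α, β are the roots of
`s² − (k10+k12+k21)s + k10·k21` with micro-constants `k10 = CL/V1`,
`k12 = Q/V1`, `k21 = Q/V2`. The IV-bolus amplitudes use the standard
eigen-decomposition forms `A = (D/V1)(α−k21)/(α−β)`,
`B = (D/V1)(k21−β)/(α−β)`, uniquely fixed by `C(0) = D/V1`.

Numerical edge cases:

- **Flip-flop degeneracy** (`Ka → ke`): when `|Ka − ke|/ke < 1e-6` the
  Bateman form switches to its analytic limit `(D/V)·Ka·t·e^{−Ka t}`,
  avoiding catastrophic cancellation while staying far below fitting
  tolerance.
- **Stiff systems**: the `twocomp_abs` ODE route uses LSODA with
  rtol 1e-8 / atol 1e-12, well below the fitting noise floor. A
  closed-form triexponential (algebraically identical; verified against
  the ODE to 1e-6 relative in the test suite) is used inside the
  estimation and simulation loops for speed, falling back to the ODE when
  Ka nearly coincides with α or β.
- Repeated disposition roots (α = β) are split by a 1e-9 relative nudge
  rather than failing.

## Two-stage estimation

**Stage 1 (individual fits).** Each subject is fitted by maximum
likelihood on log-concentrations with log-transformed parameters
(positivity by construction):

```
O(θ) = Σ_i [log C_obs,i − log C_pred,i(θ)]² / σ²  +  penalty(θ)
```

Observations at or below a positivity floor (1e-10 mg/L) are excluded.
σ enters only as a relative weight, so it defaults to 1 during fitting
(pure log-SSR; the argmin is invariant) and the residual error is
re-estimated post hoc. The penalty is quadratic in log-distance outside
per-parameter bounds with weight 1e4 — smooth, and dominant only when a
parameter is clearly out of range. Default bounds are `[base/50, base·50]`
around the heuristic base estimate.

*Automated initialisation.* The base estimate is data-driven:
V = Dose/Cmax (IV) or Dose/(2·Cmax) (oral); λz from a log-linear
regression of the last three quantifiable points; CL = λz·V for
one-compartment models and Dose/AUC (trapezoid plus λz tail) for
two-compartment models; Ka = 4·λz clipped to [0.05, 20] h⁻¹ for
one-compartment absorption. For **two-compartment absorption** the Ka seed
is 4/Tmax instead: the triexponential is invariant under exchanging Ka
with α (an exact flip-flop twin), and because λz = β ≪ α there, a 4·λz
seed starts the optimiser in the wrong, algebraically equivalent basin.
Seeding from the observed peak keeps the conventional Ka > α labelling.

The base is expanded over scale factors (0.1, 0.5, 1.0, 1.5, 2.0), each
start perturbed per-parameter by `exp(N(0, 0.1²))`. Starts are attempted
in ascending order of their initial objective; each is optimised with
Nelder–Mead (fallback: Powell on failure), and the first converged
attempt is returned. Starts with a non-finite objective are recorded as
consumed attempts. Convergence requires optimizer-reported success, a
finite objective, and all parameters strictly inside a 1e-6 relative
interior of the bounds; total failure yields an unconverged result with a
logged warning, never an exception. Default simplex tolerances are
xatol 1e-8 / fatol 1e-12 (the study harness relaxes these to
1e-6 / 1e-10: replicate-level metrics are statistical, and that accuracy
is orders of magnitude below Monte-Carlo noise at roughly half the cost).

**Stage 2 (population summary).** Typical values are geometric means of
the converged individual estimates; between-subject variability is
`CV% = 100·sqrt(exp(s²_log) − 1)` with the unbiased variance of
log-estimates, alongside the full log-scale covariance matrix. The
residual proportional SD is the RMS of pooled log-residuals. With fewer
than two converged subjects the population step raises an error; at the
workflow level individual failures are contained and reported.

This is deliberately *not* nonlinear mixed-effects estimation: no
shrinkage toward the population is applied, which is transparent and fast
for data-rich designs but inefficient for sparse ones (see Limitations).

## Covariate analysis

Relations between individual parameter estimates and covariates are
screened on the log-parameter scale with three forms

- linear: `P = θ1 (1 + θ2 (COV − COV_med))`
- power: `P = θ1 (COV/COV_med)^{θ2}`
- exponential: `P = θ1 exp(θ2 (COV − COV_med))`

with the cohort median as reference. Power and exponential forms are
ordinary least squares after transformation; the linear form is fitted by
Nelder–Mead from multiple θ2 seeds with a barrier at
`1 + θ2·(COV − ref) ≤ 0`. Model comparison uses
`AIC = n·log(SS_res/n) + 2k` with unit weights on the log scale (the log
transform already variance-stabilises). Significance of θ2 uses a
likelihood-ratio construction, `Δ = n·ln(SS_base/SS_full)` referred to
χ²(1) — the permutation test in the suite confirms ~5% type-I error at
α = 0.05. Forward selection keeps, per parameter, at most one relation:
the lowest-AIC form among those with p < α and ΔAIC < 0, ties resolved
simplest-first (linear < power < exponential). A zero-variance covariate
yields a not-testable result (p = 1).

## Non-compartmental analysis

AUC uses the linear-up/log-down trapezoid: rising or flat segments are
linear, strictly falling positive segments use
`(C1 − C2)·Δt / ln(C1/C2)`, and falling segments touching zero fall back
to linear. For IV-bolus profiles whose first sample is after t = 0, C(0)
is back-extrapolated log-linearly from the first two positive points
(standard practice; without it Dose/AUC over-estimates clearance by the
missing initial area). λz comes from the best log-linear tail among the
last 3..8 points strictly after Tmax, chosen by maximum adjusted R² with
negative slope, ties toward fewer points; `t½ = ln 2 / λz`,
`AUC_inf = AUC_last + C_last/λz`, and `CL/F = Dose/AUC_inf` provides the
model-free cross-check of the fitted clearance. Batch NCA contains
per-subject failures and reports means, CV% and the success rate.

## Synthetic populations and study conditions

The generator emulates a parallel single-dose study in an adult cohort:

- Covariates: WT ~ truncated N(70, 15²) on [40, 120] kg; AGE ~ U(20, 80)
  years; CRCL ~ truncated N(100, 25²) on [30, 160] mL/min, sampled
  independently.
- Individual parameters: covariate-adjusted typical values multiplied by
  log-normal variability with log-SD `sqrt(ln(1 + CV²))`.
- Residual error: `C_obs = C (1 + ε_p) + ε_a` with Gaussian ε, floored at
  zero. Default 10% proportional, no additive.

Built-in scenarios (100 mg dose, typical CL 5 L/h, V 50 L one-compartment
or V1 30 / V2 50 L, Q 10 L/h two-compartment, Ka 1.5 h⁻¹):

| scenario | schedule | IIV CV | true covariate effects |
|---|---|---|---|
| `onecomp` | 10 even points, 0–24 h | 30% CL, V | CL~CRCL pow 0.75; V~WT pow 0.75 |
| `onecomp_abs` | 12 points / 24 h, 6 within 2 h | 30% all | + Ka~AGE exp −0.2 |
| `twocomp` | 18 points / 48 h, dense early | 25% CL, V1; 30% Q, V2 | CL~CRCL 0.75; V1,V2~WT pow 1.0 |
| `twocomp_abs` | 20 points / 48 h | 30% all | CL~CRCL 0.75; V1~WT 1.0; Ka~AGE exp −0.02 |

What the generator does **not** emulate: covariate correlation
structures, dropout/missingness beyond zero-flooring, multiple dosing,
and nonlinear elimination. Passing tests therefore demonstrate correct
recovery under an idealised, correctly-specified data-generating process,
not robustness to model misspecification in real data.

Two consequences of these printed conditions are worth knowing:

- The `onecomp_abs` Ka~AGE coefficient (−0.2 per year over a 60-year age
  span) drives true Ka across ~e^±6, so a fraction of simulated subjects
  have absorption too fast or too slow to identify from the sampling
  design; their fits end pinned at the bounds, fail the interior
  convergence rule, and are excluded (logged). This is the main source of
  non-convergence in the absorption studies and of Ka's dominant CV%.
- With 30% IIV against the covariate dispersions above, the χ²(1) LRT at
  n = 20 has ~80% power for CL~CRCL (noncentrality ≈ n·R²/(1−R²) ≈ 8),
  and the three locally-similar forms make strict form classification
  uncertain at moderate dispersion; measured strict-form detection at
  n = 20 is therefore well below 100%. Larger cohorts and wider covariate
  ranges raise it.

## Validation harness and metrics

`run_study` executes scenario × sample-size × replicate grids with
counter-based seeds (`SeedSequence(master, spawn_key=(scenario, size,
replicate))`) for exact reproducibility. Per parameter across replicate
typical-value estimates it reports relative bias %, RMSE, CV%
(100·sd/mean), and the recovery rate — the share of replicate estimates
within ±20% of truth, boundary inclusive. Mean R² averages per-subject
concentration-scale R² (predictions from the individual fits) within and
then across replicates. Detection rates require the selected relation to
match the true covariate *and* functional form at p < 0.05 with an AIC
improvement.

The noise battery (`run_noise_battery`) fits one-compartment populations
of 50 subjects at 10/20/30% proportional noise plus a sparse 5-point
design (0.5, 2, 6, 12, 24 h), and evaluates predictive accuracy on the
**population profile**: per-timepoint geometric-mean prediction vs
geometric-mean observation. The geometric mean is the natural summary for
a log-scale model; an arithmetic profile would inherit the retransformation
bias `E[log(1+ε)] ≈ −σ²/2` (≈ −4.7% at 30% noise) and report it as
spurious fold error. Fold errors follow
`AFE = exp(mean log(pred/obs))` and `AAFE = exp(mean |log(pred/obs)|)`,
over positive pairs only.

Visual predictive checks simulate (default 1000) replicate populations
from the estimated typical values, the log-covariance of individual
estimates, and the residual model, reporting 5/50/95 percentile bands
against observed percentiles. Shrinkage is the η-shrinkage formula
adapted to two-stage output, `100·(1 − sd(log estimates)/ω_log)`; against
the population's own ω it is ~0 by construction (a two-stage limitation),
so an external ω can be supplied. The condition number is the eigenvalue
ratio of the correlation matrix of log individual estimates, with an
infinite sentinel for singular matrices.

## Problem sizes

The shipped validation profile uses 100 replicates for the
one-compartment accuracy study (n = 20/50/100), 20 replicates for the
detection grid and the two-compartment study, and single 50-subject
populations per noise-battery row. These sizes put Monte-Carlo error
comfortably below the margins being asserted (e.g. bias SE ≈ 0.35% at
100 replicates) while keeping a full validation run in the minutes range
on one core; `poppk validate --full` runs any grid at 100 replicates.

## Known limitations

- Two-stage estimation overstates between-subject variability when
  individual data are sparse (estimation noise folds into ω) and cannot
  borrow strength across subjects.
- Single-dose designs only; no infusions, multiple dosing, steady state,
  three-compartment models, or Michaelis–Menten elimination.
- Covariate selection fits one relation per parameter; joint
  multi-covariate models and multiplicity control across candidate pairs
  are out of scope (raw α = 0.05).
- The residual-error magnitude of the simulation studies (10%
  proportional) is a package default; study-level metrics such as mean R²
  move with it (e.g. two-compartment mean R² ≈ 0.98 at 10% noise,
  ≈ 0.99 at 7%).
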