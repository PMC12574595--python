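# poppk

Automated two-stage population pharmacokinetic (PopPK) analysis in Python.

`poppk` is aimed at pharmacometricians, clinical pharmacologists and
students who need a transparent, scriptable PopPK workflow for data-rich
studies: one- and two-compartment models (IV bolus or first-order oral
absorption), automated parameter initialisation, covariate screening,
non-compartmental analysis (NCA), and a Monte-Carlo harness for validating
the whole pipeline against simulated populations with known truth.

## The method

Individual concentration–time profiles are fitted by maximum likelihood on
the log scale with log-transformed parameters,

```
O(θ) = Σᵢ [log C_obs,i − log C_pred,i(θ)]² / σ²  +  boundary penalty,
```

using data-driven starting values expanded over a scale grid
(0.1, 0.5, 1, 1.5, 2) with small log-normal perturbations, Nelder–Mead
optimisation and automatic fallback to Powell's method — no user-supplied
initial estimates required. Population typical values are then the
geometric means of the individual estimates and between-subject
variability the CV% implied by the log-scale covariance (the classic
two-stage approach; deliberately not nonlinear mixed-effects).

Covariate relations `P = θ₁·f(COV; θ₂)` (linear, power, exponential; the
cohort median as reference) are screened by forward selection with
`AIC = n·log(SS_res/n) + 2k` and a χ²(1) likelihood-ratio p-value for
θ₂ = 0. NCA (linear-up/log-down AUC, Cmax/Tmax, λz with automatic
terminal-phase detection) runs alongside as a model-free cross-check, and
diagnostics include R², RMSE, fold errors
(`AFE = exp(mean log(pred/obs))`, `AAFE = exp(mean |log(pred/obs)|)`),
visual predictive checks, shrinkage and the parameter-correlation
condition number. See `docs/methods.md` for the full account.

## Worked example

Simulate a 100-subject one-compartment study (100 mg IV bolus, 30%
between-subject variability, CL scaling with creatinine clearance and V
with body weight) and analyse it blind:

```python
from poppk import PopPKModel, builtin_scenarios, simulate_population

vpop = simulate_population(builtin_scenarios(100)["onecomp"], seed=42)
results = PopPKModel(vpop.subjects, "onecomp").fit(seed=1)
results.select_covariates()
print(results.summary())
```

```
Two-stage population PK fit
==========================================
model:            onecomp
subjects:         100  (converged 99, success rate 99.0%)
residual prop SD: 0.0890
mean R^2:         0.9760

parameter      typical     BSV CV%
----------------------------------
CL               4.886        39.2
V                 48.9        34.2

selected covariate relations:
  CL ~ CRCL [power]  theta2=0.7351  p=7.7e-09  dAIC=-31.3
  V ~ WT [exponential]  theta2=0.00926  p=0.000289  dAIC=-11.1
```

No initial estimates were supplied; one hard subject fell back through
all five automated starts and is excluded with a warning. The typical
clearance (4.89 L/h) and volume (48.9 L) recover the simulation truth
(5, 50) within sampling error, the residual SD (0.089) recovers the 10%
proportional error, and the screen finds both true covariate relations:
CL~CRCL with a power exponent 0.735 against a simulated 0.75, and V~WT
as a significant effect whose best AIC at this dispersion lands on the
exponential rather than the simulated power form — over a 40–120 kg
weight range the two forms are nearly indistinguishable, a classification
ambiguity quantified in the validation harness.

The same pipeline is available from the shell:

```sh
poppk simulate --scenario onecomp --n 20 --seed 42 --out pop.csv
poppk fit --data pop.csv --model onecomp --seed 1 --out report.json
poppk nca --data pop.csv --out nca.csv
poppk validate --scenarios onecomp --sizes 20,50,100 --replicates 20 \
      --seed 1 --out validation.json
```

`fit` writes a complete JSON report (population estimates, covariate
screen, per-subject diagnostics, NCA summary, VPC bands, warnings, and the
echoed configuration); datasets are ordinary long-format CSV with columns
`ID, TIME, DV, AMT` plus covariate columns.

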