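# Methods

This note documents the models, estimation scheme, numerical choices, and the
reasoning behind the design decisions in `pkscale`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Compartmental models

All four structures share first-order oral absorption from a depot amount
`Aa` into a central amount `A1`, with concentrations defined as amounts over
apparent volumes (`C = A1/V`, `C2 = A2/V2`, `Cm = Am/Vm`). All volumes and
clearances are apparent (bioavailability-uncorrected): `V/F`, `CL/F`, and for
the metabolite `Vm/(F·Fm)`, `CLm/(F·Fm)`, because neither the absolute
bioavailability F nor the metabolized fraction Fm is identifiable from oral
data alone.

**One-compartment (pyronaridine, hamster/rat):**

    dAa/dt = −ka·Aa
    dA1/dt = ka·Aa − C·CL/F

**Two-compartment (pyronaridine, dog):** adds a peripheral amount `A2`
exchanging with the central compartment through the intercompartmental
clearance `CL2/F`; the steady-state volume is `Vss/F = V/F + V2/F`.

**Parent–metabolite with auto-induction (artesunate → dihydroartemisinin):**
the eliminated parent mass feeds the metabolite compartment, and a relative
enzyme amount multiplies the parent elimination:

    dA1/dt   = ka·Aa [+ peripheral exchange] − C·(CL/F)·AENZ
    dAm/dt   = C·(CL/F)·AENZ − Cm·CLm/(F·Fm)
    dAENZ/dt = k_enz·(1 + Emax·C/(EC50 + C)) − k_enz·AENZ

The hamster variant uses a one-compartment parent, the rat variant a
two-compartment parent. The enzyme acts on **parent elimination only**; the
model is stated that way and we follow it literally (whether metabolite
clearance is also induced is not specified anywhere).

Decisions taken where the source is silent:

* **AENZ(0) = 1.** The production term `k_enz·1` balances degradation
  `k_enz·AENZ` at `AENZ = 1`, so 1 is the pre-treatment steady state of the
  enzyme pool.
* **Emax = 0 degenerates cleanly** to a plain parent–metabolite model
  (`dAENZ/dt = 0` at baseline); this reduction is enforced by a test against
  an independently coded enzyme-free system.
* **Doses are instantaneous depot boluses, no lag time** (the lag time was
  estimated to be zero in the source analysis).
* **Model structure is carried by the parameter type.** A
  `OneCptOralParams` / `TwoCptOralParams` /
  `ParentMetaboliteAutoInductionParams` instance implies its ODE system, so
  no separate structure token can disagree with the parameter vector.

## Numerics

* Integration uses LSODA (stiff/non-stiff switching, via
  `scipy.integrate.odeint`) restarted at every dose event so depot
  discontinuities are exact; default `rtol = 1e−9`, `atol = 1e−12`.
  Reporting-quality simulations agree with the closed-form one-compartment
  solution to better than `1e−6` relative (tested).
* A sample falling exactly on a dose time is the **pre-dose (trough)** value.
* Negative concentrations from solver wobble are clamped to zero on output,
  with a warning if the excursion exceeds `100·atol`.
* The closed-form one-compartment solution rejects the flip-flop degeneracy
  `ka = ke`; callers perturb a rate by ~1e−9 relative to take the limit.
* Objective evaluations inside fits use `rtol = 1e−8`, `atol = 1e−10` —
  orders of magnitude below the precision claims being tested, and roughly
  3× faster per solve.
* The engine is unit-agnostic: one consistent unit system per dataset
  (per-kg doses with per-kg volumes/clearances). Molar and salt conversions
  (e.g., mg artesunate → nmol; pyronaridine tetraphosphate → base, factor
  51.2/90) are explicit configuration, never hardcoded into the models.

## Non-compartmental analysis

Strictly linear trapezoids for AUC and AUMC (no log-down dialect in v1, as
the source analysis used the linear method). Terminal slope: best
adjusted-r² log-linear regression over contiguous windows of ≥ 3 positive
concentrations strictly after Tmax; ties go to the longer window; an explicit
window can override the search. On profiles with more than 50 candidate
points the search considers the windows anchored at the last measurable
point (the usual best-fit convention) — the full start/end search is O(n²)
and adds nothing on dense grids. Tmax/Cmax are the observed argmax, earliest
time on ties. Trailing zeros are excluded from the regression; if the last
concentration is zero, no extrapolation is added (`AUC_inf = AUC_t`).
Multiple-dose profiles use `CL/F = dose/AUC_τ` of the final interval and the
day-3/day-1 `AUC_τ` ratio as the accumulation index (not the steady-state
formula). Internal identities (`t½ = ln2/ke`, `MRT = AUMC_inf/AUC_inf`,
`Vss/F = CL/F·MRT`) hold by construction and are asserted to 1e−9.

## Estimation

The source analysis used a commercial FOCE-ELS mixed-effects estimator;
replicating it bit-for-bit is out of scope. The in-scope substitutes are:

* **Naive-pooled maximum likelihood** (`fit_pooled`) — one parameter vector
  for all observations; matches how the destructive hamster data were
  analyzed (per-time mean pseudo-profile).
* **Two-stage population summary** (`fit_individuals_two_stage`) — stage 1
  fits each subject; stage 2 takes `θ_TV` = geometric mean of subject
  estimates and `ω²` = sample variance (ddof = 1) of their logs, consistent
  with the lognormal IIV model `θᵢ = θ_TV·e^ηᵢ`.

Residual error is additive (`C_obs = C_pred + ε`) or proportional
(`C_obs = C_pred·(1+ε)`), `ε ~ N(0, σ²)`; σ is profiled out per analyte
unless fixed. Under the proportional model zero observations cannot be
weighted, so only positive observations enter that likelihood (pre-dose and
below-quantification zeros are excluded), and the prediction in the
denominator is floored at `1e−12·max(obs)` so deep-tail solver underflow
cannot destabilize the objective.

Optimization is over log-parameters (positivity by construction):

1. a trust-region least-squares pass (`scipy.optimize.least_squares`, TRF)
   on the error-model residual vector — exact ML for additive error;
2. for proportional error, a Nelder–Mead polish of the exact concentrated
   −2 log-likelihood, which carries the `Σ ln C_pred²` term the residual sum
   of squares lacks.

The finite-difference step of the least-squares Jacobian is fixed at `1e−4`
on the log scale: the default `√ε` step sits at the ODE-solver noise floor
and produces a garbage Jacobian. (An earlier all-simplex scheme needed
thousands of evaluations on the 10-parameter rat model and still stalled in
the curved likelihood valley of the induction parameters; the gradient-based
pass followed by a simplex refinement of the exact likelihood is both faster
and more reliable, so it replaced the originally planned simplex-first
ordering.)

CV% per parameter comes from the inverse observed information (numerical
Hessian of the concentrated −2LL on the log scale, central differences,
step 1e−4), delta method: `CV% = 100·√(exp(Var[log θ]) − 1)`. A singular
information matrix flags CV% as unavailable rather than failing the fit.
`AIC = −2LL + 2p`, `BIC = −2LL + p·ln(n_obs)` with p counting structural
parameters plus estimated sigmas. Replicate subjects sharing a regimen and
sampling schedule share one model solution per objective evaluation.

### Identifiability and the recovery tests

Parameter-recovery acceptance checks exercise each of the four structures on
synthetic data (the raw animal profiles are not public, so recovery — not
reproduction of the published estimates — is the acceptance standard). The
recovery configurations were designed from a local identifiability analysis
(singular values of the log-residual Jacobian at the generating values), not
from test outcomes:

* sampling resolves every timescale (pre-Tmax absorption samples; β-phase
  tail for the two-compartment model; day-2 coverage for enzyme turnover);
* the auto-induction runs use several dose levels spanning 100×, because a
  single dose level leaves a near-flat ridge across (Emax, EC50, k_enz, CL);
* noisy runs add replicate subjects until the weakest Jacobian direction
  supports the 10% tolerance at 10% residual noise (error ≈ σ/s_min).

Two of the published parameter regimes are **practically non-identifiable**
and are therefore not used as recovery targets: a hamster-like
`k_enz ≈ 47 h⁻¹` makes the enzyme pool quasi-stationary (AENZ tracks
`1 + Emax·C/(EC50+C)` within minutes, so k_enz drops out of the observable
dynamics), and metabolite volumes with `CLm/Vm` in the thousands per hour
make the metabolite compartment quasi-stationary (Vm drops out). The
recovery configurations keep the published values where identifiable and
move only these time-scale parameters into regimes where every parameter
affects the observable curves (`k_enz ≈ 1 h⁻¹`, `CLm/Vm` of order 1 h⁻¹,
EC50 within the simulated concentration range). The simulation defaults in
`pkscale.synthetic_data` remain the published estimates throughout.

## Allometric scaling

Base-10 logarithms throughout (the published equations are written in log₁₀
form). `fit_power_law` is simple OLS of `log₁₀Y` on `log₁₀W`; r² is the
squared Pearson correlation (identical to OLS R² for one regressor),
reported to 4 decimals. `fit_fixed_exponent` estimates only the intercept,
`log₁₀a = mean(log₁₀Y − b·log₁₀W)`, used with b = −0.25 for artesunate ka
(no dog ka exists: the only dog study is intravenous). Per-kg values are
converted to absolute units with the measured species mean body weights
(0.10201, 0.2052, 9.52 kg); the 1% acceptance tolerance absorbs the rounding
in the printed two-decimal weights. Mixed per-kg/absolute regressions are
refused by construction — every `SpeciesPoint` must already be absolute.

The artesunate/DHA volume and clearance regressions include literature dog
values that are partly per-kg with an **unpublished conversion weight**, so
those fits cannot be re-derived from raw points; the package ships the
published log-log coefficients (`LITERATURE_LOGLOG_FITS`) and evaluates them
at the target weight, while the artesunate ka fixed-exponent fit is
recomputed from its two printed points.

## Synthetic data

The generator emulates the five study designs: hamster H1/H2
(180/360 mg/kg pyronaridine + 60/120 mg/kg artesunate daily × 3,
destructive-sparse — each animal contributes one terminal sample, pooled by
nominal time), rat R1 (single 60/20 mg/kg, dense, optional early times
assigned round-robin and a 216 h extension for every second animal), rat R2
(daily × 3, dense), dog D1 (single 90 mg/head). Body weights are normal with
the reported means/SDs, truncated at ±3 SD. IIV is lognormal per parameter;
the defaults are the square roots of the reported ω² where the study
estimated them. Residual defaults: additive σ = 0.36/0.34/0.20 for
pyronaridine (the reported scales, in assay concentration units);
artesunate/DHA default to a 20% proportional σ because the reported ε scales
for the multiplicative model are ambiguous in their units. Proportional
noise that drives an observation negative is clamped to zero, mimicking
below-quantification reporting. Hamster per-timepoint sample sizes are not
published, so `n_per_timepoint` is a generator parameter. All randomness
flows from one `numpy` Generator seeded by the config; identical seeds give
byte-identical datasets.

What passing tests on these data do **not** show: real assay error is not
Gaussian or homoscedastic in either error model; real animals violate the
structural model (absorption delays, enterohepatic effects, intestinal
first-pass induction — the mechanism the discussion of the source work
itself flags as the likely site of the auto-induction); and the recovery
results say nothing about bias under model misspecification.

## Pipeline and I/O

Long-format CSV with one row per dose event (`evid = 1`) or observation
(`evid = 0`) and units carried in-band; `#` lines are comments used to embed
the package version, seed, and config hash in every output, making
deterministic stages byte-reproducible. Config files are INI text with one
section per stage. The `pkscale` CLI wraps the pipeline stages (`simulate`,
`nca`, `fit`, `scale`) plus `fixtures`. NCA on multiple-dose subjects slices
the first and last dosing intervals from each profile; subjects lacking
observations are accepted for simulation input and rejected with an
explanatory error by NCA/fit.

## Known limitations

* No intravenous-route models and no PBPK/intestinal first-pass structure
  (out of scope; named as future work by the source analysis).
* No covariate modeling, inter-occasion variability, or Bayesian/FOCE
  estimation; the two-stage ω² is biased upward by per-subject estimation
  noise (visible in the geometric-mean test, where it is the intended
  behavior of the method, not a defect of the implementation).
* The terminal-phase search assumes log-linear decay after Tmax; profiles
  with secondary peaks need an explicit window.
* `AUC_inf` extrapolation quality is reported only through `terminal_r2` and
  `n_terminal_points`; no %AUC-extrapolated gate is enforced.
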