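# pkscale

Inter-species pharmacokinetic (PK) modeling and allometric scaling for the
antimalarial combination **pyronaridine + artesunate**, aimed at supporting
drug-repurposing decisions: given animal PK parameters from hamsters, rats,
and dogs, predict the PK parameters of a 70 kg human.

The package is written for pharmacometricians and DMPK scientists who need a
reproducible, scriptable version of the classic nonclinical-to-clinical
workflow:

1. **Compartmental simulation** (`pkscale.pk_models`) — four oral first-order
   absorption structures: one- and two-compartment models for pyronaridine,
   and parent–metabolite models for artesunate → dihydroartemisinin (DHA)
   with an enzyme-turnover **auto-induction** loop,

   ```
   dAENZ/dt = k_enz · (1 + Emax · C / (EC50 + C)) − k_enz · AENZ,
   ```

   where the relative enzyme amount `AENZ` (baseline 1) multiplies the parent
   elimination clearance. Repeated dosing therefore *lowers* exposure: the
   day-3/day-1 AUC ratio (accumulation index) falls below 1, as observed for
   artesunate and DHA.
2. **Non-compartmental analysis** (`pkscale.nca`) — linear-trapezoidal
   AUC/AUMC, best-adjusted-r² terminal slope, `AUC_inf = AUC_t + C_last/ke`,
   `MRT = AUMC_inf/AUC_inf`, `CL/F = dose/AUC_inf` (or `dose/AUC_τ` for
   multiple dosing), `Vss/F = CL/F · MRT`, `C_avg = AUC_τ/τ`, and the
   accumulation index.
3. **Estimation** (`pkscale.estimation`) — naive-pooled Gaussian maximum
   likelihood (additive or proportional residual error, σ profiled per
   analyte) and a two-stage population summary with lognormal
   inter-individual variability `θᵢ = θ_TV · e^ηᵢ`, `ηᵢ ~ N(0, ω²)`.
4. **Allometric scaling** (`pkscale.allometry`) — the simple power law
   `Y = a · W^b`, fitted as `log₁₀Y = log₁₀a + b·log₁₀W` by OLS across
   species (exponent fixed at −0.25 for absorption rate constants when a
   species is missing), evaluated at 70 kg.
5. **Synthetic data** (`pkscale.synthetic_data`) — generators for the five
   animal study designs (hamster destructive-sparse multiple dose, rat
   single/multiple dose, dog single dose) with body-weight variability, IIV,
   and residual noise, so the whole pipeline is testable without raw animal
   data.
6. **I/O and CLI** (`pkscale.cli_io`) — long-format CSV datasets with units
   carried in-band, INI-style pipeline configs, and a `pkscale` console tool
   (`simulate`, `nca`, `fit`, `scale`, `fixtures`).

## Worked example: predicting human pyronaridine PK

The packaged species table holds the model-based per-kg estimates
(Vss/F = 53.32, 110.00, 32.68 L/kg; CL/F = 2.15, 2.18, 0.68 L/h/kg for
hamster, rat, dog) and mean body weights (0.10201, 0.2052, 9.52 kg).

```python
from pkscale import pyronaridine_human_predictions

for name, entry in pyronaridine_human_predictions().items():
    fit = entry["fit"]
    print(f"{name:11s} b={fit.b:+.4f} log10_a={fit.log10_a:+.4f} "
          f"r2={fit.r2:.4f} human_70kg={entry['human']:.2f}")
```

prints

```
Vss_over_F  b=+0.8220 log10_a=+1.7193 r2=0.9564 human_70kg=1721.39
CL_over_F   b=+0.7295 log10_a=+0.1046 r2=0.9967 human_70kg=28.22
ka          b=-0.1931 log10_a=+0.5145 r2=0.2111 human_70kg=1.44
```

Reading: across a ~100-fold body-weight range, the apparent steady-state
volume scales with exponent 0.82 and clearance with 0.73 (both inside the
textbook 0.35–1.39 clearance and ~0.8–1.1 volume ranges), with r² of 0.96
and 0.997; extrapolation predicts Vss/F ≈ 1722 L, CL/F ≈ 28.2 L/h, and
ka ≈ 1.44 h⁻¹ for a 70 kg human. The ka regression (r² = 0.21) illustrates
why first-order rate constants scale poorly with weight.

The same table is available from the shell:

```bash
pkscale scale --out results/ --seed 0
# writes results/allometric_scaling.csv (coefficients + 70 kg predictions)
```

Simulating a study and analyzing it end to end:

```bash
pkscale fixtures --out fixtures/ --seed 7        # five designs, 9 datasets
cat > nca.ini <<'INI'
[pipeline]
stages = simulate nca
[simulate]
drug = pyronaridine
design = R1
INI
pkscale nca --config nca.ini --seed 7 --out out/
```

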