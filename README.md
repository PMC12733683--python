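# epskinetics

Kinetic analysis of microbial exopolysaccharide (EPS) fermentations:
logistic biomass growth, Luedeking–Piret product formation, two-stage
nonlinear fitting, and a replicated synthetic-study generator. Built for
bioprocess work such as *Rhodotorula glutinis* EPS production compared
between heat stress (30 °C) and the strain's optimal temperature (15 °C),
but applicable to any batch culture with biomass/product time courses.

## Models

Biomass follows the logistic law, product the Luedeking–Piret rate law:

    dX/dt = μ_max (1 − X/X_max) X
    dP/dt = α X + β dX/dt

`β dX/dt` is the growth-associated synthesis rate, `α X` the
non-growth-associated one; both coefficients nonzero means production is
partially growth-coupled. Closed forms for X(t) and P(t) are implemented in
overflow-safe form, and the specific production rate
q_P = (dP/dt)/X = α + β μ_max (1 − X/X_max) peaks at t = 0 when α, β ≥ 0.
Estimation is two-stage nonlinear least squares (biomass first, then
product with growth fixed), with multi-start protection, R² diagnostics and
a case-resampling bootstrap. See `docs/methods.md` for the full account,
including a caveat about two coefficient-labeling conventions found in the
literature.

## Worked example

```python
from epskinetics import RunConfig, run_pipeline

cfg = RunConfig(outdir="ek_demo", use_default_scenarios=True, seed=7)
report = run_pipeline(cfg)
print(report.to_text())
```

prints

```
epskinetics kinetics report (v0.1.0, seed=7)

condition: heat_stress
  logistic fit:  X0=0.09549  Xmax=5.963  mu_max=0.34155 1/h  R^2=0.9934
  Luedeking-Piret fit:  P0=1.03e-15  alpha=0.69103  beta=1.3622  R^2=0.9988
  q_P,max = 1.1488 1/h   association: mixed

condition: normal
  logistic fit:  X0=0.1179  Xmax=10.16  mu_max=0.12743 1/h  R^2=0.9949
  Luedeking-Piret fit:  P0=0.02141  alpha=0.04912  beta=0.52151  R^2=0.9984
  q_P,max = 0.11481 1/h   association: mixed

mu_max ratio heat_stress/normal = 2.68
```

Two synthetic triplicate time courses (8 sampling times, 3% CV
multiplicative noise) were generated from the built-in scenarios — growth
rates 0.33528 h⁻¹ (heat stress) and 0.13286 h⁻¹ (normal) — then both
kinetic stages were fitted per condition. For this seed the recovered
growth rates are within ~4% of the generating values, both fits exceed
R² = 0.99, and production is classified as partially growth-coupled
(both α and β nonzero). The heat-stress β is weakly identified (its term is
a tiny share of cumulative product), which is why its single-seed estimate
scatters widely while q_P,max, dominated by α, stays near its generating
value of 0.8767 h⁻¹ on average.

The same pipeline runs from the shell:

```
epskin all --seed 7 --out ek_demo      # simulate + fit + report
epskin simulate --seed 7 --out data    # just write CSV time courses
epskin fit --input data/normal.csv --out fitted
epskin report fitted/report.json
```

Fitting your own data: a tidy CSV with columns
`condition,replicate,time_h,biomass,product` (product may be empty per
row), read with `read_timecourse_csv` / fitted with `epskin fit --input`.
Assay helpers (`fit_calibration`, `concentration_from_absorbance`,
`amylase_inhibition`) cover the phenol–sulfuric standard curve and the
α-amylase inhibition formula `[1 − (A − B)/C] × 100 %`.

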