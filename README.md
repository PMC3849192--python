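# kpuu

Unbound brain-to-plasma partition ratios (Kp,uu) for CNS drug candidates,
estimated from a **single in vitro blood–brain-barrier transwell experiment**,
together with the reference assays used to validate them.

## The problem

Only the free (unbound) drug concentration in brain, Cu,br, is available to
engage most CNS targets, so the parameter that matters for CNS exposure is

    Kp,uu = Cu,br / Cu,pl

the ratio of unbound brain to unbound plasma concentration at steady state
(1 for freely equilibrating compounds, < 1 under net efflux). Measuring it in
vivo requires microdialysis, or steady-state infusion studies combined with
separate binding assays:

    Cu,br/Cu,pl = (Ctot,br / Ctot,pl) · (fu,br / fu,pl)

where fu,br comes from equilibrium dialysis of diluted brain homogenate or
from brain-slice incubations (Vu,brain = C_slice/C_ECF − V0, fu,br =
1/Vu,brain, with V0 = 0.106 mL/g of adherent water), and fu,pl from plasma
equilibrium dialysis.

This package implements a much cheaper alternative: in an endothelial/glial
co-culture insert, drug dosed at 2 µM into the luminal ("blood") compartment
is sampled after 1 h in both compartments. The receiver/donor ratio at 1 h
(`R_1h`) approximates Cu,br/Cu,pl before equilibration; a kinetic
extrapolation of the same measurement yields the steady-state ratio `R_ss`:

1. donor decline rate λ = ln(C_d0/C_d,t)/t, influx clearance CL_in = λ·V_lum;
2. receiver exit rate µ solved so the receiver curve
   C_r(τ) = (CL_in·C_d0/V_ab)·(e^(−λτ) − e^(−µτ))/(µ − λ) passes through the
   1-h measurement, CL_out = µ·V_ab;
3. R_ss = CL_in/CL_out, the plateau ratio under a constant donor — the in
   vitro analogue of the in vivo constant-rate-infusion steady state.

Monolayer integrity is checked per insert with a ¹⁴C-sucrose tracer
(Pe < 0.5·10⁻³ cm/min); failing inserts are excluded, never silently kept.

The package also ships the two reference tables used to validate the
approach (30 marketed CNS drugs with both brain-binding methods; 62
proprietary compounds), the concordance statistics (squared Pearson
correlation on untransformed ratios, boundary-inclusive within-two-fold
counts), free-brain profile prediction from plasma profiles, microdialysis
carrier-flow dilution correction, and a synthetic-data generator with known
ground truth.

## Worked example

```python
from kpuu import (TranswellGeometry, TranswellMeasurement,
                  estimate_steady_state_ratio, efficacy_coverage)

geom = TranswellGeometry(V_lum=1500, V_ab=2500)          # µL
meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=0.2, t=60)
est = estimate_steady_state_ratio(meas, geom)
print(f"R_1h = {est.R_1h:.3f}, R_ss = {est.R_ss:.3f}")
```

prints

```
R_1h = 0.125, R_ss = 0.370
```

the donor lost 20 % of its content in one hour (λ ≈ 3.72·10⁻³ min⁻¹), the
receiver reached 12.5 % of the donor concentration, and the extrapolated
steady-state unbound ratio is 0.37 — a compound with moderate efflux
restriction.

Applying an in vitro ratio to dosing: a receptor antagonist with in vitro
IC50 = 55 nM, R_ss = 0.15, and free plasma exposures of 40, 400 and 3300 nM
at three doses:

```python
res = efficacy_coverage(R_ss=0.15, Cu_pl_per_dose=[40, 400, 3300], IC50=55)
print(res.Cu_br_pred)          # [6.0, 60.0, 495.0]  (nM)
print(res.effect_anticipated)  # [False, True, True]
```

so a pharmacological effect is anticipated at the medium and high doses only.

From the shell, the same analyses are exposed as `kpuu transwell`,
`kpuu fu-slice`, `kpuu fu-homogenate`, `kpuu fu-plasma`, `kpuu invivo`,
`kpuu predict-profile`, `kpuu compare`, `kpuu concord`, `kpuu concord-pooled`
and `kpuu simulate`.

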