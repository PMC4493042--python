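# sprkin

Binding-kinetics analysis for surface plasmon resonance (SPR) sensorgrams
with from-scratch nonlinear least-squares solvers.

SPR biosensors record, in real time and without labels, the binding of an
injected analyte (e.g. an antigen) to a surface-immobilized partner (e.g.
an antibody) as a response in RU (response units, proportional to bound
mass; for refractive-index output, RU = (1.334 − RIx) × 30000). A run has
three phases: a buffer **baseline**, an **association** phase during the
injection, and a **dissociation** phase after the injection stops.

## Model

For 1:1 binding L + R ⇌ LR at constant analyte concentration C_L
(pseudo-first-order conditions), the response obeys

```
dR/dt = ka·C_L·(Rmax − R) − kd·R
```

with closed-form phase solutions

```
association:   R(t)  = LReq·(1 − e^(−kob·t)),   kob = ka·C_L + kd
dissociation:  R(t2) = LReq·e^(−kd·(t2 − t1))
```

Fitting `y = a(1 − e^(−bx))` to the association phase and `y = a·e^(−mt)`
to the dissociation phase gives `kd = m`, `ka = (b − kd)/C_L`,
`KA = ka/kd`, `KD = kd/ka` and `Rmax = a·b/(b − kd)`. Concentrations are
mass-based (g/mL), so ka carries units of mL·g⁻¹·s⁻¹.

The two-parameter fits are solved by purpose-built iterations on the 2×2
normal equations `(JᵀJ)Δ = Jᵀr`: plain **Gauss–Newton**, and **Marquardt**
damped least squares `(JᵀJ + dI)Δ = Jᵀr` with a multiplicative damping
schedule that accepts a step only if it lowers the residual sum Q. The
damping removes the strong initial-value sensitivity of the undamped
iteration (see `examples/compare_optimizers.py`).

## Worked example

`python examples/fit_sensorgram.py` simulates the reference
antigen/antibody run (16 ng/mL analyte, 250 s baseline, 251 s
association, 38 s dissociation, 1 Hz) without noise and fits it
dissociation-first:

```
dissociation: amplitude =  3187.978 RU, rate = 0.00073 s⁻¹, Q = 1.03e-24 RU², 4 iterations
 association: amplitude =  3358.232 RU, rate = 0.01188 s⁻¹, Q = 1.31e-23 RU², 5 iterations

ka   = 6.969e+05 mL·g⁻¹·s⁻¹   (association rate constant)
kd   = 0.00073 s⁻¹            (dissociation rate constant)
KA   = 9.5462e+08 mL·g⁻¹      (affinity, ka/kd)
KD   = 1.0475e-09 g·mL⁻¹     (dissociation equilibrium, kd/ka)
Rmax = 3578.1 RU              (saturation response)
```

The fitted rates are the generating values recovered to machine
precision; KD ≈ 1 ng/mL on the mass scale indicates high-affinity
antibody binding.

The same workflow is available from the shell:

```
sprkin simulate --noise-sd 0 --seed 1 --out s.csv
sprkin fit --input s.csv --conc-ng-ml 16 --b0 0.0095 --m0 0.001 --out report.json
sprkin compare --input s.csv --b0-grid 0.0095,0.011 --out compare.json
```

`fit` exits non-zero unless both phase fits converge; `report.json`
carries every quantity with explicit units and validates against the
schema returned by `sprkin.report_json_schema()`.

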