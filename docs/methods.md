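# Methods

## Binding model and its assumptions

The package fits the 1:1 pseudo-first-order Langmuir binding model. An
analyte L at constant concentration C_L binds a surface-immobilized
receptor R; the biosensor response R(t) (RU) is proportional to the
amount of complex, Rmax to the total surface capacity. The net rate is

    dR/dt = ka·C_L·(Rmax − R) − kd·R.

Assumptions: constant C_L during the injection (flow replenishes the
analyte), no mass-transport limitation, a homogeneous ligand population,
and 1:1 stoichiometry. With R(0) = 0 at the injection start the
association phase integrates to R(t) = LReq·(1 − e^(−kob·t)) with
kob = ka·C_L + kd and LReq = ka·Rmax·C_L/kob; after the injection
(C_L = 0) the response decays as LReq·e^(−kd·Δt).

Units follow the mass-concentration convention of the reference
HBsAg/HBsAb dataset: C_L in g/mL (the CLI accepts ng/mL and multiplies
by 10⁻⁹), hence ka in mL·g⁻¹·s⁻¹, KA = ka/kd in mL·g⁻¹ and
KD = kd/ka in g·mL⁻¹. KA·KD = 1 is enforced as a type invariant.

Constant derivation from the fitted phase coefficients (a, b) and
(a, m): kd = m; ka = (b − kd)/C_L; Rmax = a·b/(b − kd), the inversion of
the LReq expression. Rmax is always derived this way rather than taken
as an independent input; for the reference coefficients it evaluates to
≈ 3578 RU, slightly above the equilibrium plateau, as it must be
whenever kd > 0. The fitted dissociation decay is stored as a positive
magnitude: a solver that parameterizes the decay with the opposite sign
still describes the same kd.

## Fitters

Both solvers act on two-parameter models with analytic Jacobians:

* association `y = a(1 − e^(−bx))`: ∂y/∂a = 1 − e^(−bx),
  ∂y/∂b = x·a·e^(−bx);
* dissociation `y = a·e^(−mx)`: ∂y/∂a = e^(−mx), ∂y/∂m = −a·x·e^(−mx).

**Gauss–Newton** solves the 2×2 normal equations
[ΣA², ΣAB; ΣAB, ΣB²]·Δ = [ΣA·r, ΣB·r] at each iterate and applies the
full step. **Marquardt** adds an unscaled damping term d to the
diagonal. A trial step is accepted only if it strictly lowers
Q = Σr²; otherwise d is multiplied by 10 and the step re-solved (at
most `max_inner = 50` times per iteration); on acceptance d is divided
by 10. Damping is additive and unscaled (d·I, no diagonal scaling), so
at d = 0 the damped system is exactly the Gauss–Newton system — a
property the tests exploit.

Defaults: tolerance ε = 10⁻⁶ applied to both parameter increments
|Δ1| and |Δ2|; initial damping d0 = 0.01; damping factor 10; iteration
cap 1000. Initial values default to a0 = max(y) (the plateau sets the
response scale) and b0 = 0.01 s⁻¹ (association) / 0.001 s⁻¹
(dissociation) when the caller gives none.

Numerical choices:

* The 2×2 system is solved in closed form; |determinant| < 10⁻³⁰ is
  treated as singular. With two parameters a factorization would add
  nothing.
* Convergence is declared as soon as a solved step satisfies both
  |Δ| ≤ ε; the final step is taken only if it strictly lowers Q, so
  the accepted-Q sequence is strictly decreasing. Checking the solved
  step (rather than only accepted steps) makes initialization exactly
  at the optimum converge in one iteration instead of spinning the
  strict-decrease inner loop.
* Divergence is non-finite Q or parameters, a singular normal matrix,
  or the iteration cap without meeting ε ("diverged" / "max_iter"
  status); overflow in e^(−bx) is flagged, never raised. If no damping
  level yields a Q-reducing step the fit returns the best point with
  status "stalled".
* The fitters contain no randomness; all stochasticity lives in the
  generator behind explicit seeds.

The two-phase pipeline fits the dissociation phase first and carries
kd into constant derivation; kd is *not* re-fit during the association
stage, whose generic (a, b) fit is constrained only post hoc by the
b > kd check in `derive_constants`. A dissociation phase whose fitted
decay removes less than 10⁻⁶ of the amplitude over the observed window
is rejected as "no measurable decay" rather than reported as kd ≈ 0.

## Segmentation

Phase windows are half-open [start, start + duration) on time values,
so sampling need not be uniform. Defaults: baseline to 250 s, 251 s
association, 38 s dissociation, contiguous. The baseline-window mean is
subtracted from **both** kinetic phases (configurable off): the phase
models have no offset term, so an unsubtracted baseline would bias kd
in particular, and both phases must share one zero. Association and
dissociation times are re-zeroed to their own phase start.

## Synthetic data generator

`GeneratorSpec` defaults reproduce the reference run: LReq = 3358.232
RU, kob = 0.01188 s⁻¹, kd = 0.00073 s⁻¹, the default windows above,
1 Hz sampling. The dissociation amplitude is the association value at
the dissociation start (continuity across the b-point), not an
independent plateau. Noise is additive i.i.d. Gaussian; σ = 20 RU and
baseline level 0 are package conventions chosen as instrument-like
scatter for a ~3000 RU signal, and a `noise` callable hook admits other
models. Identical seeds give bit-identical series.

What the generator does **not** emulate: baseline drift, injection
spikes and bulk refractive-index jumps, autocorrelated noise,
mass-transport-limited binding, surface heterogeneity or rebinding.
Passing recovery tests therefore show the solvers and pipeline are
correct for the stated model, not that real sensorgrams free of those
artifacts.

## Problem sizes and accuracy

Tests and the acceptance script use the study's own scales: 252-sample
association phases and 39-sample dissociation phases. At σ = 20 RU the
observed rate kob is recovered with a median relative error of ~0.2%
over seeded replicates (the suite asserts < 2% over 200 replicates).
The dissociation window removes only ~2.7% of the amplitude over 38 s,
so kd's sampling error at that noise is ≈12% relative — single-replicate
kd checks use a 3·SE band, and precise kd work needs longer dissociation
reads or lower noise.

## Known limitations

Single-curve analysis only: no global multi-concentration fitting, no
mass-transport or bivalent/heterogeneous models, no analytic standard
errors or confidence intervals on the fitted constants, and no
proprietary instrument-format readers (CSV/TSV only).
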