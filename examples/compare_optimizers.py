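"""Compare Gauss-Newton and Marquardt convergence across initial values.

Runs both solvers on a noisy association phase from a grid of initial
rate guesses, from near-correct to wildly wrong.  The undamped
iteration diverges (or wanders to a spurious stationary point) for poor
inits; the damped Marquardt iteration reaches the optimum from all of
them.
"""

import numpy as np

import sprkin as sk

spec = sk.GeneratorSpec(noise_sd=20.0, seed=1)
phases = sk.segment_phases(sk.generate(spec), spec.windows)
t, y = phases.association.time, phases.association.response

a0 = float(np.max(y))
grid = [(a0, b0) for b0 in (0.0095, 0.011, 0.05, 0.2, 1.0)]
report = sk.compare_fitters(t, y, grid, sk.FitConfig(max_iter=200))

print(f"{'algorithm':>13} {'b0':>8} {'status':>10} {'iters':>6} {'Q (RU²)':>12} {'b fitted':>10}")
for e in report.entries:
    print(f"{e.algorithm:>13} {e.b0:8.4f} {e.status:>10} {e.iterations:6d} "
          f"{e.Q:12.4g} {e.params[1]:10.5f}")

s = report.summary()
print(f"\ndivergences: gauss_newton = {s['gauss_newton']['divergences']}, "
      f"marquardt = {s['marquardt']['divergences']}")
print("The true rate is b = 0.01188 s⁻¹; a 'converged' Gauss-Newton run with a")
print("different b has stalled at a spurious stationary point, while every")
print("Marquardt run ends at the least-squares optimum.")
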