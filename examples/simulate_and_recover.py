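"""Generate noisy sensorgrams and measure parameter-recovery accuracy.

Draws 50 seeded replicates of the reference association phase with
20 RU Gaussian noise, fits each with the Marquardt solver and reports
the distribution of the relative error in the observed rate kob.
"""

import numpy as np

import sprkin as sk

true = sk.AssociationParams(a=3358.232, b=0.01188)
t = np.arange(252.0)
clean = sk.association_response(true, t)

errors = []
for seed in range(50):
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, 20.0, len(t))
    res = sk.marquardt_fit(t, y, "association",
                           sk.FitConfig(a0=float(np.max(y)), b0=0.01))
    errors.append(abs(res.params[1] - true.b) / true.b)

errors = np.array(errors)
print(f"replicates: {len(errors)}, noise sd: 20 RU, n = {len(t)} samples")
print(f"median |Δkob|/kob = {np.median(errors):.4f}")
print(f"90th percentile  = {np.percentile(errors, 90):.4f}")
print("\nA median relative error well under 2% means the observed rate is")
print("recoverable at instrument-like noise from a single association phase.")
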