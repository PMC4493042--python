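"""Synthetic multi-phase sensorgram generator.

Produces three-phase sensorgrams (baseline → association → dissociation)
directly from the pseudo-first-order binding model with additive i.i.d.
Gaussian noise and an explicit seed, so every fitting and comparison
test runs without external instrument data.

Defaults emulate the reference HBsAg/HBsAb run at 16 ng/mL: plateau
LReq = 3358.232 RU, observed rate kob = 0.01188 s⁻¹ over a 251 s
association phase, kd = 0.00073 s⁻¹ over a 38 s dissociation phase,
after a 250 s baseline, sampled at 1 Hz.  The dissociation amplitude
equals the association value at the dissociation start (continuity),
not an independent plateau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .io import PhaseWindows, Sensorgram
from .kinetics import AssociationParams, DissociationParams, KineticConstants

__all__ = ["GeneratorSpec", "generate", "noiseless_response", "write_truth_sidecar"]

#: default noise level, RU — a package convention for instrument-like scatter
DEFAULT_NOISE_SD = 20.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and sampling plan for a synthetic sensorgram.

    Parameters
    ----------
    a, b, m : float
        Association plateau LReq (RU), observed rate kob (s⁻¹) and
        dissociation rate kd (s⁻¹).
    windows : PhaseWindows
        Phase timing (defaults: 250 s baseline, 251 s association,
        38 s dissociation).
    sampling_interval : float
        Sample spacing in seconds (default 1.0).
    noise_sd : float
        Standard deviation of additive Gaussian noise, RU (default 20).
    seed : int
        Seed for the noise stream; identical seeds give bit-identical
        output.
    baseline_level : float
        Constant pre-injection response level, RU (default 0).
    noise : callable or None
        Optional hook ``noise(rng, n) -> array`` replacing the Gaussian
        noise model.
    """

    a: float = 3358.232
    b: float = 0.01188
    m: float = 0.00073
    windows: PhaseWindows = field(default_factory=PhaseWindows)
    sampling_interval: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    baseline_level: float = 0.0
    noise: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.sampling_interval > 0):
            raise ValueError("sampling_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_constants(cls, k: KineticConstants, **kwargs) -> "GeneratorSpec":
        """Build a spec from kinetic constants: a = LReq, b = kob, m = kd."""
        return cls(a=k.LReq, b=k.kob, m=k.kd, **kwargs)


def noiseless_response(spec: GeneratorSpec, t: np.ndarray) -> np.ndarray:
    """Deterministic model response at times ``t`` (absolute seconds)."""
    w = spec.windows
    assoc = AssociationParams(spec.a, spec.b)
    # amplitude carried into dissociation: association value just before b-point
    r_end = spec.a * -np.expm1(-spec.b * (min(w.assoc_end, w.dissoc_start) - w.assoc_start))
    dissoc = DissociationParams(r_end, spec.m) if r_end > 0 else None
    r = np.full_like(t, spec.baseline_level, dtype=float)
    in_assoc = (t >= w.assoc_start) & (t < w.assoc_end)
    r[in_assoc] += assoc.a * -np.expm1(-assoc.b * (t[in_assoc] - w.assoc_start))
    gap = (t >= w.assoc_end) & (t < w.dissoc_start)
    r[gap] += r_end
    in_dissoc = t >= w.dissoc_start
    if dissoc is not None:
        r[in_dissoc] += dissoc.a * np.exp(-dissoc.m * (t[in_dissoc] - w.dissoc_start))
    return r


def generate(spec: GeneratorSpec) -> Sensorgram:
    """Generate a three-phase synthetic sensorgram.

    Samples run from t = 0 up to (excluding) the dissociation end at
    ``sampling_interval`` spacing.  Noise is i.i.d. Gaussian with sd
    ``noise_sd`` drawn from ``numpy.random.default_rng(seed)`` (or the
    custom ``noise`` hook), added to the deterministic model response.
    """
    w = spec.windows
    t = np.arange(0.0, w.dissoc_end, spec.sampling_interval)
    r = noiseless_response(spec, t)
    if spec.noise is not None or spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise is not None:
            r = r + np.asarray(spec.noise(rng, len(t)), dtype=float)
        else:
            r = r + rng.normal(0.0, spec.noise_sd, len(t))
    return Sensorgram(t, r)


def write_truth_sidecar(spec: GeneratorSpec, path) -> None:
    """Write the generating parameters next to a simulated CSV as JSON."""
    w = spec.windows
    payload = {
        "a_RU": spec.a,
        "b_per_s": spec.b,
        "m_per_s": spec.m,
        "baseline_level_RU": spec.baseline_level,
        "noise_sd_RU": spec.noise_sd,
        "seed": spec.seed,
        "sampling_interval_s": spec.sampling_interval,
        "windows": {
            "baseline_end_s": w.baseline_end,
            "assoc_start_s": w.assoc_start,
            "assoc_duration_s": w.assoc_duration,
            "dissoc_start_s": w.dissoc_start,
            "dissoc_duration_s": w.dissoc_duration,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
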