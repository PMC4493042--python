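"""From-scratch two-parameter nonlinear least-squares solvers.

Two fitters for the exponential phase models of a 1:1 binding
sensorgram, written directly from the normal equations rather than
delegating to a generic optimizer:

* Gauss–Newton: linearize y(a, b) by a first-order Taylor expansion at
  the current iterate, solve the 2x2 normal equations

      [ΣA²  ΣAB] [Δ1]   [C]          A_i = ∂y_i/∂a,  B_i = ∂y_i/∂b,
      [ΣAB  ΣB²] [Δ2] = [D],         C = ΣA_i r_i,   D = ΣB_i r_i,

  with residuals r_i = y_i − y(a, b; x_i), and update (a, b) += (Δ1, Δ2)
  until both increments fall below the tolerance ε.

* Marquardt (damped least squares): add an unscaled damping term d to
  the diagonal,

      [ΣA²+d  ΣAB  ] [Δ1]   [C]
      [ΣAB    ΣB²+d] [Δ2] = [D],

  accept a trial step only if it lowers the sum of squared residuals Q;
  otherwise increase d by a fixed factor and re-solve.  On acceptance d
  is decreased by the same factor.  Large d shortens the step toward a
  scaled gradient direction, which is what rescues inits from which the
  undamped iteration diverges.

Both fitters are deterministic (no internal randomness) and record a
full per-iteration trace for convergence-basin comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .kinetics import AssociationParams, DissociationParams

__all__ = [
    "FitConfig",
    "FitResult",
    "FitTrace",
    "TraceRecord",
    "Model",
    "ASSOCIATION",
    "DISSOCIATION",
    "PhaseFitError",
    "assoc_jacobian",
    "dissoc_jacobian",
    "damped_step",
    "gauss_newton_fit",
    "marquardt_fit",
    "fit_dissociation_then_association",
    "TwoPhaseFit",
    "compare_fitters",
    "ComparisonEntry",
    "ComparisonReport",
]

Status = Literal["converged", "diverged", "max_iter", "stalled"]

#: determinant below this is treated as a singular normal matrix
_SINGULAR_DET = 1e-30


class PhaseFitError(RuntimeError):
    """A phase fit failed; carries the name of the failing phase."""

    def __init__(self, phase: str, message: str):
        self.phase = phase
        super().__init__(f"{phase} phase: {message}")


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration shared by both fitters.

    Parameters
    ----------
    a0, b0 : float or None
        Initial amplitude (RU) and rate (s⁻¹) guesses.  ``a0`` defaults
        to max(y) (the plateau sets the natural scale); ``b0`` defaults
        to 0.01 s⁻¹ for association fits and 0.001 s⁻¹ for dissociation
        fits.
    epsilon : float
        Convergence tolerance on |Δ1| and |Δ2| (default 1e-6).
    d0 : float
        Initial Marquardt damping (default 0.01).
    damping_factor : float
        Multiplicative adjustment of d (default 10).
    max_iter : int
        Outer iteration cap (default 1000).
    max_inner : int
        Cap on damping increases within one iteration (default 50).
    """

    a0: float | None = None
    b0: float | None = None
    epsilon: float = 1e-6
    d0: float = 0.01
    damping_factor: float = 10.0
    max_iter: int = 1000
    max_inner: int = 50

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be > 0")
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not (self.damping_factor > 1):
            raise ValueError("damping_factor must be > 1")
        if self.max_iter < 1 or self.max_inner < 1:
            raise ValueError("iteration caps must be >= 1")


class TraceRecord(NamedTuple):
    """State after one (accepted) iteration: parameters, Q, damping, step."""

    iteration: int
    a: float
    b: float
    Q: float
    d: float
    delta1: float
    delta2: float


@dataclass
class FitTrace:
    """Per-iteration history of a fit, for diagnostics and comparison plots."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, *args) -> None:
        self.records.append(TraceRecord(*args))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def q_values(self) -> np.ndarray:
        return np.array([r.Q for r in self.records])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


@dataclass
class FitResult:
    """Outcome of a two-parameter fit.

    ``params`` is the fitted (a, b) for the association model or (a, m)
    for the dissociation model; ``Q`` is the final sum of squared
    residuals (RU²); ``status`` is one of converged / diverged /
    max_iter / stalled (no Q-reducing step found within the damping
    cap; the returned point is the best found).
    """

    params: tuple[float, float]
    Q: float
    iterations: int
    status: Status
    trace: FitTrace
    message: str = ""
    model: str = "association"

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def as_association_params(self) -> AssociationParams:
        return AssociationParams(a=self.params[0], b=self.params[1])

    def as_dissociation_params(self) -> DissociationParams:
        # a negative fitted decay is reported as its magnitude (kd > 0)
        return DissociationParams(a=self.params[0], m=abs(self.params[1]))


# ---------------------------------------------------------------------------
# phase models


def assoc_jacobian(a0: float, b0: float, x: np.ndarray):
    """Jacobian columns of y = a(1 - e^(-b x)) at (a0, b0).

    A_i = ∂y/∂a = 1 - e^(-b0 x_i);  B_i = ∂y/∂b = x_i a0 e^(-b0 x_i).

    Overflow for strongly negative b0 yields non-finite entries, which
    the fitters flag as divergence rather than raising.
    """
    with np.errstate(over="ignore", under="ignore"):
        e = np.exp(-b0 * x)
    return 1.0 - e, x * a0 * e


def dissoc_jacobian(a0: float, m0: float, x: np.ndarray):
    """Jacobian columns of y = a e^(-m x): A_i = e^(-m0 x_i), B_i = -a0 x_i e^(-m0 x_i)."""
    with np.errstate(over="ignore", under="ignore"):
        e = np.exp(-m0 * x)
    return e, -a0 * x * e


@dataclass(frozen=True)
class Model:
    """A two-parameter phase model: prediction and analytic Jacobian."""

    name: str

    def predict(self, p, x: np.ndarray) -> np.ndarray:
        a, b = p
        with np.errstate(over="ignore", under="ignore"):
            if self.name == "association":
                return a * (1.0 - np.exp(-b * x))
            return a * np.exp(-b * x)

    def jacobian(self, p, x: np.ndarray):
        a, b = p
        if self.name == "association":
            return assoc_jacobian(a, b, x)
        return dissoc_jacobian(a, b, x)

    def default_b0(self) -> float:
        return 0.01 if self.name == "association" else 0.001


ASSOCIATION = Model("association")
DISSOCIATION = Model("dissociation")
_MODELS = {"association": ASSOCIATION, "dissociation": DISSOCIATION}


def _resolve_model(model) -> Model:
    if isinstance(model, Model):
        return model
    try:
        return _MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; expected 'association' or 'dissociation'"
        ) from None


# ---------------------------------------------------------------------------
# normal equations


def _sum_of_squares(model: Model, p, x, y) -> float:
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        r = y - model.predict(p, x)
        return float(np.dot(r, r))


def _normal_terms(model: Model, p, x, y):
    """(ΣA², ΣAB, ΣB², C, D) of the normal equations at iterate p."""
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        A, B = model.jacobian(p, x)
        r = y - model.predict(p, x)
        return (
            float(A @ A),
            float(A @ B),
            float(B @ B),
            float(A @ r),
            float(B @ r),
        )


def _solve_2x2(saa, sab, sbb, c, d_rhs, damping=0.0):
    """Closed-form solve of the (optionally damped) 2x2 system; None if singular."""
    m11 = saa + damping
    m22 = sbb + damping
    det = m11 * m22 - sab * sab
    if not math.isfinite(det) or abs(det) < _SINGULAR_DET:
        return None
    d1 = (m22 * c - sab * d_rhs) / det
    d2 = (m11 * d_rhs - sab * c) / det
    if not (math.isfinite(d1) and math.isfinite(d2)):
        return None
    return d1, d2


def damped_step(model, p, x, y, damping: float):
    """One damped normal-equation step (Δ1, Δ2) at iterate p; None if singular.

    With damping = 0 this is exactly the Gauss–Newton step.
    """
    model = _resolve_model(model)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    saa, sab, sbb, c, d_rhs = _normal_terms(model, p, x, y)
    if not all(map(math.isfinite, (saa, sab, sbb, c, d_rhs))):
        return None
    return _solve_2x2(saa, sab, sbb, c, d_rhs, damping)


def _prepare(x, y, model, cfg):
    model = _resolve_model(model)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("at least 3 samples are required for a 2-parameter fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("time vector must be finite")
    cfg = cfg or FitConfig()
    a0 = cfg.a0 if cfg.a0 is not None else float(np.max(y))
    b0 = cfg.b0 if cfg.b0 is not None else model.default_b0()
    return model, x, y, cfg, (a0, b0)


# ---------------------------------------------------------------------------
# fitters


def gauss_newton_fit(x, y, model="association", cfg: FitConfig | None = None) -> FitResult:
    """Undamped Gauss–Newton fit of a two-parameter phase model.

    Iterates the normal-equation solve from (a0, b0), updating
    a←a+Δ1, b←b+Δ2, until max(|Δ1|, |Δ2|) ≤ ε.  A singular normal
    matrix or non-finite Q/parameters yields status ``"diverged"``
    (never an exception); exhausting ``max_iter`` yields ``"max_iter"``.
    """
    model, x, y, cfg, p = _prepare(x, y, model, cfg)
    trace = FitTrace()
    q = _sum_of_squares(model, p, x, y)
    trace.append(0, p[0], p[1], q, 0.0, math.nan, math.nan)
    for it in range(1, cfg.max_iter + 1):
        saa, sab, sbb, c, d_rhs = _normal_terms(model, p, x, y)
        if not all(map(math.isfinite, (saa, sab, sbb, c, d_rhs))):
            return FitResult(p, q, it, "diverged", trace,
                             "non-finite normal equations", model.name)
        step = _solve_2x2(saa, sab, sbb, c, d_rhs)
        if step is None:
            return FitResult(p, q, it, "diverged", trace,
                             "singular normal matrix", model.name)
        p = (p[0] + step[0], p[1] + step[1])
        q = _sum_of_squares(model, p, x, y)
        trace.append(it, p[0], p[1], q, 0.0, step[0], step[1])
        if not (math.isfinite(q) and math.isfinite(p[0]) and math.isfinite(p[1])):
            return FitResult(p, q, it, "diverged", trace,
                             "non-finite residual or parameters", model.name)
        if abs(step[0]) <= cfg.epsilon and abs(step[1]) <= cfg.epsilon:
            return FitResult(p, q, it, "converged", trace, "", model.name)
    return FitResult(p, q, cfg.max_iter, "max_iter", trace,
                     "iteration cap reached", model.name)


def marquardt_fit(x, y, model="association", cfg: FitConfig | None = None) -> FitResult:
    """Damped (Marquardt) least-squares fit of a two-parameter phase model.

    Each iteration solves the damped normal equations at the current
    point.  A trial step is accepted only if it lowers Q; otherwise the
    damping d is multiplied by ``damping_factor`` and the step
    re-solved (at most ``max_inner`` times).  On acceptance d is
    divided by the same factor.  Convergence is declared as soon as a
    solved step satisfies |Δ1| ≤ ε and |Δ2| ≤ ε (the final step is
    taken only if it strictly lowers Q).  If no damping level yields a
    Q-reducing step the current point is returned with status
    ``"stalled"`` (a local minimum at the achievable step resolution).
    """
    model, x, y, cfg, p = _prepare(x, y, model, cfg)
    trace = FitTrace()
    q = _sum_of_squares(model, p, x, y)
    if not math.isfinite(q):
        return FitResult(p, q, 0, "diverged", trace,
                         "non-finite Q at initial point", model.name)
    d = cfg.d0
    trace.append(0, p[0], p[1], q, d, math.nan, math.nan)
    for it in range(1, cfg.max_iter + 1):
        saa, sab, sbb, c, d_rhs = _normal_terms(model, p, x, y)
        if not all(map(math.isfinite, (saa, sab, sbb, c, d_rhs))):
            return FitResult(p, q, it, "diverged", trace,
                             "non-finite normal equations", model.name)
        accepted = False
        for _ in range(cfg.max_inner):
            step = _solve_2x2(saa, sab, sbb, c, d_rhs, damping=d)
            if step is None:
                d *= cfg.damping_factor
                continue
            p_trial = (p[0] + step[0], p[1] + step[1])
            q_trial = _sum_of_squares(model, p_trial, x, y)
            small = abs(step[0]) <= cfg.epsilon and abs(step[1]) <= cfg.epsilon
            if small:
                # converged: take the final sub-tolerance step only if it
                # strictly improves Q, keeping accepted-Q strictly decreasing
                if math.isfinite(q_trial) and q_trial < q:
                    p, q = p_trial, q_trial
                    trace.append(it, p[0], p[1], q, d, step[0], step[1])
                return FitResult(p, q, it, "converged", trace, "", model.name)
            if math.isfinite(q_trial) and q_trial < q:
                p, q = p_trial, q_trial
                trace.append(it, p[0], p[1], q, d, step[0], step[1])
                d /= cfg.damping_factor
                accepted = True
                break
            d *= cfg.damping_factor
        if not accepted:
            return FitResult(
                p, q, it, "stalled", trace,
                "no Q-reducing step within damping cap; returning best point",
                model.name,
            )
    return FitResult(p, q, cfg.max_iter, "max_iter", trace,
                     "iteration cap reached", model.name)


# ---------------------------------------------------------------------------
# two-phase pipeline fit


class TwoPhaseFit(NamedTuple):
    """Dissociation-first, association-second fit of a segmented sensorgram."""

    dissociation_params: DissociationParams
    association_params: AssociationParams
    dissociation_fit: FitResult
    association_fit: FitResult


def fit_dissociation_then_association(
    assoc_x, assoc_y, dissoc_x, dissoc_y,
    cfg: FitConfig | None = None,
    *,
    dissoc_cfg: FitConfig | None = None,
    fitter=marquardt_fit,
) -> TwoPhaseFit:
    """Fit kd from the dissociation phase first, then the association phase.

    The dissociation phase is fitted as y = a·e^(−m·t) and the
    association phase as y = a·(1 − e^(−b·t)); both time vectors are
    re-zeroed to their own phase start before fitting.  kd = m from the
    first fit is intended to be carried into constant derivation
    downstream (it is not re-fit during the association stage).

    ``cfg`` configures the association fit; ``dissoc_cfg`` (default:
    fresh defaults) the dissociation fit.

    Raises
    ------
    PhaseFitError
        If either sub-fit fails to converge (naming the phase), or if
        the dissociation phase shows no measurable decay (m ≈ 0).
    """
    if len(np.atleast_1d(assoc_x)) == 0 or len(np.atleast_1d(dissoc_x)) == 0:
        raise PhaseFitError("association" if len(np.atleast_1d(assoc_x)) == 0
                            else "dissociation", "empty phase")
    dx = np.asarray(dissoc_x, dtype=float)
    dx = dx - dx[0]
    d_res = fitter(dx, dissoc_y, DISSOCIATION, dissoc_cfg or FitConfig())
    if not d_res.converged:
        raise PhaseFitError("dissociation", f"fit {d_res.status}: {d_res.message}")
    a_d, m = d_res.params
    span = float(dx[-1]) if len(dx) > 1 else 0.0
    # decay fraction over the observed window distinguishes m≈0 from slow decay
    if m <= 0 or -np.expm1(-m * span) < 1e-6:
        raise PhaseFitError("dissociation", f"no measurable decay (m = {m:.3g} s⁻¹)")
    ax = np.asarray(assoc_x, dtype=float)
    ax = ax - ax[0]
    a_res = fitter(ax, assoc_y, ASSOCIATION, cfg or FitConfig())
    if not a_res.converged:
        raise PhaseFitError("association", f"fit {a_res.status}: {a_res.message}")
    return TwoPhaseFit(
        d_res.as_dissociation_params(),
        a_res.as_association_params(),
        d_res,
        a_res,
    )


# ---------------------------------------------------------------------------
# fitter comparison


@dataclass(frozen=True)
class ComparisonEntry:
    algorithm: str
    a0: float
    b0: float
    status: Status
    iterations: int
    Q: float
    params: tuple[float, float]


@dataclass
class ComparisonReport:
    """Per-init convergence comparison of Gauss–Newton vs Marquardt."""

    entries: list[ComparisonEntry]
    max_iter: int

    _DIVERGENT = ("diverged", "max_iter")

    def divergence_count(self, algorithm: str) -> int:
        return sum(
            1 for e in self.entries
            if e.algorithm == algorithm and e.status in self._DIVERGENT
        )

    def iteration_total(self, algorithm: str) -> int:
        """Total iterations, with divergent runs counted at the cap."""
        return sum(
            self.max_iter if e.status in self._DIVERGENT else e.iterations
            for e in self.entries
            if e.algorithm == algorithm
        )

    def summary(self) -> dict:
        return {
            alg: {
                "divergences": self.divergence_count(alg),
                "iteration_total": self.iteration_total(alg),
            }
            for alg in ("gauss_newton", "marquardt")
        }


def compare_fitters(
    x, y, init_grid: Sequence[tuple[float, float]],
    cfg: FitConfig | None = None, model="association",
) -> ComparisonReport:
    """Run both fitters over a grid of (a0, b0) inits and tabulate outcomes.

    Failures are recorded per entry, never raised.
    """
    if len(init_grid) == 0:
        raise ValueError("init_grid must be non-empty")
    cfg = cfg or FitConfig()
    entries = []
    for a0, b0 in init_grid:
        run_cfg = FitConfig(
            a0=a0, b0=b0, epsilon=cfg.epsilon, d0=cfg.d0,
            damping_factor=cfg.damping_factor, max_iter=cfg.max_iter,
            max_inner=cfg.max_inner,
        )
        for alg, fitter in (("gauss_newton", gauss_newton_fit),
                            ("marquardt", marquardt_fit)):
            res = fitter(x, y, model, run_cfg)
            entries.append(ComparisonEntry(
                alg, a0, b0, res.status, res.iterations, res.Q, res.params
            ))
    return ComparisonReport(entries, cfg.max_iter)
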