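"""End-to-end analysis workflow and structured report.

``run_fit`` loads a sensorgram, segments it into phases, performs the
dissociation-first / association-second fit and derives the kinetic
constants; ``run_compare`` tabulates Gauss–Newton vs Marquardt
convergence over a grid of initial values.  Reports are pydantic
models, serialized as JSON with units on every quantity and no
timestamps, so identical inputs give byte-identical reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from .fitters import (
    FitConfig,
    FitResult,
    PhaseFitError,
    compare_fitters,
    fit_dissociation_then_association,
    gauss_newton_fit,
    marquardt_fit,
)
from .io import (
    PhaseWindows,
    SegmentationError,
    Sensorgram,
    read_sensorgram,
    segment_phases,
    write_sensorgram,
)
from .kinetics import InvalidKineticsError, derive_constants

__all__ = [
    "AnalysisReport",
    "PhaseFitReport",
    "ConstantsReport",
    "CompareReport",
    "run_fit",
    "run_compare",
    "report_json_schema",
]


class InputSummary(BaseModel):
    model_config = ConfigDict(frozen=True)
    path: str
    n_samples: int
    time_start_s: float
    time_end_s: float


class PhaseFitReport(BaseModel):
    model_config = ConfigDict(frozen=True)
    phase: Literal["association", "dissociation"]
    n_points: int
    amplitude_RU: float
    rate_per_s: float
    Q_RU2: float
    iterations: int
    status: str


class ConstantsReport(BaseModel):
    """Kinetic constants with explicit units."""

    model_config = ConfigDict(frozen=True)
    ka_mL_per_g_per_s: float
    kd_per_s: float
    KA_mL_per_g: float
    KD_g_per_mL: float
    Rmax_RU: float
    CL_g_per_mL: float


class ConfigEcho(BaseModel):
    model_config = ConfigDict(frozen=True)
    algorithm: str
    a0_RU: Optional[float]
    b0_per_s: Optional[float]
    m0_per_s: Optional[float]
    epsilon: float
    d0: float
    damping_factor: float
    max_iter: int
    subtract_baseline: bool
    windows: dict[str, float]


class AnalysisReport(BaseModel):
    """Full analysis output: input, per-phase fits, constants, config, warnings."""

    model_config = ConfigDict(frozen=True)
    input: InputSummary
    fits: list[PhaseFitReport]
    constants: Optional[ConstantsReport]
    config: ConfigEcho
    warnings: list[str]

    @property
    def converged(self) -> bool:
        phases = {f.phase for f in self.fits if f.status == "converged"}
        return {"association", "dissociation"} <= phases


def report_json_schema() -> dict:
    """The published JSON schema of :class:`AnalysisReport`."""
    return AnalysisReport.model_json_schema()


_FITTERS = {"marquardt": marquardt_fit, "gauss-newton": gauss_newton_fit}


def _phase_report(phase: str, n: int, res: FitResult) -> PhaseFitReport:
    return PhaseFitReport(
        phase=phase,
        n_points=n,
        amplitude_RU=res.params[0],
        rate_per_s=abs(res.params[1]),
        Q_RU2=res.Q,
        iterations=res.iterations,
        status=res.status,
    )


def run_fit(
    input_path,
    windows: PhaseWindows | None = None,
    conc_g_per_ml: float = 16e-9,
    cfg: FitConfig | None = None,
    *,
    m0: float | None = None,
    algorithm: str = "marquardt",
    subtract_baseline: bool = True,
    ri: bool = False,
    sensorgram: Sensorgram | None = None,
    out=None,
    curve_out=None,
    trace_out=None,
) -> AnalysisReport:
    """Fit a sensorgram end to end and derive the kinetic constants.

    Segments the input with ``windows``, fits the dissociation phase
    first (init rate ``m0``), then the association phase (config
    ``cfg``), and derives ka, kd, KA, KD, Rmax at concentration
    ``conc_g_per_ml``.  If the dissociation window is empty an
    association-only partial report is returned (constants omitted,
    warning recorded).  A fit failure likewise yields a partial report
    naming the failing phase; the caller decides the exit status via
    ``report.converged``.

    Optional side outputs: ``out`` (report JSON), ``curve_out`` (CSV of
    observed vs fitted responses for both phases), ``trace_out``
    (association-fit iteration trace CSV).
    """
    windows = windows or PhaseWindows()
    cfg = cfg or FitConfig()
    fitter = _FITTERS[algorithm]
    s = sensorgram if sensorgram is not None else read_sensorgram(input_path, ri=ri)
    warnings: list[str] = []
    fits: list[PhaseFitReport] = []
    constants = None
    two = None

    dissoc_cfg = FitConfig(
        b0=m0, epsilon=cfg.epsilon, d0=cfg.d0,
        damping_factor=cfg.damping_factor, max_iter=cfg.max_iter,
        max_inner=cfg.max_inner,
    )
    try:
        phases = segment_phases(s, windows, subtract_baseline=subtract_baseline)
    except SegmentationError as exc:
        if exc.phase != "dissociation":
            raise
        warnings.append(f"dissociation window missing: {exc}; association-only report")
        phases = None
    if phases is None:
        # association-only fallback: slice and baseline-correct by hand
        assoc = s.window(windows.assoc_start, windows.assoc_end)
        if len(assoc) == 0:
            raise SegmentationError("association", "window is empty")
        base = s.window(float(s.time[0]), windows.baseline_end)
        offset = float(np.mean(base.response)) if (subtract_baseline and len(base)) else 0.0
        res = fitter(assoc.time - windows.assoc_start, assoc.response - offset,
                     "association", cfg)
        fits.append(_phase_report("association", len(assoc), res))
    else:
        try:
            two = fit_dissociation_then_association(
                phases.association.time, phases.association.response,
                phases.dissociation.time, phases.dissociation.response,
                cfg, dissoc_cfg=dissoc_cfg, fitter=fitter,
            )
        except PhaseFitError as exc:
            warnings.append(str(exc))
        if two is not None:
            fits.append(_phase_report("dissociation", len(phases.dissociation),
                                      two.dissociation_fit))
            fits.append(_phase_report("association", len(phases.association),
                                      two.association_fit))
            try:
                k = derive_constants(two.association_params,
                                     two.dissociation_params, conc_g_per_ml)
                constants = ConstantsReport(
                    ka_mL_per_g_per_s=k.ka, kd_per_s=k.kd, KA_mL_per_g=k.KA,
                    KD_g_per_mL=k.KD, Rmax_RU=k.Rmax, CL_g_per_mL=k.CL,
                )
            except InvalidKineticsError as exc:
                warnings.append(str(exc))

    report = AnalysisReport(
        input=InputSummary(
            path=str(input_path), n_samples=len(s),
            time_start_s=float(s.time[0]), time_end_s=float(s.time[-1]),
        ),
        fits=fits,
        constants=constants,
        config=ConfigEcho(
            algorithm=algorithm, a0_RU=cfg.a0, b0_per_s=cfg.b0, m0_per_s=m0,
            epsilon=cfg.epsilon, d0=cfg.d0, damping_factor=cfg.damping_factor,
            max_iter=cfg.max_iter, subtract_baseline=subtract_baseline,
            windows={
                "baseline_end_s": windows.baseline_end,
                "assoc_start_s": windows.assoc_start,
                "assoc_duration_s": windows.assoc_duration,
                "dissoc_start_s": windows.dissoc_start,
                "dissoc_duration_s": windows.dissoc_duration,
            },
        ),
        warnings=warnings,
    )
    if out is not None:
        Path(out).write_text(report.model_dump_json(indent=2) + "\n")
    if curve_out is not None and two is not None and phases is not None:
        _write_curves(curve_out, phases, two)
    if trace_out is not None and two is not None:
        two.association_fit.trace.to_csv(trace_out)
    return report


def _write_curves(path, phases, two) -> None:
    import pandas as pd

    from .kinetics import association_response, dissociation_response

    frames = []
    for name, sub, fitted in (
        ("association", phases.association,
         association_response(two.association_params, phases.association.time)),
        ("dissociation", phases.dissociation,
         dissociation_response(two.dissociation_params, phases.dissociation.time)),
    ):
        frames.append(pd.DataFrame({
            "phase": name, "time_s": sub.time,
            "observed_RU": sub.response, "fitted_RU": fitted,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class CompareEntryReport(BaseModel):
    model_config = ConfigDict(frozen=True)
    algorithm: str
    a0_RU: float
    b0_per_s: float
    status: str
    iterations: int
    Q_RU2: float


class CompareReport(BaseModel):
    """Algorithm × init convergence table with per-algorithm summaries."""

    model_config = ConfigDict(frozen=True)
    entries: list[CompareEntryReport]
    summary: dict[str, dict[str, int]]


def run_compare(
    input_path,
    b0_grid,
    windows: PhaseWindows | None = None,
    cfg: FitConfig | None = None,
    *,
    a0: float | None = None,
    subtract_baseline: bool = True,
    ri: bool = False,
    sensorgram: Sensorgram | None = None,
    out=None,
) -> CompareReport:
    """Compare both fitters over a b0 grid on the association phase.

    Each grid entry pairs a b0 with ``a0`` (default: max of the
    association response).  Failures are tabulated, never raised.
    """
    windows = windows or PhaseWindows()
    cfg = cfg or FitConfig()
    s = sensorgram if sensorgram is not None else read_sensorgram(input_path, ri=ri)
    phases = segment_phases(s, windows, subtract_baseline=subtract_baseline)
    assoc = phases.association
    a0_val = a0 if a0 is not None else float(np.max(assoc.response))
    grid = [(a0_val, float(b0)) for b0 in b0_grid]
    rep = compare_fitters(assoc.time, assoc.response, grid, cfg)
    report = CompareReport(
        entries=[
            CompareEntryReport(
                algorithm=e.algorithm, a0_RU=e.a0, b0_per_s=e.b0,
                status=e.status, iterations=e.iterations, Q_RU2=e.Q,
            )
            for e in rep.entries
        ],
        summary=rep.summary(),
    )
    if out is not None:
        Path(out).write_text(report.model_dump_json(indent=2) + "\n")
    return report
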