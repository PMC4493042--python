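"""1:1 pseudo-first-order binding model for SPR sensorgrams.

A single analyte L binding a surface-immobilized receptor R with 1:1
stoichiometry obeys the net-rate equation

    dR/dt = ka * CL * (Rmax - R) - kd * R

where R is the biosensor response (RU), CL the (constant) analyte
concentration, Rmax the saturation response, ka the association rate
constant and kd the dissociation rate constant.  Because CL is held
constant during the injection the kinetics are pseudo-first-order and
the association phase has the closed-form solution

    R(t) = LReq * (1 - exp(-kob * t)),   kob = ka*CL + kd,
    LReq = ka * Rmax * CL / (ka*CL + kd)

while the dissociation phase (CL = 0) decays as

    R(t2) = LReq * exp(-kd * (t2 - t1)).

Fitting the two phases yields (a=LReq, b=kob) and (a, m=kd), from which
all kinetic and affinity constants follow arithmetically.

Units follow the mass-concentration convention of the reference
HBsAg/HBsAb experiment: CL in g/mL, hence ka in mL·g⁻¹·s⁻¹, KA in
mL·g⁻¹ and KD in g·mL⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AssociationParams",
    "DissociationParams",
    "KineticConstants",
    "InvalidKineticsError",
    "association_response",
    "dissociation_response",
    "net_rate",
    "derive_constants",
    "association_params_from_constants",
    "NG_PER_ML_TO_G_PER_ML",
]

#: conversion factor: concentration given in ng/mL -> internal g/mL
NG_PER_ML_TO_G_PER_ML = 1e-9


class InvalidKineticsError(ValueError):
    """Fitted coefficients are kinetically inconsistent (e.g. kob <= kd)."""


@dataclass(frozen=True)
class AssociationParams:
    """Coefficients of the association model ``y = a * (1 - exp(-b*t))``.

    Attributes
    ----------
    a : float
        Equilibrium plateau LReq, in RU.  Must be positive.
    b : float
        Observed pseudo-first-order rate kob = ka*CL + kd, in s⁻¹.
        Must be positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"association plateau a must be > 0, got {self.a}")
        if not (self.b > 0):
            raise ValueError(f"observed rate b must be > 0, got {self.b}")


@dataclass(frozen=True)
class DissociationParams:
    """Coefficients of the dissociation model ``y = a * exp(-m*t)``.

    ``m`` is the dissociation rate constant kd stored as a positive
    magnitude; a decay fitted with the opposite sign convention is
    interpreted as kd = |m|.
    """

    a: float
    m: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"dissociation amplitude a must be > 0, got {self.a}")
        if self.m < 0:
            raise ValueError(
                f"decay constant m is stored as a positive magnitude, got {self.m}"
            )


@dataclass(frozen=True)
class KineticConstants:
    """Rate and affinity constants of a 1:1 interaction.

    Attributes
    ----------
    ka : float
        Association rate constant, mL·g⁻¹·s⁻¹.
    kd : float
        Dissociation rate constant, s⁻¹.
    KA : float
        Equilibrium association constant ka/kd, mL·g⁻¹.
    KD : float
        Equilibrium dissociation constant kd/ka, g·mL⁻¹.
    Rmax : float
        Saturation response (all surface sites occupied), RU.
    CL : float
        Analyte concentration, g·mL⁻¹.
    """

    ka: float
    kd: float
    KA: float
    KD: float
    Rmax: float
    CL: float

    _RTOL = 1e-12

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "CL"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isclose(self.KA, self.ka / self.kd, rtol=self._RTOL, atol=0):
            raise ValueError("KA inconsistent with ka/kd")
        if not np.isclose(self.KD, self.kd / self.ka, rtol=self._RTOL, atol=0):
            raise ValueError("KD inconsistent with kd/ka")
        if not np.isclose(self.KA * self.KD, 1.0, rtol=self._RTOL, atol=0):
            raise ValueError("KA*KD must equal 1")

    @property
    def kob(self) -> float:
        """Observed association rate ka*CL + kd, s⁻¹."""
        return self.ka * self.CL + self.kd

    @property
    def LReq(self) -> float:
        """Equilibrium plateau ka*Rmax*CL/(ka*CL + kd), RU."""
        return self.ka * self.Rmax * self.CL / self.kob


def association_response(p: AssociationParams, t) -> np.ndarray | float:
    """Association-phase response ``a * (1 - exp(-b*t))`` at time(s) ``t``.

    ``t`` is measured from the injection start (re-zeroed), in seconds.
    The response is non-decreasing in t and bounded above by the
    plateau ``a``.

    Raises
    ------
    ValueError
        If any element of ``t`` is negative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("association time must be >= 0 (re-zeroed to injection)")
    out = p.a * (1.0 - np.exp(-p.b * t))
    return out if out.ndim else float(out)


def dissociation_response(p: DissociationParams, t2, t1=0.0) -> np.ndarray | float:
    """Dissociation-phase response ``a * exp(-m*(t2 - t1))``.

    ``t1`` is the dissociation start time and ``t2`` any later time;
    the response equals ``a`` at t2 = t1 and decays monotonically.

    Raises
    ------
    ValueError
        If any t2 < t1.
    """
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 < t1):
        raise ValueError("dissociation requires t2 >= t1")
    out = p.a * np.exp(-p.m * (t2 - t1))
    return out if out.ndim else float(out)


def net_rate(R, k: KineticConstants) -> np.ndarray | float:
    """Net binding rate ``dR/dt = ka*CL*(Rmax - R) - kd*R`` in RU·s⁻¹.

    Zero exactly at the equilibrium response
    ``R_eq = ka*Rmax*CL / (ka*CL + kd)``; equals ``ka*CL*Rmax`` at R = 0.
    Meaningful for 0 <= R <= Rmax.
    """
    R = np.asarray(R, dtype=float)
    out = k.ka * k.CL * (k.Rmax - R) - k.kd * R
    return out if out.ndim else float(out)


def derive_constants(
    assoc: AssociationParams, dissoc: DissociationParams, CL: float
) -> KineticConstants:
    """Derive all kinetic constants from fitted phase coefficients.

    Given the association fit (a = LReq, b = kob), the dissociation fit
    (m = kd) and the analyte concentration CL (g/mL):

        kd   = m
        ka   = (b - kd) / CL          [from kob = ka*CL + kd]
        KA   = ka / kd,  KD = kd / ka
        Rmax = a * b / (b - kd)       [inversion of LReq = ka*Rmax*CL/kob]

    Raises
    ------
    InvalidKineticsError
        If b <= m (kob must exceed kd for a positive ka) — signals an
        inconsistent concentration or fit.
    ValueError
        If CL <= 0.
    """
    if not (CL > 0):
        raise ValueError(f"analyte concentration CL must be > 0 g/mL, got {CL}")
    kd = dissoc.m
    if not (assoc.b > kd):
        raise InvalidKineticsError(
            f"observed rate kob = {assoc.b} s⁻¹ must exceed kd = {kd} s⁻¹; "
            "check concentration and phase fits"
        )
    ka = (assoc.b - kd) / CL
    Rmax = assoc.a * assoc.b / (assoc.b - kd)
    return KineticConstants(ka=ka, kd=kd, KA=ka / kd, KD=kd / ka, Rmax=Rmax, CL=CL)


def association_params_from_constants(k: KineticConstants) -> AssociationParams:
    """Re-synthesize the association coefficients (a, b) from constants.

    Inverse of :func:`derive_constants` for the association phase:
    a = ka*Rmax*CL/(ka*CL + kd), b = ka*CL + kd.
    """
    return AssociationParams(a=k.LReq, b=k.kob)
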