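"""Temperature-dependent model parameters and the phase-equation right-hand side.

The membrane-potential phase ``theta`` obeys an Adler-type equation

    dtheta/dt = F(t, theta) = f1 + f2 * cos(theta)

with slow periodic modulation

    f1 = b - A * cos(phi),      f2 = 1 + A * cos(phi),

where ``phi`` is the modulation phase (``Omega * t`` at a steady
temperature).  One full 2*pi rotation of ``theta`` corresponds to one
action potential.  The triple ``(b, A, Omega)`` depends on the effective
temperature either linearly (the original parameterisation) or through
saturating tanh forms (the modified parameterisation used everywhere
else in this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "TanhParameterSet",
    "LinearParameterSet",
    "ParamValues",
    "tanh_params",
    "linear_params",
    "evaluate_params",
    "modulation_terms",
    "phase_velocity",
    "DEFAULT_TANH",
    "ROPER_LINEAR",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class TanhParameterSet:
    """Saturating (sigmoidal) temperature dependence of ``(b, A, Omega)``.

    Each parameter follows ``p0 -/+ p1 * tanh(C * (Teff - Tbar))`` so that
    the modulation saturates at both temperature extremes.  Rates are in
    1/ms, ``C`` in 1/degC and ``Tbar`` in degC.

    Invariants: ``C > 0``; ``A0 >= A1`` and ``Omega0 >= Omega1`` so that
    ``A`` and ``Omega`` stay nonnegative for every effective temperature
    (the default set has ``Omega0 == Omega1``, hence ``Omega -> 0`` as
    ``Teff -> -inf``).
    """

    b0: float
    b1: float
    A0: float
    A1: float
    Omega0: float
    Omega1: float
    C: float
    Tbar: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_finite(f.name, getattr(self, f.name))
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.A0 - self.A1 < 0:
            raise ValueError("A0 - A1 must be >= 0 so A stays nonnegative")
        if self.Omega0 - self.Omega1 < 0:
            raise ValueError("Omega0 - Omega1 must be >= 0 so Omega stays nonnegative")


@dataclass(frozen=True)
class LinearParameterSet:
    """Straight-line temperature dependence of ``(b, A, Omega)``.

    ``b = b0 - b1*T``, ``A = A0 + A1*T``, ``Omega = Omega0 + Omega1*T``.
    Offsets are rates (1/ms), slopes carry 1/ms per degC.  The linear
    forms are unbounded in temperature, which is the modelling motivation
    for the tanh replacement.
    """

    b0: float
    b1: float
    A0: float
    A1: float
    Omega0: float
    Omega1: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_finite(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class ParamValues:
    """``(b, A, Omega)`` evaluated at one effective temperature."""

    b: float
    A: float
    Omega: float
    Teff: float


#: Default tanh parameter set (rates in 1/ms, C in 1/degC, Tbar in degC).
#: Omega constants are stored as exact multiples of pi.
DEFAULT_TANH = TanhParameterSet(
    b0=0.4475,
    b1=0.1575,
    A0=0.3325,
    A1=0.0225,
    Omega0=3 * math.pi / 200,
    Omega1=3 * math.pi / 200,
    C=0.055,
    Tbar=33.75,
)

#: Original linear parameter set (slopes in 1/ms per degC).
ROPER_LINEAR = LinearParameterSet(
    b0=0.675,
    b1=0.007,
    A0=0.3,
    A1=0.001,
    Omega0=-math.pi / 150,
    Omega1=math.pi / 1500,
)


def _check_teff(Teff) -> None:
    if not np.all(np.isfinite(Teff)):
        raise ValueError(f"effective temperature must be finite, got {Teff!r}")


def tanh_params(pset: TanhParameterSet, Teff) -> ParamValues:
    """Evaluate the tanh parameter forms at effective temperature ``Teff``.

    Parameters
    ----------
    pset : TanhParameterSet
    Teff : float or ndarray
        Effective temperature in degC.

    Returns
    -------
    ParamValues
        ``b = b0 - b1*tanh(C*(Teff-Tbar))``, ``A = A0 + A1*tanh(...)``,
        ``Omega = Omega0 + Omega1*tanh(...)``.
    """
    _check_teff(Teff)
    s = np.tanh(pset.C * (np.asarray(Teff, dtype=float) - pset.Tbar))
    if s.ndim == 0:
        s = float(s)
    return ParamValues(
        b=pset.b0 - pset.b1 * s,
        A=pset.A0 + pset.A1 * s,
        Omega=pset.Omega0 + pset.Omega1 * s,
        Teff=Teff,
    )


def linear_params(pset: LinearParameterSet, T) -> ParamValues:
    """Evaluate the linear parameter forms at temperature ``T`` (degC).

    No clamping is applied; the result can leave the physically sensible
    range at extreme temperatures.
    """
    _check_teff(T)
    T = np.asarray(T, dtype=float)
    if T.ndim == 0:
        T = float(T)
    return ParamValues(
        b=pset.b0 - pset.b1 * T,
        A=pset.A0 + pset.A1 * T,
        Omega=pset.Omega0 + pset.Omega1 * T,
        Teff=T,
    )


def evaluate_params(pset, Teff) -> ParamValues:
    """Dispatch to :func:`tanh_params` or :func:`linear_params` by set type."""
    if isinstance(pset, TanhParameterSet):
        return tanh_params(pset, Teff)
    if isinstance(pset, LinearParameterSet):
        return linear_params(pset, Teff)
    raise TypeError(f"unsupported parameter set type: {type(pset).__name__}")


def modulation_terms(pv: ParamValues, phi):
    """Return the modulation pair ``(f1, f2)`` at modulation phase ``phi``.

    ``f1 = b - A*cos(phi)`` and ``f2 = 1 + A*cos(phi)``; their sum is
    ``1 + b`` identically.  A burst can occur only while ``f1 > f2``.
    """
    c = np.cos(phi)
    f1 = pv.b - pv.A * c
    f2 = 1.0 + pv.A * c
    return f1, f2


def phase_velocity(f1, f2, theta):
    """Phase velocity ``F = f1 + f2*cos(theta)`` (this is dtheta/dt)."""
    return f1 + f2 * np.cos(theta)
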