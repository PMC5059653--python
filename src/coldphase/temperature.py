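"""Morse-like effective-temperature dynamics for high-to-low transitions.

A step from initial effective temperature ``Ti_eff`` down to ``Tf_eff``
is modelled by

    Teff(t) = D * (1 - exp(-a*(t - tbar)))**2 + T0_eff,

which starts at ``Ti_eff``, undershoots to its minimum ``T0_eff`` at
``t = tbar`` and relaxes to ``Tf_eff``.  The same curve is generated by
the first-order ODE

    dw/dt = a * (sqrt(D) - w),        w**2 = Teff - T0_eff,

provided the initial half-width is taken *negative*,
``w(0) = -sqrt(Ti_eff - T0_eff)``; a positive start would skip the
undershoot.  The width parameter may itself depend on the state through
``a(w) = a0 * exp(alpha * (w**2 + T0_eff))``, i.e. ``a0*exp(alpha*Teff)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TransitionSpec",
    "WidthFit",
    "DEFAULT_WIDTH_FIT",
    "make_transition",
    "set_width",
    "time_of_minimum",
    "morse_teff",
    "width_rhs",
    "teff_from_w",
    "width_function",
    "initial_w",
]


@dataclass(frozen=True)
class TransitionSpec:
    """One high-to-low effective-temperature transition.

    ``D`` is the undershoot depth and ``T0_eff`` the minimum effective
    temperature; by construction ``D + T0_eff == Tf_eff`` exactly.
    ``tbar`` (time of the minimum, ms) is populated once the width
    parameter ``a`` is chosen; see :func:`set_width`.
    """

    Ti_eff: float
    Tf_eff: float
    D: float
    T0_eff: float
    tbar: float | None = None


@dataclass(frozen=True)
class WidthFit:
    """Exponential width function ``a(w) = a0 * exp(alpha*(w**2 + T0_eff))``."""

    a0: float
    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a0) and self.a0 > 0):
            raise ValueError(f"a0 must be positive and finite, got {self.a0}")
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")


#: Width-function constants obtained by fitting matched widths across
#: transitions from 40 degC (a0 in 1/ms, alpha in 1/degC).
DEFAULT_WIDTH_FIT = WidthFit(a0=4.5e-4, alpha=0.1)


def make_transition(
    Ti_eff: float, Tf_eff: float, *, D: float | None = None
) -> TransitionSpec:
    """Build a :class:`TransitionSpec` for a high-to-low step.

    By default ``D = (Ti_eff - Tf_eff)/4`` and
    ``T0_eff = (5*Tf_eff - Ti_eff)/4``.  A different depth ``D > 0`` may
    be supplied; ``T0_eff`` is then ``Tf_eff - D`` so the asymptote is
    preserved.

    Raises
    ------
    ValueError
        If ``Tf_eff >= Ti_eff`` (only downward transitions are modelled)
        or inputs are not finite.
    """
    if not (math.isfinite(Ti_eff) and math.isfinite(Tf_eff)):
        raise ValueError("temperatures must be finite")
    if Tf_eff >= Ti_eff:
        raise ValueError(
            f"transition must be high-to-low: Tf_eff={Tf_eff} >= Ti_eff={Ti_eff}"
        )
    if D is None:
        D = (Ti_eff - Tf_eff) / 4.0
    elif not (math.isfinite(D) and D > 0):
        raise ValueError(f"depth D must be positive, got {D}")
    T0_eff = Tf_eff - D
    return TransitionSpec(Ti_eff=Ti_eff, Tf_eff=Tf_eff, D=D, T0_eff=T0_eff)


def time_of_minimum(spec: TransitionSpec, a: float) -> float:
    """Time ``tbar`` at which ``Teff`` reaches its minimum ``T0_eff``.

    Fixed by the initial condition ``Teff(0) = Ti_eff``:
    ``D*(1 - exp(a*tbar))**2 = Ti_eff - T0_eff`` gives
    ``tbar = ln(1 + sqrt((Ti_eff - T0_eff)/D)) / a`` (``ln(1+sqrt(5))/a``
    for the default depth).
    """
    if a <= 0:
        raise ValueError(f"width parameter a must be positive, got {a}")
    return math.log(1.0 + math.sqrt((spec.Ti_eff - spec.T0_eff) / spec.D)) / a


def set_width(spec: TransitionSpec, a: float) -> TransitionSpec:
    """Return a copy of ``spec`` with ``tbar`` fixed by the width ``a``."""
    return replace(spec, tbar=time_of_minimum(spec, a))


def morse_teff(spec: TransitionSpec, a: float, t):
    """Closed-form Morse-like effective temperature at time(s) ``t`` (ms).

    ``Teff(t) = D*(1 - exp(-a*(t - tbar)))**2 + T0_eff`` with ``tbar``
    taken from ``spec`` if set, else derived from ``a`` via
    :func:`time_of_minimum`.
    """
    tbar = spec.tbar if spec.tbar is not None else time_of_minimum(spec, a)
    e = np.exp(-a * (np.asarray(t, dtype=float) - tbar))
    out = spec.D * (1.0 - e) ** 2 + spec.T0_eff
    return float(out) if out.ndim == 0 else out


def teff_from_w(w, spec: TransitionSpec):
    """Map the half-width state to temperature: ``Teff = T0_eff + w**2``."""
    return spec.T0_eff + np.square(w)


def width_function(fit: WidthFit, w, spec: TransitionSpec):
    """State-dependent width ``a(w) = a0 * exp(alpha*(w**2 + T0_eff))``.

    Since ``w**2 + T0_eff`` is the current effective temperature this is
    ``a0 * exp(alpha * Teff)``; strictly increasing in ``w**2``.
    """
    return fit.a0 * np.exp(fit.alpha * (np.square(w) + spec.T0_eff))


def width_rhs(w, spec: TransitionSpec, width) -> float:
    """Right-hand side of the half-width ODE ``dw/dt``.

    ``width`` is either a constant rate ``a`` (1/ms) or a
    :class:`WidthFit`, giving ``a(w)*(sqrt(D) - w)``.  ``w = sqrt(D)``
    is the fixed point (``Teff = Tf_eff``).
    """
    if isinstance(width, WidthFit):
        a = width_function(width, w, spec)
    else:
        a = width
    return a * (np.sqrt(spec.D) - w)


def initial_w(spec: TransitionSpec) -> float:
    """Negative initial half-width ``-sqrt(Ti_eff - T0_eff)``.

    The negative branch is required to reproduce the undershoot; starting
    from ``+sqrt(Ti_eff - T0_eff)`` would relax monotonically without
    ever reaching ``T0_eff``.
    """
    return -math.sqrt(spec.Ti_eff - spec.T0_eff)
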