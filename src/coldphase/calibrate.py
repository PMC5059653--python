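"""Calibration routines fixing the model's constants.

Three procedures:

1. ``calibrate_tanh_endpoints`` — derive the saturating parameter
   constants from the linear forms by matching both at the ends of a
   temperature interval (with the additional saturation condition
   ``Omega -> 0`` at ``Teff -> -inf``, i.e. ``Omega0 == Omega1``).
2. ``find_matching_a`` — bisection on the Morse width ``a`` so that the
   first burst window of a transient run is centred on the effective
   temperature minimum (the matching condition).
3. ``fit_width_function`` — least-squares fit of ``ln a`` against the
   final effective temperature across transitions, giving the
   exponential width function constants ``(a0, alpha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from coldphase.model import LinearParameterSet, TanhParameterSet, linear_params, tanh_params
from coldphase.temperature import (
    TransitionSpec,
    WidthFit,
    morse_teff,
    time_of_minimum,
)

__all__ = [
    "MatchResult",
    "CalibrationReport",
    "calibrate_tanh_endpoints",
    "find_matching_a",
    "fit_width_function",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the matching-condition search for the width ``a``."""

    a: float
    residual: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class CalibrationReport:
    """Fitted saturating parameter set plus endpoint residuals (1/ms)."""

    pset: TanhParameterSet
    residuals: dict


def calibrate_tanh_endpoints(
    linear: LinearParameterSet,
    T_low: float,
    T_high: float,
    C: float,
    Tbar: float,
) -> CalibrationReport:
    """Fit the tanh constants to the linear forms at two temperatures.

    For ``b`` and ``A`` the 2x2 linear system equating the tanh and
    linear forms at ``T_low`` and ``T_high`` is solved exactly.  For
    ``Omega`` the saturation condition imposes ``Omega0 == Omega1``, so
    only the ``T_high`` value is matched and the ``T_low`` mismatch is
    reported as a residual.
    """
    if not T_low < T_high:
        raise ValueError(f"need T_low < T_high, got {T_low} >= {T_high}")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    s_lo = math.tanh(C * (T_low - Tbar))
    s_hi = math.tanh(C * (T_high - Tbar))
    if math.isclose(s_lo, s_hi, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError(
            "singular endpoint system: tanh saturates identically at both "
            f"temperatures (C={C}, Tbar={Tbar})"
        )
    pv_lo = linear_params(linear, T_low)
    pv_hi = linear_params(linear, T_high)
    # b = b0 - b1*s  at both endpoints
    b1 = (pv_hi.b - pv_lo.b) / (s_lo - s_hi)
    b0 = pv_hi.b + b1 * s_hi
    # A = A0 + A1*s
    A1 = (pv_hi.A - pv_lo.A) / (s_hi - s_lo)
    A0 = pv_hi.A - A1 * s_hi
    # Omega = Omega0*(1 + s), anchored at the high endpoint
    Om0 = pv_hi.Omega / (1.0 + s_hi)
    pset = TanhParameterSet(
        b0=b0, b1=b1, A0=A0, A1=A1, Omega0=Om0, Omega1=Om0, C=C, Tbar=Tbar
    )
    fit_lo = tanh_params(pset, T_low)
    fit_hi = tanh_params(pset, T_high)
    residuals = {
        "b_low": fit_lo.b - pv_lo.b,
        "b_high": fit_hi.b - pv_hi.b,
        "A_low": fit_lo.A - pv_lo.A,
        "A_high": fit_hi.A - pv_hi.A,
        "Omega_low": fit_lo.Omega - pv_lo.Omega,
        "Omega_high": fit_hi.Omega - pv_hi.Omega,
    }
    return CalibrationReport(pset=pset, residuals=residuals)


def _first_window_close(
    pset: TanhParameterSet, spec: TransitionSpec, a: float, dt: float
) -> float:
    """Closing time of the first ``f1 > f2`` window of a constant-``a`` run.

    Uses the closed-form effective temperature and the pointwise
    modulation argument ``Omega(Teff(t)) * t``; the phase variable
    ``theta`` plays no role in the window geometry.  The matching
    condition aligns this closing time with the temperature minimum:
    near the minimum the argument stalls (``Omega`` drops as fast as
    ``t`` grows), so the first overlap stretches until the temperature
    turns back up, which makes the alignment mismatch monotone in ``a``
    with a unique root.
    """
    tbar = time_of_minimum(spec, a)
    pv0 = tanh_params(pset, spec.T0_eff)
    slow_period = 2.0 * math.pi / pv0.Omega if pv0.Omega > 0 else 5.0 / a
    span = tbar + 2.5 * slow_period
    t = np.arange(0.0, span, dt)
    Teff = morse_teff(spec, a, t)
    pv = tanh_params(pset, Teff)
    g = pv.b - 1.0 - 2.0 * pv.A * np.cos(pv.Omega * t)
    pos = g > 0
    if pos[0]:
        i = -1  # window already open at t = 0
    else:
        openings = np.nonzero(~pos[:-1] & pos[1:])[0]
        if openings.size == 0:
            return math.inf
        i = int(openings[0])
    closings = np.nonzero(pos[:-1] & ~pos[1:])[0]
    closings = closings[closings > i]
    if closings.size == 0:
        return math.inf
    j = int(closings[0])
    return t[j] + dt * (-g[j] / (g[j + 1] - g[j]))


def find_matching_a(
    pset: TanhParameterSet,
    spec: TransitionSpec,
    bounds=(1e-5, 1e-1),
    tol: float = 1.0,
    *,
    max_iter: int = 60,
    grid_dt: float = 0.05,
) -> MatchResult:
    """Bisection on the constant Morse width ``a`` for the matching condition.

    The mismatch is the closing time of the first ``f1 > f2`` overlap
    window minus ``tbar`` (the time of the effective-temperature
    minimum); convergence requires ``|mismatch| <= tol`` ms.  The search
    runs with constant ``a``, the configuration in which the width
    function is subsequently fitted, and evaluates the window geometry
    with the pointwise modulation argument ``Omega(Teff)*t`` (see
    :func:`_first_window_close`).

    Returns an unconverged :class:`MatchResult` if the bounds do not
    bracket a sign change.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (0 < lo < hi):
        raise ValueError(f"invalid bounds {bounds}")

    def mismatch(a: float) -> float:
        return _first_window_close(pset, spec, a, grid_dt) - time_of_minimum(spec, a)

    m_lo = mismatch(lo)
    m_hi = mismatch(hi)
    iterations = 2
    if math.copysign(1.0, m_lo) == math.copysign(1.0, m_hi):
        a, res = (lo, m_lo) if abs(m_lo) < abs(m_hi) else (hi, m_hi)
        return MatchResult(a=a, residual=res, iterations=iterations, converged=False)
    a, res = lo, m_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m_mid = mismatch(mid)
        iterations += 1
        a, res = mid, m_mid
        if abs(m_mid) <= tol:
            return MatchResult(a=a, residual=res, iterations=iterations, converged=True)
        if math.copysign(1.0, m_mid) == math.copysign(1.0, m_lo):
            lo, m_lo = mid, m_mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return MatchResult(
        a=a, residual=res, iterations=iterations, converged=abs(res) <= tol
    )


def fit_width_function(samples) -> WidthFit:
    """Least-squares fit of ``ln a`` against final effective temperature.

    ``samples`` is a sequence of ``(TransitionSpec, a)`` pairs.  The
    abscissa is ``w**2 + T0_eff`` at the final state, i.e. ``Tf_eff``;
    the fit yields intercept ``ln a0`` and slope ``alpha``.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit the width function")
    x = np.asarray([spec.Tf_eff for spec, _ in samples], dtype=float)
    y = np.log(np.asarray([a for _, a in samples], dtype=float))
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct final temperatures")
    alpha, ln_a0 = np.polyfit(x, y, 1)
    return WidthFit(a0=float(np.exp(ln_a0)), alpha=float(alpha))
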