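"""Fixed-step RK4 integration of the phase equation, steady and transient.

The steady case integrates ``dtheta/dt = F(t, theta)`` at one fixed
effective temperature with modulation phase ``phi = Omega*t``.  The
transient case integrates the coupled system ``(theta, w, phi)`` where
``w`` drives the Morse-like effective temperature and the model
parameters ``(b, A, Omega)`` are re-evaluated at ``Teff(t) = T0_eff + w**2``
every stage.

The modulation argument in transient runs is configurable.  The default
``literal`` mode uses ``Omega(Teff(t)) * t`` directly: while the
temperature falls, the argument stalls (``Omega`` shrinks as fast as
``t`` grows), which merges the overlap windows into one long first
burst around the temperature minimum — the transient peak response.
The alternative ``integrated`` mode evolves ``dphi/dt = Omega(Teff(t))``
(continuous instantaneous frequency) and produces regular bursting
throughout the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from coldphase.model import (
    LinearParameterSet,
    TanhParameterSet,
    evaluate_params,
)
from coldphase.temperature import TransitionSpec, WidthFit, initial_w

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate_steady",
    "simulate_transition",
    "steady_config",
    "transition_config",
]

TSV_COLUMNS = ("t_ms", "theta_rad", "F_per_ms", "phi_rad", "w_sqrtC", "Teff_C")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings (time in ms, phases in radians)."""

    dt: float = 0.01
    t_end: float = 1000.0
    theta0: float = 0.0
    phase_mode: str = "literal"
    record_stride: int = 1

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (self.t_end > self.dt):
            raise ValueError(f"t_end must exceed dt, got {self.t_end}")
        if not math.isfinite(self.theta0):
            raise ValueError(f"theta0 must be finite, got {self.theta0}")
        if self.phase_mode not in ("integrated", "literal"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded time series on a uniform grid.

    ``theta`` is stored unwrapped; ``w`` is ``None`` for steady runs.
    """

    t: np.ndarray
    theta: np.ndarray
    F: np.ndarray
    phi: np.ndarray
    Teff: np.ndarray
    w: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def write_tsv(self, path) -> None:
        """Write the trajectory as a TSV with deterministic formatting."""
        w = self.w if self.w is not None else np.full_like(self.t, np.nan)
        with open(Path(path), "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for row in zip(self.t, self.theta, self.F, self.phi, w, self.Teff):
                fh.write(
                    "%.4f\t%.6f\t%.6f\t%.6f\t%.6f\t%.6f\n"
                    % (row[0], row[1], row[2], row[3], row[4], row[5])
                )


def _n_steps(cfg: SimulationConfig) -> int:
    return int(round(cfg.t_end / cfg.dt))


def _check_finite(t: float, state) -> None:
    if not all(math.isfinite(v) for v in state):
        raise FloatingPointError(
            f"non-finite state {state} at t={t:.4f} ms; "
            "reduce dt or check parameter values"
        )


def simulate_steady(pset, Teff: float, cfg: SimulationConfig) -> Trajectory:
    """Integrate the phase equation at a fixed effective temperature.

    Classical fixed-step 4th-order Runge-Kutta on ``theta`` with
    ``phi = Omega*t``.  Returns a :class:`Trajectory` with ``F`` recorded
    along the solution and constant ``Teff``.
    """
    if not isinstance(pset, (TanhParameterSet, LinearParameterSet)):
        raise TypeError(f"unsupported parameter set type: {type(pset).__name__}")
    pv = evaluate_params(pset, Teff)
    b, A, Om = pv.b, pv.A, pv.Omega
    dt = cfg.dt
    n = _n_steps(cfg)
    stride = cfg.record_stride
    cos = math.cos

    def rhs(t: float, theta: float) -> float:
        c = cos(Om * t)
        return b - A * c + (1.0 + A * c) * cos(theta)

    n_rec = n // stride + 1
    t_out = np.empty(n_rec)
    th_out = np.empty(n_rec)
    f_out = np.empty(n_rec)

    theta = cfg.theta0
    t = 0.0
    t_out[0] = t
    th_out[0] = theta
    f_out[0] = rhs(t, theta)
    j = 1
    for i in range(1, n + 1):
        k1 = rhs(t, theta)
        k2 = rhs(t + 0.5 * dt, theta + 0.5 * dt * k1)
        k3 = rhs(t + 0.5 * dt, theta + 0.5 * dt * k2)
        k4 = rhs(t + dt, theta + dt * k3)
        theta += dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        t = i * dt
        if not math.isfinite(theta):
            _check_finite(t, (theta,))
        if i % stride == 0:
            t_out[j] = t
            th_out[j] = theta
            f_out[j] = rhs(t, theta)
            j += 1
    t_out = t_out[:j]
    return Trajectory(
        t=t_out,
        theta=th_out[:j],
        F=f_out[:j],
        phi=Om * t_out,
        Teff=np.full(j, float(Teff)),
    )


def simulate_transition(
    pset: TanhParameterSet,
    spec: TransitionSpec,
    width,
    cfg: SimulationConfig,
) -> Trajectory:
    """Integrate the coupled ``(theta, w, phi)`` system for one transition.

    Parameters
    ----------
    pset : TanhParameterSet
        Saturating parameter forms, re-evaluated at the instantaneous
        effective temperature each RK4 stage.
    spec : TransitionSpec
        The high-to-low transition; the half-width starts at the negative
        branch ``w(0) = -sqrt(Ti_eff - T0_eff)``.
    width : float or WidthFit
        Constant width ``a`` (1/ms) or the state-dependent ``a(w)``.
    cfg : SimulationConfig
    """
    if not isinstance(pset, TanhParameterSet):
        raise TypeError("transient runs require a TanhParameterSet")
    b0, b1 = pset.b0, pset.b1
    A0, A1 = pset.A0, pset.A1
    Om0, Om1 = pset.Omega0, pset.Omega1
    C, Tbar = pset.C, pset.Tbar
    T0 = spec.T0_eff
    sqrtD = math.sqrt(spec.D)
    literal = cfg.phase_mode == "literal"
    if isinstance(width, WidthFit):
        a0, alpha = width.a0, width.alpha

        def a_of(Teff: float) -> float:
            return a0 * math.exp(alpha * Teff)

    else:
        a_const = float(width)
        if a_const <= 0:
            raise ValueError(f"width a must be positive, got {width}")

        def a_of(Teff: float) -> float:
            return a_const

    cos, tanh = math.cos, math.tanh

    def rhs(t: float, theta: float, w: float, phi: float):
        Teff = T0 + w * w
        s = tanh(C * (Teff - Tbar))
        b = b0 - b1 * s
        A = A0 + A1 * s
        Om = Om0 + Om1 * s
        arg = Om * t if literal else phi
        c = cos(arg)
        dtheta = b - A * c + (1.0 + A * c) * cos(theta)
        dw = a_of(Teff) * (sqrtD - w)
        return dtheta, dw, Om, arg

    dt = cfg.dt
    n = _n_steps(cfg)
    stride = cfg.record_stride
    n_rec = n // stride + 1
    t_out = np.empty(n_rec)
    th_out = np.empty(n_rec)
    f_out = np.empty(n_rec)
    phi_out = np.empty(n_rec)
    w_out = np.empty(n_rec)

    theta = cfg.theta0
    w = initial_w(spec)
    phi = 0.0
    t = 0.0
    d1, _, _, arg = rhs(t, theta, w, phi)
    t_out[0], th_out[0], f_out[0], phi_out[0], w_out[0] = t, theta, d1, arg, w
    j = 1
    for i in range(1, n + 1):
        k1t, k1w, k1p, _ = rhs(t, theta, w, phi)
        h = 0.5 * dt
        k2t, k2w, k2p, _ = rhs(t + h, theta + h * k1t, w + h * k1w, phi + h * k1p)
        k3t, k3w, k3p, _ = rhs(t + h, theta + h * k2t, w + h * k2w, phi + h * k2p)
        k4t, k4w, k4p, _ = rhs(
            t + dt, theta + dt * k3t, w + dt * k3w, phi + dt * k3p
        )
        theta += dt * (k1t + 2.0 * (k2t + k3t) + k4t) / 6.0
        w += dt * (k1w + 2.0 * (k2w + k3w) + k4w) / 6.0
        phi += dt * (k1p + 2.0 * (k2p + k3p) + k4p) / 6.0
        t = i * dt
        if not (math.isfinite(theta) and math.isfinite(w) and math.isfinite(phi)):
            _check_finite(t, (theta, w, phi))
        if i % stride == 0:
            d1, _, _, arg = rhs(t, theta, w, phi)
            t_out[j], th_out[j], f_out[j], phi_out[j], w_out[j] = (
                t,
                theta,
                d1,
                arg,
                w,
            )
            j += 1
    w_arr = w_out[:j]
    return Trajectory(
        t=t_out[:j],
        theta=th_out[:j],
        F=f_out[:j],
        phi=phi_out[:j],
        Teff=T0 + w_arr**2,
        w=w_arr,
    )


def steady_config(
    pset, Teff: float, *, dt: float = 0.01, periods: float = 6.0, record_stride: int = 1
) -> SimulationConfig:
    """Default steady config: ``periods`` modulation cycles at ``Teff``."""
    Om = evaluate_params(pset, Teff).Omega
    if Om <= 0:
        raise ValueError(f"modulation frequency must be positive, got {Om}")
    return SimulationConfig(
        dt=dt, t_end=periods * 2.0 * math.pi / Om, record_stride=record_stride
    )


def transition_config(
    pset: TanhParameterSet,
    spec: TransitionSpec,
    a_ref: float,
    *,
    dt: float = 0.01,
    record_stride: int = 1,
) -> SimulationConfig:
    """Default transient config: ``max(5/a_ref, 8 cycles at Tf_eff)``."""
    Om_f = evaluate_params(pset, spec.Tf_eff).Omega
    t_end = max(5.0 / a_ref, 8.0 * 2.0 * math.pi / Om_f)
    return SimulationConfig(dt=dt, t_end=t_end, record_stride=record_stride)
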