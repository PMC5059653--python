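"""Bundled simulation scenarios: steady sweeps and transition series.

These are the standard runs used by the command-line interface and the
acceptance checks: a steady-temperature sweep over 15-40 degC, the
transition family from 40 degC down to each lower temperature, and the
staircase of 5-degree steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from coldphase.analysis import (
    BurstSummary,
    SpikeTrain,
    detect_spikes,
    isi_histogram,
    overlap_windows,
    segment_bursts,
)
from coldphase.model import DEFAULT_TANH, evaluate_params
from coldphase.simulate import (
    Trajectory,
    simulate_steady,
    simulate_transition,
    steady_config,
    transition_config,
)
from coldphase.temperature import (
    DEFAULT_WIDTH_FIT,
    WidthFit,
    make_transition,
    width_function,
)

__all__ = [
    "SteadyRun",
    "TransitionRun",
    "run_steady",
    "run_transition",
    "STEADY_TEMPS",
    "TRANSITIONS_FROM_40",
    "STEP_SERIES",
    "PRESETS",
]

logger = logging.getLogger(__name__)

STEADY_TEMPS = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
TRANSITIONS_FROM_40 = ((40.0, 35.0), (40.0, 30.0), (40.0, 25.0), (40.0, 20.0), (40.0, 15.0))
STEP_SERIES = ((35.0, 30.0), (30.0, 25.0), (25.0, 20.0), (20.0, 15.0))

PRESETS = {
    "steady_sweep": STEADY_TEMPS,
    "transitions_from_40": TRANSITIONS_FROM_40,
    "step_series": STEP_SERIES,
}


@dataclass
class SteadyRun:
    """One steady-temperature simulation plus its burst analytics."""

    Teff: float
    trajectory: Trajectory
    spikes: SpikeTrain
    bursts: BurstSummary

    @property
    def mean_sb(self) -> float:
        return float(self.bursts.sb.mean()) if len(self.bursts) else 0.0

    @property
    def mean_bp(self) -> float:
        return float(self.bursts.bp.mean()) if len(self.bursts) > 1 else float("nan")


@dataclass
class TransitionRun:
    """One high-to-low transition simulation plus its burst analytics."""

    Ti_eff: float
    Tf_eff: float
    trajectory: Trajectory
    spikes: SpikeTrain
    bursts: BurstSummary


def run_steady(
    pset=DEFAULT_TANH,
    Teff: float = 35.0,
    *,
    dt: float = 0.01,
    periods: float = 6.0,
    discard_periods: float = 1.0,
) -> SteadyRun:
    """Simulate ``periods`` modulation cycles at a fixed temperature.

    The first ``discard_periods`` cycles are treated as transient: bursts
    whose last spike falls inside them are dropped from the summary.
    """
    cfg = steady_config(pset, Teff, dt=dt, periods=periods)
    traj = simulate_steady(pset, Teff, cfg)
    spikes = detect_spikes(traj)
    windows = overlap_windows(pset, Teff, span=cfg.t_end)
    bursts = segment_bursts(spikes, windows)
    if discard_periods > 0 and len(bursts):
        t_cut = discard_periods * 2.0 * np.pi / evaluate_params(pset, Teff).Omega
        keep = bursts.last_spike >= t_cut
        bursts = BurstSummary(
            onset=bursts.onset[keep],
            offset=bursts.offset[keep],
            spike_count=bursts.spike_count[keep],
            last_spike=bursts.last_spike[keep],
        )
    return SteadyRun(Teff=Teff, trajectory=traj, spikes=spikes, bursts=bursts)


def run_transition(
    pset=DEFAULT_TANH,
    Ti_eff: float = 40.0,
    Tf_eff: float = 15.0,
    *,
    width=DEFAULT_WIDTH_FIT,
    dt: float = 0.01,
) -> TransitionRun:
    """Simulate one high-to-low transition and analyse its bursts.

    ``width`` is either a constant ``a`` (1/ms) or a :class:`WidthFit`.
    The run length is ``max(5/a_ref, 8 cycles at Tf_eff)`` with ``a_ref``
    the width evaluated at the final temperature.
    """
    spec = make_transition(Ti_eff, Tf_eff)
    if isinstance(width, WidthFit):
        a_ref = float(width_function(width, np.sqrt(spec.D), spec))
    else:
        a_ref = float(width)
    cfg = transition_config(pset, spec, a_ref, dt=dt)
    traj = simulate_transition(pset, spec, width, cfg)
    spikes = detect_spikes(traj)
    windows = overlap_windows(pset, traj)
    bursts = segment_bursts(spikes, windows)
    logger.info(
        "transition %.4g -> %.4g degC: %d spikes in %d bursts",
        Ti_eff,
        Tf_eff,
        len(spikes),
        len(bursts),
    )
    return TransitionRun(
        Ti_eff=Ti_eff, Tf_eff=Tf_eff, trajectory=traj, spikes=spikes, bursts=bursts
    )


def steady_isih(run: SteadyRun, bin_width: float = 2.0):
    """ISI histogram for a steady run (whole spike train)."""
    return isi_histogram(run.spikes, bin_width=bin_width)
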