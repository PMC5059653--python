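"""Spike, burst and interspike-interval analytics.

A spike is an upward crossing of the unwrapped phase through a multiple
of 2*pi (one full rotation = one action potential).  Bursts are groups
of spikes inside the windows where ``f1 > f2``; SB is the spike count
per burst and BP the interval between consecutive bursts' last spikes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from coldphase.model import evaluate_params, modulation_terms
from coldphase.simulate import Trajectory

__all__ = [
    "SpikeTrain",
    "BurstSummary",
    "ISIHistogram",
    "OverlapWindows",
    "detect_spikes",
    "overlap_windows",
    "segment_bursts",
    "isi_histogram",
    "isi_cluster_centers",
]

logger = logging.getLogger(__name__)

#: Burst windows are dilated by this margin (ms) on each side before spike
#: assignment: a rotation begun just inside a window completes just after it.
WINDOW_DILATION_MS = 2.0

#: Hysteresis for spike detection: the phase must retreat at least this far
#: below the next 2*pi threshold before a new crossing is counted.
SPIKE_HYSTERESIS_RAD = math.pi

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in ms."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("spike_time_ms\n")
            for s in self.spike_times:
                fh.write("%.6f\n" % s)

    @classmethod
    def read_tsv(cls, path) -> "SpikeTrain":
        times = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "spike_time")):
                    continue
                times.append(float(line.split("\t")[0]))
        return cls(np.asarray(times))


@dataclass
class BurstSummary:
    """Per-burst records and the derived SB / BP series.

    ``sb`` are spike counts per burst; ``bp`` are intervals between
    consecutive bursts' last spikes, placed at ``bp_times`` (the midtime
    of each last-spike pair).
    """

    onset: np.ndarray
    offset: np.ndarray
    spike_count: np.ndarray
    last_spike: np.ndarray

    @property
    def sb(self) -> np.ndarray:
        return self.spike_count

    @property
    def bp(self) -> np.ndarray:
        return np.diff(self.last_spike)

    @property
    def bp_times(self) -> np.ndarray:
        return 0.5 * (self.last_spike[1:] + self.last_spike[:-1])

    def __len__(self) -> int:
        return int(self.onset.size)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("onset_ms\toffset_ms\tspike_count\tlast_spike_ms\n")
            for o, f, c, ls in zip(
                self.onset, self.offset, self.spike_count, self.last_spike
            ):
                fh.write("%.6f\t%.6f\t%d\t%.6f\n" % (o, f, c, ls))


@dataclass
class ISIHistogram:
    """Uniform-bin interspike-interval histogram plus the raw ISIs."""

    bin_edges: np.ndarray
    counts: np.ndarray
    isis: np.ndarray = field(default_factory=lambda: np.empty(0))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_left_ms\tbin_right_ms\tcount\n")
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                fh.write("%.6f\t%.6f\t%d\n" % (lo, hi, c))


@dataclass
class OverlapWindows:
    """Maximal intervals where ``f1 > f2``; ``delta`` is the largest width."""

    windows: list

    @property
    def widths(self) -> np.ndarray:
        return np.asarray([e - s for s, e in self.windows])

    @property
    def delta(self) -> float:
        return float(self.widths.max()) if self.windows else 0.0

    def __len__(self) -> int:
        return len(self.windows)


def detect_spikes(traj: Trajectory) -> SpikeTrain:
    """Extract spike times from the unwrapped phase of a trajectory.

    One spike per upward crossing of ``theta`` through ``2*pi*k``;
    crossing times are linearly interpolated between samples.  After a
    counted crossing the next threshold moves up by 2*pi and is armed
    only once ``theta`` has retreated at least pi below it, so grazing
    oscillations around a threshold are counted once.
    """
    theta = traj.theta
    t = traj.t
    spikes: list[float] = []
    level = TWO_PI * math.floor(theta[0] / TWO_PI) + TWO_PI
    armed = True  # no prior spike: the first crossing always counts
    for i in range(1, theta.size):
        if not armed and theta[i] <= level - SPIKE_HYSTERESIS_RAD:
            armed = True
        if armed and theta[i - 1] < level <= theta[i]:
            frac = (level - theta[i - 1]) / (theta[i] - theta[i - 1])
            spikes.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            level += TWO_PI
            armed = theta[i] <= level - SPIKE_HYSTERESIS_RAD
    return SpikeTrain(np.asarray(spikes))


def _steady_windows(pset, Teff: float, span: float) -> OverlapWindows:
    # closed-form roots of f1 = f2: cos(phi) = (b - 1) / (2A)
    pv = evaluate_params(pset, Teff)
    b, A, Om = pv.b, pv.A, pv.Omega
    if A <= 0 or Om <= 0:
        # without modulation the sign of f1 - f2 = b - 1 - 2A cos(phi) is fixed
        f1, f2 = modulation_terms(pv, 0.0)
        return OverlapWindows([(0.0, span)] if f1 > f2 else [])
    c = (b - 1.0) / (2.0 * A)
    if c >= 1.0:
        return OverlapWindows([(0.0, span)])
    if c <= -1.0:
        return OverlapWindows([])
    phi_lo = math.acos(c)  # f1 > f2 for phi in (phi_lo, 2*pi - phi_lo) mod 2*pi
    period = TWO_PI / Om
    windows = []
    k = 0
    while True:
        start = (phi_lo + k * TWO_PI) / Om
        end = (TWO_PI - phi_lo + k * TWO_PI) / Om
        if start >= span:
            break
        windows.append((start, min(end, span)))
        k += 1
    return OverlapWindows(windows)


def _trajectory_windows(pset, traj: Trajectory) -> OverlapWindows:
    # sign-change scan of g = f1 - f2 = b - 1 - 2A cos(phi) along the run
    pv = evaluate_params(pset, traj.Teff)
    g = pv.b - 1.0 - 2.0 * pv.A * np.cos(traj.phi)
    return OverlapWindows(_sign_change_windows(traj.t, g))


def _sign_change_windows(t: np.ndarray, g: np.ndarray) -> list:
    """Maximal intervals where g > 0, edges by linear interpolation."""
    pos = g > 0
    windows = []
    start = t[0] if pos[0] else None
    idx = np.nonzero(pos[1:] != pos[:-1])[0]
    for i in idx:
        tc = t[i] + (t[i + 1] - t[i]) * (-g[i] / (g[i + 1] - g[i]))
        if pos[i + 1]:  # opening edge
            start = tc
        else:  # closing edge
            windows.append((start, tc))
            start = None
    if start is not None:
        windows.append((start, float(t[-1])))
    return windows


def overlap_windows(pset, at, span: float | None = None) -> OverlapWindows:
    """Windows where the burst condition ``f1 > f2`` holds.

    Parameters
    ----------
    pset : parameter set
    at : float or Trajectory
        A steady effective temperature (uses the closed-form roots
        ``cos(phi) = (b-1)/(2A)``; requires ``span``) or a recorded
        trajectory (numerical sign-change scan along the run).
    span : float, optional
        Time span in ms for the steady case.
    """
    if isinstance(at, Trajectory):
        return _trajectory_windows(pset, at)
    if span is None:
        raise ValueError("span is required for steady-temperature windows")
    return _steady_windows(pset, float(at), float(span))


def segment_bursts(
    spikes: SpikeTrain,
    windows,
    *,
    dilation: float = WINDOW_DILATION_MS,
) -> BurstSummary:
    """Assign spikes to overlap windows and summarise per-burst statistics.

    Windows are dilated by ``dilation`` ms on each side before
    assignment; windows that receive no spikes are dropped.  Spikes
    falling outside every dilated window are assigned to the nearest
    window with a warning.
    """
    if isinstance(windows, OverlapWindows):
        windows = windows.windows
    windows = sorted(windows)
    counts = [[] for _ in windows]
    if windows:
        starts = np.asarray([wdw[0] for wdw in windows])
        ends = np.asarray([wdw[1] for wdw in windows])
        for s in spikes.spike_times:
            inside = np.nonzero((s >= starts - dilation) & (s <= ends + dilation))[0]
            if inside.size:
                counts[inside[0]].append(s)
            else:
                dist = np.where(s < starts, starts - s, np.maximum(s - ends, 0.0))
                k = int(np.argmin(dist))
                logger.warning(
                    "spike at %.3f ms outside all dilated windows; "
                    "assigned to nearest window %d",
                    s,
                    k,
                )
                counts[k].append(s)
    onset, offset, n_sp, last = [], [], [], []
    for (ws, we), sp in zip(windows, counts):
        if not sp:
            continue
        onset.append(ws)
        offset.append(we)
        n_sp.append(len(sp))
        last.append(max(sp))
    return BurstSummary(
        onset=np.asarray(onset),
        offset=np.asarray(offset),
        spike_count=np.asarray(n_sp, dtype=int),
        last_spike=np.asarray(last),
    )


def isi_histogram(spikes: SpikeTrain, bin_width: float = 2.0) -> ISIHistogram:
    """Histogram of interspike intervals with uniform ``bin_width`` (ms)."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    isis = spikes.isis()
    if isis.size == 0:
        return ISIHistogram(
            bin_edges=np.asarray([0.0, bin_width]),
            counts=np.zeros(1, dtype=int),
            isis=isis,
        )
    n_bins = max(1, int(math.ceil(isis.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(isis, bins=edges)
    return ISIHistogram(bin_edges=edges, counts=counts.astype(int), isis=isis)


def isi_cluster_centers(isis, gap: float = 1.0) -> np.ndarray:
    """Single-linkage ISI cluster centers (clusters split at gaps > ``gap`` ms).

    Summarises a multivalued ISI-versus-temperature relation: each
    returned value is the mean of one cluster of similar intervals.
    """
    isis = np.sort(np.asarray(isis, dtype=float))
    if isis.size == 0:
        return np.empty(0)
    breaks = np.nonzero(np.diff(isis) > gap)[0] + 1
    return np.asarray([seg.mean() for seg in np.split(isis, breaks)])
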