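import logging
import math

import numpy as np
import pytest

from coldphase import DEFAULT_TANH, SimulationConfig, simulate_steady
from coldphase.analysis import (
    SpikeTrain,
    detect_spikes,
    isi_cluster_centers,
    isi_histogram,
    overlap_windows,
    segment_bursts,
)
from coldphase.model import TanhParameterSet, tanh_params
from coldphase.simulate import Trajectory


def _traj_from_theta(t, theta):
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return Trajectory(
        t=t,
        theta=theta,
        F=np.zeros_like(t),
        phi=np.zeros_like(t),
        Teff=np.full_like(t, 35.0),
    )


class TestDetectSpikes:
    def test_linear_ramp(self):
        t = np.linspace(0.0, 3.0, 3001)
        traj = _traj_from_theta(t, 2 * math.pi * t)  # 0 -> 6*pi over 3 ms
        spikes = detect_spikes(traj)
        assert np.allclose(spikes.spike_times, [1.0, 2.0, 3.0], atol=1e-9)

    def test_constant_phase_no_spikes(self):
        t = np.linspace(0.0, 10.0, 101)
        assert len(detect_spikes(_traj_from_theta(t, np.full_like(t, 1.0)))) == 0

    def test_grazing_recross_counted_once(self):
        # crosses 2*pi, dips just below and recrosses within 0.1 ms: the
        # threshold has moved on to 4*pi, so only one spike is counted
        t = np.array([0.0, 0.5, 0.55, 0.6, 1.0])
        theta = 2 * math.pi * np.array([0.0, 1.05, 0.95, 1.1, 1.2])
        spikes = detect_spikes(_traj_from_theta(t, theta))
        assert len(spikes) == 1

    def test_interpolated_crossing_time(self):
        t = np.array([0.0, 1.0])
        theta = np.array([math.pi, 3 * math.pi])  # crosses 2*pi at t = 0.5
        spikes = detect_spikes(_traj_from_theta(t, theta))
        assert spikes.spike_times[0] == pytest.approx(0.5, abs=1e-12)

    def test_nonzero_start_level(self):
        t = np.linspace(0.0, 1.0, 101)
        theta = 5.0 + 4 * math.pi * t  # first threshold is 2*pi (> 5)
        spikes = detect_spikes(_traj_from_theta(t, theta))
        assert len(spikes) == 2


class TestOverlapWindows:
    def test_steady_35C_window_width(self):
        # closed-form roots with b, A, Omega at 35 degC; frozen width
        span = 2 * math.pi / 0.050358562538719585
        wins = overlap_windows(DEFAULT_TANH, 35.0, span=span)
        assert len(wins) == 1
        assert wins.delta == pytest.approx(22.5442, abs=1e-3)

    def test_one_window_per_cycle(self):
        Om = 0.050358562538719585
        wins = overlap_windows(DEFAULT_TANH, 35.0, span=6 * 2 * math.pi / Om)
        assert len(wins) == 6

    def test_always_overlap_limit(self):
        pset = TanhParameterSet(3.0, 0.1, 0.3, 0.02, 0.05, 0.05, 0.055, 33.75)
        wins = overlap_windows(pset, 35.0, span=100.0)  # b - 1 > 2A
        assert wins.windows == [(0.0, 100.0)]

    def test_never_overlap_limit(self):
        pset = TanhParameterSet(0.2, 0.1, 0.3, 0.02, 0.05, 0.05, 0.055, 33.75)
        wins = overlap_windows(pset, 35.0, span=100.0)  # b - 1 < -2A
        assert len(wins) == 0

    def test_closed_form_agrees_with_trajectory_scan(self):
        cfg = SimulationConfig(dt=0.01, t_end=400.0)
        traj = simulate_steady(DEFAULT_TANH, 35.0, cfg)
        scanned = overlap_windows(DEFAULT_TANH, traj)
        closed = overlap_windows(DEFAULT_TANH, 35.0, span=400.0)
        assert len(scanned) == len(closed)
        assert abs(scanned.delta - closed.delta) < cfg.dt
        for (s1, e1), (s2, e2) in zip(scanned.windows, closed.windows):
            assert abs(s1 - s2) < cfg.dt and abs(e1 - e2) < cfg.dt

    def test_span_required_for_steady(self):
        with pytest.raises(ValueError, match="span"):
            overlap_windows(DEFAULT_TANH, 35.0)


class TestSegmentBursts:
    def test_constructed_example(self):
        spikes = SpikeTrain(np.array([10.0, 12.0, 14.0, 130.0, 132.0]))
        summary = segment_bursts(spikes, [(5.0, 20.0), (125.0, 140.0)])
        assert list(summary.sb) == [3, 2]
        assert summary.bp == pytest.approx([118.0])
        assert summary.bp_times == pytest.approx([73.0])  # midtime of last spikes
        assert summary.last_spike == pytest.approx([14.0, 132.0])

    def test_empty_spike_train(self):
        summary = segment_bursts(SpikeTrain(np.array([])), [(0.0, 10.0)])
        assert len(summary) == 0
        assert summary.bp.size == 0

    def test_empty_windows_dropped(self):
        spikes = SpikeTrain(np.array([10.0]))
        summary = segment_bursts(spikes, [(5.0, 20.0), (125.0, 140.0)])
        assert len(summary) == 1

    def test_stray_spike_assigned_to_nearest_with_warning(self, caplog):
        spikes = SpikeTrain(np.array([10.0, 60.0]))
        with caplog.at_level(logging.WARNING, logger="coldphase.analysis"):
            summary = segment_bursts(spikes, [(5.0, 20.0), (125.0, 140.0)])
        assert "outside all dilated windows" in caplog.text
        assert list(summary.sb) == [2]  # 60 ms is nearest the first window

    def test_dilation_captures_trailing_spike(self):
        spikes = SpikeTrain(np.array([21.5]))  # 1.5 ms past the window edge
        summary = segment_bursts(spikes, [(5.0, 20.0)])
        assert list(summary.sb) == [1]

    def test_steady_35C_burst_period_matches_modulation(self, steady_runs):
        run = steady_runs[35.0]
        assert run.mean_bp == pytest.approx(2 * math.pi / 0.050358562538719585, abs=0.5)

    def test_all_spikes_inside_dilated_windows(self, steady_runs):
        for T in (15.0, 25.0, 40.0):
            run = steady_runs[T]
            span = run.trajectory.t[-1]
            wins = overlap_windows(DEFAULT_TANH, T, span=span)
            for s in run.spikes.spike_times:
                assert any(lo - 2.0 <= s <= hi + 2.0 for lo, hi in wins.windows)


class TestISIH:
    def test_constructed_isis(self):
        h = isi_histogram(SpikeTrain(np.array([0.0, 2.0, 4.0, 10.0])), bin_width=2.0)
        assert np.allclose(h.isis, [2.0, 2.0, 6.0])
        assert h.counts.sum() == 3

    def test_single_spike_empty(self):
        h = isi_histogram(SpikeTrain(np.array([5.0])))
        assert h.isis.size == 0
        assert h.counts.sum() == 0

    def test_counts_conserved_and_bins_uniform(self, steady_runs):
        for run in steady_runs.values():
            h = isi_histogram(run.spikes, bin_width=2.0)
            assert h.counts.sum() == len(run.spikes) - 1
            assert np.allclose(np.diff(h.bin_edges), 2.0)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            isi_histogram(SpikeTrain(np.array([0.0, 1.0])), bin_width=0.0)

    def test_skipping_signature_at_high_temperature(self, steady_runs):
        # large intervals (comparable to the modulation cycle) appear at
        # 40 degC but not at 15 degC
        for T, expected in ((40.0, True), (15.0, False)):
            run = steady_runs[T]
            period = 2 * math.pi / tanh_params(DEFAULT_TANH, T).Omega
            has_large = bool(np.any(run.spikes.isis() >= 0.9 * period))
            assert has_large is expected


class TestClusters:
    def test_two_clusters(self):
        centers = isi_cluster_centers([2.0, 2.1, 8.0, 8.2], gap=1.0)
        assert centers == pytest.approx([2.05, 8.1])

    def test_empty(self):
        assert isi_cluster_centers([]).size == 0

    def test_single_cluster(self):
        centers = isi_cluster_centers([3.0, 3.5, 3.9])
        assert centers == pytest.approx([np.mean([3.0, 3.5, 3.9])])


class TestSpikeTrainIO:
    def test_tsv_roundtrip(self, tmp_path):
        st = SpikeTrain(np.array([1.25, 7.5, 100.125]))
        path = tmp_path / "spikes.tsv"
        st.write_tsv(path)
        back = SpikeTrain.read_tsv(path)
        assert np.allclose(back.spike_times, st.spike_times, atol=1e-6)

    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeTrain(np.array([1.0, 1.0, 2.0]))
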