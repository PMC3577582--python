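"""Protocol-layer tests: threshold search, APD/DI extraction,
restitution scans, tip tracking on constructed fields."""

import numpy as np
import pytest

from fourcurrent.ionic import simulate_cell
from fourcurrent.protocols import (SpiralStats, activation_times,
                                   cv_restitution,
                                   dynamic_apd_restitution,
                                   find_stimulus_threshold, measure_apd,
                                   measure_di, spiral_statistics,
                                   track_spiral_tip)
from fourcurrent.stimulus import StimulusProtocol
from fourcurrent.trace import Trace



class TestThreshold:
    def test_bracketing_for_all_sets(self, all_sets, thresholds):
        """1.5x the found threshold always excites; 0.5x never does."""
        for name, p in all_sets.items():
            thr = thresholds[name]
            for factor, expect in ((1.5, True), (0.5, False)):
                tr = simulate_cell(p, StimulusProtocol.single(factor * thr),
                                   duration=30.0, sample_ms=0.1)
                assert bool(tr.V.max() > 0.8) == expect, (name, factor)

    def test_zero_amplitude_never_excites(self, epi):
        tr = simulate_cell(epi, StimulusProtocol.single(0.0), duration=30.0)
        assert tr.V.max() == 0.0

    def test_excitation_monotone_in_amplitude(self, epi, thresholds):
        """No excite -> fail -> excite pattern as amplitude grows."""
        thr = thresholds["epi"]
        amps = np.linspace(0.2 * thr, 3.0 * thr, 50)
        excited = []
        for amp in amps:
            tr = simulate_cell(epi, StimulusProtocol.single(amp),
                               duration=25.0, sample_ms=0.2)
            excited.append(tr.V.max() > 0.8)
        excited = np.asarray(excited)
        first = np.argmax(excited)
        assert excited[first:].all() and not excited[:first].any()

    def test_unexcitable_raises(self, epi):
        dead = epi.replace(g_fi=0.0)
        with pytest.raises(ValueError, match="no excitation"):
            find_stimulus_threshold(dead, amp_hi=0.5)


class TestApdExtraction:
    def test_trapezoid_apd_exact(self):
        t = np.arange(0.0, 500.0, 0.5)
        V = np.interp(t, [0, 99, 101, 299, 301, 500], [0, 0, 1, 1, 0, 0])
        beats = measure_apd(Trace(t, V), threshold_V=0.5)
        assert len(beats) == 1
        assert beats[0].apd == pytest.approx(200.0, abs=1e-9)
        assert beats[0].t_up == pytest.approx(100.0, abs=1e-9)

    def test_subthreshold_trace_empty(self):
        t = np.arange(0.0, 100.0)
        assert measure_apd(Trace(t, np.full_like(t, 0.05))) == []

    def test_always_above_threshold_raises(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError, match="never crosses"):
            measure_apd(Trace(t, np.full_like(t, 0.9)))

    def test_bcl_identity_on_paced_train(self, epi, thresholds):
        """APD + following DI = BCL per beat (exactly one activation
        per pacing interval)."""
        bcl = 500.0
        tr = simulate_cell(epi, StimulusProtocol.pacing(
            1.5 * thresholds["epi"], bcl=bcl, n_beats=6),
            duration=3000.0, sample_ms=0.5)
        beats = measure_apd(tr)
        assert len(beats) == 6
        for k in range(len(beats) - 1):
            di_after = beats[k + 1].di_before
            assert beats[k].apd + di_after == pytest.approx(bcl, abs=1.0)

    def test_di_sequence_matches_beats(self, epi, thresholds):
        tr = simulate_cell(epi, StimulusProtocol.pacing(
            1.5 * thresholds["epi"], bcl=600.0, n_beats=4),
            duration=2400.0, sample_ms=0.5)
        dis = measure_di(tr)
        assert dis.size == len(measure_apd(tr)) - 1
        assert np.all(dis > 0)


class TestApdRestitution:
    def test_epi_curve_direction(self, epi, thresholds):
        curve = dynamic_apd_restitution(
            epi, [1000.0, 500.0, 300.0],
            amplitude=1.5 * thresholds["epi"])
        assert curve.dropped == []
        # APD non-decreasing in DI, hence larger at slower pacing
        assert np.all(np.diff(curve.value) >= 0)
        by_bcl = dict(zip(curve.bcl, curve.value))
        assert by_bcl[1000.0] > by_bcl[500.0]

    def test_refractory_bcl_reported_as_dropped(self, epi, thresholds):
        curve = dynamic_apd_restitution(
            epi, [600.0, 120.0], amplitude=1.5 * thresholds["epi"])
        assert 120.0 in curve.dropped
        assert 600.0 in curve.bcl


class TestCvRestitution:
    def test_curve_values_and_identity(self, lrd, thresholds):
        curve = cv_restitution(lrd, [1000.0, 500.0, 350.0],
                               n_beats=3,
                               amplitude=1.5 * thresholds["lrd"])
        assert curve.dropped == []
        # cm/s range sanity and monotone non-decreasing CV(DI)
        assert np.all((curve.value > 10) & (curve.value < 120))
        assert np.all(np.diff(curve.value) >= -0.5)
        assert np.all(curve.di > 0)

    def test_probe_placement_validated(self, lrd):
        with pytest.raises(ValueError, match="1 cm"):
            cv_restitution(lrd, [500.0], probes_cm=(0.5, 5.0))

    def test_no_propagation_raises(self, lrd):
        with pytest.raises(ValueError, match="distal"):
            cv_restitution(lrd, [500.0], amplitude=1e-4, n_beats=2)


def _rotating_field(grid_n, dx, times, center, R=0.0, omega=0.05, k=4.0):
    """Archimedean-spiral phase field with a singularity orbiting
    ``center`` at radius R; V in [-1, 1]."""
    x = np.arange(grid_n) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    frames = []
    for t in times:
        cx = center[0] + R * np.cos(omega * t)
        cy = center[1] + R * np.sin(omega * t)
        phase = np.arctan2(Y - cy, X - cx) - omega * t \
            + k * np.hypot(X - cx, Y - cy)
        frames.append(np.cos(phase))
    return np.stack(frames)


class TestTipTracking:
    def test_recovers_static_singularity(self):
        dx = 0.02
        n = 101
        times = np.array([0.0, 1.0])
        snaps = _rotating_field(n, dx, times, center=(1.0, 1.0))
        traj = track_spiral_tip(snaps, times, dx, V_iso=0.0)
        assert traj.n_frames == 1
        d = np.hypot(traj.x[0] - 1.0, traj.y[0] - 1.0)
        assert d <= dx * np.sqrt(2)  # within one grid cell

    def test_plane_wave_has_no_interior_tips(self):
        dx = 0.02
        x = np.arange(80) * dx
        X, _ = np.meshgrid(x, x, indexing="ij")
        snaps = np.stack([np.cos(8 * X - 0.3 * t) for t in (0.0, 1.0)])
        traj = track_spiral_tip(snaps, np.array([0.0, 1.0]), dx, V_iso=0.0)
        for pts in traj.all_tips:
            if pts.size:
                # anything found sits on the outermost cells only
                lim = x[-1] - dx
                assert np.all((pts <= dx) | (pts >= lim))

    def test_detection_stable_across_rotation(self):
        """The static singularity is recovered at every rotation phase
        of the surrounding pattern."""
        dx = 0.02
        times = np.arange(0.0, 40.0, 2.0)
        snaps = _rotating_field(101, dx, times, center=(1.0, 1.0))
        traj = track_spiral_tip(snaps, times, dx, V_iso=0.0,
                                seed_xy=(1.0, 1.0))
        assert traj.n_frames >= times.size - 2
        d = np.hypot(traj.x - 1.0, traj.y - 1.0)
        assert np.all(d <= dx * np.sqrt(2))

    def test_auto_viso_is_half_max(self):
        snaps = np.zeros((2, 10, 10))
        snaps[:, 5, 5] = 1.4
        traj = track_spiral_tip(snaps, np.array([0.0, 1.0]), 0.02)
        assert traj.V_iso == pytest.approx(0.7)


class TestSpiralStatistics:
    def _pulse_train(self, period=100.0, apd=30.0, n=12):
        t = np.arange(0.0, period * n, 0.5)
        V = ((t % period) < apd).astype(float)
        return Trace(t, V)

    def test_exact_period_on_synthetic_train(self):
        st = spiral_statistics(self._pulse_train(), threshold=0.5,
                               discard_ms=150.0)
        assert st.period == pytest.approx(100.0, abs=1e-9)
        assert st.apd + st.di == pytest.approx(100.0, abs=1e-9)

    def test_too_few_rotations_raises(self):
        with pytest.raises(ValueError, match="rotations"):
            spiral_statistics(self._pulse_train(n=4), threshold=0.5,
                              discard_ms=0.0)

    def test_identity_enforced(self):
        with pytest.raises(ValueError, match="APD"):
            SpiralStats(period=104.0, apd=90.0, di=10.0, n_rotations=6)


def test_activation_times_interpolation():
    t = np.arange(0.0, 10.0)
    V = np.where(t >= 5, 1.0, 0.0)
    at = activation_times(Trace(t, V), threshold_V=0.5)
    assert at.size == 1 and 4.0 <= at[0] <= 5.0
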