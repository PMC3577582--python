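"""Measurement protocols: excitation threshold, APD/DI extraction,
dynamic APD and CV restitution, spiral initiation, tip tracking and
spiral period statistics.

Conventions (all configurable where they matter):

* APD threshold: V = 0.1 (about -75 mV, i.e. ~90% repolarization).
* Activation time for conduction velocity: upward crossing of V = 0.5
  on the steep upstroke, linearly interpolated between samples.
* Spiral tip: intersection of the isopotential contour V = V_iso with
  the zero contour of dV/dt, the classical wavefront-meets-waveback
  definition; V_iso defaults to half the maximum depolarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ionic import simulate_cell
from .params import ModelParameters
from .stimulus import StimulusEvent, StimulusProtocol
from .tissue import TissueGrid, TissueSimulation
from .trace import Trace

__all__ = [
    "APD_THRESHOLD_DEFAULT", "ACTIVATION_THRESHOLD_DEFAULT",
    "ApBeat", "RestitutionCurve", "TipTrajectory", "SpiralStats",
    "find_stimulus_threshold", "measure_apd", "measure_di",
    "activation_times", "dynamic_apd_restitution", "cv_restitution",
    "initiate_spiral", "track_spiral_tip", "spiral_statistics",
    "measure_spiral_period",
]

#: Default repolarization threshold defining APD (~90% repolarized).
APD_THRESHOLD_DEFAULT = 0.1
#: Default upstroke threshold defining activation times for CV.
ACTIVATION_THRESHOLD_DEFAULT = 0.5


# ---------------------------------------------------------------- #
# threshold search
# ---------------------------------------------------------------- #

def find_stimulus_threshold(params: ModelParameters, dt: float = 0.01,
                            duration: float = 1.0,
                            v_success: float = 0.8,
                            window_ms: float = 20.0,
                            amp_hi: float = 10.0,
                            rtol: float = 1e-3) -> float:
    """Minimum 1-ms stimulus amplitude (ms^-1) that excites a resting cell.

    Bisection on the pulse amplitude; a trial succeeds when V exceeds
    ``v_success`` within ``window_ms`` of pulse onset.  Raises if even
    ``amp_hi`` fails to excite.
    """

    def excites(amp: float) -> bool:
        if amp <= 0.0:
            return False
        tr = simulate_cell(
            params, StimulusProtocol.single(amp, duration=duration),
            dt=dt, duration=window_ms, sample_ms=dt)
        return bool(np.max(tr.V) > v_success)

    lo, hi = 0.0, amp_hi
    if not excites(hi):
        raise ValueError(
            f"no excitation up to amplitude {amp_hi} ms^-1 "
            f"({params.label or 'custom'} set)")
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if excites(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------- #
# APD / DI extraction
# ---------------------------------------------------------------- #

@dataclass(frozen=True)
class ApBeat:
    """One action potential in a trace: activation (upward crossing),
    repolarization (downward crossing), APD and the preceding DI."""

    t_up: float
    t_down: float
    di_before: float  # ms; nan for the first beat

    @property
    def apd(self) -> float:
        return self.t_down - self.t_up


def _crossings(t: np.ndarray, V: np.ndarray, thr: float):
    """Linearly interpolated threshold crossings: (t_up[], t_down[])."""
    above = V >= thr
    change = np.nonzero(above[1:] != above[:-1])[0]
    t_up, t_down = [], []
    for i in change:
        tc = t[i] + (thr - V[i]) / (V[i + 1] - V[i]) * (t[i + 1] - t[i])
        (t_up if above[i + 1] else t_down).append(tc)
    return np.asarray(t_up), np.asarray(t_down)


def measure_apd(trace: Trace,
                threshold_V: float = APD_THRESHOLD_DEFAULT) -> list[ApBeat]:
    """Per-beat APD (time above threshold) and preceding DI.

    Incomplete action potentials at either end of the trace (above
    threshold at the start, or not yet repolarized at the end) are
    discarded.  Raises if the trace never crosses the threshold.
    """
    t_up, t_down = _crossings(trace.t, trace.V, threshold_V)
    if t_up.size == 0 and t_down.size == 0:
        if np.all(trace.V < threshold_V):
            return []
        raise ValueError("trace never crosses the APD threshold")
    beats = []
    prev_down = None
    for tu in t_up:
        later = t_down[t_down > tu]
        if later.size == 0:
            break
        td = later[0]
        di = tu - prev_down if prev_down is not None else math.nan
        beats.append(ApBeat(t_up=float(tu), t_down=float(td),
                            di_before=float(di)))
        prev_down = td
    if not beats:
        raise ValueError("no complete action potential in the trace")
    return beats


def measure_di(trace: Trace,
               threshold_V: float = APD_THRESHOLD_DEFAULT) -> np.ndarray:
    """Diastolic intervals (downward to next upward crossing), ms."""
    return np.asarray([b.di_before for b in measure_apd(trace, threshold_V)
                       if not math.isnan(b.di_before)])


def activation_times(trace: Trace,
                     threshold_V: float = ACTIVATION_THRESHOLD_DEFAULT
                     ) -> np.ndarray:
    """Upward crossings of the activation threshold, interpolated (ms)."""
    t_up, _ = _crossings(trace.t, trace.V, threshold_V)
    return t_up


# ---------------------------------------------------------------- #
# restitution
# ---------------------------------------------------------------- #

@dataclass
class RestitutionCurve:
    """(DI, APD) or (DI, CV) pairs from a pacing-rate scan."""

    kind: str  # "apd" or "cv"
    bcl: np.ndarray  # ms, captured BCLs
    di: np.ndarray  # ms
    value: np.ndarray  # APD ms, or CV cm/s
    dropped: list = field(default_factory=list)  # BCLs with capture failure
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.di)
        self.bcl = np.asarray(self.bcl, float)[order]
        self.di = np.asarray(self.di, float)[order]
        self.value = np.asarray(self.value, float)[order]

    def to_text(self, path) -> None:
        header = "".join(f"# {k}: {v}\n" for k, v in self.meta.items())
        header += f"# dropped_bcl: {self.dropped}\n"
        header += "bcl_ms\tdi_ms\t" + ("apd_ms" if self.kind == "apd"
                                       else "cv_cm_s")
        np.savetxt(path, np.column_stack([self.bcl, self.di, self.value]),
                   header=header, comments="", fmt="%.6g", delimiter="\t")


def dynamic_apd_restitution(params: ModelParameters,
                            bcls: Sequence[float],
                            beats_per_bcl: int = 10,
                            dt: float = 0.01,
                            apd_threshold: float = APD_THRESHOLD_DEFAULT,
                            amplitude: Optional[float] = None,
                            sample_ms: float = 0.5) -> RestitutionCurve:
    """Steady-pacing APD(DI) curve for a space-clamped cell.

    For each BCL the cell is paced ``beats_per_bcl`` beats (the model
    has no slow concentration memory, so ~10 beats reach the periodic
    state); the APD and preceding DI of the final beat are recorded.
    BCLs that fail 1:1 capture (fewer action potentials than stimuli)
    are reported in ``dropped`` rather than plotted.
    """
    if amplitude is None:
        amplitude = 1.5 * find_stimulus_threshold(params, dt=dt)
    bcl_ok, di, apd, dropped = [], [], [], []
    for bcl in bcls:
        protocol = StimulusProtocol.pacing(amplitude, bcl=bcl,
                                           n_beats=beats_per_bcl)
        trace = simulate_cell(params, protocol, dt=dt,
                              duration=bcl * beats_per_bcl,
                              sample_ms=sample_ms)
        try:
            beats = measure_apd(trace, apd_threshold)
        except ValueError:
            beats = []
        if len(beats) < beats_per_bcl or math.isnan(beats[-1].di_before):
            dropped.append(float(bcl))
            continue
        last = beats[-1]
        bcl_ok.append(float(bcl))
        di.append(last.di_before)
        apd.append(last.apd)
    return RestitutionCurve(
        kind="apd", bcl=np.array(bcl_ok), di=np.array(di),
        value=np.array(apd), dropped=dropped,
        meta={"set": params.label, "dt_ms": dt, "beats": beats_per_bcl,
              "apd_threshold": apd_threshold, "amplitude": amplitude})


def cv_restitution(params: ModelParameters,
                   bcls: Sequence[float],
                   dt: float = 0.01,
                   cable_length: float = 8.0,
                   dx: float = 0.02,
                   D: float = 1e-3,
                   probes_cm: tuple = (3.0, 5.0),
                   n_beats: int = 5,
                   amplitude: Optional[float] = None,
                   stim_width_cm: float = 0.1,
                   activation_threshold: float = ACTIVATION_THRESHOLD_DEFAULT,
                   apd_threshold: float = APD_THRESHOLD_DEFAULT,
                   sample_ms: float = 0.25) -> RestitutionCurve:
    """Conduction-velocity restitution on a paced 1D cable.

    The left end is paced at each BCL; CV is the probe separation over
    the activation-time difference at the final beat, in cm/s.  The DI
    is measured at the first probe before the final activation.  Raises
    if the wave never reaches the distal probe at the largest BCL.
    """
    if amplitude is None:
        amplitude = 1.5 * find_stimulus_threshold(params, dt=dt)
    xa, xb = probes_cm
    if min(xa, xb) < 1.0 or max(xa, xb) > cable_length - 1.0:
        raise ValueError("probes must sit >= 1 cm from the cable ends")
    bcl_ok, di, cv, dropped = [], [], [], []
    for bcl in bcls:
        grid = TissueGrid.cable(cable_length, dx=dx, D=D)
        sim = TissueSimulation(grid, params, dt=dt, sample_ms=sample_ms)
        sim.add_stimulus(StimulusEvent(
            start=0.0, amplitude=amplitude, duration=1.0, bcl=bcl,
            n_beats=n_beats, region=grid.box_region((0.0, stim_width_cm))))
        res = sim.advance(bcl * (n_beats - 1) + min(bcl, 500.0),
                          probes=[xa, xb])
        tr_a, tr_b = res.probes[(xa,)], res.probes[(xb,)]
        act_a = activation_times(tr_a, activation_threshold)
        act_b = activation_times(tr_b, activation_threshold)
        if bcl == max(bcls) and act_b.size == 0:
            raise ValueError("wave failed to reach the distal probe")
        if act_a.size < n_beats or act_b.size < n_beats:
            dropped.append(float(bcl))
            continue
        t_last = act_a[n_beats - 1]
        dis = measure_di(tr_a.crop(t_max=t_last + 5.0), apd_threshold)
        if dis.size == 0:
            dropped.append(float(bcl))
            continue
        bcl_ok.append(float(bcl))
        cv.append(abs(xb - xa) / (act_b[n_beats - 1] - t_last) * 1000.0)
        di.append(float(dis[-1]))
    return RestitutionCurve(
        kind="cv", bcl=np.array(bcl_ok), di=np.array(di),
        value=np.array(cv), dropped=dropped,
        meta={"set": params.label, "dt_ms": dt, "dx_cm": dx, "D": D,
              "beats": n_beats, "amplitude": amplitude,
              "probes_cm": probes_cm})


# ---------------------------------------------------------------- #
# spiral waves
# ---------------------------------------------------------------- #

@dataclass
class TipTrajectory:
    """Tracked spiral-tip positions: (t ms, x cm, y cm) triples.

    ``all_tips`` keeps every intersection point per frame (before
    nearest-neighbor linking) for diagnostic use.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    V_iso: float
    all_tips: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.t.size


def _isoline_intersections(F: np.ndarray, G: np.ndarray, dx: float):
    """Sub-cell intersections of the zero contours of two 2D fields.

    Within each grid cell both fields are interpolated bilinearly and
    the 2x2 polynomial system F = G = 0 is solved in closed form
    (quadratic after elimination).  Returns an (n, 2) array of (x, y)
    in physical units.
    """
    # cells whose corners change sign in both fields are candidates
    def sign_change(A):
        c = np.stack([A[:-1, :-1], A[1:, :-1], A[:-1, 1:], A[1:, 1:]])
        return ~(np.all(c > 0, axis=0) | np.all(c < 0, axis=0))

    cand = np.nonzero(sign_change(F) & sign_change(G))
    pts = []
    for i, j in zip(*cand):
        # bilinear coefficients over the unit cell
        f00, f10, f01, f11 = F[i, j], F[i + 1, j], F[i, j + 1], F[i + 1, j + 1]
        g00, g10, g01, g11 = G[i, j], G[i + 1, j], G[i, j + 1], G[i + 1, j + 1]
        a0, a1 = f00, f10 - f00
        a2, a3 = f01 - f00, f11 - f10 - f01 + f00
        b0, b1 = g00, g10 - g00
        b2, b3 = g01 - g00, g11 - g10 - g01 + g00
        # F = a0 + a1 u + a2 w + a3 u w = 0 ; same for G; eliminate w:
        # w = -(a0 + a1 u)/(a2 + a3 u)  ->  quadratic in u
        A = a3 * b1 - a1 * b3
        B = a3 * b0 - a0 * b3 + a2 * b1 - a1 * b2
        C = a2 * b0 - a0 * b2
        roots = []
        if abs(A) < 1e-300:
            if abs(B) > 1e-300:
                roots = [-C / B]
        else:
            disc = B * B - 4 * A * C
            if disc >= 0:
                sq = math.sqrt(disc)
                roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
        for u in roots:
            if not -1e-9 <= u <= 1 + 1e-9:
                continue
            den = a2 + a3 * u
            if abs(den) > 1e-300:
                w = -(a0 + a1 * u) / den
            else:
                den2 = b2 + b3 * u
                if abs(den2) < 1e-300:
                    continue
                w = -(b0 + b1 * u) / den2
            if -1e-9 <= w <= 1 + 1e-9:
                pts.append(((i + u) * dx, (j + w) * dx))
    return np.asarray(pts).reshape(-1, 2)


def track_spiral_tip(snapshots: np.ndarray, times: np.ndarray, dx: float,
                     V_iso: Optional[float] = None,
                     link_gate_cm: float = 0.5,
                     seed_xy: Optional[tuple] = None) -> TipTrajectory:
    """Locate and link spiral tips over a series of voltage frames.

    The tip at each frame pair is the intersection of the contour
    V = V_iso with the contour dV/dt = 0 (forward difference between
    frames).  When several intersections exist, frames are linked by
    nearest neighbor within ``link_gate_cm``; ties go to the smallest
    displacement.  ``V_iso`` defaults to half the maximum voltage over
    the whole series.  ``seed_xy`` optionally anchors the start (and
    any restart) of the linked trajectory near a known tip position.
    """
    snapshots = np.asarray(snapshots, dtype=float)
    if snapshots.ndim != 3 or snapshots.shape[0] < 2:
        raise ValueError("need >= 2 two-dimensional frames")
    if V_iso is None:
        V_iso = 0.5 * float(snapshots.max())
    t_out, x_out, y_out, all_tips = [], [], [], []
    prev = None
    for n in range(snapshots.shape[0] - 1):
        F = snapshots[n] - V_iso
        G = snapshots[n + 1] - snapshots[n]  # sign of dV/dt
        pts = _isoline_intersections(F, G, dx)
        all_tips.append(pts)
        if pts.shape[0] == 0:
            prev = None
            continue
        if prev is None:
            if seed_xy is not None:
                pick = pts[np.argmin(np.linalg.norm(
                    pts - np.asarray(seed_xy), axis=1))]
            elif pts.shape[0] == 1:
                pick = pts[0]
            else:
                pick = pts[np.argmin(np.linalg.norm(
                    pts - pts.mean(axis=0), axis=1))]
        else:
            d = np.linalg.norm(pts - prev, axis=1)
            if d.min() > link_gate_cm:
                prev = None
                continue
            pick = pts[np.argmin(d)]
        t_out.append(times[n])
        x_out.append(pick[0])
        y_out.append(pick[1])
        prev = pick
    return TipTrajectory(np.asarray(t_out), np.asarray(x_out),
                         np.asarray(y_out), V_iso=float(V_iso),
                         all_tips=all_tips)


def initiate_spiral(params: ModelParameters,
                    grid: TissueGrid,
                    dt: float = 0.01,
                    amplitude: Optional[float] = None,
                    apd_threshold: float = APD_THRESHOLD_DEFAULT,
                    s1_width_cm: float = 0.1,
                    settle_ms: float = 100.0,
                    max_wait_ms: float = 1500.0):
    """Create a single spiral by S1-S2 cross-field stimulation.

    S1 launches a plane wave from the left edge; once the repolarization
    waveback passes the domain center (the center node falls back below
    the APD threshold), S2 depolarizes the lower-left quadrant, whose
    free end curls into a spiral.  Returns ``(sim, t_s2)`` where ``sim``
    is the running :class:`TissueSimulation` holding the spiral and
    ``t_s2`` the S2 delivery time (ms).

    Raises if no phase singularity is found ``settle_ms`` after S2, with
    the S2 timing in the message to guide adjustment.
    """
    if grid.ndim != 2:
        raise ValueError("spiral initiation needs a 2D sheet")
    if amplitude is None:
        amplitude = 1.5 * find_stimulus_threshold(params, dt=dt)
    nx, ny = grid.shape
    Lx, Ly = (nx - 1) * grid.dx, (ny - 1) * grid.dx
    sim = TissueSimulation(grid, params, dt=dt)
    sim.add_stimulus(StimulusEvent(
        start=0.0, amplitude=amplitude, duration=1.0,
        region=grid.box_region((0.0, s1_width_cm), (0.0, Ly))))
    center = (Lx / 2, Ly / 2)
    # march until the center node has activated and then repolarized
    t_s2 = None
    while sim.t < max_wait_ms:
        res = sim.advance(5.0, probes=[center])
        v_now = res.probes[(center[0], center[1])].V[-1]
        if t_s2 is None and v_now > 0.5:
            t_s2 = -1.0  # center activated, wait for repolarization
        elif t_s2 == -1.0 and v_now < apd_threshold:
            t_s2 = sim.t
            break
    if t_s2 is None or t_s2 < 0:
        raise RuntimeError("S1 wave never activated/repolarized the center; "
                           "domain may be too small")
    sim.add_stimulus(StimulusEvent(
        start=t_s2, amplitude=amplitude, duration=1.0,
        region=grid.box_region((0.0, Lx / 2), (0.0, Ly / 2))))
    res = sim.advance(settle_ms, snapshot_every_ms=5.0)
    tips = track_spiral_tip(res.snapshots[-6:], res.snapshot_times[-6:],
                            grid.dx)
    if tips.n_frames == 0:
        raise RuntimeError(
            f"no phase singularity {settle_ms} ms after S2 at "
            f"t = {t_s2} ms; try shifting S2 timing by +-10 ms")
    return sim, t_s2


def measure_spiral_period(params: ModelParameters,
                          size_cm: float = 6.0,
                          dx: float = 0.02,
                          D: float = 1e-3,
                          dt: float = 0.01,
                          measure_ms: float = 2000.0,
                          discard_ms: float = 500.0,
                          apd_threshold: float = APD_THRESHOLD_DEFAULT,
                          probe_margin_cm: float = 1.0,
                          min_probe_distance_cm: float = 2.0):
    """End-to-end spiral-period study on a square sheet.

    Initiates a spiral (S1-S2), integrates ``measure_ms`` further while
    tracking the tip, then reports period/APD/DI at a recording point
    far from the core: probes on a 3x3 grid (inset ``probe_margin_cm``)
    are ranked by their minimum distance to the post-discard tip
    trajectory; among those at least ``min_probe_distance_cm`` away
    whose statistics satisfy the T = APD + DI identity, the probe with
    the median period is reported.  The median is a robust consensus:
    the rotation period is weakly position-dependent because the
    meandering core Doppler-shifts the activation sequence, stretching
    it at probes the core recedes from and compressing it at probes it
    approaches.  Returns ``(stats, tips, probe_xy)``.
    """
    grid = TissueGrid.sheet(size_cm, size_cm, dx=dx, D=D)
    sim, _ = initiate_spiral(params, grid, dt=dt,
                             apd_threshold=apd_threshold)
    t_meas0 = sim.t
    coords = np.linspace(probe_margin_cm, size_cm - probe_margin_cm, 3)
    probes = [(float(x), float(y)) for x in coords for y in coords]
    res = sim.advance(measure_ms, probes=probes, snapshot_every_ms=2.0)
    tips = track_spiral_tip(res.snapshots, res.snapshot_times, grid.dx)
    t_discard = t_meas0 + discard_ms
    in_window = tips.t >= t_discard
    tx, ty = tips.x[in_window], tips.y[in_window]
    ranked = []
    for key, tr in res.probes.items():
        px, py = (float(v) for v in key)
        dmin = float(np.min(np.hypot(tx - px, ty - py))) if tx.size else 0.0
        ranked.append((dmin, (px, py), tr))
    ranked.sort(reverse=True, key=lambda item: item[0])
    valid = []
    for dmin, probe_xy, tr in ranked:
        try:
            stats = spiral_statistics(tr, threshold=apd_threshold,
                                      discard_ms=t_discard)
        except ValueError:
            continue
        valid.append((dmin, probe_xy, stats))
    compliant = [v for v in valid if v[0] >= min_probe_distance_cm]
    pool = compliant if compliant else valid
    if not pool:
        raise RuntimeError("no probe yielded valid spiral statistics")
    pool.sort(key=lambda item: item[2].period)
    dmin, probe_xy, stats = pool[(len(pool) - 1) // 2]
    return stats, tips, probe_xy


@dataclass(frozen=True)
class SpiralStats:
    """Spiral rotation statistics at a fixed probe."""

    period: float  # ms, mean inter-activation interval
    apd: float  # ms
    di: float  # ms
    n_rotations: int

    def __post_init__(self):
        if abs(self.period - (self.apd + self.di)) > 1.0:
            raise ValueError(
                f"period {self.period:.2f} != APD+DI "
                f"{self.apd + self.di:.2f} beyond 1 ms")


def spiral_statistics(trace: Trace,
                      threshold: float = APD_THRESHOLD_DEFAULT,
                      discard_ms: float = 500.0,
                      min_rotations: int = 5) -> SpiralStats:
    """Rotation period, APD and DI from a probe trace near a spiral.

    The first ``discard_ms`` are dropped (initiation transient); the
    period is the mean inter-activation interval and APD/DI are per-
    rotation means over complete action potentials.  Raises if fewer
    than ``min_rotations`` activations remain.
    """
    tr = trace.crop(t_min=discard_ms)
    beats = measure_apd(tr, threshold)
    full = [b for b in beats if not math.isnan(b.di_before)]
    t_up = np.asarray([b.t_up for b in beats])
    if len(full) < min_rotations or t_up.size < min_rotations + 1:
        raise ValueError(
            f"only {len(full)} complete rotations after discarding "
            f"{discard_ms} ms; need >= {min_rotations}")
    period = float(np.mean(np.diff(t_up)))
    apd = float(np.mean([b.apd for b in full]))
    di = float(np.mean([b.di_before for b in full]))
    return SpiralStats(period=period, apd=apd, di=di,
                       n_rotations=len(full))
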