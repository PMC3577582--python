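"""Monodomain reaction-diffusion solver on 1D cables, 2D sheets and 3D
voxel geometries.

The transmembrane voltage obeys dV/dt = div(D grad V) - J_ion + J_stim
with no-flux boundaries at the edge of the tissue mask.  Space is a
uniform grid (spacing ``dx`` cm, node i at coordinate i*dx); time
integration is forward Euler at fixed ``dt``.  The diffusion operator is
in conservative flux form, so the sum of V over the tissue is exactly
invariant under pure diffusion.

Diffusion is either a scalar D (cm^2/ms) or a per-node symmetric 3x3
tensor built from a fiber unit-vector field and longitudinal/transverse
diffusivities (D_par, D_perp), as in transversally isotropic myocardium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .params import ModelParameters
from .stimulus import StimulusEvent, StimulusProtocol
from .trace import Trace

__all__ = [
    "TissueGrid", "FieldState", "TissueSimulation", "TissueResult",
    "diffusion_term", "simulate_tissue", "fiber_tensor",
]


def fiber_tensor(fibers: np.ndarray, D_par: float,
                 D_perp: float) -> np.ndarray:
    """Per-node diffusion tensor D_perp*I + (D_par - D_perp) f f^T.

    ``fibers``: unit vectors, shape (..., 3).  Returns shape (..., 6)
    storing (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    """
    f = np.asarray(fibers, dtype=float)
    if f.shape[-1] != 3:
        raise ValueError("fiber vectors must have 3 components")
    norm = np.linalg.norm(f, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        fu = np.where(norm > 0, f / np.where(norm == 0, 1.0, norm), 0.0)
    dd = D_par - D_perp
    out = np.empty(f.shape[:-1] + (6,))
    out[..., 0] = D_perp + dd * fu[..., 0] ** 2
    out[..., 1] = D_perp + dd * fu[..., 1] ** 2
    out[..., 2] = D_perp + dd * fu[..., 2] ** 2
    out[..., 3] = dd * fu[..., 0] * fu[..., 1]
    out[..., 4] = dd * fu[..., 0] * fu[..., 2]
    out[..., 5] = dd * fu[..., 1] * fu[..., 2]
    # nodes with no fiber direction fall back to isotropic D_perp
    out[..., :3][norm[..., 0] == 0] = D_perp
    return out


def _as3d(a: np.ndarray) -> np.ndarray:
    """View with trailing singleton axes so fields are always 3D."""
    while a.ndim < 3:
        a = a[..., np.newaxis]
    return a


@dataclass
class TissueGrid:
    """Uniform spatial mesh with tissue mask and diffusion field.

    Exactly one of ``D`` (scalar, cm^2/ms) or ``tensor`` (per-node
    symmetric tensor, shape ``shape + (6,)``) must be given.
    """

    shape: tuple
    dx: float
    D: Optional[float] = None
    tensor: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in np.atleast_1d(self.shape))
        if not 1 <= len(self.shape) <= 3:
            raise ValueError("grid must be 1-, 2- or 3-dimensional")
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if (self.D is None) == (self.tensor is None):
            raise ValueError("give exactly one of scalar D or tensor")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("tissue mask is empty")
        if self.tensor is not None:
            self.tensor = np.ascontiguousarray(self.tensor, dtype=float)
            if self.tensor.shape != self.shape + (6,):
                raise ValueError("tensor must have shape grid.shape + (6,)")
            t = self.tensor[self.mask]
            if np.any(t[:, :3] < -1e-15):
                raise ValueError("diffusion tensor has negative diagonal")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())

    @property
    def D_max(self) -> float:
        if self.D is not None:
            return float(self.D)
        return float(self.tensor[self.mask][:, :3].max())

    def stability_dt(self) -> float:
        """Explicit-Euler diffusion stability bound dx^2/(2*ndim*Dmax)."""
        return self.dx ** 2 / (2 * self.ndim * self.D_max)

    def coordinates(self, axis: int) -> np.ndarray:
        return np.arange(self.shape[axis]) * self.dx

    def node_at(self, point_cm: Sequence[float]) -> tuple:
        """Grid index of the node nearest a physical point (cm)."""
        pt = np.atleast_1d(np.asarray(point_cm, dtype=float))
        if pt.size != self.ndim:
            raise ValueError(f"point must have {self.ndim} coordinates")
        idx = tuple(int(round(x / self.dx)) for x in pt)
        for d, i in enumerate(idx):
            if not 0 <= i < self.shape[d]:
                raise ValueError(f"point {point_cm} outside the grid")
        return idx

    def box_region(self, *ranges_cm) -> np.ndarray:
        """Boolean mask for an axis-aligned box given (lo, hi) cm per axis."""
        if len(ranges_cm) != self.ndim:
            raise ValueError(f"need {self.ndim} (lo, hi) ranges")
        sel = np.ones(self.shape, dtype=bool)
        for ax, (lo, hi) in enumerate(ranges_cm):
            x = self.coordinates(ax)
            shape = [1] * self.ndim
            shape[ax] = -1
            sel &= ((x >= lo - 1e-9) & (x <= hi + 1e-9)).reshape(shape)
        return sel & self.mask

    # constructors -----------------------------------------------------
    @classmethod
    def cable(cls, length_cm: float, dx: float = 0.02,
              D: float = 1e-3) -> "TissueGrid":
        n = int(round(length_cm / dx)) + 1
        return cls(shape=(n,), dx=dx, D=D)

    @classmethod
    def sheet(cls, Lx_cm: float, Ly_cm: float, dx: float = 0.02,
              D: float = 1e-3) -> "TissueGrid":
        nx = int(round(Lx_cm / dx)) + 1
        ny = int(round(Ly_cm / dx)) + 1
        return cls(shape=(nx, ny), dx=dx, D=D)


@dataclass
class FieldState:
    """Per-node cell state over a grid (V, h, f, r, s arrays)."""

    V: np.ndarray
    h: np.ndarray
    f: np.ndarray
    r: np.ndarray
    s: np.ndarray

    @classmethod
    def resting(cls, grid: TissueGrid) -> "FieldState":
        z = np.zeros(grid.shape)
        o = np.ones(grid.shape)
        return cls(V=z.copy(), h=o.copy(), f=o.copy(), r=z.copy(), s=o.copy())

    def copy(self) -> "FieldState":
        return FieldState(*(a.copy() for a in
                            (self.V, self.h, self.f, self.r, self.s)))


def diffusion_term(V: np.ndarray, grid: TissueGrid) -> np.ndarray:
    """Conservative finite-difference div(D grad V), in ms^-1 * V-units.

    Zero at (and zero flux across) mask boundaries; the sum over all
    nodes vanishes to round-off.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    V3 = np.ascontiguousarray(_as3d(V))
    m3 = np.ascontiguousarray(_as3d(grid.mask))
    out = np.empty_like(V3)
    if grid.D is not None:
        _kernels.div_scalar(V3, m3, float(grid.D), grid.dx, out)
    else:
        T = _pad_tensor_3d(grid.tensor, grid.shape)
        _kernels.div_aniso(V3, m3, T, grid.dx, out)
    return out.reshape(grid.shape)


def _pad_tensor_3d(tensor: np.ndarray, shape: tuple) -> np.ndarray:
    t = tensor
    while t.ndim < 4:
        t = t[..., np.newaxis, :]
    return np.ascontiguousarray(t)


@dataclass
class TissueResult:
    """Output of a tissue run: probe traces plus optional snapshots."""

    probes: dict  # probe key -> Trace
    snapshot_times: Optional[np.ndarray] = None
    snapshots: Optional[np.ndarray] = None  # (n_frames, *grid.shape)
    final_state: Optional[FieldState] = None
    dropped: list = field(default_factory=list)


class TissueSimulation:
    """Resumable explicit monodomain integration.

    Stimulus events may be added while the simulation runs (used by the
    auto-timed S2 of the spiral-initiation protocol).  Event on/off
    times are honoured on the output sampling grid (default 1 ms), so
    stimulus currents are piecewise constant over sampling windows.
    """

    def __init__(self, grid: TissueGrid, params: ModelParameters,
                 dt: float = 0.01, sample_ms: float = 1.0,
                 state: Optional[FieldState] = None,
                 on_unstable: str = "raise") -> None:
        if dt <= 0:
            raise ValueError("dt must be > 0")
        bound = grid.stability_dt()
        if dt >= bound:
            msg = (f"dt = {dt} ms violates the explicit stability bound "
                   f"dx^2/(2*ndim*Dmax) = {bound:.4g} ms")
            if on_unstable == "raise":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        self.grid = grid
        self.params = params
        self.dt = dt
        self.sample_ms = sample_ms
        self.n_sub = max(1, round(sample_ms / dt))
        self.state = state.copy() if state is not None else \
            FieldState.resting(grid)
        self.t = 0.0
        self._events: list[StimulusEvent] = []
        self._p = np.array(params.pack())
        self._m3 = np.ascontiguousarray(_as3d(grid.mask))
        self._work = np.zeros(self._m3.shape)  # swap buffer / divergence scratch
        self._dtab, self._fptab, self._inv_dv = \
            _kernels.make_sigmoid_tables(self._p)
        if grid.tensor is not None:
            self._T = _pad_tensor_3d(grid.tensor, grid.shape)
        else:
            self._T = None
        self._jstim = np.zeros(self._m3.shape)
        self._jstim_key: Optional[tuple] = None

    def add_stimulus(self, event: StimulusEvent) -> None:
        if event.region is not None and \
                event.region.shape != self.grid.shape:
            raise ValueError("stimulus region shape does not match grid")
        self._events.append(event)

    def add_protocol(self, protocol: StimulusProtocol) -> None:
        for ev in protocol.events:
            self.add_stimulus(ev)

    def _active_pulses(self, t0: float):
        out = []
        for ie, ev in enumerate(self._events):
            for t_on, t_off, amp in ev.pulses():
                if t_on - 1e-6 <= t0 < t_off - 1e-6:
                    out.append((ie, t_on, amp))
        return tuple(out)

    def _build_jstim(self, t0: float) -> np.ndarray:
        key = self._active_pulses(t0)
        if key != self._jstim_key:
            self._jstim[:] = 0.0
            for ie, _, amp in key:
                region = self._events[ie].region
                if region is None:
                    self._jstim[self._m3] += amp
                else:
                    self._jstim[_as3d(region) & self._m3] += amp
            self._jstim_key = key
        return self._jstim

    def _fields3d(self):
        st = self.state
        return [np.ascontiguousarray(_as3d(a))
                for a in (st.V, st.h, st.f, st.r, st.s)]

    def advance(self, duration: float,
                probes: Sequence = (),
                record_every: int = 1,
                snapshot_every_ms: Optional[float] = None,
                snapshot_dtype=np.float32) -> TissueResult:
        """Integrate for ``duration`` ms, recording probe voltages each
        sampling window and (optionally) full V-field snapshots."""
        n_win = int(round(duration / self.sample_ms))
        # probes are physical points (cm); ints are taken as node indices
        probe_idx = []
        for pt in probes:
            pt_seq = tuple(np.atleast_1d(pt))
            if all(isinstance(i, (int, np.integer)) for i in pt_seq):
                probe_idx.append(pt_seq)
            else:
                probe_idx.append(self.grid.node_at(pt_seq))
        V3, h3, f3, r3, s3 = self._fields3d()
        # keep state views in sync with the contiguous 3D buffers
        self.state = FieldState(*(a.reshape(self.grid.shape)
                                  for a in (V3, h3, f3, r3, s3)))
        rec_t = [self.t]
        rec_v = [[float(self.state.V[ix]) for ix in probe_idx]]
        snap_t, snaps = [], []

        def want_snap(t):
            if snapshot_every_ms is None:
                return False
            return (round(t / self.sample_ms)
                    % max(1, round(snapshot_every_ms / self.sample_ms))) == 0

        if want_snap(self.t):
            snap_t.append(self.t)
            snaps.append(self.state.V.astype(snapshot_dtype).copy())
        for w in range(n_win):
            jstim = self._build_jstim(self.t)
            if self._T is None:
                _kernels.step_window_scalar(
                    V3, h3, f3, r3, s3, self._m3, float(self.grid.D),
                    self.grid.dx, self._p, self.dt, self.n_sub, jstim,
                    self._work, self._dtab, self._fptab, self._inv_dv)
            else:
                _kernels.step_window_aniso(
                    V3, h3, f3, r3, s3, self._m3, self._T,
                    self.grid.dx, self._p, self.dt, self.n_sub, jstim,
                    self._work)
            self.t += self.sample_ms
            if not np.isfinite(V3).all():
                bad = np.argwhere(~np.isfinite(V3))[0]
                raise FloatingPointError(
                    f"non-finite voltage at t = {self.t:g} ms, "
                    f"node {tuple(int(b) for b in bad[:self.grid.ndim])}")
            if (w + 1) % record_every == 0:
                rec_t.append(self.t)
                rec_v.append([float(self.state.V[ix]) for ix in probe_idx])
            if want_snap(self.t):
                snap_t.append(self.t)
                snaps.append(self.state.V.astype(snapshot_dtype).copy())
        meta = {"set": self.params.label, "dt_ms": self.dt,
                "dx_cm": self.grid.dx, "sample_ms": self.sample_ms}
        rec_v_arr = np.asarray(rec_v)
        traces = {}
        for ip, (pt, ix) in enumerate(zip(probes, probe_idx)):
            m = dict(meta)
            m["probe"] = str(pt)
            traces[tuple(np.atleast_1d(pt))] = Trace(
                np.asarray(rec_t), rec_v_arr[:, ip], {}, m)
        return TissueResult(
            probes=traces,
            snapshot_times=np.asarray(snap_t) if snaps else None,
            snapshots=np.stack(snaps) if snaps else None,
            final_state=self.state)


def simulate_tissue(grid: TissueGrid, params: ModelParameters,
                    protocol: StimulusProtocol, duration: float,
                    dt: float = 0.01, probes: Sequence = (),
                    sample_ms: float = 1.0,
                    snapshot_every_ms: Optional[float] = None,
                    on_unstable: str = "raise") -> TissueResult:
    """One-shot tissue run: build the simulation, apply the protocol,
    integrate for ``duration`` ms and return probe traces/snapshots."""
    sim = TissueSimulation(grid, params, dt=dt, sample_ms=sample_ms,
                           on_unstable=on_unstable)
    sim.add_protocol(protocol)
    return sim.advance(duration, probes=probes,
                       snapshot_every_ms=snapshot_every_ms)
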