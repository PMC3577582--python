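"""The space-clamped four-current membrane model.

The transmembrane voltage V (dimensionless, ~0 at rest, ~1 at the AP
peak) obeys

    dV/dt = -(J_fi + J_si + J_so + J_to) + J_stim,

with a fast inward (sodium-like) current J_fi gated by h, a slow inward
(calcium-like) current J_si gated by f, a fast transient outward
(I_to-like) current J_to gated by r (activation) and s (inactivation),
and an ungated slow outward current J_so.  Every gate relaxes toward a
step-function steady state with a voltage-dependent two-valued time
constant; the remaining gates (m, d, f', k) are taken at steady state.

All functions are vectorized: V and the gate variables may be scalars
or numpy arrays of matching shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from . import _kernels
from .params import ModelParameters
from .stimulus import StimulusProtocol
from .trace import Trace

__all__ = [
    "CellState", "CurrentSet", "GateSteadyStates", "GateTimeConstants",
    "theta", "steady_state_gates", "gate_time_constants",
    "membrane_currents", "cell_rhs", "cell_step", "simulate_cell",
    "RESTING_STATE",
]


def theta(x):
    """Right-continuous Heaviside step: theta(x) = 1 for x >= 0, else 0.

    The model's gate curves are built from step functions whose value
    exactly at threshold the defining equations leave open; the >= 0
    convention keeps k_inf continuous at V_c and is used everywhere.
    """
    return np.where(np.asarray(x) >= 0, 1.0, 0.0)[()]


@dataclass(frozen=True)
class CellState:
    """State of one cell: voltage V and the four gate variables."""

    V: float
    h: float
    f: float
    r: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.f, self.r, self.s], dtype=float)

    @classmethod
    def from_array(cls, y) -> "CellState":
        return cls(*(float(v) for v in y))

    @classmethod
    def resting(cls) -> "CellState":
        return cls(V=0.0, h=1.0, f=1.0, r=0.0, s=1.0)


#: The analytic resting fixed point (V=0, h=1, f=1, r=0, s=1).
RESTING_STATE = CellState.resting()


class GateSteadyStates(NamedTuple):
    m_inf: float
    h_inf: float
    f_inf: float
    s_inf: float
    d_inf: float
    fprime_inf: float
    k_inf: float
    r_inf: float


class GateTimeConstants(NamedTuple):
    tau_h: float
    tau_f: float
    tau_r: float
    tau_s: float


class CurrentSet(NamedTuple):
    J_fi: float
    J_si: float
    J_so: float
    J_to: float

    @property
    def total(self):
        return self.J_fi + self.J_si + self.J_so + self.J_to


def steady_state_gates(V, p: ModelParameters) -> GateSteadyStates:
    """Steady-state gate curves at voltage V.

    m_inf is the piecewise-linear sodium activation (zero below V_c,
    linear above, unbounded); all other curves lie in [0, 1].
    """
    V = np.asarray(V, dtype=float)[()]
    above_c = theta(V - p.V_c)
    m_inf = (V - p.V_c) * above_c
    h_inf = 1.0 - above_c
    f_inf = 1.0 - above_c
    s_inf = 1.0 - theta(V - p.V_s_eff)
    d_inf = above_c * 0.5 * (1.0 + np.tanh(p.beta_1 * (V - p.V_1)))
    fprime_inf = 0.5 * (1.0 - np.tanh(p.beta_2 * (V - p.V_2)))
    k_inf = V / p.V_c + above_c * (1.0 - V / p.V_c)
    r_inf = theta(V - p.V_r)
    return GateSteadyStates(m_inf, h_inf, f_inf, s_inf,
                            d_inf, fprime_inf, k_inf, r_inf)


def gate_time_constants(V, p: ModelParameters) -> GateTimeConstants:
    """Two-valued gate time constants (ms) at voltage V.

    h and f switch at V_c, r at V_r, s at the effective s-gate
    threshold (V_s by default).
    """
    V = np.asarray(V, dtype=float)[()]
    above_c = theta(V - p.V_c)
    tau_h = p.tau_h_plus - (p.tau_h_plus - p.tau_h_minus) * above_c
    tau_f = p.tau_f_plus - (p.tau_f_plus - p.tau_f_minus) * above_c
    tau_r = p.tau_r_minus + (p.tau_r_plus - p.tau_r_minus) * theta(V - p.V_r)
    tau_s = p.tau_s_plus - (p.tau_s_plus - p.tau_s_minus) * theta(V - p.V_s_eff)
    return GateTimeConstants(tau_h, tau_f, tau_r, tau_s)


def membrane_currents(state: CellState, p: ModelParameters) -> CurrentSet:
    """The four scaled membrane currents (ms^-1) at a given state."""
    g = steady_state_gates(state.V, p)
    J_fi = -p.g_fi * state.h * g.m_inf * (p.V_fi - state.V)
    J_si = -p.g_si * g.d_inf * state.f * g.fprime_inf
    J_so = p.g_so * g.k_inf
    J_to = p.g_to * state.r * state.s * (state.V - p.V_to)
    return CurrentSet(J_fi, J_si, J_so, J_to)


def cell_rhs(state: CellState, J_stim: float,
             p: ModelParameters) -> CellState:
    """Time derivative of the state; J_stim > 0 depolarizes."""
    J = membrane_currents(state, p)
    g = steady_state_gates(state.V, p)
    tau = gate_time_constants(state.V, p)
    return CellState(
        V=-J.total + J_stim,
        h=(g.h_inf - state.h) / tau.tau_h,
        f=(g.f_inf - state.f) / tau.tau_f,
        r=(g.r_inf - state.r) / tau.tau_r,
        s=(g.s_inf - state.s) / tau.tau_s,
    )


def cell_step(state: CellState, dt: float, J_stim: float,
              p: ModelParameters) -> CellState:
    """One forward-Euler step of length dt (ms)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d = cell_rhs(state, J_stim, p)
    return CellState(
        V=state.V + dt * d.V,
        h=state.h + dt * d.h,
        f=state.f + dt * d.f,
        r=state.r + dt * d.r,
        s=state.s + dt * d.s,
    )


def simulate_cell(p: ModelParameters,
                  protocol: StimulusProtocol,
                  dt: float = 0.01,
                  duration: Optional[float] = None,
                  sample_ms: float = 1.0,
                  record_gates: bool = False,
                  initial_state: Optional[CellState] = None) -> Trace:
    """Integrate one cell under a stimulation protocol.

    Forward Euler at step ``dt`` (ms); the returned trace is sampled
    every ``sample_ms``.  ``duration`` defaults to the protocol end
    plus 500 ms so the final action potential can complete.

    Raises ``FloatingPointError`` if the state leaves the finite range
    (numerical blow-up), reporting the time of failure.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration is None:
        duration = protocol.end_time() + 500.0
    rec_stride = max(1, round(sample_ms / dt))
    n_steps = int(round(duration / dt))
    n_steps = (n_steps // rec_stride) * rec_stride
    stim = protocol.waveform(dt, n_steps)
    y0 = (initial_state or RESTING_STATE).as_array()
    out = _kernels.integrate_cell(y0, np.array(p.pack()), dt, n_steps,
                                  stim, rec_stride, record_gates)
    t = np.arange(out.shape[1]) * (rec_stride * dt)
    if not np.all(np.isfinite(out)):
        i_bad = int(np.argmax(~np.isfinite(out).all(axis=0)))
        raise FloatingPointError(
            f"non-finite cell state at t = {t[i_bad]:g} ms "
            f"(dt = {dt} ms may be unstable)")
    gates = {}
    if record_gates:
        gates = {"h": out[1], "f": out[2], "r": out[3], "s": out[4]}
    meta = {"set": p.label, "dt_ms": dt, "sample_ms": rec_stride * dt}
    return Trace(t, out[0], gates, meta)
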