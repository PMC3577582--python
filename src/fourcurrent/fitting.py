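"""Parameter estimation from action-potential morphology templates.

The free parameters are adjusted by bounded nonlinear least squares
(Levenberg-Marquardt-type trust-region) so that the model's steady-
state paced AP matches one or more voltage-vs-time templates, each at
its own pacing rate, optionally together with conduction-velocity
targets from a short-cable run.  Model and template are aligned at the
upstroke (V = 0.5 crossing); the early-repolarization notch window
(5-50 ms after the upstroke) can be overweighted, since the transient
outward current that shapes the notch contributes little to the rest
of the waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .ionic import simulate_cell
from .params import ModelParameters
from .protocols import cv_restitution, find_stimulus_threshold
from .stimulus import StimulusProtocol
from .params import VoltageConvention

__all__ = ["ApTemplate", "FitProblem", "FitResult", "objective",
           "fit_parameters", "load_template", "make_template"]

#: Parameters that may be freed, with broad physical bounds.
_BOUNDS = {
    "tau_h_plus": (0.1, 2000.0), "tau_h_minus": (0.05, 2000.0),
    "tau_f_plus": (0.1, 5000.0), "tau_f_minus": (0.1, 5000.0),
    "tau_r_plus": (0.05, 500.0), "tau_r_minus": (0.05, 500.0),
    "tau_s_plus": (0.1, 5000.0), "tau_s_minus": (0.05, 500.0),
    "g_fi": (0.0, 50.0), "g_so": (0.0, 1.0), "g_si": (0.0, 20.0),
    "g_to": (0.0, 50.0),
    "V_fi": (1.0, 2.0), "beta_1": (0.5, 50.0), "beta_2": (0.5, 50.0),
    "V_1": (0.0, 1.5), "V_2": (0.0, 1.5),
    "V_c": (0.02, 0.55), "V_s": (0.05, 1.0),
}

_PENALTY = 1e3  # residual filled in when a trial simulation blows up


@dataclass
class ApTemplate:
    """One objective waveform: voltage vs time at a fixed pacing rate."""

    bcl: float  # ms
    t: np.ndarray  # ms, need not start at 0
    V: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.size != self.V.size or self.t.size < 10:
            raise ValueError("template needs matching t/V with >= 10 points")

    def upstroke_time(self, thr: float = 0.5) -> float:
        V, t = self.V, self.t
        up = np.nonzero((V[:-1] < thr) & (V[1:] >= thr))[0]
        if up.size == 0:  # fall back to the steepest rise
            i = int(np.argmax(np.diff(V)))
            return float(t[i])
        i = up[0]
        return float(t[i] + (thr - V[i]) / (V[i + 1] - V[i])
                     * (t[i + 1] - t[i]))


@dataclass
class FitProblem:
    """Templates + options defining the least-squares problem.

    ``free`` lists the ModelParameters field names to optimize; the
    rest stay at ``start``.  ``bounds`` optionally overrides the
    built-in physical bounds per parameter.  CV targets (BCL ms,
    cm/s) add scaled residuals from a short-cable simulation.
    """

    templates: list
    start: ModelParameters
    free: Sequence[str] = ("g_fi", "g_si", "g_so", "g_to",
                           "tau_f_minus", "tau_r_plus", "tau_s_minus")
    bounds: dict = field(default_factory=dict)
    cv_targets: list = field(default_factory=list)  # (bcl, cv_cm_s)
    cv_weight: float = 0.02  # residual units per cm/s
    notch_weight: float = 3.0
    notch_window_ms: tuple = (5.0, 50.0)
    pre_beats: int = 10
    stim_amplitude: Optional[float] = None  # default: 1.5x threshold(start)

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("need at least one template")
        self.templates = [tpl if isinstance(tpl, ApTemplate)
                          else ApTemplate(*tpl) for tpl in self.templates]
        if self.notch_weight <= 0:
            raise ValueError("weights must be > 0")
        for name in self.free:
            if name not in _BOUNDS:
                raise ValueError(f"parameter {name!r} cannot be freed")
        lo, hi = self.bounds_arrays()
        x0 = self.pack(self.start)
        if np.any(x0 < lo) or np.any(x0 > hi):
            raise ValueError("initial guess outside bounds")

    def pack(self, p: ModelParameters) -> np.ndarray:
        return np.array([getattr(p, name) for name in self.free])

    def unpack(self, x: np.ndarray) -> ModelParameters:
        return self.start.replace(**dict(zip(self.free, map(float, x))))

    def bounds_arrays(self):
        lo = np.array([self.bounds.get(n, _BOUNDS[n])[0] for n in self.free])
        hi = np.array([self.bounds.get(n, _BOUNDS[n])[1] for n in self.free])
        return lo, hi

    def n_residuals(self) -> int:
        return sum(tpl.t.size for tpl in self.templates) + len(self.cv_targets)


def _template_residual(p: ModelParameters, tpl: ApTemplate,
                       problem: FitProblem, amplitude: float,
                       dt: float) -> np.ndarray:
    """Weighted voltage mismatch of the final paced beat vs a template."""
    protocol = StimulusProtocol.pacing(amplitude, bcl=tpl.bcl,
                                       n_beats=problem.pre_beats)
    try:
        trace = simulate_cell(p, protocol, dt=dt,
                              duration=tpl.bcl * problem.pre_beats,
                              sample_ms=min(0.5, dt * 50))
    except FloatingPointError:
        return np.full(tpl.t.size, _PENALTY)
    V, t = trace.V, trace.t
    up = np.nonzero((V[:-1] < 0.5) & (V[1:] >= 0.5))[0]
    if up.size < problem.pre_beats:  # loss of capture: penalize
        return np.full(tpl.t.size, _PENALTY)
    i = up[-1]
    t_up_model = t[i] + (0.5 - V[i]) / (V[i + 1] - V[i]) * (t[i + 1] - t[i])
    rel_t = tpl.t - tpl.upstroke_time()
    model_V = np.interp(rel_t + t_up_model, t, V)
    w = np.ones(tpl.t.size)
    lo, hi = problem.notch_window_ms
    w[(rel_t >= lo) & (rel_t <= hi)] = problem.notch_weight
    return w * (model_V - tpl.V)


def objective(x: np.ndarray, problem: FitProblem,
              dt: float = 0.01) -> np.ndarray:
    """Residual vector at the free-parameter vector ``x``.

    Concatenates per-template weighted voltage residuals and scaled CV
    residuals.  Simulation failures yield large finite penalties so the
    optimizer can back away.
    """
    p = problem.unpack(x)
    amplitude = problem.stim_amplitude
    if amplitude is None:
        amplitude = 1.5 * find_stimulus_threshold(problem.start, dt=dt)
    parts = [_template_residual(p, tpl, problem, amplitude, dt)
             for tpl in problem.templates]
    if problem.cv_targets:
        bcls = [b for b, _ in problem.cv_targets]
        try:
            curve = cv_restitution(p, bcls, dt=dt, cable_length=3.0,
                                   probes_cm=(1.0, 2.0), n_beats=3,
                                   amplitude=amplitude)
            got = dict(zip(curve.bcl, curve.value))
            res = [problem.cv_weight * (got.get(b, np.nan) - cv)
                   for b, cv in problem.cv_targets]
            res = [r if math.isfinite(r) else _PENALTY for r in res]
        except (ValueError, FloatingPointError):
            res = [_PENALTY] * len(problem.cv_targets)
        parts.append(np.asarray(res))
    return np.concatenate(parts)


@dataclass
class FitResult:
    params: ModelParameters
    cost: float  # 0.5 * sum of squared residuals, scipy convention
    rms_per_template: list
    converged: bool
    n_evaluations: int
    starts: list = field(default_factory=list)  # (start idx, cost) per start
    message: str = ""


def fit_parameters(problem: FitProblem, dt: float = 0.01,
                   n_starts: int = 1, jitter: float = 0.15,
                   seed: int = 0, max_nfev: int = 400,
                   verbose: bool = False) -> FitResult:
    """Bounded least-squares fit of the free parameters.

    Deterministic for a given seed: the seed only drives the optional
    multi-start jitter (start 0 is always the unperturbed guess); the
    best of all starts is returned.  Non-convergence is reported in the
    result, not raised.
    """
    if problem.stim_amplitude is None:
        problem.stim_amplitude = 1.5 * find_stimulus_threshold(
            problem.start, dt=dt)
    lo, hi = problem.bounds_arrays()
    x0 = problem.pack(problem.start)
    if not problem.free:
        res0 = objective(x0, problem, dt)
        return FitResult(params=problem.start,
                         cost=0.5 * float(res0 @ res0),
                         rms_per_template=_per_template_rms(res0, problem),
                         converged=True, n_evaluations=1,
                         starts=[(0, 0.5 * float(res0 @ res0))])
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        trial = x0 * (1.0 + jitter * rng.uniform(-1, 1, size=x0.size))
        starts.append(np.clip(trial, lo, hi))
    best = None
    log = []
    for i, xs in enumerate(starts):
        sol = least_squares(objective, xs, bounds=(lo, hi),
                            args=(problem, dt), method="trf",
                            x_scale=np.maximum(np.abs(x0), 1e-3),
                            max_nfev=max_nfev,
                            verbose=2 if verbose else 0)
        log.append((i, float(sol.cost)))
        if best is None or sol.cost < best.cost:
            best = sol
    res = objective(best.x, problem, dt)
    return FitResult(params=problem.unpack(best.x),
                     cost=float(best.cost),
                     rms_per_template=_per_template_rms(res, problem),
                     converged=bool(best.status > 0),
                     n_evaluations=int(best.nfev),
                     starts=log, message=str(best.message))


def _per_template_rms(res: np.ndarray, problem: FitProblem) -> list:
    out = []
    i = 0
    for tpl in problem.templates:
        seg = res[i:i + tpl.t.size]
        out.append(float(np.sqrt(np.mean(seg ** 2))))
        i += tpl.t.size
    return out


def make_template(p: ModelParameters, bcl: float, dt: float = 0.01,
                  pre_beats: int = 10, sample_ms: float = 1.0,
                  amplitude: Optional[float] = None,
                  window_ms: tuple = (-10.0, 400.0)) -> ApTemplate:
    """Generate a template from the model itself (for synthetic-recovery
    studies): the final beat of a paced train, windowed around the
    upstroke."""
    if amplitude is None:
        amplitude = 1.5 * find_stimulus_threshold(p, dt=dt)
    trace = simulate_cell(p, StimulusProtocol.pacing(
        amplitude, bcl=bcl, n_beats=pre_beats), dt=dt,
        duration=bcl * pre_beats, sample_ms=sample_ms)
    V, t = trace.V, trace.t
    up = np.nonzero((V[:-1] < 0.5) & (V[1:] >= 0.5))[0]
    t_up = t[up[-1]]
    sel = (t >= t_up + window_ms[0]) & (t <= t_up + window_ms[1])
    return ApTemplate(bcl=bcl, t=t[sel] - t_up, V=V[sel])


def load_template(path, bcl: float,
                  units: str = "auto",
                  convention: Optional[VoltageConvention] = None
                  ) -> ApTemplate:
    """Read a two-column (time_ms, V) text template.

    ``units``: 'mV', 'dimensionless', or 'auto' (mV assumed when the
    voltage range exceeds 3, i.e. clearly physical units).
    """
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_ms, V)")
    t, V = data[:, 0], data[:, 1]
    if units == "auto":
        units = "mV" if np.ptp(V) > 3.0 else "dimensionless"
    if units == "mV":
        V = (convention or VoltageConvention()).to_dimensionless(V)
    elif units != "dimensionless":
        raise ValueError("units must be 'mV', 'dimensionless' or 'auto'")
    return ApTemplate(bcl=bcl, t=t, V=V)
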