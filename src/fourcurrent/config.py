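"""Run configuration: schema-validated YAML configs and the dispatch
layer shared by the command-line interface.

A RunConfig captures everything needed to reproduce a run: command,
parameter set, numerical steps (defaults dt = 0.01 ms; dx = 0.02 cm in
1D/2D and 0.025 cm in 3D), domain sizes, protocol settings and
measurement thresholds.  Every output file carries a provenance header
with the package version, the config hash and the parameter set, so a
result can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .params import ModelParameters, builtin_set, load_parameters

__all__ = ["RunConfig", "load_config", "save_config", "run"]

_COMMANDS = ("cell", "threshold", "restitution-apd", "restitution-cv",
             "spiral", "ecg", "fit", "make-geometry")


@dataclass
class RunConfig:
    command: str = "cell"
    set_name: str = "epi"
    param_file: Optional[str] = None
    dt: float = 0.01  # ms
    dx: Optional[float] = None  # cm; default 0.02 (1D/2D) or 0.025 (3D)
    D: float = 1e-3  # cm^2/ms (scalar runs)
    duration: Optional[float] = None  # ms
    bcl: float = 1000.0
    bcls: list = field(default_factory=lambda: [1000, 800, 600, 500,
                                                400, 350, 300, 250])
    n_beats: int = 10
    amplitude: Optional[float] = None  # ms^-1; default 1.5x threshold
    cable_length: float = 8.0
    sheet_size: float = 6.0
    probes_cm: list = field(default_factory=lambda: [3.0, 5.0])
    geometry_file: Optional[str] = None
    geometry_shape: list = field(default_factory=lambda: [72, 68, 64])
    apd_threshold: float = 0.1
    activation_threshold: float = 0.5
    v_iso: Optional[float] = None  # None = half of max V (auto)
    templates: list = field(default_factory=list)  # (path, bcl) pairs
    free_parameters: list = field(default_factory=list)
    out: str = "fourcurrent_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(
                f"command: unknown {self.command!r} (choose from "
                f"{', '.join(_COMMANDS)})")
        if self.dt <= 0:
            raise ValueError("dt: must be > 0")
        if self.dx is not None and self.dx <= 0:
            raise ValueError("dx: must be > 0")
        if self.bcl <= 0:
            raise ValueError("bcl: must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats: must be >= 1")
        if self.param_file is not None and not Path(self.param_file).exists():
            raise ValueError(f"param_file: {self.param_file} does not exist")
        if self.command == "ecg" and self.geometry_file is not None \
                and not Path(self.geometry_file).exists():
            raise ValueError(
                f"geometry_file: {self.geometry_file} does not exist")
        for item in self.templates:
            path = item[0] if isinstance(item, (list, tuple)) else item
            if not Path(path).exists():
                raise ValueError(f"templates: {path} does not exist")

    def dx_for(self, ndim: int) -> float:
        if self.dx is not None:
            return self.dx
        return 0.025 if ndim == 3 else 0.02

    def parameters(self) -> ModelParameters:
        if self.param_file:
            return load_parameters(self.param_file)
        return builtin_set(self.set_name)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific content (output destination excluded)."""
        payload = self.to_dict()
        payload.pop("out")
        payload = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def provenance(self, params: ModelParameters) -> dict:
        return {"generator": f"fourcurrent {__version__}",
                "config_hash": self.config_hash(),
                "set": params.label or "custom",
                "dt_ms": self.dt, "seed": self.seed}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown field(s): {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def run(config: RunConfig) -> list:
    """Execute a configured run; returns the list of files written."""
    from .ionic import simulate_cell
    from .params import VoltageConvention
    from .protocols import (cv_restitution, dynamic_apd_restitution,
                            find_stimulus_threshold, initiate_spiral,
                            spiral_statistics, track_spiral_tip)
    from .stimulus import StimulusProtocol
    from .tissue import TissueGrid

    params = config.parameters()
    prov = config.provenance(params)
    out = Path(config.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written: list = []

    def _write_kv(path, mapping):
        with open(path, "w") as fh:
            for k, v in {**prov, **mapping}.items():
                fh.write(f"{k}: {v}\n")
        written.append(path)

    cmd = config.command
    if cmd == "threshold":
        thr = find_stimulus_threshold(params, dt=config.dt)
        _write_kv(out.with_suffix(".threshold.txt"),
                  {"threshold_ms^-1": thr, "x1.5_ms^-1": 1.5 * thr})
    elif cmd == "cell":
        amp = config.amplitude
        if amp is None:
            amp = 1.5 * find_stimulus_threshold(params, dt=config.dt)
        protocol = StimulusProtocol.pacing(amp, bcl=config.bcl,
                                           n_beats=config.n_beats)
        trace = simulate_cell(params, protocol, dt=config.dt,
                              duration=config.duration, record_gates=True)
        trace.meta.update(prov)
        path = out.with_suffix(".trace.txt")
        trace.to_text(path, voltage_convention=VoltageConvention())
        written.append(path)
    elif cmd == "restitution-apd":
        curve = dynamic_apd_restitution(
            params, config.bcls, beats_per_bcl=config.n_beats,
            dt=config.dt, apd_threshold=config.apd_threshold,
            amplitude=config.amplitude)
        curve.meta.update(prov)
        path = out.with_suffix(".apd_restitution.txt")
        curve.to_text(path)
        written.append(path)
    elif cmd == "restitution-cv":
        curve = cv_restitution(
            params, config.bcls, dt=config.dt,
            cable_length=config.cable_length,
            dx=config.dx_for(1), D=config.D,
            probes_cm=tuple(config.probes_cm), amplitude=config.amplitude,
            activation_threshold=config.activation_threshold,
            apd_threshold=config.apd_threshold)
        curve.meta.update(prov)
        path = out.with_suffix(".cv_restitution.txt")
        curve.to_text(path)
        written.append(path)
    elif cmd == "spiral":
        L = config.sheet_size
        grid = TissueGrid.sheet(L, L, dx=config.dx_for(2), D=config.D)
        sim, t_s2 = initiate_spiral(params, grid, dt=config.dt,
                                    amplitude=config.amplitude,
                                    apd_threshold=config.apd_threshold)
        duration = config.duration or 1300.0
        probe = (1.0, L - 1.0)
        res = sim.advance(duration, probes=[probe], snapshot_every_ms=2.0)
        tips = track_spiral_tip(res.snapshots, res.snapshot_times,
                                grid.dx, V_iso=config.v_iso)
        stats = spiral_statistics(res.probes[probe],
                                  threshold=config.apd_threshold,
                                  discard_ms=sim.t - duration + 500.0)
        tip_path = out.with_suffix(".tip.txt")
        np.savetxt(tip_path,
                   np.column_stack([tips.t, tips.x, tips.y]),
                   header="".join(f"# {k}: {v}\n" for k, v in prov.items())
                   + f"# V_iso: {tips.V_iso}\nt_ms\tx_cm\ty_cm",
                   comments="", fmt="%.6g", delimiter="\t")
        written.append(tip_path)
        _write_kv(out.with_suffix(".spiral.txt"),
                  {"t_s2_ms": t_s2, "period_ms": stats.period,
                   "apd_ms": stats.apd, "di_ms": stats.di,
                   "rotations": stats.n_rotations})
    elif cmd == "make-geometry":
        from .geometry import save_geometry, synthesize_ventricles
        geom = synthesize_ventricles(shape=tuple(config.geometry_shape),
                                     dx=config.dx_for(3))
        path = out.with_suffix(".geometry.npz")
        save_geometry(geom, path)
        written.append(path)
    elif cmd == "ecg":
        from .ecg import pseudo_ecg
        from .geometry import load_geometry, synthesize_ventricles
        if config.geometry_file:
            geom = load_geometry(config.geometry_file)
        else:
            geom = synthesize_ventricles(shape=tuple(config.geometry_shape),
                                         dx=config.dx_for(3))
        amp = config.amplitude
        if amp is None:
            amp = 1.5 * find_stimulus_threshold(params, dt=config.dt)
        dip = pseudo_ecg(geom, params, amplitude=amp, bcl=config.bcl,
                         n_beats=config.n_beats, dt=config.dt)
        dip.meta.update(prov)
        path = out.with_suffix(".ecg.txt")
        dip.to_text(path)
        written.append(path)
    elif cmd == "fit":
        from .fitting import FitProblem, fit_parameters, load_template
        from .params import save_parameters
        if not config.templates:
            raise ValueError("templates: fit requires (path, bcl) entries")
        tpls = [load_template(path, bcl=float(bcl))
                for path, bcl in config.templates]
        kwargs = {}
        if config.free_parameters:
            kwargs["free"] = tuple(config.free_parameters)
        problem = FitProblem(templates=tpls, start=params, **kwargs)
        result = fit_parameters(problem, dt=config.dt, seed=config.seed)
        fit_path = out.with_suffix(".fit_params.yaml")
        save_parameters(result.params, fit_path)
        written.append(fit_path)
        _write_kv(out.with_suffix(".fit_report.txt"),
                  {"cost": result.cost, "converged": result.converged,
                   "rms_per_template": result.rms_per_template,
                   "n_evaluations": result.n_evaluations})
    return written
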