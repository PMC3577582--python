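"""Pseudo-ECG via the heart-dipole (far-field, homogeneous torso)
approximation.

Every depolarization front contributes a microscopic dipole
proportional to div(D grad V); summing them weighted by the position
vector from the heart's geometric center gives the heart-dipole vector

    J(t) = sum_i  r_i [div(D grad V)]_i dx^3 ,

whose projection on a lead direction is the lead signal.  Amplitudes
are in arbitrary units (the torso is not modelled); waveforms are
normalized to unit peak absolute deflection during the activation
window for comparison across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import VentricleGeometry, activation_sequence_protocol
from .params import ModelParameters
from .stimulus import StimulusProtocol
from .tissue import TissueSimulation, diffusion_term

__all__ = ["DipoleTrace", "heart_dipole", "pseudo_ecg", "DEFAULT_LEADS"]

#: Lead unit vectors; "I" is the standard limb lead taken along the
#: box x-axis (the torso frame is not defined by the monodomain model).
DEFAULT_LEADS = {"I": np.array([1.0, 0.0, 0.0])}


@dataclass
class DipoleTrace:
    """Time series of the 3-component heart-dipole vector."""

    t: np.ndarray  # ms
    J: np.ndarray  # (n, 3), arbitrary units
    leads: dict = field(default_factory=lambda: dict(DEFAULT_LEADS))
    meta: dict = field(default_factory=dict)

    def signal(self, lead: str = "I") -> np.ndarray:
        e = np.asarray(self.leads[lead], dtype=float)
        e = e / np.linalg.norm(e)
        return self.J @ e

    def normalized(self, lead: str = "I",
                   window_ms: Optional[tuple] = None) -> np.ndarray:
        """Lead signal scaled to unit peak |deflection|.

        ``window_ms`` restricts the normalization peak search (e.g. to
        the activation/QRS window); the whole trace is used otherwise.
        """
        sig = self.signal(lead)
        sel = np.ones_like(sig, dtype=bool)
        if window_ms is not None:
            sel = (self.t >= window_ms[0]) & (self.t <= window_ms[1])
        peak = np.max(np.abs(sig[sel])) if np.any(sel) else np.max(np.abs(sig))
        return sig / peak if peak > 0 else sig

    def to_text(self, path, lead: str = "I") -> None:
        header = "".join(f"# {k}: {v}\n" for k, v in self.meta.items())
        header += "time_ms\tlead_%s\tJx\tJy\tJz" % lead
        np.savetxt(path, np.column_stack([self.t, self.signal(lead), self.J]),
                   header=header, comments="", fmt="%.8g", delimiter="\t")


def heart_dipole(V: np.ndarray, geometry: VentricleGeometry) -> np.ndarray:
    """One sample of the heart-dipole vector for a voltage field.

    Uses the same conservative diffusion operator as the tissue solver,
    so on a no-flux domain the source term sums to zero and the result
    is independent of the chosen center.
    """
    grid = geometry.grid
    src = diffusion_term(np.asarray(V, dtype=float), grid)
    m = grid.mask
    w = src[m] * grid.dx ** 3
    coords = np.argwhere(m) * grid.dx - geometry.center_cm
    return coords.T @ w


def pseudo_ecg(geometry: VentricleGeometry,
               params: ModelParameters,
               amplitude: float,
               bcl: float = 400.0,
               n_beats: int = 2,
               extra_ms: float = 0.0,
               dt: float = 0.01,
               sample_ms: float = 1.0,
               leads: Optional[dict] = None,
               protocol: Optional[StimulusProtocol] = None,
               progress: bool = False) -> DipoleTrace:
    """Simulate paced beats on the ventricles and record the dipole.

    The endocardial activation sequence (A0/A5/A10 at 0/5/10 ms) is
    repeated at ``bcl`` for ``n_beats``; the dipole is sampled every
    ``sample_ms``.  A custom ``protocol`` overrides the built-in
    activation sequence.
    """
    if protocol is None:
        protocol = activation_sequence_protocol(
            geometry, amplitude=amplitude, bcl=bcl, n_beats=n_beats)
    sim = TissueSimulation(geometry.grid, params, dt=dt,
                           sample_ms=sample_ms)
    sim.add_protocol(protocol)
    duration = bcl * n_beats + extra_ms
    n = int(round(duration / sample_ms))
    t = np.empty(n + 1)
    J = np.empty((n + 1, 3))
    t[0] = sim.t
    J[0] = heart_dipole(sim.state.V, geometry)
    for i in range(n):
        sim.advance(sample_ms)
        t[i + 1] = sim.t
        J[i + 1] = heart_dipole(sim.state.V, geometry)
        if progress and (i + 1) % 100 == 0:
            print(f"  pseudo-ecg t = {sim.t:.0f} ms", flush=True)
    return DipoleTrace(t=t, J=J,
                       leads=dict(leads) if leads else dict(DEFAULT_LEADS),
                       meta={"set": params.label, "bcl_ms": bcl,
                             "beats": n_beats, "dt_ms": dt,
                             "n_tissue": geometry.n_tissue})
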