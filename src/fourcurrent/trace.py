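"""Time-series containers and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """Uniformly sampled voltage time series at one probe.

    ``t`` is in ms, ``V`` dimensionless.  ``gates`` optionally holds the
    co-recorded gate variables keyed 'h', 'f', 'r', 's'.  ``meta`` is
    free-form provenance (parameter set, dt, thresholds, ...), written
    as commented header lines.
    """

    t: np.ndarray
    V: np.ndarray
    gates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.shape != self.V.shape:
            raise ValueError("t and V must have the same length")

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan

    def crop(self, t_min: float = -np.inf, t_max: float = np.inf) -> "Trace":
        sel = (self.t >= t_min) & (self.t <= t_max)
        return Trace(self.t[sel], self.V[sel],
                     {k: v[sel] for k, v in self.gates.items()},
                     dict(self.meta))

    def to_text(self, path: str | Path, voltage_convention=None) -> None:
        """Write as commented-header delimited text (time_ms, V, [V_mV, gates])."""
        cols = [self.t, self.V]
        names = ["time_ms", "V"]
        if voltage_convention is not None:
            cols.append(voltage_convention.to_mV(self.V))
            names.append("V_mV")
        for k in sorted(self.gates):
            cols.append(self.gates[k])
            names.append(k)
        header = "".join(f"# {k}: {v}\n" for k, v in self.meta.items())
        header += "\t".join(names)
        np.savetxt(path, np.column_stack(cols), header=header,
                   comments="", fmt="%.10g", delimiter="\t")

    @classmethod
    def from_text(cls, path: str | Path) -> "Trace":
        path = Path(path)
        meta: dict = {}
        names: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if ":" in line:
                        k, v = line[1:].split(":", 1)
                        meta[k.strip()] = v.strip()
                elif line:
                    names = line.split("\t") if "\t" in line else line.split()
                    break
        data = np.loadtxt(path, skiprows=len(meta) + 1)
        data = np.atleast_2d(data)
        if not names or names[0] != "time_ms":
            raise ValueError(f"{path}: not a trace file (missing time_ms header)")
        gates = {}
        for j, name in enumerate(names):
            if name in ("h", "f", "r", "s"):
                gates[name] = data[:, j]
        return cls(data[:, 0], data[:, 1], gates, meta)
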