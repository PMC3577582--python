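"""Model parameters and voltage conventions.

The membrane model lumps all transmembrane currents into four groups —
fast inward (sodium-like), slow inward (L-type-calcium-like), slow
outward (delayed-rectifier-potassium-like) and fast transient outward
(I_to-like) — each controlled by at most two dynamical gates.  A
parameter set is one column of the published parameter table: eight gate
time constants, four conductances, and the threshold/shape constants of
the steady-state gate curves.

Voltage is dimensionless inside the package: V = (V_mV - V_rest)/dV with
V_rest = -85 mV and dV = 100 mV, so V runs roughly from 0 (rest) to ~1
(peak of the action potential).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "VoltageConvention",
    "builtin_set",
    "builtin_set_names",
    "builtin_set_path",
    "load_parameters",
    "save_parameters",
]

#: Names of the per-set fields, in table order.
_TABLE_FIELDS = (
    "tau_h_plus", "tau_h_minus", "tau_f_plus", "tau_f_minus",
    "tau_r_plus", "tau_r_minus", "tau_s_plus", "tau_s_minus",
    "g_fi", "V_fi", "g_so", "g_si", "beta_1", "beta_2",
    "V_1", "V_2", "g_to", "V_c", "V_s",
)


@dataclass(frozen=True)
class ModelParameters:
    """One complete parameter set of the four-current membrane model.

    Time constants are in ms, conductances in ms^-1, potentials and
    slopes dimensionless.  ``V_r`` (threshold of the r activation gate)
    and ``V_to`` (transient-outward reversal potential) are fixed at 0.6
    and 0.0 for every published set; they are fields so that variants
    can be explored.

    ``s_gate_threshold`` selects which potential switches the s gate:
    ``"Vs"`` (default) uses the per-cell-type ``V_s`` from the table,
    ``"Vc"`` uses the excitation threshold ``V_c`` as printed in the
    gate equations (which would leave ``V_s`` unused).
    """

    tau_h_plus: float
    tau_h_minus: float
    tau_f_plus: float
    tau_f_minus: float
    tau_r_plus: float
    tau_r_minus: float
    tau_s_plus: float
    tau_s_minus: float
    g_fi: float
    V_fi: float
    g_so: float
    g_si: float
    beta_1: float
    beta_2: float
    V_1: float
    V_2: float
    g_to: float
    V_c: float
    V_s: float
    V_r: float = 0.6
    V_to: float = 0.0
    s_gate_threshold: str = "Vs"
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("tau_h_plus", "tau_h_minus", "tau_f_plus", "tau_f_minus",
                     "tau_r_plus", "tau_r_minus", "tau_s_plus", "tau_s_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        for name in ("g_fi", "g_so", "g_si", "g_to"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if not 0 < self.V_c:
            raise ValueError("V_c must be > 0")
        if self.s_gate_threshold not in ("Vs", "Vc"):
            raise ValueError("s_gate_threshold must be 'Vs' or 'Vc'")

    @property
    def V_s_eff(self) -> float:
        """The potential at which the s gate actually switches."""
        return self.V_s if self.s_gate_threshold == "Vs" else self.V_c

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # Packed tuple consumed by the numba kernels; the order is the
    # contract documented at the top of _kernels.py.
    def pack(self) -> tuple:
        return (
            self.tau_h_plus, self.tau_h_minus, self.tau_f_plus, self.tau_f_minus,
            self.tau_r_plus, self.tau_r_minus, self.tau_s_plus, self.tau_s_minus,
            self.g_fi, self.V_fi, self.g_so, self.g_si,
            self.beta_1, self.beta_2, self.V_1, self.V_2,
            self.g_to, self.V_c, self.V_s_eff, self.V_r, self.V_to,
        )


@dataclass(frozen=True)
class VoltageConvention:
    """Mapping between dimensionless and physical membrane potential."""

    V_rest_mV: float = -85.0
    delta_V_mV: float = 100.0
    C_m: float = 1.0  # µF cm^-2

    def to_mV(self, V):
        return V * self.delta_V_mV + self.V_rest_mV

    def to_dimensionless(self, V_mV):
        return (V_mV - self.V_rest_mV) / self.delta_V_mV

    def current_to_uA_cm2(self, J):
        """Scaled current (ms^-1) -> physical current density (µA cm^-2)."""
        return J * self.C_m * self.delta_V_mV


# Published parameter table: one column per cell type / reference model.
# Epi, Endo and M-cell are fits to human ventricular myocyte recordings;
# TNNP and LRd are fits to the ten Tusscher et al. human and Luo-Rudy
# dynamic guinea-pig ionic models.
_BUILTIN: dict[str, tuple] = {
    # tau_h+  tau_h-  tau_f+  tau_f-  tau_r+ tau_r-  tau_s+ tau_s-
    #  g_fi   V_fi    g_so     g_si   beta1  beta2   V1     V2
    #  g_to   V_c     V_s
    "epi": (17.9, 11.4, 123.0, 183.0, 2.51, 2.00, 57.0, 10.6,
            4.00, 1.46, 0.0161, 0.176, 3.99, 1.56, 0.529, 0.386,
            2.10, 0.130, 0.3),
    "endo": (10.8, 10.8, 355.0, 52.3, 7.54, 6.07, 29.1, 10.4,
             1.72, 1.24, 0.00891, 0.414, 22.8, 2.95, 0.522, 0.596,
             0.300, 0.130, 0.6),
    "mcell": (11.3, 1.88, 101.0, 228.0, 2.15, 0.371, 4.67, 1.75,
              2.62, 1.60, 0.0278, 0.103, 27.1, 6.12, 0.668, 1.08,
              1.36, 0.130, 0.3),
    "tnnp": (90.5, 6.61, 43.1, 181.0, 13.5, 2.20, 99.9, 4.34,
             14.0, 1.18, 0.0498, 0.138, 11.8, 8.05, 0.200, 1.02,
             9.82, 0.350, 0.6),
    "lrd": (25.8, 0.950, 488.0, 25.4, 5.10, 13.1, 300.0, 7.11,
            10.0, 1.20, 0.0316, 2.32, 6.90, 6.36, 0.453, 0.828,
            2.50, 0.380, 0.6),
}

_ALIASES = {"m-cell": "mcell", "m_cell": "mcell", "tnnp-fit": "tnnp",
            "lrd-fit": "lrd", "epicardial": "epi", "endocardial": "endo"}


def builtin_set_names() -> tuple[str, ...]:
    return tuple(_BUILTIN)


def builtin_set_path(name: str) -> Path:
    """Path of the shipped YAML file for a built-in set (one file per
    published table column); equivalent to ``builtin_set(name)`` via
    ``load_parameters``."""
    key = _ALIASES.get(name.strip().lower(), name.strip().lower())
    path = Path(__file__).parent / "parameter_sets" / f"{key}.yaml"
    if not path.exists():
        raise KeyError(f"no shipped parameter file for {name!r}")
    return path


def builtin_set(name: str, **overrides) -> ModelParameters:
    """Return a built-in parameter set by name (epi, endo, mcell, tnnp, lrd)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _BUILTIN:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {', '.join(_BUILTIN)}")
    values = dict(zip(_TABLE_FIELDS, _BUILTIN[key]))
    values["label"] = key
    values.update(overrides)
    return ModelParameters(**values)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter set from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s): {sorted(unknown)}")
    missing = set(_TABLE_FIELDS) - set(raw)
    if missing:
        raise ValueError(f"{path}: missing parameter(s): {sorted(missing)}")
    return ModelParameters(**raw)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
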