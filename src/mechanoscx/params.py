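"""Model parameters: rate constants, Hill transduction, pool sizes.

The network couples two stimuli to the fibrogenic transcription factor
Scleraxis (SCX): a hydrostatic-pressure envelope acting through a Hill-type
integrin/FAK transduction step, and an MGF (mechano-growth factor) ligand
bolus acting through Fyn.  Each kinase (FAK, Fyn, ERK, p38) is a conserved
two-state pool of ``N`` molecules switching between inactive and active
(phosphorylated) forms; SCX is produced and degraded without conservation.

All first-order rates are per hour; pressure in kPa; copy numbers in
molecules per cell.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "RATE_NAMES",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "default_parameter_metadata",
]

#: Names of the first-order rate constants (per hour).  These are the
#: quantities that calibration searches over and robustness scans perturb;
#: the Hill shape (K_hill, h_hill), the crosstalk weight and the pool sizes
#: are structural and held fixed.
RATE_NAMES: tuple[str, ...] = (
    "k_f0", "k_fP", "k_fd",
    "k_y0", "k_yM", "k_yP", "k_yd",
    "k_p0", "k_pF", "k_pd",
    "k_e0", "k_eY", "k_ed",
    "k_s0", "k_sE", "k_sP",
    "gamma_s", "delta_m",
)


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the pressure/MGF -> Scleraxis network.

    Attributes
    ----------
    k_f0, k_fP, k_fd
        FAK basal activation, pressure-driven activation (scaled by the Hill
        response), and deactivation rates (1/h).
    k_y0, k_yM, k_yP, k_yd
        Fyn basal, MGF-driven (scaled by MGF/M_ref), pressure-driven
        activation and deactivation rates (1/h).
    k_p0, k_pF, k_pd
        p38 basal and FAK-driven (scaled by active-FAK fraction) activation,
        and deactivation rates (1/h).
    k_e0, k_eY, k_ed
        ERK basal and Fyn-driven activation, and deactivation rates (1/h).
    k_s0, k_sE, k_sP
        Scleraxis production: basal (copies/h) and per active ERK / p38
        molecule (copies/h each).
    gamma_s
        Scleraxis first-order degradation rate (1/h).
    delta_m
        MGF ligand clearance rate (1/h).
    K_hill, h_hill
        Pressure half-saturation (kPa) and Hill coefficient of the
        integrin/FAK mechanotransduction step.
    w_cross
        Weight of the Fyn->FAK crosstalk edge (0 disables it).
    N_fak, N_fyn, N_erk, N_p38
        Total copy number of each conserved kinase pool.
    M_ref
        MGF copy-number normalisation constant.
    """

    k_f0: float
    k_fP: float
    k_fd: float
    k_y0: float
    k_yM: float
    k_yP: float
    k_yd: float
    k_p0: float
    k_pF: float
    k_pd: float
    k_e0: float
    k_eY: float
    k_ed: float
    k_s0: float
    k_sE: float
    k_sP: float
    gamma_s: float
    delta_m: float
    K_hill: float = 100.0
    h_hill: float = 2.0
    w_cross: float = 2.0
    N_fak: int = 1000
    N_fyn: int = 1000
    N_erk: int = 1000
    N_p38: int = 1000
    M_ref: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any out-of-range field."""
        errors = []
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                errors.append(f"{name} must be a finite non-negative rate, got {v!r}")
        if not self.K_hill > 0:
            errors.append(f"K_hill must be > 0, got {self.K_hill!r}")
        if not self.h_hill >= 1:
            errors.append(f"h_hill must be >= 1, got {self.h_hill!r}")
        if self.w_cross < 0:
            errors.append(f"w_cross must be >= 0, got {self.w_cross!r}")
        for name in ("N_fak", "N_fyn", "N_erk", "N_p38"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n > 0):
                errors.append(f"{name} must be a positive integer, got {n!r}")
        if not self.M_ref > 0:
            errors.append(f"M_ref must be > 0, got {self.M_ref!r}")
        if errors:
            raise ValueError("invalid ParameterSet: " + "; ".join(errors))

    # -- conversions -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def rates(self) -> dict[str, float]:
        """The rate constants as an ordered name -> value mapping."""
        return {name: float(getattr(self, name)) for name in RATE_NAMES}

    def with_rates(self, rates: Mapping[str, float]) -> "ParameterSet":
        unknown = set(rates) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate names: {sorted(unknown)}")
        return self.replace(**{k: float(v) for k, v in rates.items()})

    def perturbed(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Multiply each named rate constant by its factor."""
        return self.with_rates(
            {k: getattr(self, k) * f for k, f in factors.items()}
        )

    def pack(self) -> np.ndarray:
        """Flat float64 vector consumed by the simulation kernels.

        Layout: the 18 rates in ``RATE_NAMES`` order, then K_hill, h_hill,
        w_cross, N_fak, N_fyn, N_erk, N_p38, M_ref.
        """
        tail = (self.K_hill, self.h_hill, self.w_cross,
                self.N_fak, self.N_fyn, self.N_erk, self.N_p38, self.M_ref)
        return np.array([getattr(self, n) for n in RATE_NAMES] + list(tail),
                        dtype=np.float64)


def _coerce(raw: Mapping) -> ParameterSet:
    fields = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    kwargs = {}
    for k, v in raw.items():
        if k.startswith("N_"):
            iv = int(v)
            if iv != v:
                raise ValueError(f"{k} must be an integer, got {v!r}")
            kwargs[k] = iv
        else:
            kwargs[k] = float(v)
    return ParameterSet(**kwargs)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a ParameterSet from a YAML (or JSON) mapping file.

    The file may carry a top-level ``parameters:`` mapping with sibling
    metadata keys, or be a bare mapping of field names.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    if "parameters" in raw:
        raw = raw["parameters"]
    return _coerce(raw)


def save_parameters(params: ParameterSet, path: str | Path,
                    metadata: Mapping | None = None) -> None:
    """Write a ParameterSet (plus optional provenance metadata) to YAML."""
    doc: dict = {"parameters": params.to_dict()}
    if metadata:
        doc["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _default_path(name: str):
    return importlib.resources.files("mechanoscx.data").joinpath(name)


def default_parameters() -> ParameterSet:
    """The shipped calibrated default parameter set.

    Produced by the constraint-based calibration search (see
    :mod:`mechanoscx.calibrate`); its generating seed, sampling bounds and
    constraint margins are recorded in the accompanying metadata file.
    """
    with importlib.resources.as_file(_default_path("params_default.yaml")) as p:
        return load_parameters(p)


def default_parameter_metadata() -> dict:
    """Provenance and pinned behavioural margins of the shipped defaults."""
    with importlib.resources.as_file(_default_path("params_default.meta.json")) as p:
        return json.loads(Path(p).read_text())
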