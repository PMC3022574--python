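"""Model constants and numerical controls.

All quantities carry fixed units, documented per field:
rates in s^-1 (the plus-end on-rate constant in uM^-1 s^-1), lengths in um,
concentrations in uM, forces in pN, the diffusion coefficient in um^2 s^-1.
``eta`` converts between uM and um^-3 and is not overridable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "NumericalControls",
    "ConfigurationError",
    "load_parameters",
    "filament_force",
    "nucleation_rate",
]

#: uM <-> um^-3 conversion (1 uM = 602.2 molecules per um^3); fixed.
ETA = 602.2

#: Reference capping rate (s^-1) at which the tabulated plus-end density B is
#: defined.  The leading-edge nucleation rate N0 = B * R_CAP_REF is held fixed
#: in capping-rate scans, so that B_eff = N0 / r_cap varies with r_cap.
R_CAP_REF = 1.0


class ConfigurationError(ValueError):
    """Unknown configuration key or malformed config document."""


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical constants of the treadmilling-network model.

    Defaults are the literature-derived baseline of the model.  ``delta_p``
    is the x-projected length increment per subunit; the +/-35 degree mean
    filament orientation is already folded into it.
    """

    k_on_plus: float = 12.0      # uM^-1 s^-1, plus-end on-rate constant
    k_off_plus: float = 1.4      # s^-1, plus-end off-rate
    k_off_minus: float = 0.3     # s^-1, ADP-actin minus-end off-rate
    s_ac: float = 30.0           # dimensionless, ADF/cofilin off-rate enhancement
    L_sys: float = 10.0          # um, system (lamellipodium+lamellum) length
    h: float = 0.17              # um, sheet height
    delta_p: float = 0.0022      # um, projected length increment per subunit
    D: float = 5.0               # um^2 s^-1, G-actin diffusion coefficient
    A: float = 350.0             # uM, mean total actin over the system
    B: float = 440.0             # uM, plus-end density at the leading edge
    F_mem: float = 100.0         # pN um^-1, membrane resistance per edge length
    r_cap: float = 1.0           # s^-1, plus-end capping rate
    r_ac: float = 0.5            # s^-1, ADF/cofilin binding rate
    r_ac_minus: float = 0.2      # s^-1, ADF/cofilin unbinding rate
    r_tm: float = 0.2            # s^-1, tropomyosin binding rate
    r_hyd: float = 0.3           # s^-1, hydrolysis + Pi-release cascade
    r_deb: float = 0.5           # s^-1, debranching rate
    eta: float = ETA             # uM^-1 um^-3, fixed unit conversion
    kBT: float = 4.1e-3          # pN um, thermal energy (~298 K)

    # fields that may legitimately be zero (switched-off reactions)
    _ZERO_OK = frozenset(
        {"r_cap", "r_ac", "r_ac_minus", "r_tm", "r_hyd", "r_deb", "k_off_plus"}
    )

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{f.name} must be a finite number, got {v!r}")
            lo_ok = v >= 0.0 if f.name in self._ZERO_OK else v > 0.0
            if not lo_ok:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if self.s_ac < 1.0:
            raise ValueError(f"s_ac must be >= 1, got {self.s_ac}")
        if abs(self.eta - ETA) > 1e-9:
            raise ValueError("eta is a fixed unit conversion and cannot be overridden")
        # capping must be active: the filament population is exponential in t_uc
        if self.r_cap <= 0.0:
            raise ValueError("r_cap must be strictly positive")

    def replace(self, **overrides: float) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass(frozen=True)
class NumericalControls:
    """Discretization and fixed-point iteration controls.

    ``dx`` defaults to 0.02 um; unconfined drivers coarsen it to 0.1 um.
    ``dtau_c`` is the capping-time spacing between filament groups; ``None``
    means "equal to dt" (confined) or "10*dt" (unconfined driver default).
    ``t_uc_max`` truncates the exponential uncapped-time distribution; ``None``
    means 10/r_cap.  ``tau_c_max`` is adaptive (complete depolymerization of the
    oldest group) unless set.
    """

    dx: float = 0.02             # um
    dt: float = 0.01             # s
    c0_tolerance: float = 0.05   # uM, fixed-point stop (50 nM)
    c0_initial: float = 10.0     # uM
    damping: float = 0.5         # in (0, 1]
    t_uc_max: float | None = None   # s; None -> 10 / r_cap
    tau_c_max: float | None = None  # s; None -> adaptive
    dtau_c: float | None = None     # s; None -> dt (confined drivers)
    max_iterations: int = 200
    length_threshold: float = 5.0   # uM, network-length cutoff

    def __post_init__(self) -> None:
        for name in ("dx", "dt", "c0_tolerance", "c0_initial", "length_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        for name in ("t_uc_max", "tau_c_max", "dtau_c"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when set")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def replace(self, **overrides: Any) -> "NumericalControls":
        return dataclasses.replace(self, **overrides)

    def resolved_t_uc_max(self, p: ModelParameters) -> float:
        return self.t_uc_max if self.t_uc_max is not None else 10.0 / p.r_cap

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParameters) if not f.name.startswith("_")}


def load_parameters(config: str | Path | Mapping[str, float] | None = None) -> ModelParameters:
    """Return baseline parameters overlaid with ``config`` overrides.

    ``config`` may be a mapping, a path to a flat YAML/JSON document, or
    ``None`` (pure defaults).  Keys must be ``ModelParameters`` field names;
    unknown keys raise :class:`ConfigurationError`, invalid values raise
    ``ValueError``.
    """
    if config is None:
        return ModelParameters()
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ConfigurationError("config document must be a flat key-value mapping")
        config = doc
    unknown = set(config) - _FIELD_NAMES
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in config.items()})


def filament_force(B: float, p: ModelParameters) -> float:
    """Load per pushing filament, f = F_mem / (B h delta_p eta), in pN.

    ``B`` is the plus-end density at the leading edge in uM.  With baseline
    values this is ~1 pN per filament.
    """
    if B <= 0:
        raise ValueError("B must be > 0")
    return p.F_mem / (B * p.h * p.delta_p * p.eta)


def nucleation_rate(p: ModelParameters) -> float:
    """Leading-edge nucleation rate N0 = B * r_cap_ref in uM s^-1.

    The tabulated B is the plus-end density observed at the reference capping
    rate (1 s^-1); the nucleation rate implied by it is held constant when the
    capping rate is varied, so that scans probe B_eff = N0 / r_cap.
    """
    return p.B * R_CAP_REF
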