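"""Shared physical constants and kinetic configuration.

All temperature-dependent Rubisco kinetic parameters follow the same
exponential (Arrhenius-type) form ``exp(c - Ha/(R*T))`` with a dimensionless
scaling constant ``c`` and an activation energy ``Ha`` in kJ/mol.  The
default constants are on a mole-fraction basis: the commonly tabulated
partial-pressure constants were converted at standard atmospheric pressure
(101.325 kPa), which shifts ``c`` by ln(1e6/101325) = 2.2894 for a
Pa -> umol/mol conversion (and identically for kPa -> mmol/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import core
from .core import H2O_CO2_DIFFUSIVITY, R_GAS  # noqa: F401  (re-exported)

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class ArrheniusConstants:
    """Scaling constant (dimensionless) and activation energy (kJ/mol)."""

    c: float
    Ha: float

    def at(self, tleaf_k: float):
        """Evaluate the parameter at a leaf temperature in Kelvin."""
        return core.arrhenius_parameter(self.c, self.Ha, tleaf_k)


# Tomato chloroplastic CO2 compensation point (umol/mol at 25 C: 28.24).
GAMMA_STAR_TOMATO = ArrheniusConstants(c=12.7, Ha=23.2)
# Rubisco Michaelis constant for CO2, mole-fraction basis, umol/mol
# (268.9 umol/mol at 25 C).
KC_DEFAULT = ArrheniusConstants(c=38.2668, Ha=80.99)
# Rubisco Michaelis constant for O2, mole-fraction basis, mmol/mol
# (163.7 mmol/mol at 25 C).
KO_DEFAULT = ArrheniusConstants(c=14.6666, Ha=23.72)


@dataclass(frozen=True)
class PhotoConfig:
    """Leaf-level constants used across the pipeline.

    alpha
        Leaf absorptance (dimensionless), default 0.84.
    beta
        Partitioning of absorbed quanta between the photosystems, default 0.5.
    O_mmol_mol
        Atmospheric O2 mole fraction, mmol/mol, default 210.
    gamma_star, Kc, Ko
        Arrhenius constants for the kinetic parameters; see module docstring
        for the unit basis.
    """

    alpha: float = 0.84
    beta: float = 0.5
    O_mmol_mol: float = 210.0
    gamma_star: ArrheniusConstants = field(default=GAMMA_STAR_TOMATO)
    Kc: ArrheniusConstants = field(default=KC_DEFAULT)
    Ko: ArrheniusConstants = field(default=KO_DEFAULT)

    def gamma_star_at(self, tleaf_k: float):
        return self.gamma_star.at(tleaf_k)

    def kc_at(self, tleaf_k: float):
        return self.Kc.at(tleaf_k)

    def ko_at(self, tleaf_k: float):
        return self.Ko.at(tleaf_k)

    def with_updates(self, **kwargs: Any) -> "PhotoConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PhotoConfig":
        """Build a config from flat or nested keys.

        Accepts ``alpha``, ``beta``, ``O_mmol_mol`` and either nested
        ``gamma_star: {c: ..., Ha: ...}`` mappings or dotted flat keys
        (``gamma_star.c`` etc.) for the three kinetic parameters.
        """
        known = {"alpha", "beta", "O_mmol_mol", "gamma_star", "Kc", "Ko"}
        kwargs: dict[str, Any] = {}
        nested: dict[str, dict[str, float]] = {}
        for key, value in data.items():
            if "." in key:
                name, part = key.split(".", 1)
                if name not in {"gamma_star", "Kc", "Ko"} or part not in {"c", "Ha"}:
                    raise KeyError(f"unknown config key: {key!r}")
                nested.setdefault(name, {})[part] = float(value)
            elif key in {"gamma_star", "Kc", "Ko"}:
                if isinstance(value, ArrheniusConstants):
                    kwargs[key] = value
                else:
                    kwargs[key] = ArrheniusConstants(
                        c=float(value["c"]), Ha=float(value["Ha"])
                    )
            elif key in known:
                kwargs[key] = float(value)
            else:
                raise KeyError(f"unknown config key: {key!r}")
        base = cls(**kwargs)
        for name, parts in nested.items():
            current: ArrheniusConstants = getattr(base, name)
            base = replace(
                base,
                **{
                    name: ArrheniusConstants(
                        c=parts.get("c", current.c), Ha=parts.get("Ha", current.Ha)
                    )
                },
            )
        return base

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhotoConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "O_mmol_mol": self.O_mmol_mol,
            "gamma_star": {"c": self.gamma_star.c, "Ha": self.gamma_star.Ha},
            "Kc": {"c": self.Kc.c, "Ha": self.Kc.Ha},
            "Ko": {"c": self.Ko.c, "Ha": self.Ko.Ha},
        }


DEFAULT_CONFIG = PhotoConfig()
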