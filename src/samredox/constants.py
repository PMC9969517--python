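"""Physical constants and energy-unit conversions.

The internal canonical energy unit is the electronvolt; electrode potentials
are volts. Every half-reaction treated by this package transfers exactly one
electron, so 1 eV of free-energy change corresponds numerically to 1 V of
potential ("V*e" is accepted as a unit alias for that bookkeeping).

Two temperatures coexist deliberately: ``t_marcus`` (the thermostat
temperature of the sampling dynamics, used in the 2*kB*T reorganization
factor) and ``t_thermo`` (standard-state thermochemistry, used for the
gas-phase electron free energy).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import scipy.constants as _sc

#: Boltzmann constant, eV/K.
K_B_EV: float = _sc.value("Boltzmann constant in eV/K")

#: Coulomb prefactor e^2/(4 pi eps0), in eV * Angstrom per e^2.
COULOMB_EV_ANGSTROM: float = (
    _sc.e / (4.0 * _sc.pi * _sc.epsilon_0) * 1e10
)

_HARTREE_EV = _sc.value("Hartree energy in eV")
_EV_KJ_MOL = _sc.e * _sc.N_A / 1e3
_EV_KCAL_MOL = _EV_KJ_MOL / 4.184

# Conversion factors to the canonical unit (eV).
_TO_EV: dict[str, float] = {
    "eV": 1.0,
    "hartree": _HARTREE_EV,
    "kcal/mol": 1.0 / _EV_KCAL_MOL,
    "kJ/mol": 1.0 / _EV_KJ_MOL,
    # one electron transferred: an energy of x eV maps to x V*e
    "V*e": 1.0,
}

_ALIASES = {
    "ev": "eV",
    "au": "hartree",
    "ha": "hartree",
    "hartree": "hartree",
    "kcal/mol": "kcal/mol",
    "kcal_mol": "kcal/mol",
    "kj/mol": "kJ/mol",
    "kj_mol": "kJ/mol",
    "v*e": "V*e",
    "ve": "V*e",
}


class UnitError(ValueError):
    """Raised for unrecognized energy unit names."""


def _canonical(unit: str) -> str:
    key = unit.strip().lower().replace("·", "*")
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnitError(
            f"unknown energy unit {unit!r}; supported: {sorted(_TO_EV)}"
        ) from None


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between supported units.

    Supported units: hartree, eV, kcal/mol, kJ/mol, V*e (case-insensitive).
    Round trips are identities to machine precision.
    """
    src = _canonical(from_unit)
    dst = _canonical(to_unit)
    if src == dst:
        return float(value)
    return float(value) * _TO_EV[src] / _TO_EV[dst]


@dataclass
class Constants:
    """Configurable physical-reference record.

    Parameters
    ----------
    e_she:
        Absolute potential of the standard hydrogen electrode, V. The
        default 4.281 V already accounts for the gas-phase electron free
        energy under Fermi-Dirac statistics.
    g_electron_gas:
        Standard-state Gibbs free energy of the gas-phase electron,
        kcal/mol (Fermi-Dirac value at 298.15 K).
    t_marcus:
        Temperature of the sampling ensemble, K (thermostat setting).
    t_thermo:
        Standard thermochemistry temperature, K.
    k_b:
        Boltzmann constant, eV/K.
    faraday:
        eV-per-electron to volt identity for a one-electron process.
    """

    e_she: float = 4.281
    g_electron_gas: float = -0.867  # kcal/mol
    t_marcus: float = 300.0
    t_thermo: float = 298.15
    k_b: float = K_B_EV
    faraday: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e_she", "t_marcus", "t_thermo", "k_b", "faraday"):
            if not getattr(self, name) > 0:
                raise ValueError(f"constant {name} must be positive")

    @property
    def kbt_marcus(self) -> float:
        """kB*T at the sampling temperature, eV."""
        return self.k_b * self.t_marcus

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Constants":
        return cls(**data)


#: Module-level default constants record.
DEFAULT_CONSTANTS = Constants()
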