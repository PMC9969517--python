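"""Direct static reduction potentials for optimized species.

For a one-electron half-reaction Ox + e- -> Red, the free energy of each
species is G = E_e + G_T (electronic energy plus thermal Gibbs correction,
both supplied by an external electronic-structure calculation), and

    E_red = -dG_red / (n F) - E_SHE,        n = 1

with E_SHE the absolute standard-hydrogen-electrode potential (default
4.281 V). That reference value already folds in the Fermi-Dirac free
energy of the gas-phase electron, G(e-, 298.15 K) = -0.867 kcal/mol, which
this module can also compute from first principles for verification.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import scipy.constants as sc
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from .constants import Constants, DEFAULT_CONSTANTS, convert_energy
from .model import ThermoSpecies

__all__ = [
    "gibbs_free_energy",
    "reduction_free_energy",
    "potential_from_free_energy",
    "electron_gas_free_energy",
    "electron_gas_thermodynamics",
]


def gibbs_free_energy(sp: ThermoSpecies) -> float:
    """G = E_e + G_T, in the unit the species record carries (hartree)."""
    return sp.electronic_energy + sp.thermal_correction


def reduction_free_energy(
    ox: ThermoSpecies,
    red: ThermoSpecies,
    include_electron: bool = True,
    constants: Constants = DEFAULT_CONSTANTS,
    unit: str = "hartree",
) -> float:
    """Free energy of Ox + e- -> Red.

    dG_red = G(Red) - G(Ox) - G(e-,gas); the electron term (Fermi-Dirac
    constant from the configuration record) is subtracted only when
    ``include_electron`` is true. Input species are in hartree; the result
    is returned in ``unit``.
    """
    dg_hartree = gibbs_free_energy(red) - gibbs_free_energy(ox)
    if include_electron:
        dg_hartree -= convert_energy(
            constants.g_electron_gas, "kcal/mol", "hartree"
        )
    return convert_energy(dg_hartree, "hartree", unit)


def potential_from_free_energy(
    dg: float,
    e_ref: Optional[float] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    unit: str = "eV",
) -> float:
    """Reduction potential E_red = -dG/(nF) - E_ref for n = 1 electron.

    ``dg`` is the reduction free energy in ``unit``; the one-electron
    Faraday factor makes eV numerically equal to V.
    """
    if e_ref is None:
        e_ref = constants.e_she
    dg_ev = convert_energy(dg, unit, "eV")
    return -dg_ev / constants.faraday - e_ref


# ---------------------------------------------------------------------------
# Fermi-Dirac thermodynamics of the free-electron gas
# ---------------------------------------------------------------------------

_STANDARD_PRESSURE = 1.0e5  # Pa (1 bar)


def _fd_integral_log(s: float, ln_z: float) -> float:
    """Complete Fermi-Dirac integral f_s(z) for z = exp(ln_z).

    f_s(z) = 1/Gamma(s) * int_0^inf x^(s-1) / (exp(x - ln z) + 1) dx,
    evaluated by adaptive quadrature in log-fugacity so both the classical
    (z << 1) and degenerate (ln z >> 1) regimes are reachable.
    """

    def integrand(x: float) -> float:
        return x ** (s - 1.0) / (math.exp(min(x - ln_z, 700.0)) + 1.0)

    split = max(ln_z, 1.0)
    head, _ = quad(integrand, 0.0, split, limit=200)
    tail, _ = quad(integrand, split, np.inf, limit=200)
    return (head + tail) / _gamma(s)


def _fd_integral(s: float, z: float) -> float:
    """Complete Fermi-Dirac integral f_s(z) = -Li_s(-z), z > 0."""
    if z <= 0:
        raise ValueError("fugacity must be positive")
    return _fd_integral_log(s, math.log(z))


def _fermi_energy_at_pressure(pressure: float) -> float:
    """T = 0 Fermi energy (J) of the spin-1/2 electron gas at pressure P.

    At T = 0 the degenerate gas obeys P = (2/5) n E_F with
    n = (2 m E_F / hbar^2)^(3/2) / (3 pi^2).
    """

    def p_of_ef(ef: float) -> float:
        n = (2.0 * sc.m_e * ef / sc.hbar**2) ** 1.5 / (3.0 * math.pi**2)
        return 0.4 * n * ef

    return brentq(lambda ef: p_of_ef(ef) - pressure, 1e-26, 1e-17, xtol=1e-32)


def electron_gas_thermodynamics(
    temperature: float = 298.15, pressure: float = _STANDARD_PRESSURE
) -> dict[str, float]:
    """Fermi-Dirac ideal-gas thermodynamics of the electron at (T, P).

    The electron (mass m_e, spin multiplicity 2) is treated as an ideal
    Fermi gas. The fugacity z solves the fixed-pressure condition
    P lambda^3/(g kT) = f_{5/2}(z) with lambda the thermal de Broglie
    wavelength; then per mole

        H(T) = (5/2) R T f_{5/2}(z)/f_{3/2}(z),   G_mu = R T ln z,
        S = (H - G_mu)/T.

    Enthalpy is referenced thermochemically to the T = 0 state of the gas
    at the same pressure (the degenerate Fermi sea, H_0 = N_A E_F), so the
    reported free energy is G = (H - H_0) - T S. At 298.15 K and 1 bar this
    yields H - H_0 = 0.752 kcal/mol, S = 5.43 cal/(mol K) and
    G = -0.868 kcal/mol.

    Returns a dict with ``enthalpy``, ``entropy`` (per kelvin), and
    ``gibbs``, all in eV per electron, plus the fugacity ``z``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    g_spin = 2.0
    kt = sc.k * temperature
    lam = sc.h / math.sqrt(2.0 * math.pi * sc.m_e * kt)
    a = pressure * lam**3 / (g_spin * kt)
    ln_z = brentq(lambda lz: _fd_integral_log(2.5, lz) - a, -60.0, 400.0)
    f52 = _fd_integral_log(2.5, ln_z)
    f32 = _fd_integral_log(1.5, ln_z)
    h = 2.5 * kt * f52 / f32  # J per electron
    g_mu = kt * ln_z
    s = (h - g_mu) / temperature
    h0 = _fermi_energy_at_pressure(pressure)  # H0/N = E_F at T=0
    j_to_ev = 1.0 / sc.e
    return {
        "enthalpy": (h - h0) * j_to_ev,
        "entropy": s * j_to_ev,
        "gibbs": ((h - h0) - temperature * s) * j_to_ev,
        "fugacity": math.exp(ln_z),
    }


def electron_gas_free_energy(
    temperature: float = 298.15,
    pressure: float = _STANDARD_PRESSURE,
    unit: str = "kcal/mol",
) -> float:
    """Standard-state Gibbs free energy of the gas-phase electron.

    Computed from Fermi-Dirac statistics (see
    :func:`electron_gas_thermodynamics`); -0.867 kcal/mol at 298.15 K.
    """
    g_ev = electron_gas_thermodynamics(temperature, pressure)["gibbs"]
    return convert_energy(g_ev, "eV", unit)
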