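"""Seminario-method bonded force constants from a Cartesian Hessian.

The classic construction works on the 3x3 interatomic sub-blocks of the
Hessian: for a bond i-j the eigenvalues of -H_ij projected on the unit bond
vector give the stretch constant, and for an angle i-j-k (apex j) the
perpendicular in-plane projections of the two terminal blocks combine in
inverse-addition form. Equilibrium values are read from the input geometry,
never refit. All outputs are invariant under rigid motions of the molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import convert_energy
from .model import SAMSystem

__all__ = [
    "HessianMatrix",
    "BondParam",
    "AngleParam",
    "Restraint",
    "seminario_bond",
    "seminario_angle",
    "restraint_spec",
    "read_hessian",
    "write_params",
    "read_charges",
]

BOHR_ANGSTROM = 0.529177210903

#: Default positional restraint on S and Au atoms, kcal/(mol A^2).
RESTRAINT_K = 50.0


class DisconnectedPairError(ValueError):
    pass


@dataclass
class HessianMatrix:
    """3N x 3N Cartesian second-derivative matrix with its geometry.

    ``units`` names the Hessian energy/length^2 unit; the readers accept
    ``hartree/bohr^2`` (quantum-chemistry convention) or
    ``kcal/mol/angstrom^2``.
    """

    entries: np.ndarray
    geometry: np.ndarray
    units: str = "hartree/bohr^2"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 3)
        n3 = 3 * len(self.geometry)
        if self.entries.shape != (n3, n3):
            raise ValueError(
                f"Hessian shape {self.entries.shape} inconsistent with "
                f"{len(self.geometry)} atoms"
            )
        if not np.allclose(self.entries, self.entries.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric within 1e-8")

    def block(self, i: int, j: int) -> np.ndarray:
        """3x3 sub-block d^2 E / (dr_i dr_j) in kcal/(mol A^2)."""
        sub = self.entries[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
        return sub * _to_kcal_angstrom(self.units)


def _to_kcal_angstrom(units: str) -> float:
    key = units.strip().lower().replace(" ", "")
    if key in ("hartree/bohr^2", "hartree/bohr2", "au"):
        return convert_energy(1.0, "hartree", "kcal/mol") / BOHR_ANGSTROM**2
    if key in ("kcal/mol/angstrom^2", "kcal/mol/a^2", "kcal/(mola^2)"):
        return 1.0
    raise ValueError(f"unknown Hessian units {units!r}")


@dataclass
class BondParam:
    i: int
    j: int
    k: float  # kcal/(mol A^2)
    r0: float  # Angstrom

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("bond force constant must be non-negative")


@dataclass
class AngleParam:
    i: int
    j: int  # apex
    k_atom: int
    k: float  # kcal/(mol rad^2)
    theta0: float  # degrees


def _projected_eigensum(block: np.ndarray, direction: np.ndarray) -> float:
    """Sum over eigenpairs of -block of eigenvalue * |eigvec . direction|."""
    vals, vecs = np.linalg.eig(-block)
    vals, vecs = np.real(vals), np.real(vecs)
    return float(sum(vals[m] * abs(np.dot(vecs[:, m], direction)) for m in range(3)))


def seminario_bond(h: HessianMatrix, i: int, j: int) -> BondParam:
    """Stretch constant for bond i-j from the interatomic Hessian block.

    The (i,j) and (j,i) block estimates are averaged; the equilibrium
    length is the input interatomic distance.
    """
    if i == j:
        raise ValueError("bond requires two distinct atoms")
    rij = h.geometry[j] - h.geometry[i]
    r0 = float(np.linalg.norm(rij))
    u = rij / r0
    bij = h.block(i, j)
    if np.allclose(bij, 0.0, atol=1e-12):
        raise DisconnectedPairError(f"atoms {i} and {j} share no Hessian coupling")
    k_ij = _projected_eigensum(bij, u)
    k_ji = _projected_eigensum(h.block(j, i), u)
    return BondParam(i=i, j=j, k=0.5 * (k_ij + k_ji), r0=r0)


def seminario_angle(h: HessianMatrix, i: int, j: int, k: int) -> AngleParam:
    """Bending constant for angle i-j-k (apex j).

    Perpendicular projections in the i-j-k plane of the two terminal-apex
    blocks combine as 1/k_theta = sum_t 1/(r_t^2 * projected eigensum).
    Collinear atoms have no defined bending plane.
    """
    r_ji = h.geometry[i] - h.geometry[j]
    r_jk = h.geometry[k] - h.geometry[j]
    d_ji, d_jk = np.linalg.norm(r_ji), np.linalg.norm(r_jk)
    u_ji, u_jk = r_ji / d_ji, r_jk / d_jk
    normal = np.cross(u_jk, u_ji)
    n_norm = np.linalg.norm(normal)
    if n_norm < 1e-8:
        raise ValueError("collinear atoms: angle plane undefined")
    u_n = normal / n_norm
    u_pa = np.cross(u_n, u_ji)  # in-plane, perpendicular to j-i bond
    u_pc = np.cross(u_jk, u_n)  # in-plane, perpendicular to j-k bond

    term_i = d_ji**2 * _projected_eigensum(h.block(i, j), u_pa)
    term_k = d_jk**2 * _projected_eigensum(h.block(k, j), u_pc)
    if term_i <= 0 or term_k <= 0:
        raise DisconnectedPairError("terminal atoms decoupled from the apex")
    k_theta = 1.0 / (1.0 / term_i + 1.0 / term_k)
    theta0 = math.degrees(math.acos(float(np.clip(np.dot(u_ji, u_jk), -1.0, 1.0))))
    return AngleParam(i=i, j=j, k_atom=k, k=k_theta, theta0=theta0)


# ---------------------------------------------------------------------------
# Positional restraints
# ---------------------------------------------------------------------------

@dataclass
class Restraint:
    atom_index: int
    element: str
    k: float  # kcal/(mol A^2)
    reference: np.ndarray = field(default_factory=lambda: np.zeros(3))


def restraint_spec(system: SAMSystem, k: float = RESTRAINT_K) -> list[Restraint]:
    """One positional restraint per S and per Au atom at its current position.

    The dynamics has no bonded Au-S interaction, so both partners of the
    anchoring contact are held by a harmonic restraint (default
    50 kcal/(mol A^2)) for the entire protocol.
    """
    out = []
    for idx, a in enumerate(system.atoms):
        if a.element.upper() in ("S", "AU"):
            out.append(
                Restraint(
                    atom_index=idx,
                    element=a.element,
                    k=k,
                    reference=a.position.copy(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O: engine-neutral plain-text formats
# ---------------------------------------------------------------------------

def read_hessian(path: str | Path, geometry: Sequence[Sequence[float]]) -> HessianMatrix:
    """Read a whitespace-delimited Hessian (lower-triangular or full square).

    The first line may declare units as ``# units: <name>``; the default is
    hartree/bohr^2.
    """
    path = Path(path)
    units = "hartree/bohr^2"
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line:
                    units = line.split("units:", 1)[1].strip()
                continue
            values.extend(float(tok) for tok in line.split())
    geometry = np.asarray(geometry, dtype=float).reshape(-1, 3)
    n3 = 3 * len(geometry)
    if len(values) == n3 * n3:
        entries = np.array(values).reshape(n3, n3)
    elif len(values) == n3 * (n3 + 1) // 2:
        entries = np.zeros((n3, n3))
        it = iter(values)
        for r in range(n3):
            for c in range(r + 1):
                entries[r, c] = next(it)
        entries = entries + np.tril(entries, -1).T
    else:
        raise ValueError(
            f"{path}: {len(values)} entries fit neither a full {n3}x{n3} "
            f"matrix nor its lower triangle"
        )
    return HessianMatrix(entries=entries, geometry=geometry, units=units)


def write_params(
    path: str | Path,
    bonds: Sequence[BondParam] = (),
    angles: Sequence[AngleParam] = (),
    restraints: Sequence[Restraint] = (),
) -> None:
    """Write bonded parameters and restraints as a plain tabular file."""
    with Path(path).open("w") as fh:
        fh.write("# record i j k force_k equilibrium\n")
        fh.write("# bond: k in kcal/(mol A^2), r0 in A\n")
        fh.write("# angle: k in kcal/(mol rad^2), theta0 in degrees\n")
        fh.write("# restraint: k in kcal/(mol A^2), ref x y z in A\n")
        for b in bonds:
            fh.write(f"bond {b.i} {b.j} - {b.k:.10g} {b.r0:.10g}\n")
        for a in angles:
            fh.write(
                f"angle {a.i} {a.j} {a.k_atom} {a.k:.10g} {a.theta0:.10g}\n"
            )
        for r in restraints:
            ref = " ".join(f"{x:.10g}" for x in r.reference)
            fh.write(f"restraint {r.atom_index} {r.element} - {r.k:.10g} {ref}\n")


def read_params(path: str | Path) -> dict[str, list]:
    """Read back :func:`write_params` output (lossless round trip)."""
    bonds: list[BondParam] = []
    angles: list[AngleParam] = []
    restraints: list[Restraint] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if toks[0] == "bond":
                bonds.append(
                    BondParam(int(toks[1]), int(toks[2]), float(toks[4]), float(toks[5]))
                )
            elif toks[0] == "angle":
                angles.append(
                    AngleParam(
                        int(toks[1]), int(toks[2]), int(toks[3]),
                        float(toks[4]), float(toks[5]),
                    )
                )
            elif toks[0] == "restraint":
                restraints.append(
                    Restraint(
                        atom_index=int(toks[1]),
                        element=toks[2],
                        k=float(toks[4]),
                        reference=np.array([float(x) for x in toks[5:8]]),
                    )
                )
    return {"bonds": bonds, "angles": angles, "restraints": restraints}


def read_charges(
    path: str | Path, expected_net_charge: Optional[int] = None, tol: float = 1e-4
) -> dict[str, float]:
    """Read a two-column (label, charge) ESP-charge table.

    Charges are consumed, never fit here; the column sum is validated
    against the declared net charge within ``tol`` electrons.
    """
    charges: dict[str, float] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, value = line.split()[:2]
            charges[label] = float(value)
    if expected_net_charge is not None:
        total = sum(charges.values())
        if abs(total - expected_net_charge) > tol:
            raise ValueError(
                f"charge table sums to {total:.6f} e, expected "
                f"{expected_net_charge} within {tol}"
            )
    return charges
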