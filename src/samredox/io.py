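"""Structure I/O and snapshot selection.

PDB reading and writing goes through MDAnalysis. Roles are inferred from
residue names via a configurable map on input and encoded as residue names
on output. Two PDB columns are repurposed (documented convention): the
occupancy column carries the ligand id (0 for non-organic atoms) and the
B-factor column carries the MM point charge at the format's two-decimal
precision — coordinates and role labels round-trip losslessly, charges
only approximately.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, TypeVar

import numpy as np

from .model import AtomRecord, SAMSystem

__all__ = ["read_pdb", "write_pdb", "select_snapshots", "DEFAULT_ROLE_MAP"]

T = TypeVar("T")

#: residue-name -> role map used when reading PDB files
DEFAULT_ROLE_MAP: dict[str, str] = {
    "AU": "metal",
    "GLD": "metal",
    "MTL": "metal",
    "HOH": "solvent",
    "WAT": "solvent",
    "SOL": "solvent",
    "TIP": "solvent",
    "TP3": "solvent",
    "CL": "ion",
    "CLA": "ion",
    "NA": "ion",
    "SOD": "ion",
    "ION": "ion",
    "LIG": "organic",
    "GUA": "organic",
    "THI": "organic",
    "MOL": "organic",
}

_ROLE_TO_RESNAME = {
    "metal": "AU",
    "solvent": "HOH",
    "ion": "ION",
    "organic": "LIG",
}

_ION_CHARGES = {"CL": -1.0, "NA": 1.0}


def write_pdb(system: SAMSystem, path: str | Path) -> None:
    """Write a SAMSystem to PDB (ATOM records + CRYST1 box)."""
    import MDAnalysis as mda

    n = len(system.atoms)
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    resids = [a.residue_id for a in system.atoms]
    u.add_TopologyAttr("name", [a.name[:4] for a in system.atoms])
    u.add_TopologyAttr("element", [a.element for a in system.atoms])
    u.add_TopologyAttr(
        "resname", [_ROLE_TO_RESNAME[a.role] for a in system.atoms]
    )
    u.add_TopologyAttr("resid", resids)
    u.add_TopologyAttr(
        "occupancy", [float(a.ligand_id or 0) for a in system.atoms]
    )
    u.add_TopologyAttr("tempfactor", [a.charge for a in system.atoms])
    u.atoms.positions = system.positions.astype(np.float32)
    u.dimensions = [*system.box.tolist(), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(
    path: str | Path,
    role_map: Optional[dict[str, str]] = None,
    sites: Optional[np.ndarray] = None,
) -> SAMSystem:
    """Read a PDB file into a SAMSystem.

    Roles come from the residue-name map (unmapped residue names are an
    error, reported with the offending name); organic residues become one
    ligand each, with the ligand id taken from the repurposed occupancy
    column when present, else from the residue ordering. A missing CRYST1
    box is flagged.
    """
    import MDAnalysis as mda

    role_map = {**DEFAULT_ROLE_MAP, **(role_map or {})}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise ValueError(f"{path}: missing or degenerate CRYST1 box record")
    box = np.array(u.dimensions[:3], dtype=float)

    has_occ = hasattr(u.atoms, "occupancies")
    has_bf = hasattr(u.atoms, "tempfactors")
    atoms: list[AtomRecord] = []
    next_ligand_id = 1
    resid_to_lid: dict[int, int] = {}
    for k, at in enumerate(u.atoms):
        resname = str(at.resname).strip().upper()
        role = role_map.get(resname)
        if role is None:
            raise ValueError(
                f"{path}: residue name {resname!r} (atom {k + 1}) has no "
                "role mapping; extend role_map"
            )
        element = (
            str(at.element).strip()
            if hasattr(at, "element") and str(at.element).strip()
            else str(at.name).strip()[:1]
        )
        ligand_id = None
        if role == "organic":
            rid = int(at.resid)
            if rid not in resid_to_lid:
                lid_from_occ = int(round(float(at.occupancy))) if has_occ else 0
                resid_to_lid[rid] = (
                    lid_from_occ if lid_from_occ > 0 else next_ligand_id
                )
                next_ligand_id = max(next_ligand_id, resid_to_lid[rid]) + 1
            ligand_id = resid_to_lid[rid]
        charge = float(at.tempfactor) if has_bf else 0.0
        if role == "ion" and charge == 0.0:
            charge = _ION_CHARGES.get(element.upper(), 0.0)
        atoms.append(
            AtomRecord(
                element=element.capitalize(),
                name=str(at.name).strip(),
                position=np.array(at.position, dtype=float),
                role=role,  # type: ignore[arg-type]
                residue_id=int(at.resid),
                ligand_id=ligand_id,
                charge=charge,
            )
        )
    system = SAMSystem(atoms=atoms, box=box)
    if sites is not None:
        system.sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    system.validate()
    return system


def select_snapshots(
    pool: Sequence[T],
    window_fraction: float = 0.70,
    n: int = 200,
    seed: int = 0,
    return_indices: bool = False,
) -> list:
    """Seeded uniform draw from the trailing window of an ordered pool.

    Sampling is restricted to the last ``window_fraction`` of the ordered
    snapshot list (the equilibrated tail of a production trajectory, e.g.
    the last 350 of 500 ns -> 0.70), drawn uniformly without replacement.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    size = len(pool)
    start = size - int(round(window_fraction * size))
    available = size - start
    if n > available:
        raise ValueError(
            f"requested {n} snapshots but the trailing window holds only "
            f"{available} of {size}"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(np.arange(start, size), size=n, replace=False).tolist())
    if return_indices:
        return idx
    return [pool[i] for i in idx]
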