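"""Domain types shared across the package.

The atomistic container is deliberately lightweight: a flat list of
:class:`AtomRecord` with per-atom role labels (metal / organic / solvent /
ion), per-ligand grouping, and anchor-site bookkeeping. Heavy trajectory
machinery is out of scope; snapshots are simply independent
:class:`SAMSystem` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

Role = Literal["metal", "organic", "solvent", "ion"]
VALID_ROLES = ("metal", "organic", "solvent", "ion")

HEAVY = lambda element: element.upper() not in ("H", "D")  # noqa: E731


@dataclass
class AtomRecord:
    """One atom: element, label, Cartesian position (Angstrom), role.

    ``ligand_id`` is set if and only if the atom is organic. ``fragment``
    optionally labels a sub-moiety of a ligand (e.g. the nucleobase ring
    carrying the redox-active charge).
    """

    element: str
    name: str
    position: np.ndarray
    role: Role
    residue_id: int
    ligand_id: Optional[int] = None
    charge: float = 0.0
    fragment: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.role not in VALID_ROLES:
            raise ValueError(f"atom {self.name}: unknown role {self.role!r}")
        if (self.role == "organic") != (self.ligand_id is not None):
            raise ValueError(
                f"atom {self.name}: ligand_id must be set iff role is organic"
            )

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


@dataclass
class LigandGeometry:
    """A single organic ligand with a designated sulfur anchor atom."""

    atoms: list[AtomRecord]
    anchor_index: int
    charge_state: Literal["neutral", "cation"] = "neutral"
    net_charge: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.anchor_index < len(self.atoms):
            raise ValueError("anchor_index out of range")
        if self.atoms[self.anchor_index].element.upper() != "S":
            raise ValueError("anchor atom must be sulfur")
        expected = {"neutral": 0, "cation": 1}[self.charge_state]
        if self.net_charge != expected:
            raise ValueError(
                f"{self.charge_state} ligand must carry net charge {expected:+d}"
            )

    @property
    def anchor(self) -> AtomRecord:
        return self.atoms[self.anchor_index]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if HEAVY(a.element)]

    def fragment_indices(self, label: str = "nucleobase") -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.fragment == label]

    def copy(self) -> "LigandGeometry":
        return LigandGeometry(
            atoms=[a.copy() for a in self.atoms],
            anchor_index=self.anchor_index,
            charge_state=self.charge_state,
            net_charge=self.net_charge,
        )


@dataclass
class RotationSpec:
    """Axis-angle rotation (unit axis, right-hand rule)."""

    axis: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-12:
            raise ValueError("rotation axis must be a unit vector (|u| = 1)")


@dataclass
class SAMSystem:
    """Full atomistic monolayer assembly.

    ``sites`` are candidate anchor positions on the metal surface;
    ``occupied_sites`` indexes the sites that host a ligand.
    """

    atoms: list[AtomRecord]
    box: np.ndarray
    sites: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    occupied_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 3)

    # -- convenience views ------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def indices_by_role(self, role: Role) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.role == role], dtype=int
        )

    def ligand_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.role == "organic" and a.ligand_id is not None:
                seen.setdefault(a.ligand_id, None)
        return list(seen)

    def ligand_atom_indices(self, ligand_id: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.role == "organic" and a.ligand_id == ligand_id
        ]

    def anchor_index_of(self, ligand_id: int) -> int:
        """Index of the sulfur anchor atom of a ligand."""
        for i in self.ligand_atom_indices(ligand_id):
            if self.atoms[i].element.upper() == "S":
                return i
        raise ValueError(f"ligand {ligand_id} has no sulfur anchor")

    def solvent_residue_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.role == "solvent":
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_atom_indices(self, residue_id: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_id == residue_id]

    @property
    def counterions(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "ion"]

    def net_charge(self) -> int:
        return int(round(sum(a.charge for a in self.atoms)))

    def copy(self) -> "SAMSystem":
        return SAMSystem(
            atoms=[a.copy() for a in self.atoms],
            box=self.box.copy(),
            sites=self.sites.copy(),
            occupied_sites=list(self.occupied_sites),
        )

    def validate(self) -> None:
        """Check the structural invariants of the assembly."""
        for a in self.atoms:
            if a.role not in VALID_ROLES:
                raise ValueError(f"atom {a.name}: unassigned role")
        for lid in self.ligand_ids():
            self.anchor_index_of(lid)


@dataclass
class ThermoSpecies:
    """Optimized species: electronic energy + thermal Gibbs correction."""

    electronic_energy: float  # hartree by convention of the static pipeline
    thermal_correction: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.electronic_energy)
            and np.isfinite(self.thermal_correction)
        ):
            raise ValueError("ThermoSpecies energies must be finite")


@dataclass
class ChargeConstraintSpec:
    """Fragment charge constraint: where the cationic hole is localized.

    ``atom_ids`` index atoms of the reference ligand's redox-active fragment
    in the parent system; the backend must place ``target_charge`` there.
    """

    atom_ids: list[int]
    target_charge: float = 1.0
    region_label: str = "nucleobase"

    def __post_init__(self) -> None:
        if not self.atom_ids:
            raise ValueError("charge constraint needs at least one atom")


@dataclass
class EmbeddingSpec:
    """How the environment outside the quantum region is represented.

    ``mm_point_charges``: explicit point charges for everything outside the
    QM region. ``continuum``: dielectric continuum only (no explicit
    charges). ``mm_plus_continuum``: point charges for the non-solvent
    environment, continuum for the solvent (the explicit solvent is removed
    and replaced by the continuum model).

    ``shell_min_radius`` optionally restricts MM charges to molecules at
    distance >= r from a reference point (the shrinking vacuum-bubble scan).
    """

    mode: Literal["mm_point_charges", "continuum", "mm_plus_continuum"] = (
        "mm_point_charges"
    )
    continuum: bool = field(init=False)
    shell_min_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("mm_point_charges", "continuum", "mm_plus_continuum"):
            raise ValueError(f"unknown embedding mode {self.mode!r}")
        self.continuum = self.mode in ("continuum", "mm_plus_continuum")

    @property
    def includes_explicit_solvent(self) -> bool:
        # continuum embedding replaces the explicit solvent entirely
        return self.mode == "mm_point_charges"


@dataclass
class QMRegionSpec:
    """Contents of the quantum layer.

    The reference ligand (RL) is always ``ligand_ids[0]``; the remaining
    entries are neighbor ligands. Identity lists are disjoint by
    construction and counts must match list lengths.
    """

    ligand_ids: list[int]
    au_atom_ids: list[int] = field(default_factory=list)
    water_residue_ids: list[int] = field(default_factory=list)
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    constraint: Optional[ChargeConstraintSpec] = None
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_ids:
            raise ValueError("QM region must contain the reference ligand")
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("duplicate ligand ids in QM region")

    @property
    def reference_ligand(self) -> int:
        return self.ligand_ids[0]

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_au(self) -> int:
        return len(self.au_atom_ids)

    @property
    def n_waters(self) -> int:
        return len(self.water_residue_ids)

    def atom_ids(self, system: SAMSystem) -> list[int]:
        """All atom indices of the QM region in ``system`` (disjoint union)."""
        ids: list[int] = []
        for lid in self.ligand_ids:
            ids.extend(system.ligand_atom_indices(lid))
        ids.extend(self.au_atom_ids)
        for rid in self.water_residue_ids:
            ids.extend(system.residue_atom_indices(rid))
        if len(set(ids)) != len(ids):
            raise ValueError("QM region component atom lists overlap")
        return ids


@dataclass
class GapEnsemble:
    """Paired vertical-gap samples from the two sampling ensembles.

    ``vie_samples`` are E(cation) - E(neutral) gaps at geometries drawn from
    the neutral-state trajectory; ``vae_samples`` the same gap at geometries
    from the cation-state trajectory. Both lists share that sign convention.
    """

    vie_samples: np.ndarray
    vae_samples: np.ndarray
    temperature: float = 300.0
    region: Optional[QMRegionSpec] = None

    def __post_init__(self) -> None:
        self.vie_samples = np.atleast_1d(np.asarray(self.vie_samples, dtype=float))
        self.vae_samples = np.atleast_1d(np.asarray(self.vae_samples, dtype=float))
        for name, arr in (("VIE", self.vie_samples), ("VAE", self.vae_samples)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} samples must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class MarcusResult:
    """Linear-response estimate with its validity diagnostics."""

    delta_a: float  # oxidation free energy, eV (corrected if correction applied)
    potential: float  # V vs the reference electrode
    lambda_stokes: float
    lambda_var_n: float
    lambda_var_ncat: float
    skewness_n: float
    skewness_ncat: float
    sigma_ratio: float
    normality_p_n: float
    normality_p_ncat: float
    correction_applied: bool
    delta_a_linear: float = float("nan")  # uncorrected Marcus estimate, eV
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "delta_a",
                "potential",
                "lambda_stokes",
                "lambda_var_n",
                "lambda_var_ncat",
                "skewness_n",
                "skewness_ncat",
                "sigma_ratio",
                "normality_p_n",
                "normality_p_ncat",
                "correction_applied",
                "delta_a_linear",
            )
        }
        out["diagnostics"] = dict(self.diagnostics)
        return out


@dataclass
class AdditiveDecomposition:
    """Base one-ligand potential plus gold and neighbor-ligand corrections."""

    base_1l: float
    gold_correction: float
    ligand_correction: float

    @property
    def combined(self) -> float:
        return self.base_1l + self.gold_correction + self.ligand_correction

    def to_dict(self) -> dict:
        return {
            "base_1L_V": self.base_1l,
            "gold_correction_V": self.gold_correction,
            "ligand_correction_V": self.ligand_correction,
            "combined_V": self.combined,
        }


def merge_systems(parts: Iterable[SAMSystem], box: Optional[Sequence[float]] = None,
                  sites: Optional[np.ndarray] = None,
                  occupied_sites: Optional[list[int]] = None) -> SAMSystem:
    """Concatenate component systems back into one assembly."""
    parts = list(parts)
    atoms = [a.copy() for p in parts for a in p.atoms]
    if box is None:
        box = parts[0].box
    merged = SAMSystem(atoms=atoms, box=np.asarray(box, dtype=float))
    if sites is not None:
        merged.sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    if occupied_sites is not None:
        merged.occupied_sites = list(occupied_sites)
    return merged
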