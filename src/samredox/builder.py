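"""Construction of a solvated SAM from a template monolayer and a ligand.

The template provides the anchor-site lattice and an ensemble of placeholder
thiols whose average orientation defines the target tilt. The ligand is
rotated so its own tilt vector (anchor sulfur -> heavy-atom centroid)
overlaps the ensemble tilt, replicated onto a seeded selection of sites,
given an independent random azimuthal rotation about the vertical axis
through its sulfur, and translated so each anchor coincides with its site.
Optionally the most central ligand is replaced by the cationic geometry and
the assembly is neutralized with a chloride counterion.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .model import (
    AtomRecord,
    LigandGeometry,
    RotationSpec,
    SAMSystem,
    merge_systems,
)

__all__ = [
    "compute_tilt_vector",
    "ensemble_tilt_vector",
    "rodrigues_matrix",
    "alignment_rotation",
    "apply_rotation",
    "z_rotation_matrix",
    "build_sam",
    "split_system",
    "neutralize",
]

ANCHOR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    pass


def compute_tilt_vector(ligand: LigandGeometry) -> np.ndarray:
    """Unit vector from the anchor S toward the non-anchor heavy-atom centroid."""
    heavy = [i for i in ligand.heavy_indices() if i != ligand.anchor_index]
    if not heavy:
        raise DegenerateGeometryError(
            "ligand has no heavy atoms besides the anchor; tilt undefined"
        )
    centroid = np.mean([ligand.atoms[i].position for i in heavy], axis=0)
    v = centroid - ligand.anchor.position
    norm = np.linalg.norm(v)
    if norm < 1e-10:
        raise DegenerateGeometryError("heavy-atom centroid coincides with the anchor")
    return v / norm


def _template_ligand_geometries(template: SAMSystem) -> list[LigandGeometry]:
    geoms = []
    for lid in template.ligand_ids():
        idx = template.ligand_atom_indices(lid)
        atoms = [template.atoms[i].copy() for i in idx]
        anchor = next(
            k for k, i in enumerate(idx)
            if template.atoms[i].element.upper() == "S"
        )
        geoms.append(LigandGeometry(atoms=atoms, anchor_index=anchor))
    return geoms


def ensemble_tilt_vector(template: SAMSystem) -> np.ndarray:
    """Normalized mean of the per-ligand tilt vectors of the template."""
    geoms = _template_ligand_geometries(template)
    if not geoms:
        raise ValueError("template has no organic ligands")
    mean = np.mean([compute_tilt_vector(g) for g in geoms], axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-8:
        raise DegenerateGeometryError(
            "template tilt vectors cancel; ensemble orientation ill-defined"
        )
    return mean / norm


def rodrigues_matrix(spec: RotationSpec) -> np.ndarray:
    """Rotation matrix about unit axis u by angle theta (right-hand rule).

    R = cos(t) I + sin(t) [u]_x + (1 - cos(t)) u u^T
    """
    u = spec.axis
    c, s = math.cos(spec.angle), math.sin(spec.angle)
    ux = np.array(
        [[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]]
    )
    return c * np.eye(3) + s * ux + (1.0 - c) * np.outer(u, u)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    # pick the axis least aligned with v, project out, normalize
    basis = np.eye(3)
    k = int(np.argmin(np.abs(v)))
    p = basis[k] - np.dot(basis[k], v) * v
    return p / np.linalg.norm(p)


def alignment_rotation(
    source_tilt: np.ndarray, target_tilt: np.ndarray
) -> RotationSpec:
    """Rotation carrying one unit tilt vector onto another.

    Axis from the cross product, angle from the scalar product. Parallel
    inputs give a zero rotation; anti-parallel inputs use an arbitrary
    axis perpendicular to the source tilt with angle pi (tie-break).
    """
    s = np.asarray(source_tilt, dtype=float)
    t = np.asarray(target_tilt, dtype=float)
    for v in (s, t):
        if abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise ValueError("tilt vectors must be unit vectors")
    cross = np.cross(s, t)
    sin_a = np.linalg.norm(cross)
    cos_a = float(np.dot(s, t))
    if sin_a < 1e-12:
        if cos_a > 0:  # already aligned
            return RotationSpec(axis=np.array([0.0, 0.0, 1.0]), angle=0.0)
        return RotationSpec(axis=_any_perpendicular(s), angle=math.pi)
    return RotationSpec(axis=cross / sin_a, angle=math.atan2(sin_a, cos_a))


def apply_rotation(
    atoms: Sequence[AtomRecord],
    spec: RotationSpec,
    center: np.ndarray,
) -> list[AtomRecord]:
    """Rigidly rotate atoms about an axis through ``center`` (fixed point)."""
    center = np.asarray(center, dtype=float)
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise ValueError("rotation center must be a finite 3-vector")
    r = rodrigues_matrix(spec)
    out = []
    for a in atoms:
        b = a.copy()
        b.position = r @ (a.position - center) + center
        out.append(b)
    return out


def z_rotation_matrix(phi: float) -> np.ndarray:
    """Rotation about +z by angle phi; z-coordinates are invariant."""
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _place_ligand(
    ligand: LigandGeometry,
    rotation: RotationSpec,
    phi: float,
    site: np.ndarray,
    ligand_id: int,
    residue_id: int,
) -> list[AtomRecord]:
    """Align, azimuthally rotate about the anchor, and translate to a site."""
    atoms = apply_rotation(ligand.atoms, rotation, ligand.anchor.position)
    anchor_pos = atoms[ligand.anchor_index].position
    rz = z_rotation_matrix(phi)
    placed = []
    for a in atoms:
        b = a.copy()
        b.position = rz @ (a.position - anchor_pos) + site
        b.ligand_id = ligand_id
        b.residue_id = residue_id
        placed.append(b)
    return placed


def build_sam(
    template: SAMSystem,
    ligand_neutral: LigandGeometry,
    ligand_cation: Optional[LigandGeometry] = None,
    coverage: float = 0.70,
    seed: int = 0,
    cation_site: str = "none",
) -> SAMSystem:
    """Assemble a SAM by replicating an aligned ligand onto template sites.

    ``round(coverage * n_sites)`` sites are occupied, chosen by a seeded
    uniform draw without replacement. Each placed ligand receives an
    independent uniform azimuthal rotation Phi in [0, 2 pi) about the
    vertical axis through its own sulfur, drawn from one seeded stream in
    site-index order; the anchor is translated exactly onto the site.
    ``cation_site='central'`` replaces the occupied ligand nearest the
    metal slab's xy-centroid with the cationic geometry. The build is a
    pure function of its arguments (same seed, identical coordinates).
    """
    n_sites = len(template.sites)
    if n_sites == 0:
        raise ValueError("template defines no anchor sites")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    n_occupy = int(round(coverage * n_sites))
    if n_occupy == 0:
        raise ValueError(
            f"coverage {coverage} on {n_sites} sites yields an empty SAM"
        )
    if cation_site not in ("none", "central"):
        raise ValueError("cation_site must be 'none' or 'central'")
    if cation_site == "central" and ligand_cation is None:
        raise ValueError("cation placement requested without a cationic geometry")

    rng = np.random.default_rng(seed)
    occupied = sorted(rng.choice(n_sites, size=n_occupy, replace=False).tolist())
    phis = rng.uniform(0.0, 2.0 * math.pi, size=n_occupy)

    target_tilt = ensemble_tilt_vector(template)
    source_tilt = compute_tilt_vector(ligand_neutral)
    rotation = alignment_rotation(source_tilt, target_tilt)

    # cation goes on the occupied site closest (in xy) to the slab centroid
    cation_slot: Optional[int] = None
    if cation_site == "central":
        metal_idx = template.indices_by_role("metal")
        ref_xy = (
            np.mean(template.positions[metal_idx][:, :2], axis=0)
            if metal_idx.size
            else np.mean(template.sites[:, :2], axis=0)
        )
        d_xy = [
            float(np.linalg.norm(template.sites[s][:2] - ref_xy)) for s in occupied
        ]
        cation_slot = int(np.argmin(d_xy))  # ties: lowest site index (sorted order)

    metal_and_rest = [
        a.copy() for a in template.atoms if a.role != "organic"
    ]
    max_resid = max((a.residue_id for a in template.atoms), default=0)

    atoms: list[AtomRecord] = list(metal_and_rest)
    for slot, (site_idx, phi) in enumerate(zip(occupied, phis)):
        if cation_slot is not None and slot == cation_slot:
            lig = ligand_cation
            rot = alignment_rotation(compute_tilt_vector(lig), target_tilt)
        else:
            lig, rot = ligand_neutral, rotation
        atoms.extend(
            _place_ligand(
                lig,
                rot,
                float(phi),
                template.sites[site_idx],
                ligand_id=slot + 1,
                residue_id=max_resid + slot + 1,
            )
        )

    system = SAMSystem(
        atoms=atoms,
        box=template.box.copy(),
        sites=template.sites.copy(),
        occupied_sites=occupied,
    )
    system.validate()
    return system


def split_system(system: SAMSystem) -> tuple[SAMSystem, SAMSystem, SAMSystem]:
    """Partition into (solvent, metal, organic) components.

    Ions travel with the solvent component. The partition is exhaustive and
    disjoint; :func:`samredox.model.merge_systems` reassembles the original.
    """
    system.validate()
    buckets: dict[str, list[AtomRecord]] = {"solvent": [], "metal": [], "organic": []}
    for a in system.atoms:
        key = "solvent" if a.role in ("solvent", "ion") else a.role
        buckets[key].append(a.copy())
    make = lambda atoms: SAMSystem(atoms=atoms, box=system.box.copy())  # noqa: E731
    return make(buckets["solvent"]), make(buckets["metal"]), make(buckets["organic"])


def neutralize(system: SAMSystem) -> SAMSystem:
    """Neutralize a singly cationic SAM with one chloride counterion.

    The Cl- is appended at the solvent-region candidate position (solvent
    atom sites) that maximizes the minimum distance to any organic atom,
    so the counterion perturbs the monolayer as little as possible. A
    neutral system is returned unchanged; net charges outside {0, +1} are
    unsupported.
    """
    net = system.net_charge()
    if net == 0:
        return system.copy()
    if net != 1:
        raise ValueError(f"unsupported net charge {net:+d}; expected 0 or +1")
    organic_idx = system.indices_by_role("organic")
    solvent_idx = system.indices_by_role("solvent")
    if solvent_idx.size == 0:
        raise ValueError("no solvent region available for counterion placement")
    if organic_idx.size == 0:
        raise ValueError("cationic system without organic atoms is inconsistent")
    pos = system.positions
    d = np.linalg.norm(
        pos[solvent_idx][:, None, :] - pos[organic_idx][None, :, :], axis=-1
    )
    best = solvent_idx[int(np.argmax(d.min(axis=1)))]
    out = system.copy()
    max_resid = max(a.residue_id for a in out.atoms)
    out.atoms.append(
        AtomRecord(
            element="Cl",
            name="CL",
            position=pos[best].copy(),
            role="ion",
            residue_id=max_resid + 1,
            charge=-1.0,
        )
    )
    return out
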