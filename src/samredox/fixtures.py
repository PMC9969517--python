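"""Synthetic generators for every input the pipeline consumes.

These stand in for external products that a desk-scale workflow cannot
fetch: the two-layer gold/thiol template monolayer, optimized ligand
geometries, molecular-dynamics snapshot pools, gap ensembles realizing the
two-parabola linear-response picture, and analytic harmonic Hessians used
as oracles for the force-constant extraction. Every generator is a pure
function of its arguments, including the seed.

The lattice constants (2.88 A in-plane nearest neighbor, 2.04 A
interlayer) approximate a two-layer Au(100)-like slab; a 10 x 20 top layer
with two layers gives the 400-atom metal substrate the workflow assumes.
Solvent is a simple lattice stub, not a realistic water structure.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS
from .model import AtomRecord, GapEnsemble, LigandGeometry, SAMSystem
from .seminario import HessianMatrix

__all__ = [
    "make_template",
    "make_toy_ligand",
    "sample_two_parabola_gaps",
    "make_toy_hessian",
    "make_snapshots",
]

LATTICE_A = 2.88  # in-plane spacing, Angstrom
INTERLAYER = 2.04  # layer separation, Angstrom
S_AU_HEIGHT = 2.40  # anchor site elevation above the top layer, Angstrom

# TIP3P-like stub charges for the lattice solvent
_WATER_CHARGES = {"O": -0.834, "H": 0.417}


def make_template(
    n_sites_x: int = 10,
    n_sites_y: int = 20,
    layers: int = 2,
    lattice_a: float = LATTICE_A,
    interlayer: float = INTERLAYER,
    ligand_fraction: float = 0.70,
    n_waters: int = 60,
    seed: int = 0,
    tilt_deg: float = 30.0,
) -> SAMSystem:
    """Two-layer metal slab with placeholder thiols and a solvent stub.

    The top layer spans ``n_sites_x * n_sites_y`` atoms in the xy-plane
    (outward normal +z); the lower layer sits offset by half a cell. One
    anchor site floats ``S_AU_HEIGHT`` above each top-layer atom, and a
    seeded fraction of sites carries a three-atom placeholder thiol tilted
    ``tilt_deg`` from the surface normal, whose ensemble average defines
    the template orientation. Waters are a lattice stub above the
    monolayer.
    """
    if n_sites_x < 1 or n_sites_y < 1:
        raise ValueError("slab dimensions must be at least 1")
    if layers != 2:
        raise ValueError(
            "the gold-selection ladder requires exactly two metal layers"
        )
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []

    # metal slab: top layer at z = 0, lower layer half-cell offset below
    for layer in range(layers):
        z = -layer * interlayer
        shift = 0.5 * lattice_a if layer % 2 else 0.0
        for i in range(n_sites_x):
            for j in range(n_sites_y):
                atoms.append(
                    AtomRecord(
                        element="Au",
                        name="AU",
                        position=np.array(
                            [i * lattice_a + shift, j * lattice_a + shift, z]
                        ),
                        role="metal",
                        residue_id=1,
                    )
                )

    sites = np.array(
        [
            [i * lattice_a, j * lattice_a, S_AU_HEIGHT]
            for i in range(n_sites_x)
            for j in range(n_sites_y)
        ]
    )

    n_sites = len(sites)
    n_ligands = int(round(ligand_fraction * n_sites))
    occupied = sorted(
        rng.choice(n_sites, size=n_ligands, replace=False).tolist()
    )
    tilt = np.array(
        [math.sin(math.radians(tilt_deg)), 0.0, math.cos(math.radians(tilt_deg))]
    )
    resid = 2
    lig_charges = (-0.1, 0.05, 0.05)
    for lid, site_idx in enumerate(occupied, start=1):
        base = sites[site_idx]
        for k, (elem, dist, q) in enumerate(
            zip(("S", "C", "C"), (0.0, 1.8, 3.3), lig_charges)
        ):
            atoms.append(
                AtomRecord(
                    element=elem,
                    name=f"{elem}{k}",
                    position=base + dist * tilt,
                    role="organic",
                    residue_id=resid,
                    ligand_id=lid,
                    charge=q,
                )
            )
        resid += 1

    # lattice solvent stub above the monolayer
    z_solvent = S_AU_HEIGHT + 3.3 * math.cos(math.radians(tilt_deg)) + 2.5
    spacing = 3.1
    nx = max(1, int(n_sites_x * lattice_a // spacing))
    ny = max(1, int(n_sites_y * lattice_a // spacing))
    count = 0
    layer_k = 0
    while count < n_waters:
        for i in range(nx):
            for j in range(ny):
                if count >= n_waters:
                    break
                origin = np.array(
                    [
                        (i + 0.5) * spacing,
                        (j + 0.5) * spacing,
                        z_solvent + layer_k * spacing,
                    ]
                )
                for elem, offset in (
                    ("O", np.zeros(3)),
                    ("H", np.array([0.76, 0.59, 0.0])),
                    ("H", np.array([-0.76, 0.59, 0.0])),
                ):
                    atoms.append(
                        AtomRecord(
                            element=elem,
                            name=elem,
                            position=origin + offset,
                            role="solvent",
                            residue_id=resid,
                            charge=_WATER_CHARGES[elem],
                        )
                    )
                resid += 1
                count += 1
        layer_k += 1

    z_top = max(a.position[2] for a in atoms)
    box = np.array(
        [n_sites_x * lattice_a, n_sites_y * lattice_a, z_top + interlayer + 8.0]
    )
    system = SAMSystem(
        atoms=atoms, box=box, sites=sites, occupied_sites=occupied
    )
    system.validate()
    return system


def _guanine_like_atoms() -> list[tuple[str, np.ndarray, float, Optional[str]]]:
    """S anchor + linker + an 11-heavy-atom nucleobase-like fragment."""
    spec: list[tuple[str, np.ndarray, float, Optional[str]]] = [
        ("S", np.array([0.0, 0.0, 0.0]), -0.20, None),
        ("C", np.array([0.0, 0.0, 1.80]), 0.20, None),
    ]
    # six-membered ring in the x-z plane centered above the linker
    center = np.array([0.0, 0.0, 4.60])
    ring_elems = ("C", "N", "C", "N", "C", "N")
    ring_q = (0.10, -0.10, 0.10, -0.10, 0.10, -0.10)
    for k, (elem, q) in enumerate(zip(ring_elems, ring_q)):
        ang = math.pi / 6 + k * math.pi / 3
        pos = center + 1.40 * np.array([math.cos(ang), 0.0, math.sin(ang)])
        spec.append((elem, pos, q, "nucleobase"))
    # five exocyclic heavy atoms (carbonyl O, amine N, imidazole-like C/N/C)
    for elem, offset, q in (
        ("O", np.array([2.60, 0.0, 1.20]), -0.20),
        ("N", np.array([-2.60, 0.0, 1.20]), -0.10),
        ("C", np.array([2.60, 0.0, -1.20]), 0.20),
        ("N", np.array([-2.60, 0.0, -1.20]), -0.10),
        ("C", np.array([0.0, 0.0, 2.90]), 0.20),
    ):
        spec.append((elem, center + offset, q, "nucleobase"))
    return spec


def make_toy_ligand(
    kind: str = "stick_thiol", charge_state: str = "neutral"
) -> LigandGeometry:
    """Toy ligand geometries with the sulfur anchor at the origin.

    ``stick_thiol`` is a linear 3-atom S-C-C rod along +z (tilt vector
    exactly (0, 0, 1)). ``guanine_like`` carries a labeled 11-atom
    nucleobase fragment; its cationic form adds +1 e spread uniformly over
    that fragment. Per-atom charges sum to the declared net charge.
    """
    if kind == "stick_thiol":
        if charge_state != "neutral":
            raise ValueError("stick_thiol exists only in the neutral state")
        atoms = [
            AtomRecord("S", "S0", np.array([0.0, 0.0, 0.0]), "organic", 1, 1, -0.2),
            AtomRecord("C", "C1", np.array([0.0, 0.0, 1.8]), "organic", 1, 1, 0.1),
            AtomRecord("C", "C2", np.array([0.0, 0.0, 3.3]), "organic", 1, 1, 0.1),
        ]
        return LigandGeometry(atoms=atoms, anchor_index=0)
    if kind != "guanine_like":
        raise ValueError(f"unknown toy ligand kind {kind!r}")
    if charge_state not in ("neutral", "cation"):
        raise ValueError(f"unknown charge state {charge_state!r}")
    spec = _guanine_like_atoms()
    frag_count = sum(1 for _, _, _, tag in spec if tag == "nucleobase")
    extra = (1.0 / frag_count) if charge_state == "cation" else 0.0
    atoms = []
    for k, (elem, pos, q, tag) in enumerate(spec):
        atoms.append(
            AtomRecord(
                element=elem,
                name=f"{elem}{k}",
                position=pos.copy(),
                role="organic",
                residue_id=1,
                ligand_id=1,
                charge=q + (extra if tag == "nucleobase" else 0.0),
                fragment=tag,
            )
        )
    return LigandGeometry(
        atoms=atoms,
        anchor_index=0,
        charge_state=charge_state,
        net_charge=0 if charge_state == "neutral" else 1,
    )


def sample_two_parabola_gaps(
    delta_a: float,
    lam: float,
    temperature: float = 300.0,
    n: int = 1000,
    seed: int = 0,
    curvature_ratio: float = 1.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> GapEnsemble:
    """Gap ensemble realizing the two-parabola linear-response model.

    VIE ~ Normal(delta_a + lam, sigma) on the neutral surface with
    sigma = sqrt(2 kB T lam), so the fluctuation and Stokes routes to the
    reorganization energy agree by construction. ``curvature_ratio``
    scales the cation-surface width: VAE ~ Normal(delta_a - lam_cat,
    sigma * curvature_ratio) with lam_cat = lam * curvature_ratio**2,
    keeping each state's gap mean consistent with its own curvature (the
    unequal-curvature quadratic model). A ratio of 1 recovers the
    symmetric two-parabola picture; any other value breaks the equal-width
    Marcus condition on purpose while the second-order cumulant estimate
    remains exact.
    """
    if lam < 0:
        raise ValueError("reorganization energy must be non-negative")
    if n < 1:
        raise ValueError("need at least one sample per state")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * constants.k_b * temperature * lam)
    vie = rng.normal(delta_a + lam, sigma, size=n)
    lam_cat = lam * curvature_ratio**2
    vae = rng.normal(delta_a - lam_cat, sigma * curvature_ratio, size=n)
    return GapEnsemble(
        vie_samples=vie, vae_samples=vae, temperature=temperature
    )


# ---------------------------------------------------------------------------
# Analytic harmonic Hessians (force-constant oracles)
# ---------------------------------------------------------------------------

def _bond_gradient(ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
    u = (ri - rj) / np.linalg.norm(ri - rj)
    return np.concatenate([u, -u])


def _angle_gradient(
    ri: np.ndarray, rj: np.ndarray, rk: np.ndarray
) -> np.ndarray:
    """d(theta)/d(r_i, r_j, r_k) for the angle at apex j."""
    u = ri - rj
    v = rk - rj
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos_t = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    sin_t = math.sqrt(1.0 - cos_t**2)
    gi = (cos_t * uh - vh) / (nu * sin_t)
    gk = (cos_t * vh - uh) / (nv * sin_t)
    return np.concatenate([gi, -(gi + gk), gk])


def make_toy_hessian(kind: str, **params) -> HessianMatrix:
    """Analytic equilibrium Hessians of harmonic toy potentials.

    ``diatomic_k``: a single bond of spring constant ``k`` (kcal/(mol A^2))
    and length ``r0`` along ``axis``. ``triatomic_angle``: two bonds of
    constant ``k_bond`` plus a bending term ``k_theta`` (kcal/(mol rad^2))
    at angle ``theta0_deg`` with apex at the origin. At equilibrium the
    exact Hessian is the sum of gradient outer products, symmetric by
    construction.
    """
    if kind == "diatomic_k":
        k = float(params.get("k", 300.0))
        r0 = float(params.get("r0", 1.5))
        axis = np.asarray(params.get("axis", (0.0, 0.0, 1.0)), dtype=float)
        axis = axis / np.linalg.norm(axis)
        geometry = np.array([np.zeros(3), r0 * axis])
        g = _bond_gradient(geometry[0], geometry[1])
        entries = k * np.outer(g, g)
        return HessianMatrix(
            entries=entries, geometry=geometry, units="kcal/mol/angstrom^2"
        )
    if kind == "triatomic_angle":
        k_bond = float(params.get("k_bond", 400.0))
        k_theta = float(params.get("k_theta", 80.0))
        theta0 = math.radians(float(params.get("theta0_deg", 104.5)))
        r0 = float(params.get("r0", 1.0))
        apex = np.zeros(3)
        a1 = r0 * np.array([math.sin(theta0 / 2), 0.0, math.cos(theta0 / 2)])
        a2 = r0 * np.array([-math.sin(theta0 / 2), 0.0, math.cos(theta0 / 2)])
        geometry = np.array([a1, apex, a2])
        entries = np.zeros((9, 9))
        for i, j in ((0, 1), (2, 1)):
            g = np.zeros(9)
            gb = _bond_gradient(geometry[i], geometry[j])
            g[3 * i : 3 * i + 3] = gb[:3]
            g[3 * j : 3 * j + 3] = gb[3:]
            entries += k_bond * np.outer(g, g)
        ga = _angle_gradient(geometry[0], geometry[1], geometry[2])
        entries += k_theta * np.outer(ga, ga)
        return HessianMatrix(
            entries=entries, geometry=geometry, units="kcal/mol/angstrom^2"
        )
    raise ValueError(f"unknown toy Hessian kind {kind!r}")


def make_snapshots(
    system: SAMSystem,
    n: int = 5,
    amplitude: float = 0.05,
    seed: int = 0,
) -> list[SAMSystem]:
    """Emulate trajectory frames by seeded thermal jitter of one assembly.

    Organic and solvent atoms receive isotropic Gaussian displacements of
    the given amplitude (Angstrom); restrained metal and sulfur atoms move
    a fifth as much, mirroring their positional restraints.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        snap = system.copy()
        for a in snap.atoms:
            scale = (
                amplitude * 0.2
                if (a.role == "metal" or a.element.upper() == "S")
                else amplitude
            )
            a.position = a.position + rng.normal(0.0, scale, size=3)
        out.append(snap)
    return out
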