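"""Gap-energy backends: the computation contract plus two references.

A backend computes the vertical energy gap E(cation) - E(neutral) at a
fixed snapshot geometry for a given QM region and embedding. Real
electronic-structure engines enter only through the table backend, which
ingests gaps computed offline; the mock engine is a strictly linear
electrostatic model used for property tests and for validating the
additive decomposition, where exact linearity makes the expected result
known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_EV_ANGSTROM
from .model import (
    ChargeConstraintSpec,
    EmbeddingSpec,
    GapEnsemble,
    QMRegionSpec,
    SAMSystem,
)

__all__ = [
    "EnergyBackend",
    "MockCoulombEngine",
    "TableBackend",
    "BackendCapabilityError",
    "read_gap_table",
    "write_gap_table",
]

GAP_TABLE_COLUMNS = ["snapshot_id", "state", "region_tag", "gap_eV"]


class BackendCapabilityError(RuntimeError):
    """Backend cannot honor the requested constraint or region."""


class EnergyBackend(Protocol):
    def compute_gap(
        self,
        snapshot: SAMSystem,
        state: str,
        region: QMRegionSpec,
        embedding: Optional[EmbeddingSpec] = None,
    ) -> float:
        """Vertical gap E(cation) - E(neutral), eV, at the snapshot geometry."""
        ...


def _resolve_constraint(
    snapshot: SAMSystem, region: QMRegionSpec
) -> ChargeConstraintSpec:
    if region.constraint is not None:
        rl_atoms = set(snapshot.ligand_atom_indices(region.reference_ligand))
        if not set(region.constraint.atom_ids) <= rl_atoms:
            raise BackendCapabilityError(
                "charge-constraint atoms are not all part of the reference ligand"
            )
        return region.constraint
    # default: the labeled nucleobase fragment of the RL, else the whole RL
    rl = region.reference_ligand
    frag = [
        i
        for i in snapshot.ligand_atom_indices(rl)
        if snapshot.atoms[i].fragment == "nucleobase"
    ]
    if not frag:
        frag = snapshot.ligand_atom_indices(rl)
    return ChargeConstraintSpec(atom_ids=frag)


@dataclass
class MockCoulombEngine:
    """Strictly linear point-charge model of the vertical gap.

    The total energy of either charge state is a sum of internal fragment
    terms plus pairwise Coulomb interactions between the QM fragment
    charges and the surrounding point charges, so the gap reduces to

        gap = I0 + sum_f sum_e dq_f * q_e * C / r_fe

    where dq is the +1 charge difference localized on the constrained
    (nucleobase) fragment of the reference ligand, distributed with
    ``delta_q_weights`` (uniform by default), and e runs over the
    interacting charges. Atoms inside the QM region but outside the
    reference ligand couple with ``qm_scaling`` (a fixed polarization
    factor standing in for their quantum treatment); environment charges
    couple with ``env_coupling[state]``. Continuum embedding adds the
    constant ``continuum_shift_ev`` and drops the explicit solvent
    charges. Everything is linear in the environment charges and
    deterministic.
    """

    i0_ev: float = 6.0
    qm_scaling: float = 1.1
    continuum_shift_ev: float = -0.25
    env_coupling: dict = field(default_factory=lambda: {"N": 1.0, "N+": 1.0})
    delta_q_weights: Optional[Sequence[float]] = None

    def _delta_q(self, constraint: ChargeConstraintSpec) -> np.ndarray:
        n = len(constraint.atom_ids)
        if self.delta_q_weights is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(self.delta_q_weights, dtype=float)
            if w.shape != (n,):
                raise BackendCapabilityError(
                    f"delta_q_weights length {w.size} does not match the "
                    f"{n}-atom constrained fragment"
                )
            w = w / w.sum()
        return w * constraint.target_charge

    @staticmethod
    def _coulomb(
        pos_frag: np.ndarray,
        dq: np.ndarray,
        pos_other: np.ndarray,
        q_other: np.ndarray,
    ) -> float:
        if len(pos_other) == 0:
            return 0.0
        d = np.linalg.norm(pos_frag[:, None, :] - pos_other[None, :, :], axis=-1)
        if np.any(d < 1e-6):
            raise ValueError("overlapping atoms in Coulomb evaluation")
        return float(COULOMB_EV_ANGSTROM * np.sum(np.outer(dq, q_other) / d))

    def compute_gap(
        self,
        snapshot: SAMSystem,
        state: str,
        region: QMRegionSpec,
        embedding: Optional[EmbeddingSpec] = None,
    ) -> float:
        if state not in ("N", "N+"):
            raise ValueError("state must be 'N' or 'N+'")
        embedding = embedding if embedding is not None else region.embedding
        constraint = _resolve_constraint(snapshot, region)
        dq = self._delta_q(constraint)
        pos = snapshot.positions
        charges = snapshot.charges
        frag_pos = pos[constraint.atom_ids]

        qm_ids = set(region.atom_ids(snapshot))
        rl_ids = set(snapshot.ligand_atom_indices(region.reference_ligand))
        qm_other = sorted(qm_ids - rl_ids)

        env = [i for i in range(len(snapshot.atoms)) if i not in qm_ids]
        if not embedding.includes_explicit_solvent:
            env = [i for i in env if snapshot.atoms[i].role != "solvent"]
        if embedding.mode == "continuum":
            env = []
        if embedding.shell_min_radius is not None and env:
            env = _shell_filter(
                snapshot, env, region, embedding.shell_min_radius
            )

        gap = self.i0_ev
        if qm_other:
            gap += self.qm_scaling * self._coulomb(
                frag_pos, dq, pos[qm_other], charges[qm_other]
            )
        if env:
            gap += self.env_coupling[state] * self._coulomb(
                frag_pos, dq, pos[env], charges[env]
            )
        if embedding.continuum:
            gap += self.continuum_shift_ev
        return gap


def _rl_heavy_centroid(snapshot: SAMSystem, region: QMRegionSpec) -> np.ndarray:
    rl_ids = snapshot.ligand_atom_indices(region.reference_ligand)
    heavy = [i for i in rl_ids if snapshot.atoms[i].element.upper() not in ("H", "D")]
    return np.mean(snapshot.positions[heavy], axis=0)


def _shell_filter(
    snapshot: SAMSystem,
    env: list[int],
    region: QMRegionSpec,
    min_radius: float,
) -> list[int]:
    """Keep only environment molecules at centroid distance >= min_radius.

    Whole residues are included or excluded atomically, measured from the
    reference ligand's heavy-atom centroid to the residue centroid.
    """
    center = _rl_heavy_centroid(snapshot, region)
    pos = snapshot.positions
    by_res: dict[int, list[int]] = {}
    for i in env:
        by_res.setdefault(snapshot.atoms[i].residue_id, []).append(i)
    keep: list[int] = []
    for rid, idx in by_res.items():
        centroid = np.mean(pos[idx], axis=0)
        if np.linalg.norm(centroid - center) >= min_radius:
            keep.extend(idx)
    return sorted(keep)


# ---------------------------------------------------------------------------
# Precomputed-table backend
# ---------------------------------------------------------------------------

def read_gap_table(path: str | Path) -> pd.DataFrame:
    """Read a gap table (CSV: snapshot_id, state, region_tag, gap_eV)."""
    df = pd.read_csv(path)
    missing = [c for c in GAP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gap table {path} lacks columns {missing}")
    bad = set(df["state"].unique()) - {"N", "N+"}
    if bad:
        raise ValueError(f"gap table {path} has unknown states {sorted(bad)}")
    return df[GAP_TABLE_COLUMNS]


def write_gap_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GAP_TABLE_COLUMNS].to_csv(path, index=False)


@dataclass
class TableBackend:
    """Backend serving gaps from a precomputed table.

    This is the ingestion path for real QM/MM(/continuum) engines: gaps
    are computed offline, tabulated, and looked up verbatim here.
    """

    table: pd.DataFrame

    @classmethod
    def from_csv(cls, path: str | Path) -> "TableBackend":
        return cls(table=read_gap_table(path))

    def lookup(self, snapshot_id, state: str, region_tag: str) -> float:
        rows = self.table[
            (self.table["snapshot_id"] == snapshot_id)
            & (self.table["state"] == state)
            & (self.table["region_tag"] == region_tag)
        ]
        if len(rows) != 1:
            raise KeyError(
                f"expected exactly one gap for ({snapshot_id!r}, {state!r}, "
                f"{region_tag!r}); found {len(rows)}"
            )
        return float(rows["gap_eV"].iloc[0])

    def ensemble(
        self,
        region_tag: str,
        temperature: float = 300.0,
        region: Optional[QMRegionSpec] = None,
    ) -> GapEnsemble:
        """Collect all tabulated gaps for a region tag into a GapEnsemble."""
        sub = self.table[self.table["region_tag"] == region_tag]
        return GapEnsemble(
            vie_samples=sub.loc[sub["state"] == "N", "gap_eV"].to_numpy(),
            vae_samples=sub.loc[sub["state"] == "N+", "gap_eV"].to_numpy(),
            temperature=temperature,
            region=region,
        )
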