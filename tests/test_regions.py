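"""QM-region selections, additive decomposition, scans, full protocol."""

import math

import numpy as np
import pytest

from samredox.backends import MockCoulombEngine
from samredox.builder import build_sam
from samredox.fixtures import make_snapshots, make_template, make_toy_ligand
from samredox.marcus import DiagnosticThresholds
from samredox.model import AdditiveDecomposition, EmbeddingSpec
from samredox.regions import (
    additive_potential,
    charge_shell_scan,
    convergence_scan,
    ensemble_protocol,
    make_region,
    select_au_atoms,
    select_ligands,
    select_waters,
    snapshot_potential,
    validate_additivity,
)

# ----------------------------------------------------------------------------
# brute-force helpers (pure python, minimum image in x and y)
# ----------------------------------------------------------------------------

def _bf_dist(p, q, box):
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    dz = p[2] - q[2]
    dx -= box[0] * round(dx / box[0])
    dy -= box[1] * round(dy / box[1])
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def _bf_au_selection(system, rl, n):
    pos = system.positions
    metal = list(system.indices_by_role("metal"))
    zs = [pos[i][2] for i in metal]
    mid = 0.5 * (min(zs) + max(zs))
    upper = [i for i in metal if pos[i][2] > mid]
    lower = [i for i in metal if pos[i][2] <= mid]
    s_pos = system.atoms[system.anchor_index_of(rl)].position

    def sort_by_dist(cands):
        return sorted(cands, key=lambda i: (_bf_dist(pos[i], s_pos, system.box), i))

    sel = sort_by_dist(upper)[:2]
    if n >= 4:
        sel += sort_by_dist(lower)[:2]
    if n == 8:
        nn = min(
            _bf_dist(pos[i], pos[j], system.box)
            for i in upper
            for j in upper
            if i != j
        )
        adj = [
            i
            for i in upper
            if i not in sel
            and any(
                _bf_dist(pos[i], pos[j], system.box) <= 1.2 * nn for j in sel[:2]
            )
        ]
        sel += sort_by_dist(adj)[:4]
    return sel[:n]


def _bf_water_selection(system, rl, n):
    pos = system.positions
    heavy = [
        i
        for i in system.ligand_atom_indices(rl)
        if system.atoms[i].element.upper() not in ("H", "D")
    ]
    center = np.mean(pos[heavy], axis=0)
    entries = []
    for rid in system.solvent_residue_ids():
        idx = system.residue_atom_indices(rid)
        oxy = [i for i in idx if system.atoms[i].element.upper() == "O"]
        p = pos[oxy[0]] if oxy else np.mean(pos[idx], axis=0)
        entries.append((rid, _bf_dist(p, center, system.box)))
    entries.sort(key=lambda t: (t[1], t[0]))
    return [rid for rid, _ in entries[:n]]


def _bf_ligand_selection(system, rl, n):
    pos = system.positions
    s_rl = system.atoms[system.anchor_index_of(rl)].position
    entries = []
    for lid in system.ligand_ids():
        if lid == rl:
            continue
        p = pos[system.anchor_index_of(lid)]
        entries.append((lid, _bf_dist(p, s_rl, system.box)))
    entries.sort(key=lambda t: (t[1], t[0]))
    return [rl] + [lid for lid, _ in entries[: n - 1]]


def _random_toy_system(seed):
    rng = np.random.default_rng(seed)
    nx = int(rng.integers(3, 6))
    ny = int(rng.integers(3, 6))
    template = make_template(n_sites_x=nx, n_sites_y=ny, n_waters=25, seed=seed)
    system = build_sam(
        template,
        make_toy_ligand("guanine_like", "neutral"),
        coverage=float(rng.uniform(0.6, 1.0)),
        seed=seed + 1,
    )
    lids = system.ligand_ids()
    rl = lids[int(rng.integers(0, len(lids)))]
    return system, rl


# ----------------------------------------------------------------------------
# selection ladders
# ----------------------------------------------------------------------------

class TestSelectionOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_au_matches_brute_force(self, seed):
        system, rl = _random_toy_system(seed)
        for n in (2, 4, 8):
            assert select_au_atoms(system, rl, n) == _bf_au_selection(
                system, rl, n
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_water_matches_brute_force(self, seed):
        system, rl = _random_toy_system(seed)
        assert select_waters(system, rl, 20) == _bf_water_selection(
            system, rl, 20
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_ligand_matches_brute_force(self, seed):
        system, rl = _random_toy_system(seed)
        n = min(3, len(system.ligand_ids()))
        assert select_ligands(system, rl, n) == _bf_ligand_selection(
            system, rl, n
        )

    def test_empty_and_identity_selections(self, neutral_sam, central_ligand):
        assert select_au_atoms(neutral_sam, central_ligand, 0) == []
        assert select_waters(neutral_sam, central_ligand, 0) == []
        assert select_ligands(neutral_sam, central_ligand, 1) == [central_ligand]

    def test_unsupported_gold_size(self, neutral_sam, central_ligand):
        with pytest.raises(ValueError):
            select_au_atoms(neutral_sam, central_ligand, 3)

    def test_water_shortage_signals(self, neutral_sam, central_ligand):
        with pytest.raises(ValueError):
            select_waters(neutral_sam, central_ligand, 10_000)

    @pytest.mark.parametrize("seed", range(10))
    def test_prefix_and_nesting_properties(self, seed):
        system, rl = _random_toy_system(seed)
        au = {n: select_au_atoms(system, rl, n) for n in (0, 2, 4, 8)}
        assert au[2] == au[4][:2] == au[8][:2]
        assert au[4] == au[8][:4]
        w5, w10, w20 = (select_waters(system, rl, n) for n in (5, 10, 20))
        assert set(w5) < set(w10) < set(w20)
        assert w5 == w10[:5] == w20[:5]
        n_max = min(4, len(system.ligand_ids()))
        ladders = [select_ligands(system, rl, n) for n in range(1, n_max + 1)]
        for small, big in zip(ladders, ladders[1:]):
            assert small == big[: len(small)]

    def test_gold_layer_membership(self, neutral_sam, central_ligand):
        """First pair upper layer, second pair lower layer."""
        sel = select_au_atoms(neutral_sam, central_ligand, 8)
        z = neutral_sam.positions[sel][:, 2]
        mid = float(np.mean(
            neutral_sam.positions[neutral_sam.indices_by_role("metal")][:, 2]
        ))
        assert all(v > mid for v in z[:2])
        assert all(v < mid for v in z[2:4])
        assert all(v > mid for v in z[4:])


# ----------------------------------------------------------------------------
# additive scheme
# ----------------------------------------------------------------------------

class TestAdditiveScheme:
    def test_zero_corrections(self):
        dec = additive_potential(1.0, 1.0, 1.0)
        assert dec.combined == pytest.approx(1.0)
        assert dec.gold_correction == 0.0 and dec.ligand_correction == 0.0

    def test_stated_arithmetic(self):
        dec = additive_potential(1.00, 0.90, 0.60)
        assert dec.combined == pytest.approx(0.50)

    def test_bookkeeping_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.normal(size=3)
            dec = additive_potential(a, b, c)
            assert dec.base_1l + dec.gold_correction + dec.ligand_correction == (
                pytest.approx(dec.combined, abs=0.0)
            )

    def test_linear_engine_additivity_is_exact(self, neutral_snapshots,
                                               central_ligand, mock_engine):
        report = validate_additivity(
            mock_engine, neutral_snapshots, rl=central_ligand, small_au=2
        )
        assert report["max_relative_error"] < 1e-10
        assert len(report["per_snapshot"]) == len(neutral_snapshots)

    def test_additivity_error_permutation_invariant(self, neutral_snapshots,
                                                    central_ligand, mock_engine):
        fwd = validate_additivity(mock_engine, neutral_snapshots, central_ligand)
        rev = validate_additivity(
            mock_engine, list(reversed(neutral_snapshots)), central_ligand
        )
        assert sorted(r["relative_error"] for r in fwd["per_snapshot"]) == (
            pytest.approx(sorted(r["relative_error"] for r in rev["per_snapshot"]))
        )

    def test_decoupled_environment_zero_error(self, neutral_snapshots,
                                              central_ligand):
        engine = MockCoulombEngine(
            qm_scaling=0.0, env_coupling={"N": 0.0, "N+": 0.0}
        )
        report = validate_additivity(engine, neutral_snapshots, central_ligand)
        assert report["max_relative_error"] == pytest.approx(0.0, abs=1e-15)


# ----------------------------------------------------------------------------
# scans
# ----------------------------------------------------------------------------

class TestConvergenceScan:
    def test_single_size_equals_direct_evaluation(self, neutral_snapshots,
                                                  central_ligand, mock_engine):
        snap = neutral_snapshots[0]
        df = convergence_scan(mock_engine, [snap], "au", [4], central_ligand)
        region = make_region(snap, central_ligand, 1, 4)
        direct = snapshot_potential(mock_engine, snap, region)
        assert df["potential_V"].iloc[0] == pytest.approx(direct)

    def test_constant_engine_flat_series(self, neutral_snapshots, central_ligand):
        engine = MockCoulombEngine(
            qm_scaling=0.0, env_coupling={"N": 0.0, "N+": 0.0}
        )
        df = convergence_scan(
            engine, neutral_snapshots[:2], "au", [0, 2, 4, 8], central_ligand
        )
        for _, grp in df.groupby("snapshot"):
            assert grp["potential_V"].nunique() == 1

    def test_water_series_converges_with_distance_decay(self, mock_engine):
        """Waters at increasing radii: scan increments shrink monotonically."""
        from samredox.model import AtomRecord, SAMSystem

        lig = make_toy_ligand("guanine_like", "neutral")
        atoms = [a.copy() for a in lig.atoms]
        rid = 50
        for k in range(6):
            origin = np.array([8.0 + 5.0 * k, 0.0, 4.6])
            for elem, off, q in (
                ("O", np.zeros(3), -0.834),
                ("H", np.array([0.76, 0.59, 0.0]), 0.417),
                ("H", np.array([-0.76, 0.59, 0.0]), 0.417),
            ):
                atoms.append(
                    AtomRecord(elem, elem, origin + off, "solvent", rid, None, q)
                )
            rid += 1
        system = SAMSystem(atoms=atoms, box=np.array([500.0, 500.0, 500.0]))
        df = convergence_scan(
            mock_engine, [system], "water", [0, 1, 2, 3, 4, 5, 6], 1
        )
        diffs = np.abs(np.diff(df["potential_V"].to_numpy()))
        assert all(a > b for a, b in zip(diffs, diffs[1:]))

    def test_sizes_must_ascend(self, neutral_snapshots, central_ligand,
                               mock_engine):
        with pytest.raises(ValueError):
            convergence_scan(
                mock_engine, neutral_snapshots, "au", [4, 2], central_ligand
            )


class TestChargeShellScan:
    def test_large_radius_gives_bare_gap(self, neutral_snapshots,
                                         cation_snapshots, central_ligand,
                                         mock_engine):
        df = charge_shell_scan(
            mock_engine, neutral_snapshots, cation_snapshots, central_ligand,
            radii=[1000.0],
        )
        assert df["mean_vie_eV"].iloc[0] == pytest.approx(mock_engine.i0_ev)
        assert df["mean_vae_eV"].iloc[0] == pytest.approx(mock_engine.i0_ev)

    def test_zero_radius_equals_full_embedding(self, neutral_snapshots,
                                               cation_snapshots, central_ligand,
                                               mock_engine):
        df = charge_shell_scan(
            mock_engine, neutral_snapshots, cation_snapshots, central_ligand,
            radii=[50.0, 0.0],
        )
        full_vie = np.mean(
            [
                mock_engine.compute_gap(
                    s, "N", make_region(s, central_ligand, 1, 0)
                )
                for s in neutral_snapshots
            ]
        )
        assert df["mean_vie_eV"].iloc[-1] == pytest.approx(full_vie)

    def test_flat_vie_and_decreasing_vae_with_negative_near_charges(self):
        """Neutral-state coupling off: VIE flat; negative charges pulled in
        shell by shell lower the VAE monotonically."""
        from samredox.model import SAMSystem

        lig = make_toy_ligand("guanine_like", "neutral")
        atoms = [a.copy() for a in lig.atoms]
        rid = 50
        for radius in (6.0, 10.0, 14.0, 18.0):
            for ang in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
                atoms.append(
                    type(atoms[0])(
                        "O", "O",
                        np.array([radius * np.cos(ang), radius * np.sin(ang), 4.6]),
                        "solvent", rid, None, -0.3,
                    )
                )
                rid += 1
        system = SAMSystem(atoms=atoms, box=np.array([500.0, 500.0, 500.0]))
        engine = MockCoulombEngine(
            i0_ev=6.0, env_coupling={"N": 0.0, "N+": 1.0}
        )
        df = charge_shell_scan(
            engine, [system], [system], 1, radii=[30.0, 16.0, 12.0, 8.0, 0.0]
        )
        assert df["mean_vie_eV"].nunique() == 1  # flat
        vae = df["mean_vae_eV"].to_numpy()
        assert all(a > b for a, b in zip(vae, vae[1:]))  # decreasing
        assert all(
            a >= b for a, b in zip(df["potential_V"], df["potential_V"][1:])
        )

    def test_radii_must_descend(self, neutral_snapshots, cation_snapshots,
                                central_ligand, mock_engine):
        with pytest.raises(ValueError):
            charge_shell_scan(
                mock_engine, neutral_snapshots, cation_snapshots,
                central_ligand, radii=[5.0, 10.0],
            )


# ----------------------------------------------------------------------------
# full protocol
# ----------------------------------------------------------------------------

class TestEnsembleProtocol:
    @pytest.fixture()
    def pools(self, neutral_sam, cation_sam):
        return (
            make_snapshots(neutral_sam, n=30, seed=31),
            make_snapshots(cation_sam, n=30, seed=32),
        )

    def test_deterministic_for_fixed_seed(self, pools, central_ligand,
                                          mock_engine):
        a = ensemble_protocol(
            mock_engine, *pools, central_ligand, n_snapshots=20, seed=7
        )
        b = ensemble_protocol(
            mock_engine, *pools, central_ligand, n_snapshots=20, seed=7
        )
        assert a.potential == b.potential
        assert a.decomposition.to_dict() == b.decomposition.to_dict()

    def test_decoupled_environment_reduces_to_base(self, pools, central_ligand):
        engine = MockCoulombEngine(
            qm_scaling=0.0, env_coupling={"N": 0.0, "N+": 0.0}
        )
        res = ensemble_protocol(
            engine, *pools, central_ligand, n_snapshots=20, seed=7
        )
        assert res.decomposition.gold_correction == pytest.approx(0.0, abs=1e-12)
        assert res.decomposition.ligand_correction == pytest.approx(0.0, abs=1e-12)
        assert res.potential == pytest.approx(res.marcus_1l.potential)

    def test_combined_matches_direct_large_region(self, pools, central_ligand,
                                                  mock_engine):
        """Linear engine: additive protocol equals the direct 2L+4Au run."""
        from samredox.marcus import analyze
        from samredox.model import GapEnsemble

        always_pass = DiagnosticThresholds(
            alpha=0.0, sigma_ratio_bounds=(0.0, np.inf),
            lambda_rel_tol=np.inf,
        )
        res = ensemble_protocol(
            mock_engine, *pools, central_ligand, n_snapshots=20, seed=7,
            thresholds=always_pass,
        )
        rng = np.random.default_rng(7)
        pick_n = sorted(rng.choice(30, size=20, replace=False).tolist())
        pick_c = sorted(rng.choice(30, size=20, replace=False).tolist())
        vie = [
            mock_engine.compute_gap(
                pools[0][k], "N", make_region(pools[0][k], central_ligand, 2, 4)
            )
            for k in pick_n
        ]
        vae = [
            mock_engine.compute_gap(
                pools[1][k], "N+", make_region(pools[1][k], central_ligand, 2, 4)
            )
            for k in pick_c
        ]
        direct = analyze(
            GapEnsemble(vie_samples=np.array(vie), vae_samples=np.array(vae)),
            always_pass,
        )
        assert res.potential == pytest.approx(direct.potential, abs=1e-10)

    def test_pool_shortage_signals(self, pools, central_ligand, mock_engine):
        with pytest.raises(ValueError):
            ensemble_protocol(
                mock_engine, *pools, central_ligand, n_snapshots=100, seed=1
            )

    def test_decomposition_identity(self, pools, central_ligand, mock_engine):
        res = ensemble_protocol(
            mock_engine, *pools, central_ligand, n_snapshots=20, seed=3
        )
        dec = res.decomposition
        assert dec.combined == (
            res.marcus_1l_au.potential
            + res.marcus_2l.potential
            - res.marcus_1l.potential
        )
        assert isinstance(dec, AdditiveDecomposition)
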