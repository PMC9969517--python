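# samredox

Redox potentials of nucleobase self-assembled monolayers (SAMs) on gold,
computed the way large solvated interfaces have to be computed: by sampling
an ensemble of geometries and estimating the oxidation free energy from
vertical energy gaps within Marcus linear response, instead of optimizing a
single structure.

The package is aimed at computational chemists modelling electrochemical
DNA biosensors — devices in which guanine-plus-linker ligands are
S-anchored to a gold slab and the read-out is the one-electron oxidation of
a guanine. It implements every desk-scale layer of that protocol:

* **SAM construction** — replicate an optimized ligand onto the anchor
  sites of a template monolayer: tilt-vector alignment by the Rodrigues
  rotation, per-ligand random azimuthal rotation about the axis through its
  own sulfur, seeded site occupation at a chosen coverage (default 70%),
  optional replacement of the most central ligand by the cation, and
  chloride neutralization.
* **Marcus-theory estimation** — for a gap ensemble
  (VIE sampled on the neutral surface, VAE on the cation surface),

  `ΔA = (⟨VIE⟩_N + ⟨VAE⟩_N+) / 2`,   `λ = (⟨VIE⟩ − ⟨VAE⟩)/2 = σ²/(2k_BT)`,

  with diagnostics for the three validity conditions (Gaussian gaps, equal
  widths, Stokes/variance agreement) and a second-order-cumulant quadratic
  correction `(σ²_N+ − σ²_N)/(4k_BT)` applied automatically when they fail.
  Potentials are referenced to the absolute standard hydrogen electrode,
  `E_red = ΔA − E_SHE` with `E_SHE = 4.281 V`.
* **Static potentials** — the direct approach for optimized species,
  `E_red = −ΔG_red/(nF) − E_SHE` with `G = E_e + G_T` per species and the
  gas-phase electron free energy from Fermi–Dirac statistics
  (−0.867 kcal/mol at 298.15 K), which the package can also derive from the
  FD integrals rather than quote.
* **QM-region machinery** — deterministic selection ladders for gold atoms,
  waters and neighbor ligands; the additive decomposition
  `E(2L+4Au) ≈ E(1L) + [E(1L+4Au) − E(1L)] + [E(2L) − E(1L)]`
  with its per-snapshot validation; environment charge-shell (vacuum
  bubble) scans; and the 200-snapshot averaged protocol.
* **Energy backends** — a strictly linear point-charge mock engine (used
  for property tests and for validating the additive scheme, where
  linearity makes the expected answer exact) and a table backend that
  ingests gap ensembles computed offline by real QM/MM/continuum engines.
* **Force-field extraction** — Seminario bond and angle constants from a
  Cartesian Hessian, plus the 50 kcal/(mol Å²) S/Au positional restraints.

## Worked example

```python
import numpy as np
from samredox import (
    build_sam, neutralize, MockCoulombEngine, ensemble_protocol,
)
from samredox.fixtures import make_template, make_toy_ligand, make_snapshots

template = make_template(n_sites_x=4, n_sites_y=5, n_waters=30, seed=11)
neutral = build_sam(template, make_toy_ligand("guanine_like", "neutral"),
                    coverage=0.70, seed=5)
cation = neutralize(build_sam(
    template,
    make_toy_ligand("guanine_like", "neutral"),
    make_toy_ligand("guanine_like", "cation"),
    coverage=0.70, seed=5, cation_site="central",
))
rl = 8  # reference ligand: the central (cationic) ligand of this build

result = ensemble_protocol(
    MockCoulombEngine(),
    make_snapshots(neutral, n=30, seed=31),
    make_snapshots(cation, n=30, seed=32),
    rl, n_snapshots=20, seed=7,
)
print(f"combined potential: {result.potential:.4f} V vs SHE")
print({k: round(v, 4) for k, v in result.decomposition.to_dict().items()})
```

Output:

```
combined potential: 0.3636 V vs SHE
{'base_1L_V': 0.3775, 'gold_correction_V': 0.0, 'ligand_correction_V': -0.0139,
 'combined_V': 0.3636}
```

The base term is the Marcus potential with only the reference ligand in the
quantum layer; the corrections are what putting four gold atoms or the
nearest neighbor ligand into that layer changes (the mock engine couples
gold atoms only through their charges, which are zero, hence the exact zero
gold correction). The same protocol accepts a `TableBackend` carrying real
engine gaps in place of the mock.

The same steps are available from the shell:

```bash
samredox fixtures --outdir fx --seed 3
samredox build-sam --template fx/template.pdb --ligand fx/ligand_neutral.pdb \
    --coverage 0.70 --seed 4 --out system.pdb
samredox marcus --gaps fx/gaps.csv --region-tag 1L
samredox protocol --seed 2 --n-snapshots 50 --out protocol.json
```

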