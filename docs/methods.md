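# Methods

This note documents the models implemented in `samredox`, the defaults that
matter, the design choices made where the procedure was genuinely open, and
what the synthetic inputs do and do not emulate.

## Scope and layering

The package computes one-electron reduction potentials of guanine–linker
ligands, free in solution or assembled into a monolayer on a two-layer gold
slab. Two regimes are covered:

* **Static (optimized species).** For species with a well-defined minimum,
  `G = E_e + G_T` per species, `ΔG_red = G(Red) − G(Ox) − G(e⁻,gas)`, and
  `E_red = −ΔG_red/(nF) − E_SHE` with `n = 1` hard-wired (every
  half-reaction treated here transfers one electron). Electronic energies
  and thermal corrections are *consumed* as inputs; no electronic-structure
  or frequency calculation is performed.
* **Dynamic (ensembles).** For the solvated SAM there is no single minimum;
  the free energy is estimated from vertical gap ensembles under Marcus
  linear response (below).

Everything that requires an external engine — DFT/CDFT/COSMO energies,
classical MD, ESP fitting, topology assembly — is outside the package and
enters only through data files (gap tables, Hessians, charge tables,
ThermoSpecies records). The package supplies the statistics, the geometry,
the bookkeeping, and a linear mock backend that makes the machinery fully
testable without any engine.

## Units, constants, temperatures

Canonical energy unit: eV; potentials: V (numerically equal for one
electron). Conversions use CODATA factors via scipy. Defaults
(all overridable in the YAML config):

| quantity | default | role |
| --- | --- | --- |
| `E_SHE` | 4.281 V | absolute SHE reference, electron term included |
| `G(e⁻, gas)` | −0.867 kcal/mol | Fermi–Dirac value entering ΔG_red |
| `T_marcus` | 300 K | sampling-thermostat temperature, used in 2k_BT |
| `T_thermo` | 298.15 K | standard-state thermochemistry |
| coverage | 0.70 | occupied fraction of anchor sites |
| `n_snapshots` | 200 | ensemble size of the averaged protocol |
| restraint k | 50 kcal/(mol Å²) | S and Au positional restraints |

Two temperatures coexist deliberately: the dynamics that generates the
ensembles is thermostatted at 300 K, while the electron-gas free energy is
a 298.15 K standard-state quantity. Using one for the other changes
nothing at the reported precision but the distinction is kept explicit.

## Fermi–Dirac thermodynamics of the electron

The gas-phase electron is treated as an ideal spin-½ Fermi gas at 1 bar.
At 298.15 K the degeneracy parameter is of order one (the thermal
de Broglie wavelength is ~4.3 nm), so neither the classical limit nor the
Sommerfeld expansion applies; the complete FD integrals
`f_s(z) = −Li_s(−z)` are evaluated by adaptive quadrature in
log-fugacity and the fixed-pressure condition
`Pλ³/(g k_BT) = f_{5/2}(z)` is solved for z. Per mole,
`H = (5/2)RT f_{5/2}/f_{3/2}` and `S = (H − RT ln z)/T`.

Enthalpy is referenced thermochemically to the T = 0 state of the gas at
the same pressure — the degenerate Fermi sea, with `H₀ = N_A E_F` — so the
reported free energy is `G = (H − H₀) − TS`. This referencing (third-law
entropy, `H_T − H₀` enthalpy) is what the electrochemical literature value
corresponds to; it yields `H − H₀ = 0.752 kcal/mol`,
`S = 5.43 cal mol⁻¹ K⁻¹`, `G = −0.868 kcal/mol` at 298.15 K. Note that the
grand-canonical `G = μN` of the same gas is *positive* (≈ +0.09 kcal/mol);
the two differ exactly by the T = 0 reference. The default constant
(−0.867 kcal/mol) is what enters the `E_SHE` bookkeeping; the FD
computation is exposed for verification and for other temperatures.

## Marcus linear response and its diagnostics

With the gap sign convention `ΔE = E(cation) − E(neutral)` at fixed
geometry, VIE samples come from the neutral-surface ensemble and VAE
samples from the cation-surface ensemble, and

* `ΔA = (⟨VIE⟩ + ⟨VAE⟩)/2`
* `λ_Stokes = (⟨VIE⟩ − ⟨VAE⟩)/2`, `λ_var,s = σ_s²/(2 k_B T)` per state s.

Validity diagnostics, with configurable thresholds:

1. *Gaussian shape*: a normality test per state at α = 0.05. The default
   is the D'Agostino–Pearson omnibus test because its p-values remain
   well-calibrated at the 10⁴-sample ensembles used here, where
   Shapiro–Wilk p-values are unreliable; Shapiro–Wilk is available as a
   configuration option for small ensembles.
2. *Equal widths*: `σ_VIE/σ_VAE` inside [0.8, 1.25].
3. *Route agreement*: both `λ_var` estimates within 20% (relative) of
   `λ_Stokes`.

When any diagnostic fails, the symmetric second-order cumulant
(quadratic-model) estimate

`ΔA = (⟨VIE⟩ + ⟨VAE⟩)/2 + (σ²_N+ − σ²_N)/(4 k_B T)`

is applied and flagged; it reduces exactly to the linear estimate for
equal widths, is continuous in the two widths, and is exact for the
unequal-curvature quadratic (two-parabola) model. The exact Q-model with
its full curvature dependence is a possible extension; the cumulant form
was chosen because it is the standard Gaussian-limit-consistent correction
and is fully testable against the generator below. Sample means are
unweighted over snapshots.

Degenerate ensembles (zero width) are legal: normality is vacuous, the
width ratio is taken as 1, λ_var = 0.

## SAM construction

The template provides the anchor-site lattice and an ensemble of
placeholder thiols. Construction steps and the choices behind them:

* **Tilt vector** of a ligand: unit vector from the anchor sulfur to the
  centroid of all non-anchor heavy atoms. The procedure needs *some*
  orientation-complete definition; this one reproduces the obvious answer
  for linear ligands and is well-defined for any geometry with at least
  one non-anchor heavy atom. The template orientation is the normalized
  mean of per-ligand tilt vectors.
* **Alignment**: axis from the cross product, angle from the scalar
  product, rotation by the explicit Rodrigues matrix. Anti-parallel tilt
  pairs (cross ≈ 0, dot ≈ −1) use any axis perpendicular to the source
  tilt with angle π — a documented tie-break for a measure-zero case.
* **Site occupation**: `round(coverage × n_sites)` sites drawn uniformly
  without replacement from a seeded generator. The 70% default coverage is
  a property of the template monolayer; no physical rule selects *which*
  sites are vacant, so a seeded uniform draw is used.
* **Azimuthal disorder**: one Φ ~ U[0, 2π) per ligand about the vertical
  axis through its own sulfur, drawn from a single seeded stream in
  site-index order. Because the axis passes through the anchor, rotation
  and translation to the site commute, and the anchor lands exactly on the
  site (tested to 1e-8 Å).
* **Cation placement**: "a centered ligand" is resolved as the occupied
  site minimizing xy-distance to the metal slab centroid, ties broken by
  lowest site index.
* **Neutralization**: a +1 assembly receives one Cl⁻ at the solvent-atom
  position maximizing the minimum distance to any organic atom — the
  least-perturbing placement among available solvent positions. Net
  charges outside {0, +1} are rejected (one localized hole at a time).

The build is a pure function of (template, ligands, coverage, seed,
cation_site); equal seeds give bit-identical coordinates.

## QM-region selection and the additive scheme

Selections are pure functions of geometry with deterministic tie-breaks
(atom/ligand/residue index), using minimum-image distances in x and y only
(the surface is periodic in-plane; no z-periodicity is physical here):

* **Gold ladder** (n ∈ {0, 2, 4, 8}): 2 upper-layer atoms nearest the RL
  sulfur; then 2 lower-layer nearest; then 4 upper-layer lattice neighbors
  of the first pair (within 1.2× the nearest-neighbor spacing), ordered by
  distance to the sulfur. Layers are split at the z-midpoint of the metal.
  "Adjacent" needed a metric; lattice nearest-neighborhood is the natural
  one.
* **Waters**: whole molecules, by oxygen distance to the RL heavy-atom
  centroid.
* **Ligands**: RL first, then by anchor-sulfur distance.

All selections are prefixes/nested as the size grows, so convergence scans
compare nested regions.

The additive decomposition replaces one expensive large-region evaluation
by three cheap ones: `E(1L) + [E(1L+Au) − E(1L)] + [E(2L) − E(1L)]`. Its
validation compares this combination against the direct full-region
evaluation per snapshot (relative error; absolute fallback below 1e-8 V).
For any backend whose environment coupling is linear and free of
cross-terms the identity is exact — the mock engine is built to be exactly
such a backend, so the validation oracle has a closed-form answer (zero)
— while engines with polarization or charge transfer between components
break it at the percent level.

The charge-shell scan switches environment point charges on from far to
near: at radius r, whole molecules whose centroid lies at distance ≥ r
from the RL heavy-atom centroid contribute. The reference point (centroid
rather than the sulfur) is a configuration choice; molecules are never
split across the shell boundary.

The averaged protocol draws `n_snapshots` geometries from the neutral pool
(for VIEs) and independently from the cation pool (for VAEs), evaluates
the three reduced regions per draw, runs the Marcus analysis per region,
and combines the potentials additively. VIE snapshots never come from the
cation pool or vice versa.

## Energy backends

The backend contract is a single operation: the vertical gap at a fixed
snapshot geometry for a given region and embedding, honoring a charge
constraint that localizes the +1 on the RL's nucleobase fragment (the
package's stand-in for constrained-DFT localization: a data statement, not
an SCF procedure; charge delocalization across ligands is deliberately not
modelled).

* **Mock engine**: `gap = I₀ + Σ Δq·q·C/r` over interacting charges, with
  the +1 difference vector spread over the constrained fragment
  (configurable weights, uniform by default). In-region non-RL atoms
  couple with a fixed scaling (default 1.1, a polarization stand-in);
  environment atoms couple with a state-dependent factor (default 1);
  continuum embedding drops explicit solvent charges and adds a constant
  shift (default −0.25 eV). Strictly linear and deterministic by
  construction.
* **Table backend**: verbatim lookup of gaps computed offline
  (CSV columns: snapshot_id, state ∈ {N, N+}, region_tag, gap_eV); the
  ingestion path for real QM/MM/COSMO results.

Embedding modes: `mm_point_charges` (explicit charges everywhere),
`continuum` (no explicit charges), `mm_plus_continuum` (explicit solvent
removed and replaced by the continuum; non-solvent environment keeps its
charges — the multilayer scheme used for production ensembles).

## Seminario force constants

Bond: eigen-decomposition of the 3×3 interatomic sub-block of −H,
projecting eigenvalues on the unit bond vector, averaged over the (i,j)
and (j,i) blocks; equilibrium length read from the geometry. Angle: the
classic construction — perpendicular in-plane projections of the two
terminal–apex blocks combined in inverse-addition form.

Accuracy, measured against analytic harmonic Hessians: a pure diatomic
spring is recovered exactly (to 1e-10, invariant under rigid motions to
1e-6 over 50 random rotations+translations). On a coupled bond+angle
triatomic the terminal-apex blocks mix bond and angle modes: the bond
constant comes back within ~2% and the bending constant carries a known
upward bias of order 10–25% depending on the equilibrium angle. This is an
inherent property of the classic eigen-projection (the issue the
modified-Seminario literature addresses), documented here so downstream
users treat extracted angle constants as semi-quantitative. Equilibrium
values are exact geometry readbacks. Hessians are read from plain-text
full-square or lower-triangular files with a units header
(hartree/bohr² default); ESP charge tables are consumed, validated to sum
to the declared net charge within 1e-4 e, never fitted.

Positional restraints: one per S and per Au atom, k = 50 kcal/(mol Å²),
reference = current position (there is no bonded Au–S term in the force
field, so both partners of the anchoring contact are restrained for the
entire protocol).

## Synthetic inputs: what they emulate, what they do not

* **Template slab**: square-lattice two-layer slab, 2.88 Å in-plane and
  2.04 Å interlayer spacing (Au(100)-like; the exact values are
  config-exposed and no assertion depends on them). A 10×20 top layer with
  two layers gives the 400-atom substrate of the full-scale workflow;
  tests mostly use 4×5. Placeholder thiols share a common 30° tilt.
* **Solvent**: a lattice stub with TIP3P-like charges — enough geometry
  for selection and embedding logic, *not* a realistic water structure.
* **Snapshots**: seeded Gaussian jitter of one assembly (restrained metal
  and sulfur atoms move a fifth as much). They emulate thermal disorder,
  not true Boltzmann sampling: passing tests demonstrate the estimators
  and bookkeeping, not force-field quality.
* **Gap generator**: the two-parabola model. VIE ~ N(ΔA + λ, σ) with
  σ = √(2k_BTλ), so the Stokes and variance routes agree by construction.
  `curvature_ratio` scales the cation-surface width *and* shifts its mean
  consistently (VAE ~ N(ΔA − λr², σr)), realizing the unequal-curvature
  quadratic model for which the cumulant correction is exact.
* **Toy ligands**: a 3-atom stick thiol and a "guanine-like" ligand with a
  labeled 11-heavy-atom nucleobase fragment and per-atom charges summing
  to the declared net charge. Chemically schematic, geometrically
  sufficient.

Consequently, the headline experimental-scale numbers of the full workflow
(free-ligand potentials ~1 V, the large potential decreases upon SAM
assembly, linker-dependent shifts) are *not* reproduced here: they require
real QM/MM/COSMO gap ensembles over hundreds of nanoseconds of dynamics,
which enter through the table backend when available. What the suite does
establish quantitatively: the electron-gas free energy, the SHE
referencing, exact additive-scheme behavior for linear backends, Marcus
parameter recovery within sampling error, the quadratic-correction
algebra, builder determinism and coverage arithmetic, and the selection
ladders against brute-force oracles.

## Numerical choices and edge cases

* FD integrals: adaptive quadrature split at the log-fugacity; fugacity
  solved by bracketed root-finding over ln z ∈ [−60, 400] (classical
  through degenerate regimes).
* Distance ties in selections break on index; builds are therefore
  reproducible across platforms at fixed seed.
* `validate_additivity` falls back to absolute error when the full
  potential is below 1e-8 V (relative error undefined).
* Degenerate tilt (ligand with no non-anchor heavy atoms, or cancelling
  template tilts) raises rather than guessing.
* Coverage yielding zero ligands, unsupported gold-ladder sizes, water or
  ligand shortages, and snapshot-pool shortages raise with counts in the
  message.
* PDB I/O (via MDAnalysis): coordinates round-trip at the format's
  3-decimal precision; the occupancy column carries the ligand id and the
  B-factor the MM charge (2-decimal, lossy — authoritative charges live in
  charge tables, not PDB).
* Snapshot "time" is abstracted to ordered indices; the
  last-350-of-500-ns selection rule becomes a trailing-window fraction
  (default 0.70) with a seeded uniform draw inside the window.

## Problem sizes used by tests and the acceptance script

Tests and `scripts/acceptance.py` run on 4×5×2 toy slabs (40 metal atoms,
14 ligands at 70% coverage), 5-snapshot additivity checks, 20–30 snapshot
protocol runs, and 10⁴-sample gap ensembles — sizes chosen so the entire
suite completes in seconds while every estimator operates far from its
small-sample regime. The builder checks alone use the full 10×20×2 slab
(400 metal atoms).

## Known limitations

* The mock engine's "QM treatment" of in-region components is a scaled
  Coulomb coupling; it validates bookkeeping and linearity, not
  electronic-structure effects (charge transfer, polarization
  self-consistency, image charges in the metal).
* Angle force constants from the classic Seminario construction carry the
  upward bias described above.
* No z-periodicity and no Ewald treatment: electrostatics in the mock
  engine are direct sums, appropriate for the cluster-style toy systems.
* One localized hole at a time: multi-cation assemblies and inter-ligand
  delocalization are out of scope.
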