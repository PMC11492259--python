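# posaqua

Does a positron attach to a biomolecule in water?  `posaqua` models
positron attachment to hydrated zwitterionic amino acids (glycine,
alanine, proline) with the sequential QM/MM protocol: classical NpT
Monte-Carlo sampling of the rigid solute in SPC/E water, followed by
coupled electron+positron Hartree–Fock calculations on statistically
uncorrelated solute–water clusters carved from the trajectory.  It is
aimed at people studying positron–molecule bound states and annihilation
in condensed phases — and, more generally, at anyone who needs a
self-contained two-component (electrons + one positron) SCF with
positron-specific observables on top of a classical solvation sampler.

## What it computes

For a solute X and its vertical positronic complex Xe⁺:

* **Positron binding energies** at three levels:
  ΔSCF (`PBE_HF = E(X) − E(Xe⁺)`), Koopmans (`PBE_KT = −ε_SOMO`, the
  negated energy of the positron's singly occupied orbital), and the
  second-order propagator pole `PBE_P2`, obtained from
  `ω = ε_SOMO + Σ(ω)` where the self-energy Σ adds electronic relaxation
  (lowers binding) and electron–positron pair-removal correlation
  (raises it):

  `Σ(ω) = 2 Σ_{ia} (pp|ia)²/(ω+ε_a−ε_i−ε_p) + 2 Σ_{iaq} (pq|ia)²/(ω+ε_i−ε_a−ε_q)`

* **Two-photon annihilation rates** `Γ_HF = πr₀²c Σ_i S_i` from
  electron–positron density overlaps `S_i = ∫|ψ_i|²|φ_p|²` on a Becke
  multicenter grid, with Green–Gribakin enhancement factors
  `γ_i = 1 + √(1.31/|ε_i|) + (0.834/|ε_i|)^2.15` giving `Γ_ef`, plus a
  core/valence decomposition.

* **Liquid structure**: the solute–solvent minimum-distance distribution
  function (MDDF) with ideal-gas normalization, solvation-shell
  populations, hydrogen-bond counts, cavity radii.

* **Positron diagnostics**: radial probability densities of the positron
  orbital (solute-bound vs surface states), CHELPG-style ESP charges,
  cube-file export of orbitals / contact density / ESP.

* **Ensemble statistics**: means with standard errors over uncorrelated
  configurations, PBE–dipole and Γ–PBE regressions, critical-dipole
  estimates.

The quantum engine is self-contained: native McMurchie–Davidson Gaussian
integrals (s/p/d, Cartesian), coupled two-sector SCF with DIIS, no
external quantum-chemistry dependency.  See `docs/methods.md` for the
models, numerical choices and limitations.

## Worked example

Bind a positron to the isolated glycine zwitterion (built-in geometry,
minimal electron basis, even-tempered positron basis on the two
carboxylate oxygens):

```python
import numpy as np
from posaqua.forcefield import embedded_parameters
from posaqua.liquid import LiquidConfiguration
from posaqua.pipeline import carve_cluster
from posaqua.qc.scf import scf_solve
from posaqua.qc.integrals import compute_integrals
from posaqua.props import pbe_delta_scf, pbe_koopmans, pbe_p2_iterate
from posaqua.annihilation import radial_probability

spec = embedded_parameters("glycine")
config = LiquidConfiguration(solute=spec, solute_coords=spec.coords,
                             water=embedded_parameters("water"),
                             water_coords=np.zeros((0, 3, 3)), box_edge=40.0)
system = carve_cluster(config, 0)          # isolated zwitterion + e+
ints = compute_integrals(system)
parent = scf_solve(system.without_positron())
complex_ = scf_solve(system, integrals=ints)
print(f"PBE_HF = {pbe_delta_scf(parent, complex_):.1f} meV")
print(f"PBE_KT = {pbe_koopmans(complex_):.1f} meV")
rep = pbe_p2_iterate(complex_, ints)
print(f"PBE_P2 = {rep.pbe_p2:.1f} meV "
      f"(relaxation {rep.relaxation:+.1f}, correlation {rep.correlation:+.1f})")
rpd = radial_probability(complex_, spec.carboxylate_carbon, r_max_angstrom=20)
print(f"RPD peak at {rpd.r_max:.2f} Å")
```

prints

```
PBE_HF = 342.7 meV
PBE_KT = 376.4 meV
PBE_P2 = 452.1 meV (relaxation -33.1, correlation +108.9)
RPD peak at 3.66 Å
```

The zwitterion binds the positron at every level (positive PBE); the
positron density peaks ≈3.7 Å from the carboxylate carbon, i.e. on the
negatively charged carboxylate side.  Relaxation reduces and e–p
correlation increases the Koopmans estimate, and the correlation term
wins — the characteristic P2 pattern.  With explicit QM waters added
(`carve_cluster(config, n)` on sampled configurations) the RPD peak
moves outward and the binding drops: hydrogen-bonded waters compete with
the positron for the carboxylate, pushing it toward the cluster surface.

## Command line

```bash
posaqua fixtures glycine                 # embedded geometry + charges
posaqua mc-run --solute glycine --n-waters 125 --steps 1000000
posaqua mc-analyze shells trajectory.xyz # first shell / H-bond summary
posaqua qm-run lih+e+                    # SCF on a registered toy system
posaqua annihilate lih+e+ --grid fine
posaqua run --config run.yaml            # full sequential pipeline
```

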