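# Methods

`posaqua` implements a sequential QM/MM (s-QM/MM) study of positron
attachment to hydrated zwitterionic amino acids: classical Monte-Carlo
sampling of the solvated solute first, then coupled electron+positron
quantum calculations on statistically uncorrelated snapshots.  This note
records the models, the numerical choices, and what the scaled-down
defaults do and do not demonstrate.

## Classical sampling

**Model.** Rigid-body isothermal–isobaric (NpT) Metropolis Monte Carlo at
298.15 K and 1 atm.  Waters are SPC/E (q_O = −0.8476 e, q_H = +0.4238 e,
r_OH = 1.0 Å, HOH = 109.47°, one LJ site on O).  The amino-acid
zwitterions carry OPLS-AA-style site parameters on rigid MMFF94-optimized
geometries.  Both the geometries and the solute charges are stand-ins of
literature quality, not a specific published zwitterion parameterization;
the solvation-shell observables (below) turn out to be insensitive at the
0.1-Å level.

**Moves.** One MC step is one trial move: a random rigid translation
(uniform cube) plus rotation (random axis, uniform angle) of one water.
Every N-th step (N = number of molecules) is instead a volume move,
uniform in V, accepted on exp(−β(ΔU + pΔV) + M ln(V′/V)).  Step sizes are
tuned to ≈40 % acceptance during equilibration and then frozen, so
production samples a fixed chain.

**Interactions.** Site–site 12-6 LJ (Lorentz–Berthelot) + Coulomb.
Truncation is molecule-based: a pair of molecules interacts as a whole
when their reference-site (first heavy atom) minimum-image distance is
inside the cutoff, which keeps interacting groups charge-neutral.  The
default cutoff is 0.49× the initial box edge (the largest value that
volume fluctuations cannot push past the half-box limit).  Two long-range
treatments are implemented: the standard LJ tail correction (always on by
default) and a conducting-boundary reaction-field (RF) term
q_i q_j (r²/2r_c³ − 3/2r_c) inside the cutoff (on by default).  RF was
chosen after comparing both schemes on neat SPC/E water: with RF the
configurational energy per molecule (−47.3 kJ/mol) and density
(1.005–1.010 g/cm³) match published cutoff/RF SPC/E simulations, while
plain truncation overbinds (−48.4 kJ/mol).  No Ewald summation.

**Scaled-down defaults.** 125–250 waters and 10⁶–4×10⁶ production steps
replace the full-scale protocol (1000 waters, ~10⁹ steps).  At these box
sizes the solute concentration is 8–4× higher than in the 1000-water box,
and the measured density of the glycine solution (≈1.00–1.01 g/cm³)
sits correspondingly above the infinite-dilution SPC/E value — the
ideal-mixing estimate for one glycine in 250 waters is ≈1.004 g/cm³, so
this is a real concentration effect, not a sampling artifact.  The
slowest mode of the simulation is the volume/structure relaxation
(integrated autocorrelation times of order 10⁵ steps for 250 waters), so
density averages from runs much shorter than 10⁶ steps are unreliable.

**Thinning.** The energy series is autocorrelated with Sokal's automatic
windowing; the decorrelation interval is 2.5×τ_int, which brings the
lag-1 autocorrelation of an AR(1)-like series under 0.1.  Snapshots for
the quantum stage are evenly spaced picks at least one interval apart.

## Solvation-shell statistics

The minimum-distance distribution function (MDDF) histograms, per solvent
molecule, the minimum over all solute-site/solvent-site distances.  The
normalization reference is an ideal-gas Monte-Carlo estimate: the same
statistic for uniformly random rigid waters (default 2×10⁴ insertions per
configuration) in the same box, which makes the bulk plateau exactly 1
without any analytic reference-volume construction.  Landmarks are read
off a Savitzky–Golay-smoothed curve (the raw curve is kept alongside):

* first peak: first local maximum with G > 0.5;
* first minimum (first-shell boundary): center of the near-minimal region
  (within 5 % of the valley depth) between the first peak and the bulk
  recovery point.  The centroid convention matters because hydrated
  zwitterions have a deep, flat valley (G ≈ 0 over ~0.2 Å) where a plain
  argmin is degenerate and jumps under re-binning;
* cavity onset: first r with raw G > 0.01 (a convention; the underlying
  curve rises from zero smoothly);
* bulk onset: first r from which |G−1| stays below 0.1.

Hydrogen bonds use a geometric criterion (donor–acceptor heavy-atom
distance ≤ 3.5 Å, H–donor–acceptor angle ≤ 30°) with an optional
pair-energy term (≤ −2 kcal/mol, on by default).  The exact thresholds
are a convention; counts for alternative criteria can be requested
side by side.

## Two-component quantum stage

**Integrals.** Native McMurchie–Davidson evaluation over contracted
Cartesian Gaussians up to d (6 components), numba-compiled: overlap,
kinetic, first moments, point-charge attraction, four-index Coulomb, and
mixed electron–positron blocks.  The Boys function uses the downward
series for T < 35 and the asymptotic form beyond.  Every Cartesian
component is normalized to unit self-overlap.  Validation is by closed
forms (Gaussian product theorem, (ss|ss) with erf), multicenter-grid
quadrature cross-checks for p/d attraction and repulsion blocks, exact
one-particle limits (H atom, H₂⁺), the He RHF limit, and rigid
rotation/translation invariance of total energies.

**SCF.**  Closed-shell electrons (or a single electron) coupled to at
most one positron.  The electron Fock operator carries 2J−K plus the
attraction to the positron density; the positron operator (no exchange —
one particle) carries the attraction to the doubly occupied electron
density.  Both sectors are solved simultaneously: DIIS after two cycles,
30 % Fock damping for the first six, canonical orthogonalization dropping
overlap eigenvalues below 10⁻⁸ (positron even-tempered sets are near
dependent by design).  Convergence: ΔE < 10⁻⁸ hartree and RMS ΔD < 10⁻⁶.

**Bases.** The built-in electron basis is minimal: 3-Gaussian expansions
of Slater 1s/2s/2p orbitals fitted in-repo (the 1s fit reproduces the
classic STO-3G coefficients to 7 digits) with standard Slater exponents.
Gaussian94-format files are read for user-supplied bases.  The positron
basis is even-tempered, α_k = α₀βᵏ, centered on the two carboxylate
oxygens; defaults α₀ = 1.6×10⁻³, β = 3.0, 7 exponents in s and p.  These
were picked by minimizing the positron SOMO energy (maximal binding) of
the isolated glycine fixture on a small grid; the optimum is flat to
~0.1 %.  d functions are supported but off by default in the pipeline for
cost.

**Positron binding energies.**  PBE_HF = E(X) − E(Xe⁺) from two
independently converged SCFs (vertical attachment: same geometry).
PBE_KT = −ε_SOMO.  PBE_P2 solves ω = ε_SOMO + Σ(ω) by Newton iteration
(bisection fallback) for the quasi-particle pole continuously connected
to the SOMO, with the second-order self-energy

    Σ(ω) = 2 Σ_{ia}  (pp|ia)² / (ω + ε_a − ε_i − ε_p)      (relaxation)
         + 2 Σ_{iaq} (pq|ia)² / (ω + ε_i − ε_a − ε_q)      (pair removal)

over occupied (i) / virtual (a) electron and virtual (q) positron
orbitals; the factor 2 is the closed-shell spin sum.  Near-vanishing
denominators (<10⁻⁶ hartree) are shift-regularized and logged.  On a
model system with hand-set integrals the pole equation is exactly an
arrowhead-matrix eigenvalue problem, which provides an exact
diagonalization oracle; the relaxation part is negative (reduces
binding) and the pair-removal part positive for every bound fixture.
PBE_P2 = PBE_KT + relaxation + correlation holds identically at the
converged pole.  Unbound cases are reported as PBE ≤ 0, never as errors.

**Annihilation.**  Γ_HF = πr₀²c Σ_i S_i with per-orbital density overlaps
S_i = ∫|ψ_i|²|φ_p|² evaluated on a Becke-partitioned multicenter grid
(three smoothing passes, Bragg-radius size adjustment).  The radial grids
are Gauss-Chebyshev with the standard rational mapping; the angular grid
is a Gauss-Legendre × uniform-φ product (exact to spherical-harmonic
degree 2n_θ−1, comparable to the customary Lebedev grids at the default
n_θ = 17).  Overlaps are computed once per spatial orbital and doubled
for spin.  A two-level grid check (Δ > 1 % between levels raises) guards
coarse grids.  The rate constant πr₀²c ≈ 50.47 ns⁻¹ per atomic unit of
contact density is re-derived from CODATA values at call time.
Enhancement factors γ_i = 1 + √(1.31/|ε_i|) + (0.834/|ε_i|)^2.15
(orbital energies in hartree) multiply each orbital's contribution in
Γ_ef; the parameter triple is provisional pending an authoritative
source, and the deep-core limit γ→1 and the Γ_ef ≥ Γ_HF ordering are
asserted in tests.  Core/valence splits use an orbital-energy threshold
of −2 hartree (captures C/N/O 1s).

**Other diagnostics.**  Radial probability densities of the positron
orbital are spherical-shell integrals about the carboxylate carbon, with
peak position, height and FWHM (linear interpolation).  ESP charges are
CHELPG-style: least-squares point charges on a cubic grid (0.3 Å
spacing) between the vdW surface and a 2.8 Å envelope, constrained to
the total charge; by convention the positron is excluded from the fitted
density.  Cube-file export covers the positron orbital/density, the
contact density ρ_e|φ_p|², and the ESP.

## Pipeline and ensemble statistics

`run_pipeline` chains sampling → thinning → carving → SCF → properties,
checkpointing each stage as plain text and quarantining (not aborting
on) configurations whose SCF fails, with reasons recorded in the
manifest.  The QM region is the solute plus the n waters nearest by the
same minimum-distance metric as the MDDF; remaining waters can enter the
Hamiltonians as SPC/E point charges (electrostatic embedding).  Ensemble
means carry standard errors (σ/√n); regressions are plain OLS with
unadjusted R²; the critical dipole comes either from the x-intercept of
the PBE–dipole regression or from the smallest dipole among bound rows.

## What the scaled-down defaults show

Desk-scale runs reproduce the structural observables quantitatively
(glycine: density ≈ 1.00 g/cm³, first shell boundary ≈ 2.1–2.3 Å with
≈7 waters, ≈7 solute–water hydrogen bonds, cavity onset ≈ 1.53 Å) and
the quantum physics qualitatively with the minimal bases: the isolated
glycine zwitterion binds the positron at several hundred meV with the
RPD peaked ≈3.7 Å from the carboxylate carbon, and adding explicit QM
waters pushes the ensemble-mean peak monotonically outward (≈6 Å at two
waters, ≈7 Å at five) while the binding drops — the solute-to-surface
transition.  Absolute binding energies and annihilation rates are
basis-limited (the minimal set underestimates contact densities roughly
tenfold) and are not asserted against the full-scale benchmarks; those
checks live in `scripts/validate_fullscale.py` and need user-supplied
geometries and bases.  Single-configuration RPD peaks need not be
monotonic in cluster size; only ensemble means are.

## Known limitations

* No Ewald summation; the cutoff+RF scheme carries an O(0.01 g/cm³)
  density bias and the small boxes a comparable concentration effect.
* Single positron only; no positron excited states, no positronium
  channel, no third-order propagator.
* Electron sector is closed-shell (or exactly one electron).
* Basis sets up to d; bundled electron basis is minimal.
* The solute geometries/charges are stand-ins; full-scale benchmark
  numbers are reproduced only in trend, not in value.
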