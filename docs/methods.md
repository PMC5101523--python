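# Methods

## Model

The package implements an anharmonic (nonlinear) elastic network model
of a pigment–protein complex, together with the two analyses that model
supports: detection of discrete breathers in microcanonical dynamics,
and vibronic optical spectra driven by a single localised mode.

### Coarse-graining

Each amino acid becomes one point node of mass 110 amu at its Cα
position.  Each retained bacteriochlorophyll-a pigment becomes 8 nodes
at the MG, C2A, C2B, C2C, C2D, C2, C10 and C18 atoms — five on the
chlorin ring and three on the phytol tail, a split chosen to mirror the
relative masses of the two moieties.  Pigment nodes also carry 110 amu
each (8 × 110 = 880 amu, close to the ~911 amu molecular mass of the
pigment); a per-node mass override is available in the scheme
configuration.  Which pigments are retained is an explicit list in the
scheme (for the FMO trimer the weakly bound eighth pigment of each
monomer is conventionally dropped, leaving 7 per monomer), not a
hard-coded rule.  Waters, ions and other heteroatoms are discarded;
altloc handling and tolerant parsing are delegated to Biopython.

### Potential

Nodes closer than a cutoff R_c in the input geometry are connected by
springs with pair potential

    v(r) = (k2/2)(r − R0)² + (k4/4)(r − R0)⁴

with R0 the equilibrium separation, so V = 0 and ∇V = 0 exactly at the
input structure.  The contact set is frozen at t = 0.  Defaults are
R_c = 10 Å, k2 = 10 kcal/mol/Å², k4 = 10 kcal/mol/Å⁴.  The contact rule
is a strict inequality (r < R_c); ties at exactly R_c are excluded.
The prefactor convention (k2/2, k4/4) is the standard one for this
family of network models; with k2 = 10 and 110 amu nodes it puts the
top of the harmonic band of a compact protein-sized network near
100 cm⁻¹.

### Units

Internal units are Å, kcal/mol and amu.  The derived time unit is
√(amu·Å²/(kcal/mol)) = 48.888 fs, re-derived from CODATA constants in
`units.py`; an angular frequency of 1 rad per time unit is
108.591 cm⁻¹.  All reported frequencies are wavenumbers in cm⁻¹; the
integrator step is specified in fs (default 1 fs).

### Normal modes

The Hessian at equilibrium gets only harmonic contributions (the
quartic term has zero curvature at x = 0): each contact contributes the
familiar k2·ûûᵀ block along the bond.  The mass-weighted Hessian is
diagonalised densely (`scipy.linalg.eigh`; 3N ≈ 4000 is seconds of
work).  Frequencies below 0.1 cm⁻¹ are classified as rigid-body modes —
far below any physical mode at these parameters.  Amplitude shares are
squared components of the *mass-weighted* eigenvectors summed per node;
this convention makes shares sum to one exactly, and with near-uniform
masses it is numerically indistinguishable from Cartesian shares.
Degenerate pairs (unavoidable in C3-symmetric structures) are reported
as returned by the solver, ordered by frequency; analyses that need a
unique mode use the highest mode isolated from its neighbours by a
configurable gap (default 0.5 cm⁻¹).

### Excitation and dynamics

A chosen normal mode is excited with total energy E0.  The default
protocol is a velocity kick: zero displacement, velocities proportional
to the mode's Cartesian pattern, scaled so the kinetic energy equals E0
exactly.  (With displacement excitation the anharmonic potential makes
the displacement–energy relation nonlinear; that protocol is available
too, solving for the amplitude by bracketed root finding.)  An optional
seeded random velocity perturbation of small relative magnitude (the
total energy is rescaled back to E0) breaks symmetries that exact
arithmetic would otherwise preserve: a perfectly C3-symmetric initial
condition stays symmetric forever in exact arithmetic, whereas the
physical mechanism for localisation is the amplification of tiny
asymmetries by modulational instability.  The perturbation makes that
seed explicit and reproducible instead of leaving it to accumulated
round-off.

Integration is velocity Verlet, microcanonical, no thermostat or
friction.  Full state is sampled at a configurable stride (default
100 steps); designated probe coordinates are recorded at every step for
spectral analysis.  Per-node energies — kinetic plus half of each
incident bond's potential energy — are computed at the sampling stride.
The half-bond split makes node energies sum exactly to the total
energy.  The integrator aborts with a diagnostic if the total energy
drifts more than 5% (a symplectic integrator at a sane step drifts by
orders of magnitude less; the guard catches an unstable step size).

### Breather detection

A discrete breather is identified by its two signatures: the main peak
of the displacement power spectrum of the most energetic node lies
*above* the top of the harmonic band, and the time-averaged node-energy
distribution is localised.  Power spectra use mean removal, a Hann
window and magnitude-squared FFT; peak positions are refined by
quadratic interpolation around the grid maximum, which recovers sub-bin
accuracy for narrow peaks (a 300 ps window gives 0.11 cm⁻¹ bins).
"Breather" is declared when the gap exceeds the spectral resolution.

Because the probe node is not known before the dynamics are run, the
orchestrated experiment uses two phases: a transient (default choice in
the drivers: 50–100 ps) with energy bookkeeping only, after which the
node with the largest time-averaged energy becomes the dense probe for
the analysis window.  Localisation measures use a short window (default
5 ps, several breather periods) at the end of the run: breathers in a
translation-invariant chain wander, and averaging over hundreds of ps
smears a strongly localised but mobile excitation into an apparently
flat profile.  The participation ratio is (Σe)²/(N·Σe²) on
time-averaged node energies — 1 for uniform, 1/N for single-node
localisation.  Energy traces of a node or group are Fourier-transformed
after mean removal and their dominant peaks reported separately below
and above 20 cm⁻¹, because a breather modulates local energy both at
twice its own frequency and in a slow (< 10 cm⁻¹) envelope.

### Vibronic spectra

The electronic model is a Frenkel exciton Hamiltonian: site energies
ε_i, couplings J_ij, one shared excitation.  A single harmonic mode of
frequency ω couples linearly to the excited state of a chosen pigment
subset with strength g_i = ω√S (Huang-Rhys factor S; this is the
standard polaron convention, giving reorganisation energy Sω and the
Poisson intensity progression e^{−S}Sⁿ/n!).  The basis is
|site i, mode level n⟩ with n_levels oscillator levels (default 15 —
converged to < 0.1% against 25 levels at S ≤ 0.5).  Absorption starts
from the electronic ground state with the mode in its vacuum; no
thermal population of the 100 cm⁻¹ mode is included (a documented
approximation at 77 K).

Transition amplitudes contract the eigenvector with the site dipoles on
the n = 0 level: μ_ψ = Σ_i μ_i ⟨ψ|i,0⟩.  Linear absorption weights are
|μ_ψ|²; linear dichroism weights are |μ_ψ|² (1 − 3cos²θ_ψ) with θ_ψ the
angle between μ_ψ and the supplied trimer symmetry axis (the standard
convention for oriented trimeric samples); rotational strengths use the
same zero-level amplitudes,
R_ψ = Σ_{i<j} ⟨ψ|i,0⟩⟨ψ|j,0⟩ (r_i − r_j)·(μ_i × μ_j).
Each transition is broadened with a Lorentzian of configurable
half-width (Markovian lineshape); static disorder adds independent
Gaussian draws (FWHM default 100 cm⁻¹) to every site energy, the
Hamiltonian is rediagonalised per realisation (default 1000), and the
mean spectrum is returned.  Disorder draws are independent per site;
given that the model treats one monomer's sites, no cross-monomer
correlation question arises, and the choice is recorded here.  Spectra
are in arbitrary units with a peak-normalisation utility; site
energies, couplings and dipole geometries for a real complex are user
inputs through the config schema and are not bundled.

A note on moments: the intensity-weighted mean of the Franck–Condon
progression is ε exactly (the polaron shift −Sω is cancelled by the
+ωE[n] = +Sω of the progression); the 0–0 line and the spectrum peak
sit at ε − Sω.  Moment checks are done on stick spectra: a Lorentzian
has no finite first moment, so moments of grid-truncated broadened
curves are biased toward the grid centre.

## Synthetic study systems

The generators provide systems with independently known answers:

* **Anharmonic chain** (default 64 nodes, 5 Å spacing, 110 amu,
  k2 = k4 = 10): genuinely one-dimensional; the periodic boundary is an
  image-shifted extra edge, so the monatomic dispersion
  ω_k = 2√(k2/m)|sin(πk/N)| and band edge √(4k2/m) hold exactly.  This
  is the classic testbed in which discrete breathers are well
  characterised.
* **C3 toy trimer** (default 3 × 20 random blob nodes at 7 Å from the
  axis, σ = 2.5 Å, minimum node spacing 3 Å, plus 3 core nodes on the
  axis): three byte-identical monomer copies related by exact 120°
  rotations, core nodes contacting all three monomers.  The Hessian
  commutes with the permutation–rotation operator to machine precision,
  so non-degenerate modes split exactly equally across monomers — the
  surrogate for the delocalised high-frequency modes of a real trimer.
  The blob parameters were chosen once to give a compact, well-connected
  network (mean degree ≈ 24 at R_c = 10 Å) with a band edge near
  155 cm⁻¹, i.e. the same stiffness scale as the stiffer parameterisation
  of the protein model.
* **Toy PDB serialisation** writes CA ATOM records for residue nodes
  and HETATM records with the standard pigment atom names for pigment
  nodes, exercising the full coarse-graining read path.
* **Exciton fixtures**: a monomer (displaced-oscillator closed form), a
  dimer (2×2 exciton closed form, dark-state and CD couplet geometry)
  and a seeded random heptamer with the mode coupled to sites {3, 4, 7}
  by default.

What the surrogates do *not* reproduce: real secondary structure,
residue-specific contacts, pigment binding geometry, or ab initio site
energies.  Tests passing on these systems validate the machinery —
unit conversions, integrator, spectral estimators, Hamiltonian
construction — and the generic physics (breather formation above an
energy threshold, spontaneous C3 symmetry breaking, Franck–Condon
structure), not the specific numbers of any particular protein.
Analyses of a real structure require the user-supplied PDB file and
exciton parameters through the same interfaces.

## Study conditions used by the drivers and the acceptance script

* Chain breather search: band-edge mode, E0 = 60 kcal/mol (high) vs
  0.5 kcal/mol (low), 5% velocity perturbation, 100 ps transient +
  300 ps analysis window at 1 fs.  60 kcal/mol over 64 nodes puts the
  bond-stretch nonlinearity k4·x²/k2 at ~0.2, comfortably in the
  breather-forming regime; 0.5 kcal/mol is deep in the harmonic regime.
* Trimer symmetry breaking: highest non-degenerate (A-symmetry) mode,
  E0 = 120 kcal/mol, 2% perturbation, 50 ps transient + 150 ps window.
  The trimer's band edge (~155 cm⁻¹) corresponds to the stiffer variant
  of the protein model, which needs proportionally more energy to
  localise; 120 kcal/mol sits well inside the localising regime across
  perturbation seeds, while which monomer wins is seed-dependent, as it
  should be for spontaneous symmetry breaking.
* Integrator invariants: 10⁶ steps of 1 fs on an 8-node chain
  (energy drift), 10⁴ steps forward/backward (reversibility).
* Spectra: 1000 disorder realisations, FWHM 100 cm⁻¹, Lorentzian
  half-width 20–30 cm⁻¹, 15 oscillator levels, S = 0.3, ω ∈ {100, 180}
  cm⁻¹.

These sizes keep the full suite and the acceptance script at a few
minutes on one CPU while leaving every measured effect far from its
detection threshold.

## Numerical choices and edge cases

* Eigen-decomposition is deterministic for a fixed input; frequencies
  are reproducible to better than 1e-6 cm⁻¹ across runs.
* Bonds of exactly zero instantaneous length carry no force direction
  (the force magnitude is finite but the unit vector is undefined);
  they are assigned zero force.
* `excite` with the displacement protocol brackets the amplitude by
  doubling until the potential exceeds E0, then uses Brent's method to
  1e-12.
* Peak refinement clamps the quadratic-interpolation offset to ±half a
  bin to stay robust against asymmetric peak shoulders.
* The zero-frequency bin and everything below max(2 bins, 0.05 cm⁻¹)
  are excluded when locating "low-frequency" energy peaks, so the
  removed mean and window leakage cannot masquerade as a peak.

## Known limitations

* No solvent friction or thermostat: the model targets the shielded
  core of a rigid complex; surface modes of a real protein would be
  damped, which the model does not represent.
* Contact topology is frozen at t = 0; very large displacements that
  would break or form contacts are outside the model's validity.
* The breather detector reports the dominant peak only; multi-breather
  states in very long chains are summarised by a single report.
* Vibronic CD/LD conventions are stated above; other conventions exist
  in the literature and would change the spectra's absolute shapes but
  not the qualitative mode-placement comparisons.
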