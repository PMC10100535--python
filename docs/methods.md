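# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `hopdyn`, and what the synthetic setup does and does not
establish about real condensed-phase photodynamics.

## Unit system

Lengths in Å, times in fs, energies in eV, masses in amu, temperatures in K,
converted once at module boundaries (`hopdyn.units`).  The two constants doing
real work are ħ = 0.6582119569 eV·fs and the kinetic-energy conversion
1 amu·Å²/fs² = 103.6427 eV.

## Model surfaces

The electronic structure is a real symmetric diabatic matrix over `n_dof`
nuclear coordinates.  Diagonal elements are linear-plus-harmonic wells

    V_ii(R) = e0_i + g_i·(R − R0_i) + ½ Σ_d k_id (R_d − R0_id)²,

off-diagonals are Gaussians `A_ij exp(−|R − Rc_ij|²/2w²)`.  This family was
chosen because the eigendecomposition gives adiabatic energies while the
Hellmann–Feynman expressions give *exact* gradients and coupling vectors

    ∇E_α = ⟨α|∇V|α⟩,     d_βα = ⟨β|∇V|α⟩/(E_α − E_β),

so every downstream stage can be validated against finite-difference and
matrix-exponential oracles at tight tolerance.  The stock constructor
(`make_avoided_crossing_model`) builds 2- or 3-state tilted-well systems with a
Gaussian coupling centered at **every** pairwise diabatic crossing found along
the first coordinate.  Placing couplings on all seams matters: an uncoupled
seam between non-adjacent diabats otherwise leaves the top adiabat without a
decay channel in exactly the region trajectories visit.  Default parameters
(mass 12 amu, curvature 0.08 eV/Å², separation 4 Å, offsets 0.5 eV, coupling
0.05 eV / width 1 Å) give well-separated surfaces with ~0.1 eV avoided
crossings; the analysis drivers use a faster variant (mass 6, curvature 0.3,
separation 2, offsets 0.3) so that characteristic decay happens within a few
hundred fs of simulated time.

Eigenvectors carry a deterministic gauge (largest-magnitude component
positive); trajectory code additionally enforces sign continuity of `d_βα`
between steps by flipping when the overlap with the previous step is negative.
Adiabatic gaps below 1e-10 eV flag the result as degenerate and zero the
affected couplings rather than returning a spuriously divergent vector; the
trajectory integrator then reuses the previous step's couplings for the flagged
pairs.  No gap threshold ever forbids a hop.

**Oscillator-strength surrogate.**  A fixed symmetric "transition dipole"
matrix is transformed into the adiabatic basis, and
`f_α ∝ (E_α − E_0)·|μ_0α|²`.  This makes strengths smooth functions of the
diabatic mixing angle, which is all the initial-condition selection criterion
needs; the magnitudes are arbitrary by construction.

## Surrogate solvent bath

Bath particles (default mass 18.015 amu, alternating partial charges ±0.4 e)
are placed without overlap (min 2.6 Å) in a shell around the solute and given
Maxwell–Boltzmann velocities.  The bath potential is fully analytic:

* harmonic tethers to the initial sites (k = 0.08 eV/Å²),
* soft pair repulsion `2.0·exp(−r/0.4 Å)` eV,
* solute–bath coupling `g · s(R) · Σ_j q_j (1 + r_j²)^{−1/2}` with
  `s(R) = Σ R_d` and g = `coupling_strength` (default 0.01 eV/Å).

The coupling form is a free design choice — the reference protocol specifies
only that a classical water model surrounds the solute, which is not
desk-recomputable — and is documented rather than inferred.  The bath
reproduces canonical kinetic statistics under the thermostat and exerts
configuration-dependent forces on the solute, which is what the embedding and
thermostat machinery needs.  It does **not** reproduce water structure,
hydrogen bonding, dielectric response or realistic friction; passing tests
show the *algorithms* are correct, not that a particular chromophore's
lifetime in water is predicted.  Notably, with the default weak coupling the
bath drains solute energy slowly, so closed-system recrossing (repopulation of
upper surfaces at constant total energy) persists in long gas-like runs — a
known difference from strongly dissipative solvated dynamics that is visible
in `analysis/02_swarm_dynamics.py`.

## Subtractive embedding

`E = E(full, low) − E(QM, low) + E(QM, high)`, gradients combined with the
same signs, forces as negative gradients.  Mechanical embedding only: the
high-level engine never sees bath coordinates.  Engines are callables
`(geometry, state) → (energy, gradient)`; the low-level engine dispatches on
geometry length (QM region vs full system).  Whether the low-level term
includes intramolecular solute contributions is immaterial to `E_total` — they
cancel between the first two terms — which the cancellation-identity test
verifies to machine precision.

## Nuclear dynamics and thermostat

Velocity Verlet throughout (the standard choice for this class of dynamics;
time step 0.5 fs for ground-state sampling, 0.1 fs for hopping dynamics).
The Andersen thermostat acts on solvent DOFs only: each masked DOF is redrawn
from the Maxwell–Boltzmann distribution with probability `1 − exp(−ν·dt)` per
step (default ν = 0.01 fs⁻¹ for sampling; configurable).  Chromophore
velocities pass through the thermostat bit-identically, which is asserted in
the tests.  Ground-state runs store every 10th step (decorrelating initial
conditions) together with vertical excitation energies and surrogate
strengths; swarm starting points are the snapshots whose excitation energy
lies in a configured window *and* whose strength exceeds a configured
threshold.  Neither cutoff has a privileged default — both are required run
inputs, as in the reference protocol.

## Fewest-switches surface hopping

Amplitudes evolve by `iħ ċ_α = E_α c_α − iħ Σ_β σ_αβ c_β` with
`σ_αβ = Ṙ·d_αβ` taken analytically from the model (no overlap-based numerical
time-derivative couplings are needed).  Energies and couplings are
interpolated linearly across each nuclear step and the linear ODE is
integrated by RK4 over 20 substeps (each substep assembled as a matrix map;
substeps double adaptively up to 16× while the per-step norm drift exceeds
1e-10).  Norm drift above 1e-8 triggers a logged renormalization; above 1e-4
the trajectory is aborted as numerically unsound.

Hop probabilities follow the standard fewest-switches prescription (the
rectified form `g_{α→β} = max(0, 2Δt Re(c_β c_α* σ_αβ)/|c_α|²)`, clamped onto
the simplex); the convention pairs with the amplitude equation above so hops
track amplitude population flow.  One uniform draw per step selects the target
by cumulative bins.  Accepted hops rescale the velocity along `d_βα`
(mass-weighted quadratic, smaller-|γ| root); with no usable coupling direction
the rescale falls back to isotropic.  Frustrated hops leave velocities
unchanged by default; reflecting the component along the coupling is available
per config.  Direct S2→S0 hops are algorithmically allowed.  No decoherence
correction is applied by default (none is used in the reference protocol); an
optional energy-based exponential damping is provided but off.

The ensemble-vs-amplitude internal-consistency ratio is observable from the
stored amplitude histories but deliberately not asserted as an invariant —
fewest-switches dynamics satisfies it only approximately.  A single-passage
comparison against the Landau–Zener probability is kept as a wide-band sanity
test (±0.15 at P ≈ 0.5).

## Lifetimes and errors

Populations are trajectory fractions per surface on a common grid; they form a
partition of unity by construction.  The sequential kinetic fit minimizes the
joint unweighted least squares of the S₂ and S₁ curves over (log τ₂, log τ₁)
(positivity by parameterization; S₀ is redundant and excluded; weights are a
design choice — the reference states the fit but not the weighting).  Starting
values are deterministic: the 1/e crossing of S₂, and of S₁'s post-peak tail.
The degenerate τ₁ = τ₂ case uses its analytic limit `(t/τ)e^{−t/τ}`.  For
two-state swarms (one excited surface) the τ₂ → 0 limit — a single
exponential on the excited population — is fitted instead.

**Subset error protocol.**  For division level k = 2, 3, … (kept while a
subset still holds more than 30 trajectories): reshuffle the swarm order,
split into k parts, fit each, record the sample standard deviation (ddof = 1)
of the fitted lifetimes across parts; average each level over 10 reshuffles;
fit the level spreads linearly against 1/N (N = trajectories per subset,
intercept included) and evaluate at the full-swarm N.  "Spread" as a standard
deviation is a documented choice — half-ranges would be an alternative
reading.  The 1/N abscissa is implemented as specified even though subset
spreads of a mean-like estimator empirically scale as 1/√N; the linear-in-1/N
extrapolation with intercept nevertheless tracks the true sampling error well
at study scale (at n = 190 with τ₁ = 0.83 ps it yields σ ≈ 0.08 ps against a
true swarm-to-swarm scatter of ≈ 0.06 ps), and the conventional 1/√N abscissa
is available behind the `abscissa` option.  Extrapolated values are clamped at
zero; fewer than two usable division levels is an error, not a silent skip.

## Orchestration and determinism

A master seed spawns named `SeedSequence` child streams: one per stochastic
stage (bath construction, ground-state sampling, subset reshuffles) and one
per trajectory id.  Rerunning a config is byte-identical; enlarging the swarm
appends trajectories without perturbing existing ones.  Artifacts are
delimited text tables (populations; a lifetime summary in the column order
n, τ₂, σ, τ₁, σ), extended-XYZ geometries (12-decimal coordinates; write∘read
is the identity to 1e-10), and a JSON manifest with config echo, seed-stream
map, versions and a config hash.

## Problem sizes

The shipped drivers and tests use deliberately small systems — 1-DOF solute
models, 4–20 bath particles, swarms of 6–28 hopping trajectories, 150–400
sampled-swarm trajectories, horizons of 45–300 fs — sized so the full suite
and drivers run in minutes on a single core while still exercising every code
path at statistically meaningful scale.  The statistical machinery (fitting,
subset errors, bias checks) is validated at the full study scale of 190
trajectories via the kinetic hop-time sampler, which is exact for the
sequential decay process.

## Known limitations

* Mechanical embedding only; no electrostatic polarization of the QM
  Hamiltonian, link atoms, covalent boundaries, or periodic boundaries.
* No intersystem crossing or spin–orbit coupling; no conical-intersection
  geometry optimization.
* The surrogate bath is not water (see above); dissipation is weak by default.
* FSSH itself carries its usual caveats (overcoherence without a decoherence
  correction, approximate internal consistency); this package implements the
  plain algorithm faithfully rather than improving on it.
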