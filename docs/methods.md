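# Methods

## Model overview

`oligobrush` implements a molecular-level self-consistent field theory for
charge-regulating oligonucleotide brushes. A fixed number of 12-mer A/G
chains per unit area is tethered to an impenetrable planar wall; water,
H⁺, OH⁻, Na⁺, Mg²⁺ and Cl⁻ are exchanged with a bulk reservoir at fixed
chemical potentials (semi-grand canonical ensemble). The system is assumed
laterally homogeneous, so all structure is resolved only along z, the
distance from the wall, discretized into `n_layers` slabs of width `dz`
(defaults 100 × 0.3 nm). Units throughout: kT for energy, nm for length,
e for charge; molar inputs convert at the boundary (1 M = 0.602214 nm⁻³).

Two position-dependent conjugate fields close the theory:

* **π(z)** — the lateral-pressure (packing) field, the Lagrange multiplier
  of the incompressibility constraint Σ_species φ(z) = 1 in every layer.
  Gauged to zero in the bulk; the bulk osmotic pressure is absorbed into
  the exchange chemical potentials.
* **ψ(z)** — the mean electrostatic potential, obeying the Poisson equation
  ε_w ψ'' = −⟨ρ_q⟩ with zero field at the wall (no surface charge) and a
  grounded far boundary.

Given (π, ψ), everything else is closed-form:

* free species follow Boltzmann profiles
  ρ_γ(z) = ρ_γᵇ exp(−π v_γ − z_γ ψ);
* each monomer type i ∈ {A, G} populates four states (bare i⁻, iH, iNa,
  iMg⁺) with fractions solved analytically from the three mass-action laws
  f_iX/f_i⁻ = K⁰_iX ρ_X(z) v_w and the normalization Σ_s f_is = 1 — the
  per-type normalization multipliers never appear as solver unknowns;
* conformation probabilities are
  P(α) ∝ g_α exp(−Σ_k n_i(α;k) w_i(k)) with the per-monomer field
  w_i = ln f_i⁻ + π v_p − ψ measured relative to its bulk value, evaluated
  with log-sum-exp; g_α is the multiplicity of the binned occupancy class.

The monomer charge ladder is (−1, 0, 0, +1) across (i⁻, iH, iNa, iMg⁺).
Bound complexes carry the summed volume of their parts (v_iH = v_p + v_H,
v_iNa = v_p + v_Na, v_iMg = v_p + v_Mg): the reaction volume changes are
exactly zero, so no explicit exp(−πΔv) factor survives in the mass-action
laws, while the packing constraint still feels every bound ion. This
volume bookkeeping is what produces the re-entrant stretching of dense
brushes — each captured Mg²⁺ adds 0.18 nm³ to the layer it occupies — and
is the one place where we deliberately departed from treating all monomer
states as equal-volume, which would make binding sterically free and
suppress that mechanism.

## Chain ensemble

The conformational ensemble is a rotational isomeric state model of a
freely-rotating bead chain: bond length b = 0.6 nm (the scale of the
ssDNA phosphate–phosphate virtual bond), bond angle 112°, and three
torsion states (trans 180°, gauche ±60°) on each of the N−3 = 9 interior
torsions of a 12-mer. All 3⁹ = 19 683 assignments are embedded, each under
`rotations_per_state` independent uniform solid-body rotations about the
grafted bead (uniform random rotation matrices from a seeded generator);
embeddings with any bead center below the wall are rejected (measured
acceptance ≈ 0.27). Bead centers are binned into half-open layers
[kδ, (k+1)δ); identical occupancy vectors are merged with integer
multiplicities, which preserves all statistical weights exactly while
shrinking the working set several-fold. The grafted bead sits at δ/2 so it
is strictly inside the first layer. The default 38 rotations per state
yield ≈ 2×10⁵ accepted conformations; the test suite uses seeded reduced
ensembles (3×10³–4×10⁴) and separately asserts that doubling the
default-size ensemble moves the polymer profile by < 2% sup-norm.

No intra-chain excluded volume is enforced beyond wall rejection;
inter-monomer repulsion is carried entirely by the packing constraint.
Base pairing, stacking and secondary structure are out of scope.

## Chemistry and parameter provenance

| parameter | value | provenance |
|---|---|---|
| pKₐ(A), pKₐ(G) | 3.5, 1.6 | measured acid constants |
| ΔG Mg²⁺ (A, G) | −32.1, −35.6 kJ/mol | measured in 10 mM NaCl background |
| ΔG Na⁺ (A, G) | −21 kJ/mol | non-specific backbone component; an implementation default, not a measured site constant |
| v_Mg²⁺(aq), v_Na⁺, v_Cl⁻ | 0.18, 0.05, 0.05 nm³ | stated species volumes |
| v_w = v_H = v_OH | 0.030 nm³ | standard for this theory family (not stated) |
| v_p (monomer) | 0.30 nm³ | model choice (not stated) |
| ε_r, pKw, T | 78.5, 14.0, 298 K | standard water at 298 K |

Constants enter the mass-action laws as dimensionless K⁰ on the ρ·v_w
activity scale. pKₐ values are molar by definition and are always
converted (K⁰ = 10^pKₐ / (0.602214 v_w)). The Mg²⁺ and Na⁺ free energies
are used directly as K⁰ = exp(−ΔG/RT), exactly as the model equations are
written; a `reference="molar"` switch converts them like the pKₐ values
instead, isolating the standard-state convention in one function.

**Mg²⁺ exchange pathway.** The Mg²⁺ free energies were measured on
surfaces equilibrated with NaCl, where the divalent ion displaces
non-specifically associated Na⁺. We therefore read them as exchange free
energies relative to the Na⁺-dressed site: the bare-site association used
in the mass-action law is ΔG_iMg + ΔG_iNa = −53.1 / −56.6 kJ/mol
(`mg_exchange_pathway=True`, the default). Used instead as bare-site
constants (flag off), Mg²⁺ binding is far too weak to reproduce the
regime this model family reports for these systems — deprotonated
fractions of order 10⁻⁴ and brush pH approaching 9 — whereas the exchange
reading recovers both. The flag keeps the alternative one switch away.

The derivation direction of the mass-action laws is fixed by the free
energy: strong association must increase the bound fraction, so
f_bound/f_bare = K⁰·(activity).

## Numerics

* Unknowns: the stacked vector (π, ψ) on layer centers (2 × n_layers).
  Residuals: per-layer packing violation, and the second-order central
  discrete Poisson residual with a Neumann ghost at the wall
  (ψ₋₁ = ψ₀) and a Dirichlet ghost (ψ_n = 0) one spacing past the far
  edge.
* Solver: damped Newton with a forward-difference Jacobian (all columns
  evaluated in one vectorized batch), LU solve, and an Armijo backtracking
  line search on ‖r‖²; convergence at max-norm residual ≤ 1e-8 (default).
  Dense brushes are reached by geometric continuation in grafting density
  (factor ≈ 3.2 per rung, warm-started, with log-bisection of any failing
  rung). Typical cost: 3–6 Newton steps per rung.
* Boltzmann exponents are clipped at ±500 during early iterations; clip
  events are counted and must be zero at convergence.
* The semi-grand potential per unit area is evaluated in field-substituted
  form, βW/A = −σₚ ln(Q/G) − Σ_γ ∫(ρ_γ − ρ_γᵇ) dz − ∫π dz −
  (ε/2)∫(ψ')² dz, with the electrostatic term in the Legendre-transformed
  (field-eliminated) sign convention so that stationarity in ψ yields the
  Poisson equation with its physical sign. By the envelope theorem its
  finite-difference gradient equals dz times the residual vector; the test
  suite asserts this identity directly, and the brute-force oracle solves
  toy problems by root-finding that gradient without ever touching the
  analytic residual assembly.
* Discretization error is second order: halving dz changes the converged
  potential at a fixed position by O(dz²) (asserted by Richardson ratio on
  a toy problem).
* Global electroneutrality holds in the telescoped sense exactly (net
  charge = dielectric flux through the far boundary); the flux itself
  decays with the diffuse tail, so the strict 1e-6 e/nm² check is run on a
  grid deep enough (60 nm) for the tail to vanish. At the standard 30 nm
  grid a dense brush leaves a ~1e-4 residual flux — a property of the
  printed grid, not of the solver.

## Observables

* **Bound ions per chain**: N_X = δ Σ_k (⟨ρ_A⟩f_AX + ⟨ρ_G⟩f_GX)/σₚ — the
  monomer-number-density form, exact irrespective of state volumes; the
  four per-chain counts partition the 12 monomers exactly.
* **Deprotonated polymer fraction** f_P⁻(z): volume-weighted share of bare
  monomers; layers without polymer are reported missing (NaN), not zero.
* **Local pH**: −log₁₀ of the local molar H⁺ concentration — the only
  definition consistent with a "bulk pH 7" input.
* **Brush height**: first-moment height h = 2⟨z⟩_φ of the polymer profile.
* **"Inside the brush"**: layers with φ_p > 10⁻⁴ × max φ_p — a
  reproducible region for min/max summaries.

## What the synthetic ensemble does and does not emulate

The RIS generator emulates the configurational diversity of a short,
flexible, grafted chain: wall-constrained, orientationally isotropic,
torsionally disordered. It does not emulate sequence-dependent stiffness,
electrostatic persistence length, intra-chain excluded volume, base
stacking, or solvent-mediated Mg²⁺ pairing (the ion is a point charge with
a hydrated volume). Tests passing on this ensemble therefore validate the
field theory and its thermodynamics, not the conformational statistics of
any specific real oligonucleotide; geometry parameters (b, bond angle,
torsions) are explicit knobs.

## Scale choices

Acceptance-level runs use ≈ 2×10⁵ accepted conformations (the profile
observables are converged to well under 1% at this size; see the
ensemble-doubling test). The in-suite solves use 3×10³–4×10⁴-conformation
seeded ensembles, chosen so the full test suite and the acceptance script
each complete in about a minute; all stochastic fixtures echo their seed
and size.

## Known limitations

* The minimum brush pH of a dense, Mg-free brush is sensitive to the Na⁺
  site constant, which is not an experimentally measured quantity here.
  With the −21 kJ/mol default, Na⁺ binding neutralizes enough brush charge
  that the model floors near pH 5.6; a substantially weaker Na⁺
  association (K of order 1 M⁻¹) would acidify the layer by roughly one
  more unit. We keep the documented default rather than tune it; the
  constant is a single config key (`chemistry.dG_ANa` / `dG_GNa`).
* One-dimensional: no lateral heterogeneity, microphase separation, or
  grafting defects; walls are uncharged and non-adsorbing; the dielectric
  constant is uniform.
* Mean-field electrostatics: ion–ion correlations beyond steric packing
  and charge regulation are absent.
* No secondary/tertiary structure, no Mg²⁺ hydration-shell ion pairing,
  no reaction volume changes beyond the additive-volume convention.
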