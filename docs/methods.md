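# Methods

This note records the models, numerical choices and deliberate
simplifications behind `deff`, in the order a reader meets them: the pair
potentials, parameter typing, the condensed-phase energy model, sampling,
the alchemical path and free-energy estimation, curve fitting, and what the
synthetic fixtures do and do not emulate.

## Units

kcal/mol, Ångström, elementary charge, Kelvin, atm. Coulomb constant
k_e = 332.06371 kcal·Å/(mol·e²); gas constant R = 1.9872×10⁻³ kcal/(mol·K);
1 atm = 1.4584×10⁻⁵ kcal/(mol·Å³). No function accepts other units.

## Pair potentials

The double-exponential form

U(r) = ε/(α−β)·[β·e^{α(1−r/r_m)} − α·e^{β(1−r/r_m)}],  α > β > 0,

has its single stationary point at r = r_m with value −ε, decays as
e^{−βr/r_m} at long range, and is finite at contact:
U(0) = ε(β·e^α − α·e^β)/(α−β) (≈ 6.9×10⁶ ε for the default shape). α and β
are *global*: one pair per library, shared by all types. ε = 0 is a legal
"vdW-disabled" value (used for polar hydrogens) and every form returns
exactly zero for it, without evaluating exponentials.

The damped Buckingham-6-8 reference form is
A·e^{−Br} − f₆(r)C₆/r⁶ − f₈(r)C₈/r⁸ with Tang–Toennies damping
f_n(r) = 1 − e^{−Br}·Σ_{k≤n}(Br)^k/k!, using the repulsive decay B as the
damping rate. The published B68 water model specifies its own damping in
supplementary material we do not reproduce; Tang–Toennies is the standard
stand-in and is clearly bounded: f_n/r^n → B^n/n! as r → 0, so U(0⁺) → A.
For Br < n the damping factor is evaluated through the complementary series
e^{−Br}·Σ_{k>n}(Br)^k/k! to avoid catastrophic cancellation (the direct
form loses all precision below r ≈ 0.3 Å).

All radial derivatives are analytic and tested against central finite
differences at 10⁻⁶ relative over r ∈ [0.3, 5]·r_m.

## Parameter libraries and typing

Parameters live in a single-file XML dialect (`<DEForceField>` with
`<GlobalShape>`, ordered `<DoubleExponential>/<Atom>` records,
`<Electrostatics>`, `<VirtualSites>`); attribute units are fixed, not
annotated. Typing is direct chemical perception: each record's SMIRKS
pattern (exactly one tagged atom) is matched against the molecule via
RDKit, and the **last** matching record in file order wins, so generic
types precede refinements. Assignment is a pure function of
(graph, library); unmatched atoms raise rather than defaulting — elements
outside the parameterised set (S, P, F, I here) are rejected.

Partial charges are input data, read from SDF property fields or set by
fixtures; charge generation is out of scope. 1-4 scaling defaults to 0.5
(vdW) and 0.8333333 (electrostatics), the Amber-style convention; the
values are library attributes, not constants.

## Condensed-phase energy model

Orthorhombic boxes, minimum-image convention, O(N²) dense-matrix pair loops
— appropriate for the few hundred particles this package targets. vdW pairs
are cut off at r_c (default min(9 Å, L/2)) with a quintic smoothstep taper
over the final 1 Å; electrostatics use reaction-field with ε_RF = 78.3,
shifted to vanish at the cutoff. (The production-scale reference for this
kind of model is particle-mesh Ewald; reaction-field keeps the artifact
dependency-free and is accurate enough for the small boxes here, but
absolute electrostatic energies are not comparable to Ewald values.) A
long-range correction integrates the attractive DE exponential beyond the
cutoff analytically, 2π/V·Σ_{i≠j} I_ij with
I_ij = −ε_ij·α/(α−β)·e^β·∫_{r_c}^∞ r²e^{−βr/r_m,ij} dr in closed form; the
repulsive α-term is negligible beyond any sane cutoff and is omitted.

Scaled 1-4 pairs are separate bonded-style terms so the main pair loop
never special-cases them. Unlike-pair parameters follow Lorentz–Berthelot
(arithmetic r_m, geometric ε).

Virtual sites are massless charged particles on the H-parent-H bisector at
a fixed distance from the parent (the 4-point water M-site); the builder
moves the parent's charge onto the site. Sites are re-placed from parent
coordinates before every energy evaluation, making the energy a pure
function of real-atom positions; forces on sites are projected onto parents
through the analytic Jacobian of the bisector construction, so net force
and torque on an isolated molecule vanish.

## Monte Carlo sampling

Sampling is rigid-body Metropolis MC, not MD: molecules translate and
rotate as rigid units (quaternion-free Rodrigues rotations about the
centroid), so constraint dynamics are avoided entirely while sampling the
same NVT/NPT ensembles. Volume moves are linear in V with the
molecule-count Jacobian, acceptance
exp(−β(ΔU + PΔV) + N·ln(V′/V)), which makes the ideal-gas mean volume
(N+1)kT/P — one of the analytic checks in the tests. Water geometry is held
rigid at O-H = 0.9572 Å, ∠HOH = 104.52°.

Move sizes default to 0.25 Å / 0.35 rad (≈40–60 % acceptance in the water
boxes); the move mixture is translation:rotation:volume = N:N:1. A tagged
solute can be picked preferentially (`solute_move_weight`); the selection
probability is configuration-independent, so detailed balance needs no
acceptance correction. Incremental energies re-sum only the moved
molecule's interactions; the running total is verified against a fresh
recomputation to 10⁻⁸ relative in the tests.

Two engine paths exist: a plain-numpy reference loop (NPT, external
potentials, anything unusual) and a numba-compiled NVT fast path
(~5 µs/step for ~100 particles) used automatically for rigid
translation/rotation sampling. They implement the same ensemble but
different RNG streams; determinism per seed holds on each path separately.

Estimators: ρ = M_total/⟨V⟩ with block-averaged standard errors;
ΔH_vap = U_gas − ⟨U_liq⟩/N + RT (rigid molecules; U_gas = 0 for a rigid
monomer with no intramolecular non-bonded pairs).

## Alchemical path and free energies

Decoupling, not annihilation: only solute–environment terms change.
Electrostatics scale linearly in λ_elec and reach zero before vdW departs —
the schedule type enforces this ordering. The vdW leg uses the DE natural
soft core

U_sc(r; λ) = λ·U_DE(r; ε, r_m, λα, λβ),

which is the plain potential at λ = 1 (bit-for-bit: same code path), zero
at λ = 0, and finite everywhere in between. One fine point: U_sc(0; λ) has
slope −ε at λ = 0⁺, so the contact value dips slightly negative (bounded
below by −ε) before the wall grows — harmless for sampling, but the
"monotone in λ at r = 0" intuition only holds for λ ≳ 0.3. A Beutler-style
LJ soft core is included for comparison. The solute–environment share of
the tail correction is scaled linearly in λ_vdw; using the softened decay
λβ instead would make the tail integral diverge as λ → 0.

The default schedule is two-legged: n_elec evenly spaced electrostatic
windows at full vdW, then n_vdw vdW windows at zero charge, sharing the
corner state — (5, 16) gives the standard 20-window path.

MBAR is solved by quasi-Newton minimisation of the convex objective
followed by self-consistent polish to a 10⁻¹⁰ residual; uncertainties come
from the SVD form of the asymptotic covariance of the weight matrix, and
the overlap matrix (rows summing to one) is reported for diagnostics. K = 2
reduces to BAR (tested against an independent Bennett-equation solver).
Statistical inefficiencies g = 1 + 2Σ(1−t/T)C(t) decorrelate each window's
samples — computed on the reduced-energy *difference to the neighbouring
window*, the observable MBAR actually consumes, because the total energy
decorrelates an order of magnitude more slowly and would waste most of the
data. Cross-evaluation of retained configurations at all windows exploits
two exact structures: the environment energy is a per-sample constant
(MBAR-gauge-invariant, dropped), and only the cheap solute–environment
terms vary with λ. The first 20 % of each window is discarded as
equilibration; windows are chained serially from the previous window's
final configuration.

Sign conventions: ΔG_solv = G(coupled) − G(decoupled), negative for
favourable solvation; ΔG_trans(aq→nonaq) = ΔG_solv(nonaq) − ΔG_solv(aq),
uncertainties in quadrature.

## Curve fitting

`fit_de_to_curve` runs bounded nonlinear least squares over
(ε, r_m, α, s) with β = α − e^s, so α > β cannot be violated. Residuals are
weighted w_i = exp(−max(E_i, 0)/2 kcal·mol⁻¹), down-weighting the repulsive
wall so the well region dominates. Defaults: ε ∈ (0, 10], r_m ∈ [0.5, 10],
α ∈ [6, 30], β ≥ 2. The fit is deterministic given the initial point
(seeded from the reference minimum and the default global shape when
omitted). Recovery is exact (residual < 10⁻⁸, parameters to 10⁻⁴ relative)
when the reference lies in the DE family; fits to LJ or damped B68
references locate the reference well position and depth to ~1–2 %.

Dimer scans translate a rigid monomer along an axis and report
E(AB) − E(A) − E(B) in vacuum with no cutoff; coincident chargeless atoms
are legal (the DE form is finite there).

## Synthetic fixtures: what they emulate, what they do not

The packaged library is a *stand-in*: ~12 SMIRKS records with plausible
C/H/O/N/Br values and a TIP4P-FB-like 4-point water (vdW on oxygen only,
ε = 0.179, r_m = 3.55; q_H = +0.52587 balanced by an M-site of −1.05174 at
0.1053 Å), with the trained global shape α = 16.766, β = 4.427. The
trained per-type values of the real force field are not reproduced here.
Water boxes are jittered lattices at 0.997 g/mL with a guaranteed 2 Å
minimum O-O separation, deterministic per seed. Consequently, passing tests
demonstrate correctness of the machinery — energies, sampling,
estimators, path convergence — on a self-consistent model; they say
nothing about agreement with experimental water or solvation data, which
would require the trained parameter set and far longer sampling.

## Problem sizes and scaled-down studies

All studies run at desk scale, chosen so each carries meaningful
statistics: the window-count convergence study uses a neon-like single-site
solute (ε = 0.069 kcal/mol, r_m = 3.1 Å, q = 0 — noble-gas range, chosen
because its solvation cage relaxes several times faster than a
methane-sized probe, which a pilot power analysis showed is what limits
resolving a 0.1 kcal/mol criterion) in 20 four-point waters, with 2–3×10⁶
MC steps per window on the 6-window leg and 1–1.5×10⁶ on the 16-window leg
(roughly equalising the two legs' variances; the reproduction script uses
the upper sampling and reports the gap's quadrature uncertainty beside
it). The null-solute and
Boltzmann-distribution checks use 16 waters and a two-particle box
respectively; NPT water properties use 24–32 waters. Reported MBAR
uncertainties at these sizes are approximate (correlated-sample effects
survive decorrelation at the ~2× level in the hardest windows); replicate
spreads across seeds were used to size the studies.

## Known limitations

- Reaction-field (not Ewald) electrostatics; orthorhombic boxes only;
  O(N²) loops.
- The B68 damping function and the trained per-type parameters are
  stand-ins for supplementary-material originals.
- MC, not MD: no dynamical observables; fluctuation properties
  (compressibility, heat capacity, dielectric constant) have no estimators.
- The λ-mapping (prefactor λ, shape λα/λβ) is one reading of "scale the
  shape parameters down with λ"; it is exposed as the single built-in
  strategy and validated by the window-count convergence study rather than
  assumed.
- Virtual-site support covers bisector (M-site) geometry only.
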