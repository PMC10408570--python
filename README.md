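# deff — a double-exponential non-bonded potential toolkit

`deff` is a compact molecular-modelling library for working with the
**double-exponential (DE) pair potential** as a drop-in alternative to
Lennard-Jones in condensed-phase force fields:

```
U_DE(r) = ε/(α−β) · [ β·e^{α(1−r/r_m)} − α·e^{β(1−r/r_m)} ]
```

As in the 12-6 form, `ε` is the well depth and `r_m` the minimum-energy
separation; the two dimensionless *global* shape parameters `α` (repulsive
steepness) and `β` (attractive decay) are shared by every atom type
(defaults `α = 16.766`, `β = 4.427`). Unlike LJ, the DE energy is **finite
at r = 0**,

```
U_DE(0) = ε (β·e^α − α·e^β)/(α−β),
```

which gives it a *natural soft core*: alchemical decoupling needs no change
of functional form, just `U(r; λ) = λ·U_DE(r; ε, r_m, λα, λβ)`.

The package is aimed at force-field developers and students of free-energy
methods who want a small, fully-inspectable stack rather than a production
MD engine. It provides:

- **potentials** — closed-form LJ 12-6, DE, damped Buckingham-6-8
  (Tang–Toennies) and Coulomb energies with analytic radial derivatives;
- **params** — SMIRKS-keyed parameter libraries in a single-file XML
  dialect, assigned to molecules by direct chemical perception (last
  matching pattern wins), with partial charges taken as input data;
- **system** — Lorentz–Berthelot combination, 1-2/1-3 exclusions and scaled
  1-4 pairs, bisector virtual sites (4-point water M-site), periodic
  energies/forces with a switched cutoff, reaction-field electrostatics and
  an analytic DE tail correction;
- **mc** — rigid-body Metropolis Monte Carlo in NVT and NPT with density
  and heat-of-vaporisation estimators (a JIT-compiled inner loop samples
  millions of moves per minute on one core);
- **alchemy / fe** — λ-schedules, the DE natural soft core, a Beutler LJ
  soft core for comparison, and a self-contained MBAR solver with
  asymptotic uncertainties and overlap diagnostics;
- **curvefit** — dimer dissociation scans and bounded least-squares fitting
  of DE parameters to reference curves (e.g. a Buckingham-6-8 water
  oxygen–oxygen potential);
- **workbench** — deterministic fixture generators (water boxes, toy
  solutes, a monatomic DE fluid) and a packaged stand-in parameter library.

## Worked example: solvation free energy of a methane-like solute

```python
from deff import (MCSettings, default_schedule, fixture_library,
                  make_toy_solute, make_water_box, solvation_dg)

library = fixture_library()
solute, params = make_toy_solute("methane_ua")      # single site, ε=0.2, r_m=4.0, q=0
system, conf = make_water_box(16, library, seed=3,
                              solute=solute, solute_params=params)

schedule = default_schedule(n_elec=2, n_vdw=8)      # elec off first, then vdW
settings = MCSettings(temperature=298.15, n_steps=300_000, seed=4,
                      sample_stride=200, solute_move_weight=6.0)
est = solvation_dg(system, conf, schedule, settings)
print(f"dG_solv = {est.delta_f:+.3f} +/- {est.uncertainty:.3f} kcal/mol")
```

Output (examples/05_solvation_free_energy.py):

```
windows: 9  (2 elec + 8 vdW, shared corner)
dG_solv = +4.067 +/- 0.113 kcal/mol
```

The sign convention is `ΔG_solv = G(coupled) − G(decoupled)`; the positive
value says inserting an apolar particle into water costs free energy —
cavity formation outweighs the weak dispersion gain. Transfer free energies
between two solvents follow as
`ΔG_trans(aq→nonaq) = ΔG_solv(nonaq) − ΔG_solv(aq)` via
`deff.transfer_dg`, with uncertainties added in quadrature.

The `examples/` directory holds one short script per capability (pair
potentials, SMIRKS assignment, box energetics, NPT water properties,
solvation, DE↔B68 curve fitting); each prints the numbers it computes and a
line on what they mean. A thin `deff` CLI mirrors the library
(`deff assign`, `deff energy`, `deff curve`, `deff scan-dimer`,
`deff fit-curve`, `deff mc`, `deff schedule`, `deff fep`, `deff transfer`,
`deff make-fixture`).

Note: the packaged parameter library carries *synthetic stand-in* per-type
values (plausible C/H/O/N/Br chemistry and a TIP4P-FB-like 4-point water);
only the global shape (α, β) corresponds to trained values. Numbers
computed from it characterise the machinery, not a trained force field.

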