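"""Alchemical coupling paths for solvation free energies.

The DE potential is finite at r = 0, so it admits a *natural* soft core: no
change of functional form is needed to decouple a solute.  The path used
here scales the pair energy linearly in lambda and simultaneously scales the
shape parameters,

    U_sc(r; lambda) = lambda * U_DE(r; epsilon, r_m, lambda*alpha, lambda*beta),

which flattens the (finite) repulsive wall as lambda -> 0 and avoids the
end-point singularities that plain linear scaling of an LJ potential
suffers.  A Beutler-style LJ soft core is provided for comparison.

Decoupling semantics: only solute-environment interactions are modified;
solvent-solvent and intra-solute terms are untouched (this is decoupling,
not annihilation).  Electrostatics are removed first — linearly in
lambda_elec with vdW fully on — then vdW via the soft core, the standard
ordering for solvation free energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import GlobalShape, PairParams, _de_core
from .system import Configuration, InteractingSystem, _energy_components

__all__ = [
    "AlchemicalState",
    "Schedule",
    "softcore_de",
    "softcore_lj",
    "alchemical_energy",
    "default_schedule",
]


@dataclass(frozen=True)
class AlchemicalState:
    """One window on the coupling path; (1, 1) fully interacting, (0, 0)
    decoupled."""

    lambda_elec: float
    lambda_vdw: float

    def __post_init__(self) -> None:
        for name in ("lambda_elec", "lambda_vdw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class Schedule:
    """Ordered window list from fully interacting to decoupled.

    Electrostatics must reach zero before vdW starts departing from one, so
    charged solutes are never exposed without a repulsive core.
    """

    states: list[AlchemicalState]

    def __post_init__(self) -> None:
        s = self.states
        if not s:
            raise ValueError("empty schedule")
        if s[0] != AlchemicalState(1.0, 1.0) or s[-1] != AlchemicalState(0.0, 0.0):
            raise ValueError("schedule must run from (1,1) to (0,0)")
        for st in s:
            if st.lambda_vdw < 1.0 and st.lambda_elec > 0.0:
                raise ValueError(
                    "lambda_elec must reach 0 before lambda_vdw leaves 1"
                )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def to_json_obj(self) -> list[dict]:
        return [
            {"lambda_elec": s.lambda_elec, "lambda_vdw": s.lambda_vdw} for s in self.states
        ]

    @classmethod
    def from_json_obj(cls, obj) -> "Schedule":
        return cls([AlchemicalState(d["lambda_elec"], d["lambda_vdw"]) for d in obj])


def default_schedule(n_elec: int = 5, n_vdw: int = 16) -> Schedule:
    """Two-leg schedule: n_elec evenly spaced electrostatic windows at full
    vdW, then n_vdw vdW windows at zero charge; the shared corner state is
    counted once, so the default (5, 16) gives a 20-window path."""
    if n_elec < 2 or n_vdw < 2:
        raise ValueError("need at least two windows per leg")
    states = [AlchemicalState(le, 1.0) for le in np.linspace(1.0, 0.0, n_elec)]
    states += [AlchemicalState(0.0, lv) for lv in np.linspace(1.0, 0.0, n_vdw)[1:]]
    return Schedule(states)


def softcore_de(r, p: PairParams, s: GlobalShape, lam: float):
    """DE natural soft core: lam * U_DE(r; eps, r_m, lam*alpha, lam*beta).

    Exactly the plain DE energy at lam = 1 (same code path, bit for bit),
    exactly zero at lam = 0, and finite for every r >= 0 at every lam.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if lam == 0.0:
        r = np.asarray(r, dtype=float)
        return np.zeros_like(r) if r.ndim else 0.0
    # lam*alpha > lam*beta holds automatically for lam > 0.
    return lam * _de_core(r, p.epsilon, p.r_m, lam * s.alpha, lam * s.beta)


def softcore_lj(r, p: PairParams, lam: float, alpha_sc: float = 0.5):
    """Beutler-style LJ soft core for reference comparisons.

    The 12-6 form is evaluated at an effective separation
    r_eff^6 = alpha_sc (1 - lam) r_m^6 / 2 + r^6 and scaled by lam; finite at
    r = 0 whenever lam < 1, and identical to plain LJ at lam = 1.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=float)
    if lam == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    if p.epsilon == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    r_eff6 = alpha_sc * (1.0 - lam) * p.r_m**6 / 2.0 + r**6
    x6 = p.r_m**6 / r_eff6
    out = lam * p.epsilon * (x6 * x6 - 2.0 * x6)
    return out if r.ndim else float(out)


def alchemical_energy(
    system: InteractingSystem, conf: Configuration, state: AlchemicalState
) -> dict:
    """Decomposed energy with solute-environment coupling set by ``state``.

    Solute-environment vdW follows the DE soft core at lambda_vdw and the
    electrostatics scale linearly in lambda_elec; everything else is the
    plain Hamiltonian.  At (1, 1) this reproduces :func:`total_energy`
    exactly (identical code path).
    """
    if system.solute_mol is None:
        raise ValueError("system has no tagged solute molecule")
    return _energy_components(system, conf, state.lambda_elec, state.lambda_vdw)
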