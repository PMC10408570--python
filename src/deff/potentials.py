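"""Closed-form pairwise potentials: LJ 12-6, double-exponential, damped
Buckingham-6-8 and Coulomb, with analytic radial derivatives.

The double-exponential (DE) form used throughout the package is

    U(r) = eps/(alpha - beta) * [beta * exp(alpha(1 - r/r_m))
                                 - alpha * exp(beta(1 - r/r_m))]

with well depth ``eps`` at separation ``r_m`` and two dimensionless global
shape parameters: ``alpha`` sets the steepness of the exponential repulsion,
``beta`` the decay of the attraction.  Unlike LJ the DE form is finite at
r = 0 (a "natural soft core"), with

    U(0) = eps * (beta * e^alpha - alpha * e^beta) / (alpha - beta).

All energies kcal/mol, lengths Angstrom (see :mod:`deff.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import COULOMB_CONSTANT

__all__ = [
    "PairParams",
    "GlobalShape",
    "B68Params",
    "lj_energy",
    "de_energy",
    "de_energy_at_zero",
    "b68_energy",
    "coulomb_energy",
    "pair_gradient",
    "DEFAULT_SHAPE",
]


@dataclass(frozen=True)
class PairParams:
    """Per-pair (or per-atom, before combination) vdW parameters.

    epsilon -- well depth, kcal/mol; zero is legal and disables the vdW term
    r_m     -- minimum-energy separation, Angstrom
    """

    epsilon: float
    r_m: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.r_m <= 0:
            raise ValueError(f"r_m must be > 0, got {self.r_m}")


@dataclass(frozen=True)
class GlobalShape:
    """Global DE shape parameters (dimensionless); requires alpha > beta > 0.

    The DE form is singular at alpha == beta, so the constraint is strict.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise InvalidShapeError(
                f"need alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )


class InvalidShapeError(ValueError):
    """Raised when DE shape parameters violate alpha > beta > 0."""


#: Trained global shape of the general DE force field.
DEFAULT_SHAPE = GlobalShape(alpha=16.766, beta=4.427)


@dataclass(frozen=True)
class B68Params:
    """Damped Buckingham-6-8 parameters.

    A  -- repulsive prefactor, kcal/mol
    B  -- repulsive decay rate, 1/Angstrom (also used as the damping rate)
    C6 -- dispersion coefficient, kcal*A^6/mol
    C8 -- dispersion coefficient, kcal*A^8/mol
    """

    A: float
    B: float
    C6: float
    C8: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C6", "C8"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_array(r):
    return np.asarray(r, dtype=float)


def lj_energy(r, p: PairParams):
    """12-6 Lennard-Jones energy eps*[(r_m/r)^12 - 2(r_m/r)^6].

    Diverges as r -> 0; r must be strictly positive.  With epsilon = 0 the
    result is exactly 0 for any r > 0.
    """
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("LJ energy undefined for r <= 0")
    if p.epsilon == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x6 = (p.r_m / r) ** 6
    out = p.epsilon * (x6 * x6 - 2.0 * x6)
    return out if r.ndim else float(out)


def de_energy(r, p: PairParams, s: GlobalShape):
    """Double-exponential energy; finite for all r >= 0.

    Equals -epsilon at r = r_m and ``de_energy_at_zero`` at r = 0.
    """
    return _de_core(r, p.epsilon, p.r_m, s.alpha, s.beta)


def _de_core(r, epsilon: float, r_m: float, alpha: float, beta: float):
    # Shared kernel so the alchemical soft core (scaled alpha, beta) follows
    # bit-identical code paths at lambda = 1.
    if not alpha > beta:
        raise InvalidShapeError(f"need alpha > beta, got {alpha} <= {beta}")
    r = _as_array(r)
    if np.any(r < 0):
        raise ValueError("separation must be >= 0")
    if epsilon == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x = 1.0 - r / r_m
    pref = epsilon / (alpha - beta)
    out = pref * (beta * np.exp(alpha * x) - alpha * np.exp(beta * x))
    return out if r.ndim else float(out)


def de_energy_at_zero(p: PairParams, s: GlobalShape) -> float:
    """Closed-form r = 0 limit of the DE potential.

    Strictly positive for epsilon > 0: the repulsive wall is finite, which is
    what makes the DE form usable on alchemical paths without a separate
    soft-core modification.
    """
    if not s.alpha > s.beta:
        raise InvalidShapeError(f"need alpha > beta, got {s.alpha} <= {s.beta}")
    if p.epsilon == 0.0:
        return 0.0
    return (
        p.epsilon
        * (s.beta * math.exp(s.alpha) - s.alpha * math.exp(s.beta))
        / (s.alpha - s.beta)
    )


def _tang_toennies(n: int, br):
    """Damping factor f_n = 1 - exp(-br) * sum_{k=0..n} (br)^k / k!.

    For small br the direct form cancels catastrophically (f_n ~ (br)^{n+1}),
    so the complementary series f_n = exp(-br) * sum_{k>n} (br)^k / k! is
    used there; the two branches agree to machine precision at the split.
    """
    br = _as_array(br)
    series = np.ones_like(br)
    term = np.ones_like(br)
    for k in range(1, n + 1):
        term = term * br / k
        series = series + term
    direct = 1.0 - np.exp(-br) * series
    # complementary sum, converged well before 40 terms for br < n
    tail = np.zeros_like(br)
    term_t = term.copy()
    for k in range(n + 1, n + 40):
        term_t = term_t * br / k
        tail = tail + term_t
    small = br < float(n)
    return np.where(small, np.exp(-br) * tail, direct)


def b68_energy(r, p: B68Params):
    """Damped Buckingham-6-8: A e^{-Br} - f6(r) C6/r^6 - f8(r) C8/r^8.

    Tang-Toennies damping (rate B) removes the r^-6 / r^-8 divergence, so the
    energy is bounded on (0, inf) and tends to A as r -> 0.
    """
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("B68 energy requires r > 0")
    br = p.B * r
    out = p.A * np.exp(-br)
    # f_n(r)/r^n -> B^n/n! as r -> 0: evaluate via the series to stay finite.
    if p.C6 > 0:
        out = out - _tang_toennies(6, br) * p.C6 / r**6
    if p.C8 > 0:
        out = out - _tang_toennies(8, br) * p.C8 / r**8
    return out if r.ndim else float(out)


def coulomb_energy(r, q1, q2):
    """Point-charge Coulomb energy k_e q1 q2 / r, k_e = 332.06371."""
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("Coulomb energy undefined for r <= 0")
    out = COULOMB_CONSTANT * np.asarray(q1, dtype=float) * np.asarray(q2, dtype=float) / r
    return out if r.ndim else float(out)


# ---------------------------------------------------------------------------
# Analytic radial derivatives
# ---------------------------------------------------------------------------


def lj_gradient(r, p: PairParams):
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("LJ gradient undefined for r <= 0")
    if p.epsilon == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x6 = (p.r_m / r) ** 6
    out = 12.0 * p.epsilon * (x6 - x6 * x6) / r
    return out if r.ndim else float(out)


def de_gradient(r, p: PairParams, s: GlobalShape):
    return _de_core_gradient(r, p.epsilon, p.r_m, s.alpha, s.beta)


def _de_core_gradient(r, epsilon: float, r_m: float, alpha: float, beta: float):
    if not alpha > beta:
        raise InvalidShapeError(f"need alpha > beta, got {alpha} <= {beta}")
    r = _as_array(r)
    if epsilon == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x = 1.0 - r / r_m
    pref = epsilon * alpha * beta / ((alpha - beta) * r_m)
    out = pref * (np.exp(beta * x) - np.exp(alpha * x))
    return out if r.ndim else float(out)


def b68_gradient(r, p: B68Params):
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("B68 gradient requires r > 0")
    br = p.B * r
    out = -p.A * p.B * np.exp(-br)
    for n, c in ((6, p.C6), (8, p.C8)):
        if c == 0:
            continue
        fn = _tang_toennies(n, br)
        # d/dr [f_n] = exp(-br) * B * (br)^n / n!
        dfn = np.exp(-br) * p.B * br**n / math.factorial(n)
        out = out - c * (dfn / r**n - n * fn / r ** (n + 1))
    return out if r.ndim else float(out)


def coulomb_gradient(r, q1, q2):
    r = _as_array(r)
    if np.any(r <= 0):
        raise ValueError("Coulomb gradient undefined for r <= 0")
    out = -COULOMB_CONSTANT * np.asarray(q1, dtype=float) * np.asarray(q2, dtype=float) / r**2
    return out if r.ndim else float(out)


def pair_gradient(form: str, r, *params):
    """Radial derivative dU/dr of the named pair potential.

    ``form`` is one of ``"lj"``, ``"de"``, ``"b68"``, ``"coulomb"``; the
    remaining arguments are the same as the matching energy function.  Zero at
    r = r_m for the LJ and DE forms (their minimum).
    """
    form = form.lower()
    if form == "lj":
        return lj_gradient(r, *params)
    if form == "de":
        return de_gradient(r, *params)
    if form == "b68":
        return b68_gradient(r, *params)
    if form == "coulomb":
        return coulomb_gradient(r, *params)
    raise ValueError(f"unknown potential form {form!r}")
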