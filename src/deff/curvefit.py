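"""Dimer dissociation scans and least-squares fitting of DE parameters.

The DE family can be bootstrapped from an existing reference potential — in
particular an O-O Buckingham-6-8 water curve — by bounded nonlinear least
squares over (epsilon, r_m, alpha, beta).  The constraint alpha > beta is
enforced by reparameterising beta = alpha - exp(s), so the optimiser can
never cross the singular line alpha = beta.

Residuals are Boltzmann-like down-weighted, w_i = exp(-max(E_i, 0)/w0) with
w0 = 2 kcal/mol by default, so the steep repulsive wall does not dominate
the physically relevant well region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .potentials import GlobalShape, PairParams, de_energy
from .system import Configuration, total_energy

__all__ = ["RadialCurve", "dimer_scan", "curve_rmse", "fit_de_to_curve", "DEFitResult"]


@dataclass
class RadialCurve:
    """Energy (kcal/mol) on a strictly increasing radial grid (Angstrom)."""

    r: np.ndarray
    energy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.r.shape != self.energy.shape or self.r.ndim != 1:
            raise ValueError("r and energy must be equal-length 1-D arrays")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"r_angstrom": self.r, "energy_kcal_mol": self.energy}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "RadialCurve":
        df = pd.read_csv(path)
        return cls(df["r_angstrom"].to_numpy(), df["energy_kcal_mol"].to_numpy(), label)

    def minimum(self) -> tuple[float, float]:
        """(r, E) of the grid minimum refined by local quadratic fit."""
        i = int(np.argmin(self.energy))
        if 0 < i < len(self.r) - 1:
            # parabola through the three bracketing points
            r3, e3 = self.r[i - 1 : i + 2], self.energy[i - 1 : i + 2]
            a, b, c = np.polyfit(r3, e3, 2)
            if a > 0:
                r_min = -b / (2 * a)
                return float(r_min), float(np.polyval([a, b, c], r_min))
        return float(self.r[i]), float(self.energy[i])


def dimer_scan(
    mol_a,
    mol_b,
    axis,
    distances,
    library,
    *,
    origin_atom_a: int = 0,
    origin_atom_b: int = 0,
    params_a=None,
    params_b=None,
) -> RadialCurve:
    """Rigid dissociation scan: interaction energy E(AB) - E(A) - E(B).

    Monomer B is translated along ``axis`` so that its ``origin_atom_b``
    sits at each requested distance from ``origin_atom_a`` of the (fixed)
    monomer A.  Vacuum conditions, no cutoff, full vdW + Coulomb between the
    monomers.  Overlapping geometries are legal for the (finite) DE form.
    ``params_a``/``params_b`` bypass SMIRKS assignment with explicit
    per-atom parameters.
    """
    from .workbench import build_system  # late import: builder lives there

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    distances = np.asarray(distances, dtype=float)

    system, conf = build_system(
        [mol_a, mol_b], library, box=None, params_override=[params_a, params_b]
    )
    e_a = _monomer_energy(mol_a, library, params_a)
    e_b = _monomer_energy(mol_b, library, params_b)
    na = mol_a.n_atoms
    base_b = np.asarray(mol_b.coordinates, dtype=float)
    ref_a = np.asarray(mol_a.coordinates, dtype=float)[origin_atom_a]

    energies = []
    x = conf.coordinates.copy()
    # count of A particles in the assembled system (A's atoms + A's vsites
    # come first); locate them by molecule id
    b_particles = np.flatnonzero(system.mol_id == 1)
    b_atoms = b_particles[~system.is_vsite[b_particles]]
    for d in distances:
        target = ref_a + d * axis
        shift = target - base_b[origin_atom_b]
        x[b_atoms] = base_b + shift
        e_ab = total_energy(system, Configuration(x.copy()))["total"]
        energies.append(e_ab - e_a - e_b)
    return RadialCurve(distances, np.asarray(energies), label="dimer_scan")


def _monomer_energy(mol, library, params=None) -> float:
    from .workbench import build_system

    if mol.n_atoms == 1:
        return 0.0
    system, conf = build_system([mol], library, box=None, params_override=[params])
    return total_energy(system, conf)["total"]


def curve_rmse(curve: RadialCurve, reference: RadialCurve, weights=None) -> float:
    """Weighted RMS difference, kcal/mol, on the reference grid.

    The candidate curve is linearly interpolated onto the reference grid;
    grids that do not overlap the reference range are an error.
    """
    if curve.r[0] > reference.r[0] + 1e-9 or curve.r[-1] < reference.r[-1] - 1e-9:
        raise ValueError(
            f"curve grid [{curve.r[0]}, {curve.r[-1]}] does not cover the "
            f"reference grid [{reference.r[0]}, {reference.r[-1]}]"
        )
    e = np.interp(reference.r, curve.r, curve.energy)
    diff = e - reference.energy
    w = np.ones_like(diff) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * diff**2) / np.sum(w)))


@dataclass
class DEFitResult:
    params: PairParams
    shape: GlobalShape
    residual_rmse: float  # kcal/mol, weighted
    converged: bool
    message: str = ""


def _boltzmann_weights(energy: np.ndarray, scale: float = 2.0) -> np.ndarray:
    return np.exp(-np.maximum(energy, 0.0) / scale)


def fit_de_to_curve(
    reference: RadialCurve,
    initial: tuple[float, float, float, float] | None = None,
    *,
    bounds: dict | None = None,
    weight_scale: float = 2.0,
) -> DEFitResult:
    """Fit (epsilon, r_m, alpha, beta) of the DE form to a reference curve.

    ``initial`` is (epsilon, r_m, alpha, beta); when omitted it is seeded
    from the reference minimum and the package's default global shape.
    Deterministic given the initial point.  The reference must bracket the
    well: at least one repulsive point (E > 0) and the minimum region.
    """
    e_ref = reference.energy
    if not (np.any(e_ref > 0) and np.any(e_ref < 0)):
        raise ValueError("reference must cover the repulsive wall and the well")
    r_min, e_min = reference.minimum()
    if initial is None:
        initial = (max(-e_min, 1e-3), r_min, 16.766, 4.427)
    eps0, rm0, a0, b0 = initial
    b = {"epsilon": (1e-6, 10.0), "r_m": (0.5, 10.0), "alpha": (6.0, 30.0), "beta": (2.0, 8.0)}
    if bounds:
        b.update(bounds)
    w = _boltzmann_weights(e_ref, weight_scale)
    sqw = np.sqrt(w)

    def unpack(theta):
        eps, rm, alpha, s = theta
        beta = alpha - np.exp(s)
        return eps, rm, alpha, beta

    def residuals(theta):
        eps, rm, alpha, beta = unpack(theta)
        if beta <= 0:
            beta = 1e-6
        x = 1.0 - reference.r / rm
        u = eps / (alpha - beta) * (beta * np.exp(alpha * x) - alpha * np.exp(beta * x))
        return sqw * (u - e_ref)

    s0 = np.log(max(a0 - b0, 1e-3))
    theta0 = np.array([eps0, rm0, a0, s0])
    lo = [b["epsilon"][0], b["r_m"][0], b["alpha"][0], np.log(1e-3)]
    hi = [b["epsilon"][1], b["r_m"][1], b["alpha"][1], np.log(b["alpha"][1] - b["beta"][0])]
    theta0 = np.clip(theta0, lo, hi)
    sol = least_squares(residuals, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    eps, rm, alpha, beta = unpack(sol.x)
    beta = max(beta, 1e-6)
    fitted = RadialCurve(reference.r, de_energy(reference.r, PairParams(eps, rm), GlobalShape(alpha, beta)))
    rmse = curve_rmse(fitted, reference, weights=w)
    return DEFitResult(
        params=PairParams(eps, rm),
        shape=GlobalShape(alpha, beta),
        residual_rmse=rmse,
        converged=bool(sol.success),
        message=sol.message,
    )
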