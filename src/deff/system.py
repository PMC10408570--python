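"""Interacting particle systems: combining rules, exclusions, virtual sites,
and decomposed periodic/vacuum energies and forces.

Geometry conventions
--------------------
Orthorhombic periodic boxes only, minimum-image convention, with the box
edges carried on the :class:`Configuration` (they vary under NPT sampling).
Non-periodic ("vacuum") systems sum over all pairs with no cutoff.

Periodic non-bonded treatment: a radial cutoff with a quintic switching
taper on the vdW terms, reaction-field electrostatics (dielectric 78.3)
continuous at the cutoff, and an analytic isotropic long-range (tail)
correction for the attractive exponential of the DE potential.  Scaled 1-4
intramolecular pairs are handled as explicit bonded-style terms so the main
pair loop never special-cases them.

Virtual sites are massless charged particles placed on the H-parent-H
bisector (the M-site construction of 4-point water models); their forces are
projected back onto the parent atoms by the chain rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .potentials import GlobalShape, PairParams
from .units import COULOMB_CONSTANT

__all__ = [
    "Configuration",
    "InteractingSystem",
    "VirtualSite",
    "combine_pair",
    "build_exclusions",
    "place_virtual_sites",
    "total_energy",
    "forces",
]

#: Reaction-field dielectric for periodic electrostatics.
EPSILON_RF = 78.3

DEFAULT_CUTOFF = 9.0
DEFAULT_SWITCH_WIDTH = 1.0


def combine_pair(p_i: PairParams, p_j: PairParams) -> PairParams:
    """Lorentz-Berthelot combination: arithmetic r_m, geometric epsilon."""
    return PairParams(
        epsilon=math.sqrt(p_i.epsilon * p_j.epsilon),
        r_m=0.5 * (p_i.r_m + p_j.r_m),
    )


def build_exclusions(mol) -> dict[tuple[int, int], str]:
    """Classify intramolecular pairs by bond-path length.

    Returns ``{(i, j): "excluded" | "scaled14"}`` with i < j: directly bonded
    (1-2) and angle (1-3) pairs are excluded, dihedral-spanning (1-4) pairs
    are tagged for scaling, and more distant pairs interact fully (absent
    from the map).  Pairs in different molecules are never excluded.
    """
    n = mol.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in mol.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    out: dict[tuple[int, int], str] = {}
    for src in range(n):
        # BFS to depth 3 is enough: deeper pairs interact fully.
        dist = {src: 0}
        frontier = [src]
        for d in (1, 2, 3):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in dist:
                        dist[b] = d
                        nxt.append(b)
            frontier = nxt
        for j, d in dist.items():
            if j <= src:
                continue
            out[(src, j)] = "scaled14" if d == 3 else "excluded"
    return out


@dataclass
class Configuration:
    """Cartesian coordinates (Angstrom) plus optional orthorhombic box edges."""

    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.array(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.array(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edges must be positive")

    def copy(self) -> "Configuration":
        return Configuration(
            self.coordinates.copy(), None if self.box is None else self.box.copy()
        )

    @property
    def volume(self) -> float:
        if self.box is None:
            raise ValueError("non-periodic configuration has no volume")
        return float(np.prod(self.box))


@dataclass(frozen=True)
class VirtualSite:
    """A bisector site: placed at ``parent + distance * u`` where u is the
    unit vector along ``x_h1 + x_h2 - 2 x_parent``."""

    site: int
    parent: int
    h1: int
    h2: int
    distance: float


class InteractingSystem:
    """Per-particle parameters plus the pairwise bookkeeping for energies.

    Parameters
    ----------
    epsilon, r_m, charge
        Per-particle DE well depth (kcal/mol), location (A) and charge (e).
    mol_id
        Integer molecule index per particle; rigid-body moves and exclusion
        logic operate on these groups.
    is_vsite
        Boolean mask of massless virtual sites.
    vsites
        Bisector-site definitions (see :class:`VirtualSite`).
    exclusions
        ``{(i, j): "excluded" | "scaled14"}`` over global particle indices.
    shape
        Global DE (alpha, beta).
    masses
        Per-particle masses, g/mol; zero for virtual sites.
    solute_mol
        Optional molecule id tagged as the alchemical solute.
    """

    def __init__(
        self,
        epsilon,
        r_m,
        charge,
        mol_id,
        shape: GlobalShape,
        *,
        is_vsite=None,
        vsites: list[VirtualSite] | None = None,
        exclusions: dict[tuple[int, int], str] | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        switch_width: float = DEFAULT_SWITCH_WIDTH,
        scale14_vdw: float = 0.5,
        scale14_elec: float = 0.8333333,
        masses=None,
        solute_mol: int | None = None,
        epsilon_rf: float = EPSILON_RF,
    ) -> None:
        self.epsilon = np.asarray(epsilon, dtype=float)
        self.r_m = np.asarray(r_m, dtype=float)
        self.charge = np.asarray(charge, dtype=float)
        self.mol_id = np.asarray(mol_id, dtype=int)
        n = len(self.epsilon)
        if not (len(self.r_m) == len(self.charge) == len(self.mol_id) == n):
            raise ValueError("per-particle arrays must share one length")
        self.n_particles = n
        self.shape = shape
        self.is_vsite = (
            np.zeros(n, dtype=bool) if is_vsite is None else np.asarray(is_vsite, bool)
        )
        self.vsites = list(vsites or [])
        for v in self.vsites:
            if self.mol_id[v.site] != self.mol_id[v.parent]:
                raise ValueError("virtual sites must be intramolecular")
        self.cutoff = float(cutoff)
        self.switch_width = float(switch_width)
        self.scale14_vdw = float(scale14_vdw)
        self.scale14_elec = float(scale14_elec)
        self.epsilon_rf = float(epsilon_rf)
        self.masses = (
            np.zeros(n) if masses is None else np.asarray(masses, dtype=float)
        )
        self.solute_mol = solute_mol

        exclusions = dict(exclusions or {})
        # Pair bookkeeping as dense masks: fine at the particle counts this
        # package targets (a few hundred).
        include = ~np.eye(n, dtype=bool)
        sc14: list[tuple[int, int]] = []
        for (i, j), kind in exclusions.items():
            if self.mol_id[i] != self.mol_id[j]:
                raise ValueError(f"intermolecular pair ({i},{j}) cannot be excluded")
            include[i, j] = include[j, i] = False
            if kind == "scaled14":
                sc14.append((min(i, j), max(i, j)))
            elif kind != "excluded":
                raise ValueError(f"unknown exclusion kind {kind!r}")
        self.pair_mask = include
        self.scaled14_pairs = sorted(set(sc14))

        # Combined LB parameter matrices.
        self.eps_ij = np.sqrt(np.outer(self.epsilon, self.epsilon))
        self.rm_ij = 0.5 * (self.r_m[:, None] + self.r_m[None, :])
        self.qq_ij = COULOMB_CONSTANT * np.outer(self.charge, self.charge)

        self.solute_mask = (
            self.mol_id == solute_mol if solute_mol is not None else np.zeros(n, bool)
        )
        # Pair classes for alchemical scaling: solute-environment cross pairs.
        cross = np.logical_xor(self.solute_mask[:, None], self.solute_mask[None, :])
        self.alchemical_pairs = cross & self.pair_mask

        self._tail_coefficients()

    # -- tail correction -------------------------------------------------

    def _pair_tail_integrals(self) -> np.ndarray:
        """Integral of r^2 times the attractive DE exponential beyond the
        cutoff, per ordered particle pair: I_ij = -eps_ij a/(a-b) e^b *
        int_rc^inf r^2 e^{-b r / rm_ij} dr (closed form)."""
        a, b = self.shape.alpha, self.shape.beta
        rc = self.cutoff
        with np.errstate(divide="ignore", invalid="ignore"):
            k = b / self.rm_ij  # decay rate, 1/A
            integral = np.exp(-k * rc) * (rc**2 / k + 2 * rc / k**2 + 2 / k**3)
        return -self.eps_ij * a / (a - b) * np.exp(b) * integral

    def _tail_coefficients(self) -> None:
        integ = self._pair_tail_integrals()
        np.fill_diagonal(integ, 0.0)
        cross = np.logical_xor(self.solute_mask[:, None], self.solute_mask[None, :])
        # Tail energy = 2*pi/V * sum over ordered pairs; split so the
        # solute-environment share can be scaled on alchemical paths.
        self.tail_coeff_env = 2.0 * math.pi * float(np.sum(integ[~cross]))
        self.tail_coeff_solute = 2.0 * math.pi * float(np.sum(integ[cross]))

    # -- geometry helpers ------------------------------------------------

    def molecule_indices(self) -> list[np.ndarray]:
        ids = np.unique(self.mol_id)
        return [np.flatnonzero(self.mol_id == m) for m in ids]


def place_virtual_sites(conf: Configuration, system: InteractingSystem) -> Configuration:
    """Return a configuration with every virtual site repositioned from its
    parents: on the H-parent-H bisector at the stored distance."""
    if not system.vsites:
        return conf
    out = conf.copy()
    x = out.coordinates
    for v in system.vsites:
        o, h1, h2 = x[v.parent], x[v.h1], x[v.h2]
        vvec = h1 + h2 - 2.0 * o
        norm = np.linalg.norm(vvec)
        if norm < 1e-10:
            raise ValueError(
                f"degenerate geometry for virtual site {v.site}: bisector undefined"
            )
        x[v.site] = o + v.distance * vvec / norm
    return out


# ---------------------------------------------------------------------------
# Energy machinery
# ---------------------------------------------------------------------------


def _switch(r: np.ndarray, r_on: float, r_off: float) -> tuple[np.ndarray, np.ndarray]:
    """Quintic smoothstep taper S(r) and dS/dr: 1 below r_on, 0 above r_off."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    if r_off > r_on:
        inside = (r > r_on) & (r < r_off)
        t = (r[inside] - r_on) / (r_off - r_on)
        s[inside] = 1 - t**3 * (10 - 15 * t + 6 * t**2)
        ds[inside] = -30 * t**2 * (1 - t) ** 2 / (r_off - r_on)
    s[r >= r_off] = 0.0
    return s, ds


def _de_matrix(r, eps_ij, rm_ij, alpha: float, beta: float, *, grad: bool = False):
    """Vectorised DE energy (and optionally dU/dr) over distance matrices."""
    with np.errstate(over="ignore", invalid="ignore"):
        x = 1.0 - r / rm_ij
        ea = np.exp(alpha * x)
        eb = np.exp(beta * x)
        u = eps_ij / (alpha - beta) * (beta * ea - alpha * eb)
    u = np.where(eps_ij > 0, u, 0.0)
    if not grad:
        return u
    with np.errstate(invalid="ignore"):
        du = eps_ij * alpha * beta / ((alpha - beta) * rm_ij) * (eb - ea)
    du = np.where(eps_ij > 0, du, 0.0)
    return u, du


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _distance_matrix(conf: Configuration):
    x = conf.coordinates
    delta = x[:, None, :] - x[None, :, :]
    if conf.box is not None:
        delta = _min_image(delta, conf.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    np.fill_diagonal(r, np.inf)
    return delta, r


def _lambda_factors(system: InteractingSystem, lambda_elec: float, lambda_vdw: float):
    """Per-pair scale factors and DE shape for the alchemical cross pairs."""
    a, b = system.shape.alpha, system.shape.beta
    return lambda_vdw, lambda_vdw * a, lambda_vdw * b, lambda_elec


def _energy_components(
    system: InteractingSystem,
    conf: Configuration,
    lambda_elec: float = 1.0,
    lambda_vdw: float = 1.0,
    *,
    grad: bool = False,
):
    """Decomposed non-bonded energy; the soft-core path for solute-environment
    pairs scales both the prefactor and the DE shape by lambda_vdw."""
    conf = place_virtual_sites(conf, system)
    periodic = conf.box is not None
    if periodic and np.any(conf.box < 2 * system.cutoff):
        raise ValueError(
            f"box {conf.box} too small for cutoff {system.cutoff} (need >= 2x)"
        )
    delta, r = _distance_matrix(conf)
    a, bshape = system.shape.alpha, system.shape.beta
    n = system.n_particles

    normal = system.pair_mask & ~system.alchemical_pairs
    alch = system.alchemical_pairs
    pref, a_l, b_l, le = _lambda_factors(system, lambda_elec, lambda_vdw)

    dudr = np.zeros((n, n)) if grad else None

    # --- vdW ---
    if periodic:
        r_off = system.cutoff
        r_on = r_off - system.switch_width
        sw, dsw = _switch(r, r_on, r_off)
        in_range = r < r_off
    else:
        sw = np.ones_like(r)
        dsw = np.zeros_like(r)
        in_range = np.isfinite(r)

    if grad:
        u_n, du_n = _de_matrix(r, system.eps_ij, system.rm_ij, a, bshape, grad=True)
    else:
        u_n = _de_matrix(r, system.eps_ij, system.rm_ij, a, bshape)
    mask_n = normal & in_range
    vdw = 0.5 * float(np.sum(np.where(mask_n, u_n * sw, 0.0)))
    if grad:
        dudr += np.where(mask_n, du_n * sw + u_n * dsw, 0.0)

    if np.any(alch) and pref > 0.0:
        if grad:
            u_a, du_a = _de_matrix(r, system.eps_ij, system.rm_ij, a_l, b_l, grad=True)
        else:
            u_a = _de_matrix(r, system.eps_ij, system.rm_ij, a_l, b_l)
        mask_a = alch & in_range
        vdw += 0.5 * pref * float(np.sum(np.where(mask_a, u_a * sw, 0.0)))
        if grad:
            dudr += pref * np.where(mask_a, du_a * sw + u_a * dsw, 0.0)

    # --- electrostatics ---
    qq = system.qq_ij.copy()
    if np.any(alch):
        qq = np.where(alch, le * qq, qq)
    with np.errstate(divide="ignore", invalid="ignore"):
        if periodic:
            rc = system.cutoff
            krf = (system.epsilon_rf - 1.0) / (2.0 * system.epsilon_rf + 1.0) / rc**3
            crf = 1.0 / rc + krf * rc**2
            u_e = qq * (1.0 / r + krf * r**2 - crf)
            mask_e = system.pair_mask & (r < rc)
        else:
            # coincident chargeless pairs (legal for the finite DE form)
            # must not poison the sum with 0/0
            u_e = np.where(qq != 0.0, qq / r, 0.0)
            mask_e = system.pair_mask & np.isfinite(r)
    elec = 0.5 * float(np.sum(np.where(mask_e, u_e, 0.0)))
    if grad:
        with np.errstate(invalid="ignore"):
            if periodic:
                du_e = qq * (-1.0 / r**2 + 2.0 * krf * r)
            else:
                du_e = np.where(qq != 0.0, -qq / r**2, 0.0)
        dudr += np.where(mask_e, du_e, 0.0)

    # --- scaled 1-4 bonded-style terms (never alchemical: intra-molecule) ---
    for i, j in system.scaled14_pairs:
        rij = r[i, j]
        u14 = _de_matrix(
            np.array(rij), np.array(system.eps_ij[i, j]), np.array(system.rm_ij[i, j]), a, bshape
        )
        vdw += system.scale14_vdw * float(u14)
        elec += system.scale14_elec * float(system.qq_ij[i, j] / rij)
        if grad:
            _, du14 = _de_matrix(
                np.array(rij),
                np.array(system.eps_ij[i, j]),
                np.array(system.rm_ij[i, j]),
                a,
                bshape,
                grad=True,
            )
            g14 = system.scale14_vdw * float(du14) - system.scale14_elec * float(
                system.qq_ij[i, j] / rij**2
            )
            dudr[i, j] += g14
            dudr[j, i] += g14

    # --- long-range correction ---
    if periodic:
        lrc = (system.tail_coeff_env + lambda_vdw * system.tail_coeff_solute) / conf.volume
    else:
        lrc = 0.0

    out = {"vdw": vdw, "elec": elec, "long_range_correction": lrc}
    out["total"] = vdw + elec + lrc
    if grad:
        return out, dudr, delta, r, conf
    return out


def total_energy(system: InteractingSystem, conf: Configuration) -> dict:
    """Decomposed potential energy {vdw, elec, long_range_correction, total}.

    Virtual sites are (re)placed from their parents before evaluation, so the
    energy is a pure function of the real-atom coordinates.
    """
    return _energy_components(system, conf)


def forces(
    system: InteractingSystem,
    conf: Configuration,
    lambda_elec: float = 1.0,
    lambda_vdw: float = 1.0,
) -> np.ndarray:
    """Analytic forces -dU/dx, kcal/(mol*A), per particle.

    Virtual-site rows are zero: their raw forces are projected onto the
    parent atoms through the Jacobian of the bisector construction.
    """
    _, dudr, delta, r, placed = _energy_components(
        system, conf, lambda_elec, lambda_vdw, grad=True
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = delta / r[:, :, None]
    unit = np.nan_to_num(unit)
    # F_i = -sum_j dU/dr_ij * (x_i - x_j)/r_ij; dudr holds ordered-pair rates.
    f = -np.einsum("ij,ijk->ik", dudr, unit)

    # Chain-rule projection of virtual-site forces onto parents.
    x = placed.coordinates
    for v in system.vsites:
        fm = f[v.site]
        if not np.any(fm):
            continue
        o, h1, h2 = x[v.parent], x[v.h1], x[v.h2]
        vvec = h1 + h2 - 2.0 * o
        norm = np.linalg.norm(vvec)
        u = vvec / norm
        proj = (np.eye(3) - np.outer(u, u)) / norm  # d(unit)/d(vvec)
        jac_h = v.distance * proj  # dx_M/dx_h1 = dx_M/dx_h2
        f[v.h1] += jac_h @ fm
        f[v.h2] += jac_h @ fm
        f[v.parent] += (np.eye(3) - 2.0 * jac_h) @ fm
        f[v.site] = 0.0
    return f
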