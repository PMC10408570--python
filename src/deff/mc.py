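"""Rigid-body Metropolis Monte Carlo in NVT and NPT.

Molecules are moved as rigid bodies (random translations and rotations about
the molecular centroid), with occasional isotropic volume moves under NPT.
Rigid sampling makes intramolecular terms constant, so the acceptance rule
only needs the interaction energy of the moved molecule with its
environment, evaluated incrementally.

NPT acceptance for a linear volume change uses the molecule-count Jacobian:

    acc = min(1, exp(-beta (dU + P dV) + N_mol ln(V'/V)))

so an ideal system samples P(V) ~ V^N exp(-beta P V) with <V> = (N+1) kT / P.

An optional alchemical state routes the solute-environment interactions
through the DE soft core, which is how the free-energy layer drives this
engine at each lambda window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .alchemy import AlchemicalState
from .system import (
    Configuration,
    InteractingSystem,
    _de_matrix,
    _energy_components,
    _min_image,
    _switch,
    place_virtual_sites,
)
from .units import ATM_TO_KCAL_PER_MOL_A3, GAS_CONSTANT, AMU_PER_A3_TO_G_PER_ML

__all__ = ["MCSettings", "SampleSet", "run_mc", "density_estimate", "hvap_estimate"]


@dataclass
class MCSettings:
    """Sampling controls; pressure=None selects NVT.

    max_translation / max_rotation are half-widths of the uniform proposal
    (Angstrom / radian); max_volume is the half-width of the linear volume
    proposal in Angstrom^3.  Move kinds are attempted in the ratio
    N_mol : N_mol : 1 (translation : rotation : volume) unless overridden.
    """

    temperature: float
    pressure: float | None = None  # atm
    max_translation: float = 0.25
    max_rotation: float = 0.35
    max_volume: float = 150.0
    n_steps: int = 10000
    seed: int = 0
    sample_stride: int = 50
    keep_configurations: bool = True
    move_weights: tuple[float, float, float] | None = None
    #: Relative weight for picking the tagged solute molecule in rigid-body
    #: moves (preferential sampling).  1.0 = uniform; larger values
    #: decorrelate the solute-environment energy faster.  The selection
    #: probability is configuration-independent, so detailed balance holds
    #: without an acceptance correction.
    solute_move_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sample_stride < 1 or self.n_steps < 1:
            raise ValueError("strides and step counts must be >= 1")


@dataclass
class SampleSet:
    """Output of one MC run: scalar time series plus optional snapshots."""

    energies: np.ndarray  # kcal/mol, per sample
    volumes: np.ndarray  # A^3, per sample (constant under NVT)
    configurations: list[Configuration] | None
    acceptance: dict
    ensemble: str  # "nvt" | "npt"
    temperature: float
    pressure: float | None
    seed: int

    def __post_init__(self) -> None:
        if len(self.energies) != len(self.volumes):
            raise ValueError("energy and volume series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.energies)


def _molecule_energy(
    system: InteractingSystem,
    x: np.ndarray,
    box: np.ndarray | None,
    members: np.ndarray,
    lambda_elec: float,
    lambda_vdw: float,
    external=None,
) -> float:
    """Interaction energy of one molecule with the rest of the system.

    Intramolecular terms are omitted entirely — they are rigid-body
    invariants here.  Mirrors the pair treatment of
    :func:`deff.system.total_energy` (switch, reaction field, soft core).
    """
    n = system.n_particles
    other = np.ones(n, dtype=bool)
    other[members] = False
    delta = x[members][:, None, :] - x[None, :, :]
    if box is not None:
        delta = _min_image(delta, box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    r[:, :] = np.where(other[None, :], r, np.inf)

    rows_mask = system.pair_mask[members] & other[None, :]
    rows_alch = system.alchemical_pairs[members] & other[None, :]
    normal = rows_mask & ~rows_alch
    a, b = system.shape.alpha, system.shape.beta
    eps = system.eps_ij[members]
    rm = system.rm_ij[members]
    qq = system.qq_ij[members]

    if box is not None:
        r_off = system.cutoff
        sw, _ = _switch(r, r_off - system.switch_width, r_off)
        in_range = r < r_off
    else:
        sw = np.ones_like(r)
        in_range = np.isfinite(r)

    u = _de_matrix(r, eps, rm, a, b)
    e = float(np.sum(np.where(normal & in_range, u * sw, 0.0)))
    if np.any(rows_alch) and lambda_vdw > 0.0:
        u_a = _de_matrix(r, eps, rm, lambda_vdw * a, lambda_vdw * b)
        e += lambda_vdw * float(np.sum(np.where(rows_alch & in_range, u_a * sw, 0.0)))

    qq_eff = np.where(rows_alch, lambda_elec * qq, qq)
    with np.errstate(divide="ignore", invalid="ignore"):
        if box is not None:
            rc = system.cutoff
            krf = (system.epsilon_rf - 1.0) / (2.0 * system.epsilon_rf + 1.0) / rc**3
            crf = 1.0 / rc + krf * rc**2
            u_e = qq_eff * (1.0 / r + krf * r**2 - crf)
            mask_e = rows_mask & (r < rc)
        else:
            u_e = qq_eff / r
            mask_e = rows_mask & np.isfinite(r)
    e += float(np.sum(np.where(mask_e, u_e, 0.0)))

    if external is not None:
        e += external(x[members], members)
    return e


def _rotation_matrix(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def run_mc(
    system: InteractingSystem,
    conf0: Configuration,
    settings: MCSettings,
    *,
    state: AlchemicalState | None = None,
    external=None,
) -> SampleSet:
    """Metropolis sampling with rigid-molecule moves; deterministic per seed.

    ``state`` (if given) samples the alchemically modified Hamiltonian at
    that window.  ``external(coords_subset, indices) -> kcal/mol`` adds an
    external one-body potential (a test hook for analytic distributions).
    """
    rng = np.random.default_rng(settings.seed)
    le, lv = (state.lambda_elec, state.lambda_vdw) if state else (1.0, 1.0)
    npt = settings.pressure is not None
    conf = place_virtual_sites(conf0, system)
    if npt and conf.box is None:
        raise ValueError("NPT requires a periodic configuration")

    def full_energy(c: Configuration) -> float:
        comp = _energy_components(system, c, le, lv)
        e = comp["total"]
        if external is not None:
            e += external(c.coordinates, np.arange(system.n_particles))
        return e

    energy = full_energy(conf)
    if not np.isfinite(energy):
        raise ValueError(f"non-finite starting energy {energy}")

    beta = 1.0 / (GAS_CONSTANT * settings.temperature)
    p_kcal = (
        settings.pressure * ATM_TO_KCAL_PER_MOL_A3 if settings.pressure is not None else 0.0
    )
    molecules = system.molecule_indices()
    n_mol = len(molecules)
    real = [m[~system.is_vsite[m]] for m in molecules]
    mol_vsites = [[v for v in system.vsites if system.mol_id[v.site] == system.mol_id[m[0]]] for m in molecules]

    w = settings.move_weights
    if w is None:
        w = (n_mol, n_mol, 1 if npt else 0)
    weights = np.asarray(w, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no moves enabled")
    probs = weights / weights.sum()

    mol_weights = np.ones(n_mol)
    if system.solute_mol is not None and settings.solute_move_weight != 1.0:
        for idx, m in enumerate(molecules):
            if system.mol_id[m[0]] == system.solute_mol:
                mol_weights[idx] = settings.solute_move_weight
    mol_probs = mol_weights / mol_weights.sum()

    x = conf.coordinates
    box = conf.box.copy() if conf.box is not None else None

    # Fast path: NVT rigid moves with no external potential run through the
    # JIT-compiled kernel (same ensemble, different RNG stream than the
    # reference loop below).
    if not npt and external is None and (settings.move_weights is None or weights[2] == 0):
        return _run_mc_jit(
            system, x, box, settings, le, lv, energy, molecules, real, mol_probs, probs
        )

    attempted = np.zeros(3, dtype=int)
    accepted = np.zeros(3, dtype=int)
    energies, volumes, configs = [], [], []

    def replace_vsites(indices) -> None:
        for v in indices:
            o, h1, h2 = x[v.parent], x[v.h1], x[v.h2]
            vvec = h1 + h2 - 2.0 * o
            x[v.site] = o + v.distance * vvec / np.linalg.norm(vvec)

    for step in range(settings.n_steps):
        kind = rng.choice(3, p=probs)
        attempted[kind] += 1
        if kind in (0, 1):  # rigid translation / rotation
            im = rng.choice(n_mol, p=mol_probs)
            members, ratoms = molecules[im], real[im]
            old = x[members].copy()
            e_old = _molecule_energy(system, x, box, members, le, lv, external)
            if kind == 0:
                shift = rng.uniform(-settings.max_translation, settings.max_translation, 3)
                x[ratoms] += shift
            else:
                rot = _rotation_matrix(rng, settings.max_rotation)
                centroid = x[ratoms].mean(axis=0)
                x[ratoms] = (x[ratoms] - centroid) @ rot.T + centroid
            replace_vsites(mol_vsites[im])
            e_new = _molecule_energy(system, x, box, members, le, lv, external)
            d_u = e_new - e_old
            if d_u <= 0 or rng.random() < np.exp(-beta * d_u):
                accepted[kind] += 1
                energy += d_u
            else:
                x[members] = old
        else:  # volume move
            v_old = float(np.prod(box))
            v_new = v_old + rng.uniform(-settings.max_volume, settings.max_volume)
            if v_new <= 0 or v_new ** (1.0 / 3.0) < 2.0 * system.cutoff:
                continue  # auto-reject infeasible proposals
            s = (v_new / v_old) ** (1.0 / 3.0)
            x_old, box_old, e_old_total = x.copy(), box.copy(), energy
            for im in range(n_mol):
                ratoms = real[im]
                c = x[ratoms].mean(axis=0)
                x[ratoms] += (s - 1.0) * c
            box *= s
            replace_vsites(system.vsites)
            e_new_total = full_energy(Configuration(x, box))
            d_u = e_new_total - e_old_total
            arg = -beta * (d_u + p_kcal * (v_new - v_old)) + n_mol * np.log(v_new / v_old)
            if arg >= 0 or rng.random() < np.exp(arg):
                accepted[kind] += 1
                energy = e_new_total
            else:
                x, box, energy = x_old, box_old, e_old_total

        if (step + 1) % settings.sample_stride == 0:
            energies.append(energy)
            volumes.append(float(np.prod(box)) if box is not None else 0.0)
            if settings.keep_configurations:
                configs.append(
                    Configuration(x.copy(), box.copy() if box is not None else None)
                )

    final = Configuration(x, box.copy() if box is not None else None)
    stats = {
        "attempted": {"translation": int(attempted[0]), "rotation": int(attempted[1]), "volume": int(attempted[2])},
        "accepted": {"translation": int(accepted[0]), "rotation": int(accepted[1]), "volume": int(accepted[2])},
        "running_energy": float(energy),
        "fresh_energy": float(full_energy(final)),
        "final_configuration": final,
    }
    return SampleSet(
        energies=np.asarray(energies),
        volumes=np.asarray(volumes),
        configurations=configs if settings.keep_configurations else None,
        acceptance=stats,
        ensemble="npt" if npt else "nvt",
        temperature=settings.temperature,
        pressure=settings.pressure,
        seed=settings.seed,
    )


def _run_mc_jit(
    system, x, box, settings, le, lv, energy0, molecules, real, mol_probs, probs
) -> SampleSet:
    """Drive the numba NVT kernel and package its output as a SampleSet."""
    from ._kernels import rigid_mc_nvt

    n = system.n_particles
    pbc = box is not None
    box_arr = box if pbc else np.ones(3)
    same = system.mol_id[:, None] == system.mol_id[None, :]
    ptype = np.where(same | ~system.pair_mask, 0, np.where(system.alchemical_pairs, 2, 1)).astype(np.int8)
    mol_ptr = np.zeros(len(molecules) + 1, dtype=np.int64)
    mol_idx = np.concatenate(molecules).astype(np.int64)
    real_ptr = np.zeros(len(molecules) + 1, dtype=np.int64)
    real_idx = np.concatenate(real).astype(np.int64)
    for i, m in enumerate(molecules):
        mol_ptr[i + 1] = mol_ptr[i] + len(m)
        real_ptr[i + 1] = real_ptr[i] + len(real[i])
    vs_by_mol: list[list] = [[] for _ in molecules]
    mol_of = {system.mol_id[m[0]]: i for i, m in enumerate(molecules)}
    for v in system.vsites:
        vs_by_mol[mol_of[system.mol_id[v.site]]].append(v)
    vs_ptr = np.zeros(len(molecules) + 1, dtype=np.int64)
    flat = []
    for i, vlist in enumerate(vs_by_mol):
        vs_ptr[i + 1] = vs_ptr[i] + len(vlist)
        flat.extend(vlist)
    vs_site = np.array([v.site for v in flat], dtype=np.int64)
    vs_parent = np.array([v.parent for v in flat], dtype=np.int64)
    vs_h1 = np.array([v.h1 for v in flat], dtype=np.int64)
    vs_h2 = np.array([v.h2 for v in flat], dtype=np.int64)
    vs_dist = np.array([v.distance for v in flat], dtype=float)

    rc = system.cutoff
    krf = (system.epsilon_rf - 1.0) / (2.0 * system.epsilon_rf + 1.0) / rc**3
    crf = 1.0 / rc + krf * rc**2
    n_samples = settings.n_steps // settings.sample_stride
    x_out = np.empty((n_samples, n, 3))
    e_out = np.empty(n_samples)
    p_trans = probs[0] / (probs[0] + probs[1])
    beta_t = 1.0 / (GAS_CONSTANT * settings.temperature)

    acc_t, att_t, acc_r, att_r, de_total = rigid_mc_nvt(
        x, box_arr, pbc,
        system.eps_ij, system.rm_ij, system.qq_ij, ptype,
        system.mol_id.astype(np.int64), mol_ptr, mol_idx, real_ptr, real_idx,
        vs_ptr, vs_site, vs_parent, vs_h1, vs_h2, vs_dist,
        np.cumsum(mol_probs),
        system.shape.alpha, system.shape.beta, le, lv,
        rc, rc - system.switch_width, krf, crf,
        p_trans, settings.max_translation, settings.max_rotation,
        beta_t, settings.n_steps, settings.sample_stride,
        settings.seed % (2**32), x_out, e_out,
    )
    energies = energy0 + e_out
    vol = float(np.prod(box)) if pbc else 0.0
    configs = None
    if settings.keep_configurations:
        configs = [
            Configuration(x_out[i], box_arr.copy() if pbc else None)
            for i in range(n_samples)
        ]
    final = Configuration(x.copy(), box_arr.copy() if pbc else None)
    comp = _energy_components(system, final, le, lv)
    stats = {
        "attempted": {"translation": int(att_t), "rotation": int(att_r), "volume": 0},
        "accepted": {"translation": int(acc_t), "rotation": int(acc_r), "volume": 0},
        "running_energy": float(energy0 + de_total),
        "fresh_energy": float(comp["total"]),
        "final_configuration": final,
    }
    return SampleSet(
        energies=energies,
        volumes=np.full(n_samples, vol),
        configurations=configs,
        acceptance=stats,
        ensemble="nvt",
        temperature=settings.temperature,
        pressure=None,
        seed=settings.seed,
    )


def _block_se(series: np.ndarray, n_blocks: int = 10) -> float:
    n = len(series)
    if n < n_blocks:
        n_blocks = max(2, n)
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def density_estimate(samples: SampleSet, system: InteractingSystem) -> tuple[float, float]:
    """Mass density rho = M_total / <V> in g/mL with a block-averaged SE."""
    if samples.ensemble != "npt":
        raise ValueError("density requires NPT samples (volume fluctuates)")
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    m_total = float(system.masses.sum())  # g/mol
    v_mean = samples.volumes.mean()
    rho = m_total / v_mean * AMU_PER_A3_TO_G_PER_ML
    # first-order error propagation through 1/<V>
    se = rho * _block_se(samples.volumes) / v_mean
    return rho, se


def hvap_estimate(
    liquid: SampleSet, gas_energy: float, n_molecules: int, temperature: float
) -> tuple[float, float]:
    """Heat of vaporisation for rigid molecules:

        dH_vap = U_gas - <U_liq>/N + RT

    Intramolecular terms cancel between phases under rigid geometry; for a
    single rigid molecule with no intramolecular non-bonded pairs the gas
    energy is zero.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if liquid.n_samples == 0:
        raise ValueError("empty sample set")
    u_per = liquid.energies / n_molecules
    dh = gas_energy - u_per.mean() + GAS_CONSTANT * temperature
    return float(dh), _block_se(u_per)
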