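"""Multistate free-energy estimation (MBAR) and solvation workflows.

The multistate Bennett acceptance ratio estimator solves, for K thermodynamic
states with N_k samples each, the self-consistent equations

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_l N_l exp(f_l - u_l(x_n))

for the dimensionless free energies f_k (u is the reduced potential U/kT,
plus PV/kT in NPT ensembles).  The solver minimises the equivalent convex
objective with quasi-Newton steps and polishes with self-consistent
iteration; uncertainties come from the standard asymptotic covariance of the
weight matrix.  BAR is recovered exactly at K = 2.

The solvation workflow runs rigid-body MC at every window of an alchemical
schedule, cross-evaluates every retained configuration at every state,
decorrelates each window's samples by its statistical inefficiency and feeds
the reduced-potential matrix to MBAR.  Sign convention:
dG_solv = G(coupled) - G(decoupled), negative for favourable solvation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alchemy import Schedule
from .mc import MCSettings, run_mc
from .system import (
    Configuration,
    InteractingSystem,
    _de_matrix,
    _energy_components,
    _min_image,
    _switch,
    place_virtual_sites,
)
from .units import ATM_TO_KCAL_PER_MOL_A3, GAS_CONSTANT

__all__ = [
    "ReducedPotentialMatrix",
    "FreeEnergyEstimate",
    "ConvergenceError",
    "mbar",
    "statistical_inefficiency",
    "subsample",
    "solvation_dg",
    "transfer_dg",
]


class ConvergenceError(RuntimeError):
    """MBAR could not converge (typically: no phase-space overlap)."""


@dataclass
class ReducedPotentialMatrix:
    """u[k, n]: reduced energy of sample n at state k; N_k sample origins.

    Columns are ordered by origin state: the first N_0 samples were drawn
    from state 0, the next N_1 from state 1, and so on.
    """

    u: np.ndarray
    N_k: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.N_k = np.asarray(self.N_k, dtype=int)
        if self.u.ndim != 2:
            raise ValueError("u must be a (K, N) matrix")
        if len(self.N_k) != self.u.shape[0]:
            raise ValueError("one N_k entry per state required")
        if int(self.N_k.sum()) != self.u.shape[1]:
            raise ValueError(
                f"sum(N_k) = {int(self.N_k.sum())} != {self.u.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite reduced potentials")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# N_k " + " ".join(str(int(n)) for n in self.N_k) + "\n")
            np.savetxt(fh, self.u)

    @classmethod
    def load(cls, path) -> "ReducedPotentialMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# N_k"):
                raise ValueError("missing '# N_k' header line")
            n_k = np.array([int(tok) for tok in header.split()[2:]])
            u = np.loadtxt(fh, ndmin=2)
        return cls(u, n_k)


@dataclass
class FreeEnergyEstimate:
    """dF between designated end states, kcal/mol, with diagnostics.

    ``free_energies`` are the per-state dimensionless f_k (gauge f_0 = 0);
    ``overlap`` is the K x K overlap matrix whose rows sum to one.
    """

    delta_f: float
    uncertainty: float
    free_energies: np.ndarray
    overlap: np.ndarray
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")

    def __neg__(self) -> "FreeEnergyEstimate":
        return dc_replace(self, delta_f=-self.delta_f)


def _mbar_weights(u: np.ndarray, n_k: np.ndarray, f: np.ndarray):
    """log D_n = logsumexp_k [ln N_k + f_k - u_kn]; W_nk = e^{f_k-u_kn}/D_n."""
    with np.errstate(divide="ignore"):
        log_nk = np.where(n_k > 0, np.log(np.maximum(n_k, 1e-300)), -np.inf)
    log_denom = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
    log_w = f[:, None] - u - log_denom[None, :]
    return np.exp(log_w).T, log_denom  # (N, K)


def mbar(matrix: ReducedPotentialMatrix, kT: float = 1.0) -> FreeEnergyEstimate:
    """Solve the MBAR equations; returns dF(first state -> last state).

    Converges the self-consistency residual below 1e-10 (dimensionless) or
    raises :class:`ConvergenceError`.  ``kT`` (kcal/mol) converts the
    dimensionless result to energy units.
    """
    u = matrix.u
    n_k = matrix.N_k.astype(float)
    k_states, n_total = u.shape
    active = n_k > 0
    if not np.any(active):
        raise ValueError("no samples at all")

    # Shift each column by its minimum: exact gauge freedom of the estimator,
    # removes overflow without changing any free-energy difference.
    shift = u.min(axis=0)
    u = u - shift[None, :]

    log_nk = np.log(np.where(active, n_k, 1.0))

    def objective(f_free: np.ndarray):
        f = np.zeros(k_states)
        f[1:] = f_free
        log_denom = logsumexp(
            np.where(active, log_nk + f, -np.inf)[:, None] - u, axis=0
        )
        val = float(np.sum(log_denom)) - float(np.sum(np.where(active, n_k * f, 0.0)))
        w = np.exp(f[:, None] - u - log_denom[None, :])  # (K, N)
        grad = np.where(active, n_k, 0.0) * (w.sum(axis=1) - 1.0)
        return val, grad[1:]

    res = minimize(objective, np.zeros(k_states - 1), jac=True, method="L-BFGS-B")
    f = np.zeros(k_states)
    f[1:] = res.x

    # Self-consistent polish to tight residual.
    residual = np.inf
    for _ in range(2000):
        log_denom = logsumexp(
            np.where(active, log_nk + f, -np.inf)[:, None] - u, axis=0
        )
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < 1e-12:
            break
    if not np.isfinite(residual) or residual > 1e-10:
        raise ConvergenceError(
            f"MBAR self-consistency residual {residual:.3e} > 1e-10; "
            "check overlap between adjacent states"
        )

    w_nk, _ = _mbar_weights(u, np.where(active, n_k, 0.0), f)
    # Asymptotic covariance via SVD of the weight matrix:
    #   Theta = V S (I - S V^T diag(N) V S)^+ S V^T
    _, s, vt = np.linalg.svd(w_nk, full_matrices=False)
    v = vt.T
    inner = np.eye(len(s)) - (s[:, None] * v.T) @ (n_k[:, None] * v) * s[None, :]
    theta = (v * s[None, :]) @ np.linalg.pinv(inner) @ (s[:, None] * vt)

    var = theta[0, 0] + theta[-1, -1] - 2.0 * theta[0, -1]
    uncertainty = math.sqrt(max(var, 0.0)) * kT

    overlap = (w_nk.T @ w_nk) * n_k[None, :]
    return FreeEnergyEstimate(
        delta_f=float(f[-1] - f[0]) * kT,
        uncertainty=uncertainty,
        free_energies=f,
        overlap=overlap,
        kT=kT,
    )


# ---------------------------------------------------------------------------
# Decorrelation
# ---------------------------------------------------------------------------


def statistical_inefficiency(series: np.ndarray) -> float:
    """g = 1 + 2 * sum_t (1 - t/T) C(t), truncated at the first non-positive
    normalised autocorrelation; g = 1 for uncorrelated or constant data."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n):
        c = float(np.dot(x[:-t], x[t:]) / ((n - t) * var))
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def subsample(series, max_samples: int | None = None) -> np.ndarray:
    """Indices of approximately decorrelated samples: stride ceil(g).

    ``max_samples`` optionally caps the number of indices by widening the
    stride (useful when downstream cross-evaluation cost matters more than
    keeping every nominally independent sample).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        return np.arange(len(series))
    g = statistical_inefficiency(series)
    stride = int(math.ceil(g))
    if max_samples is not None:
        stride = max(stride, int(math.ceil(len(series) / max_samples)))
    return np.arange(0, len(series), stride)


# ---------------------------------------------------------------------------
# Solvation and transfer workflows
# ---------------------------------------------------------------------------


def _solute_cross_batch(
    system: InteractingSystem, conf: Configuration, lambdas_vdw: np.ndarray
) -> tuple[np.ndarray, float]:
    """Soft-core vdW at every lambda plus unit-coupling electrostatics,
    in a single JIT-compiled pair sweep."""
    from ._kernels import solute_cross_kernel

    sol_idx = np.flatnonzero(system.solute_mask).astype(np.int64)
    pbc = conf.box is not None
    rc = system.cutoff
    krf = (system.epsilon_rf - 1.0) / (2.0 * system.epsilon_rf + 1.0) / rc**3
    crf = 1.0 / rc + krf * rc**2
    vdw, elec = solute_cross_kernel(
        conf.coordinates,
        conf.box if pbc else np.ones(3),
        pbc,
        sol_idx,
        system.eps_ij,
        system.rm_ij,
        system.qq_ij,
        system.mol_id.astype(np.int64),
        system.shape.alpha,
        system.shape.beta,
        np.asarray(lambdas_vdw, dtype=float),
        rc,
        rc - system.switch_width,
        krf,
        crf,
    )
    return vdw, float(elec)


def _solute_cross_terms(
    system: InteractingSystem, conf: Configuration, lambda_vdw: float
) -> tuple[float, float]:
    """(soft-core vdW, unit-charge electrostatic) solute-environment energy.

    The electrostatic term is returned at full coupling; multiply by
    lambda_elec.  Mirrors the pair treatment of the main energy loop.
    """
    members = np.flatnonzero(system.solute_mask)
    others = np.flatnonzero(~system.solute_mask)
    x = conf.coordinates
    delta = x[members][:, None, :] - x[others][None, :, :]
    if conf.box is not None:
        delta = _min_image(delta, conf.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    mask = system.pair_mask[np.ix_(members, others)]
    a, b = system.shape.alpha, system.shape.beta
    eps = system.eps_ij[np.ix_(members, others)]
    rm = system.rm_ij[np.ix_(members, others)]
    qq = system.qq_ij[np.ix_(members, others)]
    if conf.box is not None:
        rc = system.cutoff
        sw, _ = _switch(r, rc - system.switch_width, rc)
        in_range = r < rc
        krf = (system.epsilon_rf - 1.0) / (2.0 * system.epsilon_rf + 1.0) / rc**3
        crf = 1.0 / rc + krf * rc**2
        u_e = qq * (1.0 / r + krf * r**2 - crf)
        e_elec = float(np.sum(np.where(mask & in_range, u_e, 0.0)))
    else:
        sw = np.ones_like(r)
        in_range = np.ones_like(r, dtype=bool)
        e_elec = float(np.sum(np.where(mask, qq / r, 0.0)))
    if lambda_vdw > 0.0:
        u_v = _de_matrix(r, eps, rm, lambda_vdw * a, lambda_vdw * b)
        e_vdw = lambda_vdw * float(np.sum(np.where(mask & in_range, u_v * sw, 0.0)))
    else:
        e_vdw = 0.0
    return e_vdw, e_elec


def reduced_potentials(
    system: InteractingSystem,
    configurations: list[Configuration],
    origins: np.ndarray,
    schedule: Schedule,
    temperature: float,
    pressure: float | None = None,
    relative: bool = False,
) -> ReducedPotentialMatrix:
    """Cross-evaluate configurations at every window of the schedule.

    Exploits the structure of the alchemical Hamiltonian: the environment
    part is computed once per configuration and only the (cheap)
    solute-environment terms are re-evaluated per lambda.  With
    ``relative=True`` the per-sample environment constant (and PV term) is
    dropped entirely — a pure gauge choice that leaves every MBAR
    free-energy difference unchanged.
    """
    kT = GAS_CONSTANT * temperature
    k_states = len(schedule)
    n = len(configurations)
    u = np.empty((k_states, n))
    lams = [(st.lambda_elec, st.lambda_vdw) for st in schedule]
    distinct_lv = sorted({lv for _, lv in lams})
    lv_arr = np.asarray(distinct_lv)
    lv_pos = {lv: i for i, lv in enumerate(distinct_lv)}
    for j, conf in enumerate(configurations):
        conf = place_virtual_sites(conf, system)
        vdw_all, elec1 = _solute_cross_batch(system, conf, lv_arr)
        if relative:
            # MBAR is exactly invariant to adding a per-sample constant to
            # every state, so the (expensive) environment energy can be
            # dropped: only terms that differ between states remain.
            base = 0.0
        else:
            full = _energy_components(system, conf, 1.0, 1.0)["total"]
            tail1 = (
                system.tail_coeff_solute / conf.volume if conf.box is not None else 0.0
            )
            base = full - vdw_all[lv_pos[1.0]] - elec1 - tail1 if 1.0 in lv_pos else None
            if base is None:
                vdw1, _ = _solute_cross_batch(system, conf, np.array([1.0]))
                base = full - vdw1[0] - elec1 - tail1
        tail_sol = (
            system.tail_coeff_solute / conf.volume if conf.box is not None else 0.0
        )
        pv = (
            pressure * ATM_TO_KCAL_PER_MOL_A3 * conf.volume
            if pressure is not None and conf.box is not None and not relative
            else 0.0
        )
        for k, (le, lv) in enumerate(lams):
            u[k, j] = (base + le * elec1 + vdw_all[lv_pos[lv]] + lv * tail_sol + pv) / kT
    n_k = np.bincount(origins, minlength=k_states)
    # reorder columns grouped by origin state
    order = np.argsort(origins, kind="stable")
    return ReducedPotentialMatrix(u[:, order], n_k)


def solvation_dg(
    system: InteractingSystem,
    conf0: Configuration,
    schedule: Schedule,
    settings: MCSettings,
    *,
    equilibration_fraction: float = 0.2,
) -> FreeEnergyEstimate:
    """Full equilibrium solvation free energy: MC at every window, MBAR.

    Windows are sampled serially, each seeded from the previous window's
    final configuration; the first ``equilibration_fraction`` of each
    window's samples is discarded before decorrelation.  Returns
    dG_solv = G(coupled) - G(decoupled) in kcal/mol.
    """
    if system.solute_mol is None:
        raise ValueError("system has no tagged solute molecule")
    kT = GAS_CONSTANT * settings.temperature
    states = list(schedule)
    configs: list[Configuration] = []
    origins: list[int] = []
    conf = conf0
    for k, state in enumerate(states):
        win = dc_replace(settings, seed=settings.seed + 1000 * k, keep_configurations=True)
        samples = run_mc(system, conf, win, state=state)
        conf = samples.acceptance["final_configuration"]
        n_eq = int(equilibration_fraction * samples.n_samples)
        # Decorrelate on the observable MBAR consumes: the reduced-energy
        # difference to the neighbouring window (cheap solute-environment
        # cross terms only), not the slowly-relaxing total energy.
        neighbour = states[k + 1] if k + 1 < len(states) else states[k - 1]
        lv_pair = np.array([state.lambda_vdw, neighbour.lambda_vdw])
        du = []
        for c in samples.configurations[n_eq:]:
            vv, e_here = _solute_cross_batch(system, c, lv_pair)
            du.append(
                (neighbour.lambda_elec - state.lambda_elec) * e_here + (vv[1] - vv[0])
            )
        kept = subsample(np.asarray(du), max_samples=400) + n_eq
        configs.extend(samples.configurations[i] for i in kept)
        origins.extend([k] * len(kept))
    matrix = reduced_potentials(
        system,
        configs,
        np.asarray(origins),
        schedule,
        settings.temperature,
        settings.pressure,
        relative=settings.pressure is None,
    )
    est = mbar(matrix, kT=kT)
    # mbar reports dF(coupled -> decoupled); solvation is the reverse.
    return dc_replace(est, delta_f=-est.delta_f)


def transfer_dg(
    dg_aq: FreeEnergyEstimate, dg_nonaq: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """Transfer free energy dG_trans(aq -> nonaq) = dG_solv(nonaq) - dG_solv(aq).

    Uncertainties from the two independent legs add in quadrature.
    """
    return FreeEnergyEstimate(
        delta_f=dg_nonaq.delta_f - dg_aq.delta_f,
        uncertainty=math.hypot(dg_aq.uncertainty, dg_nonaq.uncertainty),
        free_energies=np.array([0.0, dg_nonaq.delta_f - dg_aq.delta_f]),
        overlap=np.eye(2),
        kT=dg_aq.kT,
    )
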