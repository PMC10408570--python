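"""Rigid-body Metropolis MC: determinism, exactness of bookkeeping, and
agreement with analytic ensemble averages."""

import numpy as np
import pytest
from scipy import integrate, stats

from deff.fe import subsample
from deff.mc import MCSettings, SampleSet, density_estimate, hvap_estimate, run_mc
from deff.potentials import GlobalShape, PairParams, de_energy
from deff.system import Configuration, InteractingSystem
from deff.units import GAS_CONSTANT, ATM_TO_KCAL_PER_MOL_A3
from deff.workbench import make_water_box

SHAPE = GlobalShape(16.766, 4.427)


def ideal_system(n, seed=0, edge=30.0):
    rng = np.random.default_rng(seed)
    system = InteractingSystem(
        np.zeros(n), np.ones(n), np.zeros(n), np.arange(n), SHAPE,
        cutoff=1.0, switch_width=0.2, masses=np.full(n, 18.0),
    )
    conf = Configuration(rng.uniform(0, edge, (n, 3)), box=[edge] * 3)
    return system, conf


class TestEngine:
    def test_ideal_nvt_accepts_everything(self):
        system, conf = ideal_system(10)
        settings = MCSettings(temperature=300.0, n_steps=2000, seed=1, sample_stride=100)
        ss = run_mc(system, conf, settings)
        acc, att = ss.acceptance["accepted"], ss.acceptance["attempted"]
        assert acc["translation"] == att["translation"]
        assert acc["rotation"] == att["rotation"]

    def test_same_seed_identical(self, small_water_box):
        system, conf = small_water_box
        settings = MCSettings(temperature=298.15, n_steps=3000, seed=9, sample_stride=50)
        a = run_mc(system, conf.copy(), settings)
        b = run_mc(system, conf.copy(), settings)
        np.testing.assert_array_equal(a.energies, b.energies)
        np.testing.assert_array_equal(
            a.acceptance["final_configuration"].coordinates,
            b.acceptance["final_configuration"].coordinates,
        )

    def test_nonfinite_start_rejected(self):
        system = InteractingSystem([1.0] * 2, [1.0] * 2, [0.0] * 2, [0, 1], SHAPE)
        conf = Configuration([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        # overlapping DE particles are finite, so craft a Coulomb singularity
        system2 = InteractingSystem([0.0] * 2, [1.0] * 2, [1.0, 1.0], [0, 1], SHAPE)
        with pytest.raises(ValueError, match="non-finite"):
            run_mc(system2, conf, MCSettings(temperature=300.0, n_steps=10, seed=0))

    @pytest.mark.parametrize("pressure", [None, 1.0])
    def test_energy_bookkeeping_no_drift(self, small_water_box, pressure):
        # incremental running energy must match a fresh recomputation on
        # both the jitted NVT path and the reference NPT path
        system, conf = small_water_box
        settings = MCSettings(
            temperature=298.15, pressure=pressure, n_steps=4000, seed=5,
            sample_stride=200, max_volume=30.0,
        )
        ss = run_mc(system, conf.copy(), settings)
        run_e = ss.acceptance["running_energy"]
        fresh = ss.acceptance["fresh_energy"]
        assert run_e == pytest.approx(fresh, rel=1e-8, abs=1e-8)

    def test_harmonic_well_variance(self):
        # single particle in U = k|x - c|^2 / 2: each coordinate is Gaussian
        # with variance kT/k (Boltzmann statistics of the sampler)
        k = 2.0
        t = 300.0
        centre = np.array([15.0, 15.0, 15.0])
        system, conf = ideal_system(1, edge=30.0)
        conf.coordinates[0] = centre

        def well(coords, idx):
            return 0.5 * k * float(np.sum((coords - centre) ** 2))

        settings = MCSettings(
            temperature=t, n_steps=60000, seed=12, sample_stride=10,
            max_translation=0.8, move_weights=(1, 0, 0),
        )
        ss = run_mc(system, conf, settings, external=well)
        pos = np.array([c.coordinates[0] for c in ss.configurations])
        dev = pos - centre
        idx = subsample(dev[:, 0])
        dev = dev[idx]
        var = dev.var(axis=0, ddof=1).mean()
        expected = GAS_CONSTANT * t / k
        se = expected * np.sqrt(2.0 / (len(dev) * 3))
        assert abs(var - expected) < 3 * se


class TestBoltzmannPair:
    def test_radial_distribution_matches_quadrature(self):
        # two DE particles in a periodic box: p(r) ~ r^2 exp(-U_eff(r)/kT)
        # for r < L/2, with U_eff the switched/cutoff pair energy the
        # sampler itself uses
        eps, r_m, t, edge = 0.5, 3.4, 300.0, 16.0
        cutoff, sw = 7.0, 1.0
        kT = GAS_CONSTANT * t
        system = InteractingSystem(
            [eps] * 2, [r_m] * 2, [0.0] * 2, [0, 1], SHAPE,
            cutoff=cutoff, switch_width=sw, masses=[16.0] * 2,
        )
        conf = Configuration([[1.0, 1.0, 1.0], [4.4, 1.0, 1.0]], box=[edge] * 3)
        settings = MCSettings(
            temperature=t, n_steps=800000, seed=21, sample_stride=100,
            max_translation=1.2,
        )
        ss = run_mc(system, conf, settings)

        def u_eff(r):
            u = de_energy(r, PairParams(eps, r_m), SHAPE)
            r_on = cutoff - sw
            s = np.ones_like(r)
            inside = (r > r_on) & (r < cutoff)
            tt = (r[inside] - r_on) / sw
            s[inside] = 1 - tt**3 * (10 - 15 * tt + 6 * tt**2)
            s[r >= cutoff] = 0.0
            return u * s

        grid = np.linspace(1e-6, edge / 2, 4000)
        pdf = grid**2 * np.exp(-u_eff(grid) / kT)
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]

        delta = np.array(
            [c.coordinates[1] - c.coordinates[0] for c in ss.configurations]
        )
        delta -= edge * np.round(delta / edge)
        r_samples = np.linalg.norm(delta, axis=1)
        r_samples = r_samples[subsample(r_samples)]
        r_samples = r_samples[r_samples < edge / 2]
        res = stats.kstest(r_samples, lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01


class TestNPT:
    def test_ideal_gas_mean_volume(self):
        # <V> = (N+1) kT / P for linear volume moves with N ln(V'/V) Jacobian
        n, t, p = 100, 300.0, 1.0
        v_expected = (n + 1) * GAS_CONSTANT * t / (p * ATM_TO_KCAL_PER_MOL_A3)
        edge = v_expected ** (1 / 3)
        system, conf = ideal_system(n, edge=edge)
        settings = MCSettings(
            temperature=t, pressure=p, n_steps=30000, seed=4, sample_stride=10,
            move_weights=(1, 0, 1), max_volume=0.15 * v_expected,
            keep_configurations=False,
        )
        ss = run_mc(system, conf, settings)
        vols = ss.volumes[len(ss.volumes) // 5 :]
        idx = subsample(vols)
        v_mean = vols.mean()
        se = vols[idx].std(ddof=1) / np.sqrt(len(idx))
        assert abs(v_mean - v_expected) < 3 * se


class TestEstimators:
    def _npt_samples(self, volumes, energies=None):
        volumes = np.asarray(volumes, dtype=float)
        e = np.zeros_like(volumes) if energies is None else np.asarray(energies)
        return SampleSet(
            energies=e, volumes=volumes, configurations=None,
            acceptance={}, ensemble="npt", temperature=300.0, pressure=1.0, seed=0,
        )

    def test_density_doubles_with_mass(self):
        system, _ = ideal_system(10)
        samples = self._npt_samples(np.full(100, 1000.0))
        rho1, _ = density_estimate(samples, system)
        heavy = InteractingSystem(
            system.epsilon, system.r_m, system.charge, system.mol_id, SHAPE,
            cutoff=1.0, masses=system.masses * 2,
        )
        rho2, _ = density_estimate(samples, heavy)
        assert rho2 == pytest.approx(2 * rho1)

    def test_density_rejects_nvt(self):
        samples = SampleSet(
            energies=np.zeros(10), volumes=np.zeros(10), configurations=None,
            acceptance={}, ensemble="nvt", temperature=300.0, pressure=None, seed=0,
        )
        system, _ = ideal_system(5)
        with pytest.raises(ValueError, match="NPT"):
            density_estimate(samples, system)

    def test_density_known_value(self):
        # 10 particles of mass 18 in <V> = 300 A^3
        system, _ = ideal_system(10)
        samples = self._npt_samples(np.full(50, 300.0))
        rho, se = density_estimate(samples, system)
        assert rho == pytest.approx(10 * 18.0 / 300.0 / 0.6022140857)
        assert se == 0.0

    def test_hvap_rt_arithmetic(self):
        liquid = self._npt_samples(np.full(60, 1.0), energies=np.full(60, -10.0 * 8))
        dh, _ = hvap_estimate(liquid, gas_energy=0.0, n_molecules=8, temperature=298.15)
        assert dh == pytest.approx(10.0 + 0.0019872 * 298.15)
        assert dh == pytest.approx(10.59248, abs=1e-5)

    def test_hvap_ideal_is_rt(self):
        liquid = self._npt_samples(np.full(60, 1.0), energies=np.zeros(60))
        dh, _ = hvap_estimate(liquid, 0.0, 8, 300.0)
        assert dh == pytest.approx(GAS_CONSTANT * 300.0)

    def test_hvap_rejects_bad_n(self):
        liquid = self._npt_samples(np.full(10, 1.0))
        with pytest.raises(ValueError):
            hvap_estimate(liquid, 0.0, 0, 300.0)
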