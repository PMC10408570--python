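"""Combining rules, exclusions, virtual sites, periodic energies and forces."""

import numpy as np
import pytest

from deff.params import MolecularGraph
from deff.potentials import GlobalShape, PairParams, de_energy
from deff.system import (
    Configuration,
    InteractingSystem,
    build_exclusions,
    combine_pair,
    forces,
    place_virtual_sites,
    total_energy,
)
from deff.workbench import build_system, fixture_library, water_molecule

SHAPE = GlobalShape(16.766, 4.427)


class TestCombinePair:
    def test_lorentz_berthelot(self):
        out = combine_pair(PairParams(0.1, 3.0), PairParams(0.4, 4.0))
        assert out.epsilon == pytest.approx(0.2)
        assert out.r_m == pytest.approx(3.5)

    def test_idempotent_on_identical(self):
        p = PairParams(0.3, 3.3)
        out = combine_pair(p, p)
        assert out.epsilon == pytest.approx(p.epsilon)
        assert out.r_m == pytest.approx(p.r_m)

    def test_symmetric(self):
        a, b = PairParams(0.11, 2.9), PairParams(0.27, 4.1)
        assert combine_pair(a, b) == combine_pair(b, a)

    def test_zero_epsilon_disables(self):
        out = combine_pair(PairParams(0.0, 3.0), PairParams(0.5, 4.0))
        assert out.epsilon == 0.0


class TestExclusions:
    def test_butane_chain(self):
        # C0-C1-C2-C3 chain: ends are a 1-4 pair
        mol = MolecularGraph(
            ["C"] * 4, [0] * 4, np.zeros(4), [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)]
        )
        ex = build_exclusions(mol)
        assert ex[(0, 3)] == "scaled14"
        assert ex[(0, 1)] == "excluded"
        assert ex[(0, 2)] == "excluded"
        assert ex[(1, 3)] == "excluded"

    def test_water_hh_excluded(self):
        ex = build_exclusions(water_molecule())
        assert ex[(1, 2)] == "excluded"  # H-H via the oxygen
        assert ex[(0, 1)] == "excluded"

    def test_intermolecular_pairs_never_excluded(self, library):
        waters = []
        for shift in (0.0, 5.0):
            w = water_molecule()
            w.coordinates = w.coordinates + shift
            waters.append(w)
        system, _ = build_system(waters, library)
        a = np.flatnonzero(system.mol_id == 0)
        b = np.flatnonzero(system.mol_id == 1)
        assert system.pair_mask[np.ix_(a, b)].all()

    def test_distant_intramolecular_pair_interacts(self):
        # 5-atom chain: ends are 1-5, fully interacting
        mol = MolecularGraph(
            ["C"] * 5, [0] * 5, np.zeros(5), [(i, i + 1, 1.0) for i in range(4)]
        )
        ex = build_exclusions(mol)
        assert (0, 4) not in ex


class TestVirtualSites:
    def test_zero_distance_coincides_with_parent(self, library):
        system, conf = build_system([water_molecule()], library)
        v = system.vsites[0]
        conf2 = conf.copy()
        system.vsites[0] = type(v)(v.site, v.parent, v.h1, v.h2, 0.0)
        placed = place_virtual_sites(conf2, system)
        np.testing.assert_allclose(
            placed.coordinates[v.site], placed.coordinates[v.parent]
        )
        system.vsites[0] = v

    def test_site_on_bisector_at_distance(self, library):
        system, conf = build_system([water_molecule()], library)
        v = system.vsites[0]
        x = conf.coordinates
        d = np.linalg.norm(x[v.site] - x[v.parent])
        assert d == pytest.approx(v.distance)
        # bisector of the packaged geometry points along +z from O at origin
        np.testing.assert_allclose(
            x[v.site], [0.0, 0.0, v.distance], atol=1e-12
        )

    def test_rotation_equivariance(self, library):
        from scipy.spatial.transform import Rotation

        system, conf = build_system([water_molecule()], library)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        conf_rot = conf.copy()
        conf_rot.coordinates = conf.coordinates @ rot.T
        placed = place_virtual_sites(conf_rot, system)
        expected = place_virtual_sites(conf, system).coordinates @ rot.T
        np.testing.assert_allclose(placed.coordinates, expected, atol=1e-12)

    def test_collinear_geometry_rejected(self, library):
        system, conf = build_system([water_molecule()], library)
        bad = conf.copy()
        # H atoms diametrically opposite: bisector vanishes
        bad.coordinates[1] = [0.9572, 0.0, 0.0]
        bad.coordinates[2] = [-0.9572, 0.0, 0.0]
        with pytest.raises(ValueError, match="degenerate"):
            place_virtual_sites(bad, system)

    def test_parent_charge_moved_to_site(self, library):
        system, _ = build_system([water_molecule()], library)
        v = system.vsites[0]
        assert system.charge[v.parent] == pytest.approx(0.0)
        assert system.charge[v.site] == pytest.approx(-1.05174)
        assert system.charge.sum() == pytest.approx(0.0, abs=1e-12)
        assert system.masses[v.site] == 0.0


class TestTotalEnergy:
    def test_de_dimer_at_minimum(self):
        p = PairParams(0.3, 3.4)
        system = InteractingSystem(
            [p.epsilon] * 2, [p.r_m] * 2, [0.0, 0.0], [0, 1], SHAPE
        )
        conf = Configuration([[0.0, 0.0, 0.0], [3.4, 0.0, 0.0]])
        comp = total_energy(system, conf)
        assert comp["vdw"] == pytest.approx(-0.3)
        assert comp["elec"] == 0.0
        assert comp["total"] == pytest.approx(-0.3)

    def test_single_molecule_excluded_pairs_zero(self, library):
        system, conf = build_system([water_molecule()], library)
        comp = total_energy(system, conf)
        assert comp["total"] == 0.0

    def test_lattice_translation_invariance(self, small_water_box):
        system, conf = small_water_box
        e0 = total_energy(system, conf)["total"]
        shifted = conf.copy()
        shifted.coordinates = shifted.coordinates + conf.box
        e1 = total_energy(system, shifted)["total"]
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_vacuum_rigid_motion_invariance(self, library):
        from scipy.spatial.transform import Rotation

        waters = []
        for shift in (0.0, 3.1):
            w = water_molecule()
            w.coordinates = w.coordinates + shift
            waters.append(w)
        system, conf = build_system(waters, library)
        e0 = total_energy(system, conf)["total"]
        rot = Rotation.from_rotvec([0.4, 0.9, -0.2]).as_matrix()
        moved = conf.copy()
        moved.coordinates = conf.coordinates @ rot.T + np.array([5.0, -2.0, 1.0])
        assert total_energy(system, moved)["total"] == pytest.approx(e0, rel=1e-10)

    def test_decomposition_sums_to_total(self, small_water_box):
        system, conf = small_water_box
        comp = total_energy(system, conf)
        assert comp["total"] == comp["vdw"] + comp["elec"] + comp["long_range_correction"]

    def test_ideal_system_exactly_zero(self):
        rng = np.random.default_rng(3)
        n = 20
        system = InteractingSystem(
            np.zeros(n), np.ones(n), np.zeros(n), np.arange(n), SHAPE, cutoff=2.0
        )
        conf = Configuration(rng.uniform(0, 10, (n, 3)), box=[10.0] * 3)
        assert total_energy(system, conf)["total"] == 0.0

    def test_box_too_small_rejected(self):
        system = InteractingSystem(
            [0.1] * 2, [3.0] * 2, [0.0] * 2, [0, 1], SHAPE, cutoff=9.0
        )
        conf = Configuration([[0.0] * 3, [1.0] * 3], box=[10.0] * 3)
        with pytest.raises(ValueError, match="too small"):
            total_energy(system, conf)

    def test_scaled14_contribution(self):
        # two particles, bonded path of length 3: energy is scaled vdW+elec
        mol = MolecularGraph(
            ["C"] * 4,
            [0] * 4,
            np.array([0.2, -0.2, 0.2, -0.2]),
            [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)],
            coordinates=np.array(
                [[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [3.0, 1.5, 0.0]], float
            ),
        )
        p = [PairParams(0.1, 3.5)] * 4
        lib = fixture_library()
        system, conf = build_system([mol], lib, params_override=[p])
        comp = total_energy(system, conf)
        r14 = np.linalg.norm(mol.coordinates[3] - mol.coordinates[0])
        u_vdw = de_energy(r14, PairParams(0.1, 3.5), lib.shape)
        u_elec = 332.06371 * 0.2 * -0.2 / r14
        assert comp["vdw"] == pytest.approx(lib.scale14_vdw * u_vdw)
        assert comp["elec"] == pytest.approx(lib.scale14_elec * u_elec)


class TestForces:
    def test_dimer_forces_vanish_at_minimum(self):
        p = PairParams(0.3, 3.4)
        system = InteractingSystem(
            [p.epsilon] * 2, [p.r_m] * 2, [0.0, 0.0], [0, 1], SHAPE
        )
        conf = Configuration([[0.0, 0.0, 0.0], [3.4, 0.0, 0.0]])
        f = forces(system, conf)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_matches_finite_difference(self, small_water_box):
        system, conf = small_water_box
        f = forces(system, conf)
        h = 1e-5
        real = np.flatnonzero(~system.is_vsite)
        rng = np.random.default_rng(0)
        for i in rng.choice(real, 4, replace=False):
            for d in range(3):
                cp, cm = conf.copy(), conf.copy()
                cp.coordinates[i, d] += h
                cm.coordinates[i, d] -= h
                fd = -(
                    total_energy(system, cp)["total"] - total_energy(system, cm)["total"]
                ) / (2 * h)
                assert f[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_isolated_water_pair_zero_net_force_and_torque(self, library):
        waters = []
        for shift in ((0.0, 0.0, 0.0), (2.9, 0.4, 0.2)):
            w = water_molecule()
            w.coordinates = w.coordinates + np.asarray(shift)
            waters.append(w)
        system, conf = build_system(waters, library)
        f = forces(system, conf)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8)
        torque = np.cross(conf.coordinates, f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-8)
        # all force routed to real atoms
        np.testing.assert_allclose(f[system.is_vsite], 0.0)

    def test_net_force_zero_periodic(self, small_water_box):
        system, conf = small_water_box
        f = forces(system, conf)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8)
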