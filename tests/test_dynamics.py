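import numpy as np
import pytest

from fgpore.builder import (
    make_free_bead_system,
    make_free_cargo_system,
    make_inert_cargo,
    make_kap_complex,
)
from fgpore.dynamics import (
    ArrayPotential,
    ForceEvaluator,
    LangevinParams,
    Restraint,
    run,
)
from fgpore.forcefield import (
    electrostatic_pair_energy,
    excluded_volume_energy,
    hydrophobic_pair_energy,
)
from fgpore.units import KB


def harmonic_dimer(ff):
    """Two bonded beads, no nonbonded partners."""
    topo = make_free_bead_system(2, spacing=0.0, params=ff)
    topo.positions[1] = [ff.bond_length, 0.0, 0.0]
    topo.bonds = np.array([[0, 1]], dtype=np.int64)
    return topo


class TestDeterministicLimit:
    def test_energy_conserved_at_zero_temperature(self, ff):
        topo = harmonic_dimer(ff)
        topo.positions[1, 0] = ff.bond_length + 0.01  # stretched
        lang = LangevinParams(temperature=0.0, friction=0.0, timestep=0.02, seed=0)
        res = run(topo, ff, lang, n_steps=10000, coord_every=10)
        etot = res.potential + res.kinetic
        early = etot[1:501].mean()
        late = etot[-500:].mean()
        assert abs(late - early) / abs(early) < 1e-4


class TestThermostat:
    def test_free_bead_equipartition(self, ff):
        # OU stationary law: mean KE per dof = kT/2 within 2%
        lang = LangevinParams(temperature=300.0, friction=50.0, timestep=0.02, seed=4)
        topo = make_free_bead_system(64, spacing=10.0, params=ff)
        res = run(topo, ff, lang, n_steps=2500, coord_every=5)
        ke = res.kinetic[20:]
        kT_est = 2.0 * ke.mean() / res.n_dof
        assert kT_est == pytest.approx(KB * 300.0, rel=0.02)

    def test_restrained_cargo_boltzmann_variance(self, ff):
        k = 15.0
        lang = LangevinParams(temperature=300.0, friction=5.0, timestep=0.02, seed=8)
        topo = make_free_cargo_system(make_inert_cargo(1.0), params=ff)
        res = run(
            topo, ff, lang, restraints=(Restraint("z", k, 0.0),),
            n_steps=120000, coord_every=10, cargo_mass=12.0, cargo_friction=2.0,
        )
        z = res.centers[2000:, 2]
        assert z.var() == pytest.approx(KB * 300.0 / k, rel=0.15)

    def test_bond_rms_fluctuation_below_2pm(self, ff):
        topo = harmonic_dimer(ff)
        lang = LangevinParams(temperature=300.0, friction=50.0, timestep=0.02, seed=2)
        res = run(topo, ff, lang, n_steps=20000, coord_every=1, frame_every=10)
        lengths = np.array(
            [np.linalg.norm(f[1] - f[0]) for f in res.frames[100:]]
        )
        rms = np.sqrt(np.mean((lengths - ff.bond_length) ** 2))
        assert rms < 0.02


class TestDeterminism:
    def test_same_seed_identical_trajectories(self, light_ff):
        lang = LangevinParams(seed=7, friction=5.0)
        outs = []
        for _ in range(2):
            topo = make_free_bead_system(8, spacing=2.0, params=light_ff)
            res = run(topo, light_ff, lang, n_steps=500, coord_every=50)
            outs.append(res.state.positions.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_zero_steps_initial_frame_only(self, ff):
        topo = make_free_bead_system(4, params=ff)
        lang = LangevinParams(seed=0)
        res = run(topo, ff, lang, n_steps=0, frame_every=1)
        assert len(res.frames) == 1
        assert len(res.times) == 1


class TestRigidBody:
    def test_inter_spot_distances_preserved(self, ff):
        lang = LangevinParams(seed=3, friction=5.0)
        topo = make_free_cargo_system(make_kap_complex(10.0, 7, 1.3), params=ff)
        spots0 = topo.positions[topo.cargo.index][-7:].copy()
        d0 = np.linalg.norm(spots0[:, None] - spots0[None, :], axis=-1)
        res = run(topo, ff, lang, n_steps=2000, cargo_mass=120.0)
        spots1 = res.state.positions[topo.cargo.index][-7:]
        d1 = np.linalg.norm(spots1[:, None] - spots1[None, :], axis=-1)
        assert np.abs(d1 - d0).max() < 1e-9

    def test_quaternion_stays_normalised(self, ff):
        lang = LangevinParams(seed=3, friction=5.0)
        topo = make_free_cargo_system(make_kap_complex(10.0, 4, 1.3), params=ff)
        res = run(topo, ff, lang, n_steps=2000, cargo_mass=120.0)
        assert np.linalg.norm(res.state.cargo_quat) == pytest.approx(1.0, abs=1e-9)

    def test_frozen_orientation_does_not_rotate(self, ff):
        lang = LangevinParams(seed=3, friction=5.0)
        topo = make_free_cargo_system(make_kap_complex(10.0, 4, 1.3), params=ff)
        res = run(topo, ff, lang, n_steps=500, freeze_orientation=True)
        assert np.array_equal(res.state.cargo_quat, [1.0, 0.0, 0.0, 0.0])


class TestNeighborList:
    def test_forces_match_all_pairs_reference(self, ff, rng):
        """Neighbor-list forces equal a direct all-pairs evaluation built
        from the scalar pair functions (independent bookkeeping route)."""
        n = 40
        topo = make_free_bead_system(n, spacing=0.0, params=ff)
        topo.positions[:] = rng.uniform(-2.5, 2.5, size=(n, 3))
        topo.hydrophobicity[:] = rng.uniform(0, 1, n)
        topo.charge[:] = rng.choice([-1.0, 0.0, 1.0], n)
        ev = ForceEvaluator(topo, ff)
        e_list, f_list = ev.compute(topo.positions)

        e_ref = 0.0
        f_ref = np.zeros((n, 3))
        for i in range(n):
            for j in range(i + 1, n):
                d = topo.positions[j] - topo.positions[i]
                r = np.linalg.norm(d)
                eps = ff.eps_max * topo.hydrophobicity[i] * topo.hydrophobicity[j]
                if eps > 0:
                    e, fr = hydrophobic_pair_energy(
                        r, eps, topo.radius[i] + topo.radius[j],
                        ff.vdw_cutoff, ff.rep_strength,
                    )
                else:
                    e, fr = excluded_volume_energy(
                        r, topo.contact[i] + topo.contact[j], ff.rep_strength
                    )
                eq, frq = electrostatic_pair_energy(
                    r, topo.charge[i], topo.charge[j], ff
                )
                e_ref += float(e[0] + eq[0])
                fvec = (fr[0] + frq[0]) * (-d / r)
                f_ref[i] += fvec
                f_ref[j] -= fvec
        assert e_list == pytest.approx(e_ref, rel=1e-9, abs=1e-9)
        assert np.allclose(f_list, f_ref, rtol=1e-8, atol=1e-8)

    def test_list_valid_after_motion(self, light_ff, rng):
        n = 30
        topo = make_free_bead_system(n, spacing=0.0, params=light_ff)
        topo.positions[:] = rng.uniform(-2, 2, size=(n, 3)) * 1.5
        lang = LangevinParams(seed=5, friction=5.0)
        res = run(topo, light_ff, lang, n_steps=300, force_cap=1e4)
        ev_fresh = ForceEvaluator(topo, light_ff)
        e_fresh, f_fresh = ev_fresh.compute(res.state.positions)
        e_old, f_old = res.evaluator.compute(res.state.positions)
        assert e_old == pytest.approx(e_fresh, rel=1e-9)
        assert np.allclose(f_old, f_fresh, atol=1e-8)


class TestRestraints:
    def test_restraint_energy_forces(self):
        r = Restraint("z", 10.0, 1.0)
        e, f = r.energy_force(np.array([0.0, 0.0, 2.0]))
        assert e == pytest.approx(5.0)
        assert f[2] == pytest.approx(-10.0)

    def test_radial_restraint_centered(self):
        r = Restraint("r", 10.0, 0.0)
        e, f = r.energy_force(np.array([3.0, 4.0, 0.0]))
        assert e == pytest.approx(0.5 * 10 * 25)
        assert np.allclose(f[:2], [-30.0, -40.0])

    def test_invalid_coordinate(self):
        with pytest.raises(ValueError):
            Restraint("q", 1.0)

    def test_array_potential_applied(self, ff):
        topo = make_free_bead_system(3, spacing=5.0, params=ff)
        pot = ArrayPotential(lambda p: (float(np.sum(p[:, 2] ** 2)), -2.0 * p * [0, 0, 1]))
        lang = LangevinParams(temperature=0.0, friction=0.0, seed=0)
        topo.positions[:, 2] = 1.0
        res = run(topo, ff, lang, restraints=(pot,), n_steps=1)
        # a downhill force must reduce z
        assert np.all(res.state.positions[:, 2] < 1.0)


class TestKineticTemperature:
    def test_grafted_fixture_within_3_percent(self, ff):
        from fgpore.builder import build_system, generate_synthetic_fixture

        geom, anchors, seqs = generate_synthetic_fixture(0.25, seed=11, n_chains=8)
        topo = build_system(geom, anchors, seqs, seed=1, params=ff)
        lang = LangevinParams(temperature=300.0, friction=50.0, timestep=0.02, seed=6)
        res = run(topo, ff, lang, n_steps=4000, coord_every=5, force_cap=1e4)
        ke = res.kinetic[100:]
        T_est = 2.0 * ke.mean() / (res.n_dof * KB)
        assert T_est == pytest.approx(300.0, rel=0.03)
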