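"""Langevin integrator: free-particle statistics, forces, determinism."""

import numpy as np
import pytest

from gelscape.brownian import (
    ParticleFrame,
    SimConfig,
    init_equilibrate,
    kinetic_temperature,
    langevin_step,
    neighbor_pairs,
    pair_forces,
    pair_table,
    run_quench,
)


def make_free_frame(n=64, L=50.0, seed=0, kT=1.0):
    rng = np.random.default_rng(seed)
    species = np.zeros(n, dtype=np.int64)
    masses = np.ones(n)
    return ParticleFrame(time=0.0, box_edge=L,
                         positions=rng.uniform(0, L, (n, 3)),
                         velocities=rng.standard_normal((n, 3)) * np.sqrt(kT),
                         species=species, radii=np.full(n, 0.5), masses=masses)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_particles=1)
        with pytest.raises(ValueError):
            SimConfig(phi=0.9)

    def test_box_edge_from_volume_fraction(self):
        cfg = SimConfig(n_particles=1000, phi=0.12, size_ratio=1.1)
        n_a, n_b = 500, 500
        vol = 4 * np.pi / 3 * (n_a * 0.5**3 + n_b * 0.55**3)
        assert cfg.box_edge == pytest.approx((vol / 0.12) ** (1 / 3))


class TestNeighborPairs:
    def test_triangle(self):
        fr = make_free_frame(3, L=20.0)
        fr.positions = np.array([[5.0, 5, 5], [6.0, 5, 5], [5.5, 5.9, 5]])
        pairs, d = neighbor_pairs(fr, 1.2)
        assert len(pairs) == 3

    def test_periodic_image_pair(self):
        fr = make_free_frame(2, L=10.0)
        fr.positions = np.array([[0.2, 5, 5], [9.9, 5, 5]])
        pairs, d = neighbor_pairs(fr, 1.0)
        assert len(pairs) == 1
        assert d[0] == pytest.approx(0.3)

    def test_cutoff_must_fit_in_box(self):
        fr = make_free_frame(4, L=2.0)
        with pytest.raises(ValueError):
            neighbor_pairs(fr, 1.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        fr = make_free_frame(150, L=8.0, seed=3)
        pairs, _ = neighbor_pairs(fr, 1.5)
        found = {tuple(sorted(p)) for p in pairs.tolist()}
        expected = set()
        for i in range(150):
            for j in range(i + 1, 150):
                d = fr.positions[i] - fr.positions[j]
                d -= 8.0 * np.round(d / 8.0)
                if np.sqrt((d * d).sum()) < 1.5:
                    expected.add((i, j))
        assert found == expected


class TestLangevin:
    def test_velocity_decay_without_noise(self):
        cfg = SimConfig(n_particles=8, phi=0.001, eps_over_kT=0.0, dt=0.01,
                        zeta=1.0, seed=0)
        fr = make_free_frame(8, L=cfg.box_edge)
        v0 = fr.velocities.copy()
        table = pair_table(cfg)
        rng = np.random.default_rng(0)
        for _ in range(200):
            fr, _ = langevin_step(fr, cfg, table, rng, noise=False)
        # v(t) = v0 exp(-t/zeta), t = 2
        assert np.allclose(fr.velocities, v0 * np.exp(-2.0), rtol=1e-10)

    def test_equipartition_with_noise(self):
        cfg = SimConfig(n_particles=125, phi=0.001, eps_over_kT=0.0, dt=0.05,
                        zeta=1.0, seed=0)
        fr = make_free_frame(125, L=cfg.box_edge, kT=0.3)  # start cold
        table = pair_table(cfg)
        rng = np.random.default_rng(5)
        temps = []
        for i in range(4000):
            fr, _ = langevin_step(fr, cfg, table, rng)
            if i >= 500:
                temps.append(kinetic_temperature(fr))
        assert np.mean(temps) == pytest.approx(1.0, abs=0.03)

    def test_diffusion_einstein_relation(self):
        # D = kT zeta / m for friction m/zeta; MSD slope = 6 D
        cfg = SimConfig(n_particles=200, phi=0.0005, eps_over_kT=0.0, dt=0.05,
                        zeta=1.0, seed=0)
        fr = make_free_frame(200, L=cfg.box_edge)
        table = pair_table(cfg)
        rng = np.random.default_rng(8)
        # thermalize, then accumulate unwrapped displacements
        for _ in range(400):
            fr, _ = langevin_step(fr, cfg, table, rng)
        disp = np.zeros((200, 3))
        msd_t, msd = [], []
        prev = fr.positions.copy()
        for i in range(1, 1201):
            fr, _ = langevin_step(fr, cfg, table, rng)
            d = fr.positions - prev
            d -= cfg.box_edge * np.round(d / cfg.box_edge)
            disp += d
            prev = fr.positions.copy()
            if i % 100 == 0:
                msd_t.append(i * cfg.dt)
                msd.append((disp**2).sum(axis=1).mean())
        slope = np.polyfit(msd_t, msd, 1)[0]
        assert slope == pytest.approx(6.0, rel=0.15)

    def test_energy_conservation_without_thermostat(self):
        cfg = SimConfig(n_particles=32, phi=0.05, eps_over_kT=1.0, dt=0.0025,
                        seed=2, equil_time=2.0)
        fr = init_equilibrate(cfg)
        table = pair_table(cfg)
        rng = np.random.default_rng(0)
        energies = []
        forces = None
        for i in range(4000):
            fr, forces = langevin_step(fr, cfg, table, rng, forces,
                                       noise=False, friction=False)
            if i % 40 == 0:
                _, pe = pair_forces(fr, table)
                ke = 0.5 * (fr.masses[:, None] * fr.velocities**2).sum()
                energies.append(ke + pe)
        energies = np.array(energies)
        drift = np.polyfit(np.arange(len(energies)), energies, 1)[0] * len(energies)
        assert abs(drift) / cfg.n_particles < 1e-3
        assert np.ptp(energies) / cfg.n_particles < 0.02

    def test_noise_without_friction_rejected(self):
        cfg = SimConfig(n_particles=8, phi=0.01)
        fr = make_free_frame(8, L=cfg.box_edge)
        with pytest.raises(ValueError):
            langevin_step(fr, cfg, pair_table(cfg), np.random.default_rng(0),
                          noise=True, friction=False)


class TestInitAndQuench:
    def test_same_seed_same_frame(self):
        cfg = SimConfig(n_particles=64, phi=0.12, seed=9, equil_time=1.0)
        f1 = init_equilibrate(cfg)
        f2 = init_equilibrate(cfg)
        assert np.array_equal(f1.positions, f2.positions)
        assert np.array_equal(f1.velocities, f2.velocities)

    def test_different_seeds_decorrelate(self):
        cfg1 = SimConfig(n_particles=64, phi=0.12, seed=1, equil_time=0.0)
        cfg2 = SimConfig(n_particles=64, phi=0.12, seed=2, equil_time=0.0)
        f1, f2 = init_equilibrate(cfg1), init_equilibrate(cfg2)
        assert not np.allclose(f1.positions, f2.positions)

    def test_species_counts_equal_and_masses_density_matched(self):
        cfg = SimConfig(n_particles=100, phi=0.12, seed=0, equil_time=0.0)
        fr = init_equilibrate(cfg)
        assert (fr.species == 0).sum() == (fr.species == 1).sum()
        assert np.allclose(fr.masses[fr.species == 1], 1.1**3)

    def test_no_core_overlaps_after_equilibration(self):
        cfg = SimConfig(n_particles=125, phi=0.12, seed=4, equil_time=2.0)
        fr = init_equilibrate(cfg)
        _, d = neighbor_pairs(fr, 1.0)
        assert (len(d) == 0) or d.min() > 0.85

    def test_zero_duration_quench_single_frame(self):
        cfg = SimConfig(n_particles=27, phi=0.12, seed=0, equil_time=0.0)
        fr = init_equilibrate(cfg)
        traj = run_quench(fr, cfg, quench_time=0.0)
        assert len(traj) == 1
        assert np.array_equal(traj[0].positions, fr.positions)

    def test_quench_grows_coordination(self):
        from gelscape.clusters import SimulationCriterion, contact_pairs, mean_coordination
        from gelscape.potentials import MiePotential, inflection_radius
        cfg = SimConfig(n_particles=125, phi=0.12, eps_over_kT=4.0, seed=7,
                        equil_time=3.0, quench_time=15.0, frame_interval=3.0)
        start = init_equilibrate(cfg)
        traj = run_quench(start, cfg)
        cut = inflection_radius(MiePotential())
        sig = np.array([[1.0, 1.05], [1.05, 1.1]])
        crit = SimulationCriterion(cutoff=cut, sigma=sig)
        z0 = mean_coordination(contact_pairs(traj[0], crit))
        z1 = mean_coordination(contact_pairs(traj.frames[-1], crit))
        assert z1 > z0 + 0.5      # bonds accumulate during the quench

    def test_same_seed_same_trajectory(self):
        cfg = SimConfig(n_particles=27, phi=0.10, eps_over_kT=3.0, seed=3,
                        equil_time=0.5, quench_time=1.0, frame_interval=0.5)
        t1 = run_quench(init_equilibrate(cfg), cfg)
        t2 = run_quench(init_equilibrate(cfg), cfg)
        assert all(np.array_equal(a.positions, b.positions)
                   for a, b in zip(t1.frames, t2.frames))


class TestForces:
    def test_matches_all_pairs_reference(self):
        cfg = SimConfig(n_particles=60, phi=0.15, eps_over_kT=2.0, seed=1,
                        equil_time=0.0)
        fr = init_equilibrate(cfg)
        table = pair_table(cfg)
        forces, energy = pair_forces(fr, table)
        # brute-force reference
        ref = np.zeros_like(forces)
        e_ref = 0.0
        L = fr.box_edge
        pref = table.prefactor * table.epsilon
        for i in range(fr.n):
            for j in range(i + 1, fr.n):
                d = fr.positions[i] - fr.positions[j]
                d -= L * np.round(d / L)
                r = np.sqrt((d * d).sum())
                si, sj = fr.species[i], fr.species[j]
                if r >= table.cutoff[si, sj]:
                    continue
                sr = table.sigma[si, sj] / r
                e_ref += pref * (sr**table.n - sr**table.m) + table.shift[si, sj]
                fmag = pref / r * (table.n * sr**table.n - table.m * sr**table.m)
                ref[i] += fmag / r * d
                ref[j] -= fmag / r * d
        assert np.allclose(forces, ref, atol=1e-12)
        assert energy == pytest.approx(e_ref, abs=1e-12)
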