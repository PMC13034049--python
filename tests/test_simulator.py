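"""Engine checks: thermostat, closed-form dynamics, slab setup, trajectory I/O."""

import numpy as np
import pytest
from scipy.integrate import quad

from coacervmd import forcefield as ff
from coacervmd import simulator as sim
from coacervmd.constructs import assemble_construct
from coacervmd.parameters import KB, MVSQ2E


def ideal_tracers(n=64, box_edge=100.0, temperature=300.0, seed=1):
    """Noninteracting point beads (no charge, eps_lj = 0)."""
    tracer = assemble_construct("peptide", sequence="G", name="tracer")
    ffc = ff.ForceFieldConfig(eps_lj=0.0)
    topo = ff.build_topology([(tracer, n)], ffc)
    topo.charges[:] = 0.0
    rng = np.random.default_rng(seed)
    box = np.full(3, box_edge)
    coords = rng.uniform(0, box_edge, (n, 3))
    sigv = np.sqrt(KB * temperature / (topo.masses * MVSQ2E))
    vel = rng.standard_normal((n, 3)) * sigv[:, None]
    state = sim.SystemState(coords, vel, box, temperature, 0.1, topo)
    return state, ffc, topo


class TestThermostat:
    def test_mean_kinetic_temperature(self):
        """Equipartition: time-averaged kinetic temperature within 2%."""
        state, ffc, _ = ideal_tracers(n=256, seed=3)
        temps = []
        for k in range(40):
            sim.run_langevin(state, ffc, sim.SimulationConfig(
                steps=500, dt=10.0, friction=1e-2, seed=100 + k, stride=500))
            temps.append(state.kinetic_temperature())
        assert np.mean(temps[5:]) == pytest.approx(300.0, rel=0.02)

    def test_zero_friction_energy_conservation(self):
        """gamma = 0 reduces BAOAB to velocity Verlet: relative total-energy
        drift below 1e-4 over 1e4 steps on a small bonded system."""
        # short enough that no nonbonded pair ever crosses the truncation
        # cutoff (plain-truncated potentials are only conservative then)
        c = assemble_construct("ss", sequence="ACGT", kbend_ss=20.0, name="s4")
        ffc = ff.ForceFieldConfig()
        topo = ff.build_topology([(c, 1)], ffc)
        rng = np.random.default_rng(4)
        coords = sim.template_coords(c, ffc, rng) + 80.0
        sigv = np.sqrt(KB * 298.0 / (topo.masses * MVSQ2E))
        vel = rng.standard_normal(coords.shape) * sigv[:, None]
        state = sim.SystemState(coords, vel, np.full(3, 160.0), 298.0, 0.1,
                                topo)

        def total_energy():
            pe = ff.total_energy_forces(state.coords, state.box, topo,
                                        ff.ElectrostaticsParams.from_state(
                                            298.0, 0.1), ffc)[0]
            ke = 0.5 * MVSQ2E * np.sum(topo.masses[:, None]
                                       * state.velocities**2)
            return pe + ke

        e0 = total_energy()
        sim.run_langevin(state, ffc, sim.SimulationConfig(
            steps=10_000, dt=2.0, friction=0.0, seed=1, stride=10_000))
        e1 = total_energy()
        assert abs(e1 - e0) / abs(e0) < 1e-4


class TestClosedFormDynamics:
    def test_free_tracer_diffusion(self):
        """Langevin free particle: D = kBT/(m gamma) within 5%."""
        from coacervmd.condensate_analysis import diffusion_coefficients

        state, ffc, topo = ideal_tracers(n=128, seed=5)
        gamma = 1e-3
        traj = sim.run_langevin(state, ffc, sim.SimulationConfig(
            steps=50_000, dt=10.0, friction=gamma, seed=6, stride=100))
        res = diffusion_coefficients(traj, "tracer", fit_window=(0.05, 0.3))
        d_theory = KB * 300.0 / (topo.masses[0] * MVSQ2E * gamma)
        assert res.D == pytest.approx(d_theory, rel=0.05)
        assert res.r_squared > 0.99

    def test_harmonic_dimer_bond_variance(self):
        """Bond-length variance of a k(r-r0)^2 dimer against the Boltzmann
        radial distribution evaluated by numerical quadrature."""
        dimer = assemble_construct("peptide", sequence="GG", name="dimer")
        ffc = ff.ForceFieldConfig(eps_lj=0.0)
        topo = ff.build_topology([(dimer, 1)], ffc)
        topo.charges[:] = 0.0
        k, r0, temperature = ffc.k_bond, ffc.r0_peptide, 300.0
        kt = KB * temperature

        w = lambda r: r**2 * np.exp(-k * (r - r0) ** 2 / kt)
        z = quad(w, 0, r0 + 10)[0]
        mean_r = quad(lambda r: r * w(r), 0, r0 + 10)[0] / z
        var_ref = quad(lambda r: (r - mean_r) ** 2 * w(r), 0, r0 + 10)[0] / z
        # quadrature oracle agrees with the stiff-spring closed form kT/(2k)
        assert var_ref == pytest.approx(kt / (2 * k), rel=0.02)

        rng = np.random.default_rng(7)
        coords = np.array([[50.0, 50, 50], [50.0 + r0, 50, 50]])
        sigv = np.sqrt(kt / (topo.masses * MVSQ2E))
        vel = rng.standard_normal((2, 3)) * sigv[:, None]
        state = sim.SystemState(coords, vel, np.full(3, 100.0), temperature,
                                0.1, topo)
        traj = sim.run_langevin(state, ffc, sim.SimulationConfig(
            steps=200_000, dt=10.0, friction=5e-3, seed=8, stride=50))
        d = traj.frames[20:, 1] - traj.frames[20:, 0]
        r = np.linalg.norm(d, axis=1)
        assert np.var(r) == pytest.approx(var_ref, rel=0.05)

    @pytest.mark.parametrize("k_bend", [10.0, 25.0])
    def test_persistence_length_vs_bending(self, k_bend):
        """Adjacent bond-vector correlation of a semiflexible strand matches
        the discrete worm-like-chain estimate l_p = 2 k_bend b / kBT."""
        c = assemble_construct("ss", length=40, seed=3, kbend_ss=k_bend,
                               name="stiff")
        ffc = ff.ForceFieldConfig(eps_lj=0.0)
        topo = ff.build_topology([(c, 1)], ffc)
        topo.charges[:] = 0.0
        rng = np.random.default_rng(9)
        temperature = 300.0
        coords = np.zeros((40, 3))
        coords[:, 2] = np.arange(40) * ffc.r0_ss
        coords += 120.0
        sigv = np.sqrt(KB * temperature / (topo.masses * MVSQ2E))
        vel = rng.standard_normal((40, 3)) * sigv[:, None]
        state = sim.SystemState(coords, vel, np.full(3, 400.0), temperature,
                                0.1, topo)
        traj = sim.run_langevin(state, ffc, sim.SimulationConfig(
            steps=60_000, dt=10.0, friction=2e-3, seed=10, stride=200))
        cos_sum, n_sum = 0.0, 0
        for f in traj.frames[traj.n_frames // 4:]:
            bonds = np.diff(f, axis=0)
            u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
            cos_sum += np.sum(np.einsum("ij,ij->i", u[:-1], u[1:]))
            n_sum += len(u) - 1
        mean_cos = cos_sum / n_sum
        lp = -ffc.r0_ss / np.log(mean_cos)
        lp_wlc = 2.0 * k_bend * ffc.r0_ss / (KB * temperature)
        assert lp == pytest.approx(lp_wlc, rel=0.20)

    def test_persistence_length_monotone_in_k_bend(self):
        """Stiffer chains decorrelate slower (uses short matched runs)."""
        lps = []
        for k_bend in (5.0, 20.0):
            c = assemble_construct("ss", length=30, seed=3, kbend_ss=k_bend,
                                   name="s")
            ffc = ff.ForceFieldConfig(eps_lj=0.0)
            topo = ff.build_topology([(c, 1)], ffc)
            topo.charges[:] = 0.0
            rng = np.random.default_rng(11)
            coords = np.zeros((30, 3))
            coords[:, 2] = np.arange(30) * ffc.r0_ss
            coords += 120.0
            sigv = np.sqrt(KB * 300.0 / (topo.masses * MVSQ2E))
            vel = rng.standard_normal((30, 3)) * sigv[:, None]
            state = sim.SystemState(coords, vel, np.full(3, 400.0), 300.0,
                                    0.1, topo)
            traj = sim.run_langevin(state, ffc, sim.SimulationConfig(
                steps=20_000, dt=10.0, friction=2e-3, seed=12, stride=200))
            cs, ns = 0.0, 0
            for f in traj.frames[traj.n_frames // 4:]:
                bonds = np.diff(f, axis=0)
                u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
                cs += np.sum(np.einsum("ij,ij->i", u[:-1], u[1:]))
                ns += len(u) - 1
            lps.append(-ffc.r0_ss / np.log(cs / ns))
        assert lps[1] > lps[0]


class TestSlabInit:
    def test_target_concentrations(self, library):
        state = sim.init_slab(
            [(library["pL22"], 33), (library["ssDNA-10"], 22)], 298.0, 0.025,
            seed=5, concentrations={"pL22": 0.120, "ssDNA-10": 0.080},
            ff=ff.ForceFieldConfig(cutoff_elec=20.0), min_xy=42.0)
        conc = state.concentrations()
        assert conc["pL22"] == pytest.approx(0.120, rel=0.02)
        assert conc["ssDNA-10"] == pytest.approx(0.080, rel=0.02)
        # elongated along z, but with the dense region thinner than the
        # cross-section so it stays a slab rather than a column
        assert state.box[2] / state.box[0] >= 2.0
        z = np.mod(state.coords[:, 2], state.box[2])
        h_occupied = np.percentile(z, 97.5) - np.percentile(z, 2.5)
        assert h_occupied <= 1.1 * state.box[0]

    def test_single_molecule(self, library, ffconfig):
        state = sim.init_slab([(library["ssDNA-10"], 1)], 298.0, 0.1, seed=1,
                              ff=ffconfig, min_xy=2 * ffconfig.max_cutoff + 2)
        assert state.n_beads == 10

    def test_determinism(self, library):
        ffc = ff.ForceFieldConfig(cutoff_elec=20.0)
        kw = dict(concentrations={"pL22": 0.120, "ssDNA-10": 0.080},
                  ff=ffc, min_xy=42.0)
        a = sim.init_slab([(library["pL22"], 10), (library["ssDNA-10"], 7)],
                          298.0, 0.05, seed=9, **kw)
        b = sim.init_slab([(library["pL22"], 10), (library["ssDNA-10"], 7)],
                          298.0, 0.05, seed=9, **kw)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.velocities, b.velocities)

    def test_beads_start_inside_slab(self, library):
        ffc = ff.ForceFieldConfig(cutoff_elec=20.0)
        state = sim.init_slab(
            [(library["pL22"], 20), (library["ssDNA-20"], 7)], 298.0, 0.05,
            seed=2, concentrations={"pL22": 0.120, "ssDNA-20": 0.040},
            ff=ffc, min_xy=42.0)
        z = np.mod(state.coords[:, 2], state.box[2])
        lz = state.box[2]
        # all beads within the central 60% plus a molecule radius
        assert np.all(np.abs(z - lz / 2) < 0.35 * lz + 40.0)

    def test_run_determinism(self):
        state1, ffc, _ = ideal_tracers(seed=20)
        t1 = sim.run_langevin(state1, ffc, sim.SimulationConfig(
            steps=2000, seed=21, stride=500))
        state2, _, _ = ideal_tracers(seed=20)
        t2 = sim.run_langevin(state2, ffc, sim.SimulationConfig(
            steps=2000, seed=21, stride=500))
        assert np.array_equal(t1.frames, t2.frames)


class TestTrajectoryIO:
    def _traj(self, rng, frames=5, beads=8):
        return sim.Trajectory(
            frames=rng.normal(scale=20, size=(frames, beads, 3)),
            times=np.arange(frames) * 100.0, box=np.array([40.0, 40.0, 120.0]),
            T=303.0, ionic_strength=0.075,
            species=np.array(["molA"] * 4 + ["molB"] * 4),
            mol_id=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
            bead_types=np.array(["DA", "DC", "DG", "DT", "K", "R", "G", "D"]),
            charges=np.array([-1.0, -1, -1, -1, 1, 1, 0, -1]))

    def test_roundtrip(self, rng, tmp_path):
        traj = self._traj(rng)
        path = tmp_path / "t.xyz"
        sim.write_trajectory(traj, path)
        back = sim.read_trajectory(path)
        assert np.allclose(back.frames, traj.frames, atol=1.01e-4)
        assert np.array_equal(back.species, traj.species)
        assert np.array_equal(back.mol_id, traj.mol_id)
        assert np.array_equal(back.bead_types, traj.bead_types)
        assert back.T == traj.T
        assert back.ionic_strength == traj.ionic_strength
        assert np.allclose(back.box, traj.box)
        assert np.allclose(back.times, traj.times)

    def test_empty_trajectory(self, tmp_path):
        traj = sim.Trajectory(frames=np.empty((0, 0, 3)), times=np.empty(0),
                              box=np.ones(3), T=300.0, ionic_strength=0.1,
                              species=np.empty(0, dtype=str),
                              mol_id=np.empty(0, dtype=np.int64),
                              bead_types=np.empty(0, dtype=str),
                              charges=np.empty(0))
        path = tmp_path / "empty.xyz"
        sim.write_trajectory(traj, path)
        back = sim.read_trajectory(path)
        assert back.n_frames == 0

    def test_truncated_file_names_frame(self, rng, tmp_path):
        traj = self._traj(rng)
        path = tmp_path / "t.xyz"
        sim.write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        (tmp_path / "trunc.xyz").write_text("\n".join(lines[:-3]) + "\n")
        with pytest.raises(sim.SimulationError, match="frame 4"):
            sim.read_trajectory(tmp_path / "trunc.xyz")
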