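"""Single-molecule descriptors: closed-form and brute-force oracles."""

import numpy as np
import pytest

from coacervmd import polyanion_metrics as pm
from coacervmd.constructs import assemble_construct
from coacervmd.parameters import COULOMB_K
from coacervmd.polyanion_metrics import (
    AtomRecord,
    ConformationEnsemble,
    MetricsError,
    build_surface_points,
    contour_length,
    mean_surface_potential,
    normalized_surface_potential,
    read_pqr,
    rmsd_normalized,
)


class TestContourLength:
    def test_printed_step_lengths(self, library):
        assert contour_length(library["ssDNA-10"]) == pytest.approx(6.0)
        assert contour_length(library["dsDNA-20"]) == pytest.approx(6.8)
        assert contour_length(library["hdsDNA"]) == pytest.approx(9.4)
        assert contour_length(library["hp5DNA"]) == pytest.approx(
            10 * 0.6 + 5 * 0.34)

    def test_peptide_rejected(self, library):
        with pytest.raises(MetricsError):
            contour_length(library["pL22"])


class TestRMSD:
    def test_frozen_ensemble_zero(self, rng):
        frame = rng.normal(size=(12, 3))
        ens = ConformationEnsemble(np.tile(frame, (6, 1, 1)))
        rmsd, rmsd_n = rmsd_normalized(ens, 12)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert rmsd_n == pytest.approx(0.0, abs=1e-10)

    def test_rigid_rotations_removed(self, rng):
        frame = rng.normal(size=(15, 3)) * 5
        frames = []
        for th in np.linspace(0, 2, 8):
            rot = np.array([[np.cos(th), -np.sin(th), 0],
                            [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
            frames.append(frame @ rot.T + th * np.array([7.0, -3.0, 2.0]))
        rmsd, _ = rmsd_normalized(ConformationEnsemble(np.array(frames)), 15)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_two_frame_against_scipy_oracle(self):
        """Two-frame ensemble: deviations about the mean are half the
        residual of the optimal pairwise superposition, computed
        independently with scipy's Kabsch solver."""
        from scipy.spatial.transform import Rotation

        base = np.array([[0.0, 0, 0], [20.0, 0, 0], [0.0, 20, 0],
                         [0.0, 0, 20], [20.0, 20, 20]])
        moved = base.copy()
        moved[4, 0] += 0.4
        ens = ConformationEnsemble(np.stack([base, moved]))
        rmsd, rmsd_n = rmsd_normalized(ens, 5)
        a = base - base.mean(axis=0)
        b = moved - moved.mean(axis=0)
        rot, _ = Rotation.align_vectors(a, b)
        resid = a - rot.apply(b)
        rmsd_pair = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert rmsd == pytest.approx(rmsd_pair / 2, rel=1e-6)
        assert rmsd_n == pytest.approx(rmsd / 5)

    def test_mismatched_bead_counts_rejected(self, rng):
        with pytest.raises(MetricsError):
            ConformationEnsemble(rng.normal(size=(1, 5, 3)))

    def test_normalization_flattens_linear_scaling(self, rng):
        """Constructed ensembles whose fluctuation amplitude grows linearly
        with N: RMSD_n is length-independent by construction."""
        vals = {}
        for n in (10, 20, 40):
            base = np.zeros((n, 3))
            base[:, 0] = np.arange(n) * 5.0
            frames = [base + 0.05 * n * rng.standard_normal((n, 3))
                      for _ in range(300)]
            rmsd, rmsd_n = rmsd_normalized(ConformationEnsemble(np.array(frames)), n)
            vals[n] = rmsd_n
        spread = (max(vals.values()) - min(vals.values())) / np.mean(
            list(vals.values()))
        assert spread < 0.2

    def test_fjc_sqrt_scaling(self, rng):
        """Brute-force freely-jointed-chain oracle: raw RMSD grows ~sqrt(N),
        so RMSD alone cannot rank chains of different lengths."""
        rmsds = {}
        for n in (10, 40):
            frames = []
            for _ in range(250):
                steps = rng.standard_normal((n - 1, 3))
                steps /= np.linalg.norm(steps, axis=1, keepdims=True)
                frames.append(np.vstack([np.zeros(3),
                                         np.cumsum(steps * 5.0, axis=0)]))
            rmsds[n] = rmsd_normalized(ConformationEnsemble(np.array(frames)),
                                       n)[0]
        assert rmsds[40] / rmsds[10] == pytest.approx(2.0, rel=0.25)


PQR_FIXTURE = """\
REMARK synthetic two-atom fixture
ATOM      1  P     DA A   1      0.000   0.000   0.000 -1.0000 1.9000
ATOM      2  N1    DA A   1      3.000   0.000   0.000  0.2500 1.5000
"""


class TestPQR:
    def test_two_atom_fixture(self, tmp_path):
        path = tmp_path / "toy.pqr"
        path.write_text(PQR_FIXTURE)
        atoms = read_pqr(path)
        assert len(atoms) == 2
        assert sum(a.charge for a in atoms) == pytest.approx(-0.75)
        assert atoms[0].radius == 1.9

    def test_agrees_with_mdanalysis(self, tmp_path):
        """Cross-check the reader against MDAnalysis' PQR parser."""
        import warnings

        path = tmp_path / "toy.pqr"
        path.write_text(PQR_FIXTURE)
        atoms = read_pqr(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import MDAnalysis as mda

            u = mda.Universe(str(path))
        assert np.allclose(u.atoms.charges,
                           [a.charge for a in atoms])
        assert np.allclose(u.atoms.radii, [a.radius for a in atoms])
        assert np.allclose(u.atoms.positions,
                           np.array([a.xyz for a in atoms]))

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.pqr"
        path.write_text("REMARK nothing\n")
        with pytest.warns(UserWarning):
            assert read_pqr(path) == []

    def test_missing_radius_names_line(self, tmp_path):
        path = tmp_path / "bad.pqr"
        path.write_text("ATOM 1 P DA 1 0.0 0.0\n")
        with pytest.raises(MetricsError, match="line 1"):
            read_pqr(path)


class TestSurfaceGrid:
    def test_single_atom_shell_distances(self):
        atoms = [AtomRecord("X", np.zeros(3), -1.0, 2.0)]
        grid = build_surface_points(atoms, spacing=0.5, probe=1.4)
        r = np.linalg.norm(grid.points, axis=1)
        assert len(grid.points) > 100
        assert np.all(r >= 3.4 - 1e-9)
        assert np.all(r <= 3.9 + 1e-9)

    def test_two_far_atoms_double_count(self):
        a = [AtomRecord("X", np.zeros(3), -1.0, 2.0)]
        b = [AtomRecord("X", np.zeros(3), -1.0, 2.0),
             AtomRecord("Y", np.array([40.0, 0, 0]), -1.0, 2.0)]
        na = len(build_surface_points(a, 0.5, 1.4).points)
        nb = len(build_surface_points(b, 0.5, 1.4).points)
        assert nb == pytest.approx(2 * na, rel=0.1)

    def test_halving_spacing_quadruples_count(self):
        atoms = [AtomRecord("X", np.zeros(3), -1.0, 2.0)]
        n1 = len(build_surface_points(atoms, 1.0, 1.4).points)
        n2 = len(build_surface_points(atoms, 0.5, 1.4).points)
        # shell volume ~ 4 pi R^2 * spacing; point density ~ spacing^-3
        assert n2 / n1 == pytest.approx(4.0, rel=0.2)

    def test_no_atoms_rejected(self):
        with pytest.raises(MetricsError):
            build_surface_points([], 0.5, 1.4)


class TestSurfacePotential:
    def test_point_charge_closed_form(self):
        atoms = [AtomRecord("X", np.zeros(3), -1.0, 2.0)]
        grid = build_surface_points(atoms, spacing=0.3, probe=1.4)
        phi = mean_surface_potential(atoms, grid, eps=2.0)
        r_mean = np.mean(1.0 / np.linalg.norm(grid.points, axis=1))
        # closed form -K/(eps R) at the mean inverse shell radius
        assert phi == pytest.approx(-COULOMB_K / 2.0 * r_mean, rel=1e-9)
        mid_r = 3.4 + 0.3 / 2 + 1.4 * 0  # inner radius + half voxel
        assert phi == pytest.approx(-COULOMB_K / (2.0 * mid_r), rel=0.03)

    def test_dipole_near_cancellation(self):
        q = 1.0
        dip = [AtomRecord("P", np.array([-1.0, 0, 0]), +q, 2.0),
               AtomRecord("M", np.array([+1.0, 0, 0]), -q, 2.0)]
        mono = [AtomRecord("M", np.zeros(3), -q, 2.0)]
        gd = build_surface_points(dip, 0.4, 1.4)
        gm = build_surface_points(mono, 0.4, 1.4)
        phi_d = mean_surface_potential(dip, gd)
        phi_m = mean_surface_potential(mono, gm)
        assert abs(phi_d) < 0.01 * abs(phi_m)

    def test_linearity_in_charge(self):
        atoms = [AtomRecord("X", np.array([0.0, 0, 0]), -0.5, 1.8),
                 AtomRecord("Y", np.array([4.0, 0, 0]), -1.0, 2.2)]
        grid = build_surface_points(atoms, 0.5, 1.4)
        phi1 = mean_surface_potential(atoms, grid)
        doubled = [AtomRecord(a.name, a.xyz, 2 * a.charge, a.radius)
                   for a in atoms]
        assert mean_surface_potential(doubled, grid) \
            == pytest.approx(2 * phi1, rel=1e-12)

    def test_rotation_invariance(self, rng):
        atoms = [AtomRecord("X", rng.normal(size=3) * 3, -1.0, 1.9)
                 for _ in range(5)]
        grid = build_surface_points(atoms, 0.6, 1.4)
        phi1 = mean_surface_potential(atoms, grid)
        th = 1.1
        rot = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        atoms_r = [AtomRecord(a.name, rot @ a.xyz, a.charge, a.radius)
                   for a in atoms]
        grid_r = pm.SurfaceGrid(grid.points @ rot.T, grid.spacing, grid.probe)
        assert mean_surface_potential(atoms_r, grid_r) \
            == pytest.approx(phi1, rel=1e-9)

    def test_ln_normalization(self):
        assert normalized_surface_potential(0.0, 10) == 0.0
        phi = -3.7
        n_e = int(round(np.e))  # N=3: ln N ~ 1.0986, close to e
        assert normalized_surface_potential(phi, 20) \
            == pytest.approx(phi / np.log(20))
        with pytest.raises(MetricsError):
            normalized_surface_potential(phi, 1)

    def test_rod_series_flattened_by_ln_n(self):
        """Uniformly charged straight rods N = 10/20/40 (line-charge oracle):
        Phi_e grows ~affinely in ln N, so Phi_e/ln N varies much less than
        Phi_e itself across the series."""
        phis = {}
        for n in (10, 20, 40):
            atoms = [AtomRecord("P", np.array([0.0, 0, 5.0 * k]), -1.0, 2.0)
                     for k in range(n)]
            grid = build_surface_points(atoms, spacing=0.8, probe=1.4)
            phis[n] = mean_surface_potential(atoms, grid)
        raw = [phis[n] for n in (10, 20, 40)]
        norm = [phis[n] / np.log(n) for n in (10, 20, 40)]
        raw_spread = (max(raw) - min(raw)) / abs(np.mean(raw))
        norm_spread = (max(norm) - min(norm)) / abs(np.mean(norm))
        assert raw_spread > 0.30
        assert norm_spread < 0.15


class TestMetricOrdering:
    def test_ds_rod_higher_potential_than_ss_rod(self):
        """Double rods concentrate charge: |Phi_e_tilde| (ds) > (ss) at equal
        contour length (bead-rod construction)."""
        n = 10
        ss = [AtomRecord("P", np.array([0.0, 0, 6.0 * k]), -1.0, 3.5)
              for k in range(n)]
        ds = ([AtomRecord("P", np.array([0.0, 0, 3.4 * k]), -1.0, 3.5)
               for k in range(n)]
              + [AtomRecord("P", np.array([13.0, 0, 3.4 * k]), -1.0, 3.5)
                 for k in range(n)])
        g_ss = build_surface_points(ss, 0.8, 1.4)
        g_ds = build_surface_points(ds, 0.8, 1.4)
        phi_ss = mean_surface_potential(ss, g_ss) / np.log(n)
        phi_ds = mean_surface_potential(ds, g_ds) / np.log(n)
        assert abs(phi_ds) > abs(phi_ss)

    def test_flexible_ensemble_larger_rmsd_n_than_stiff(self, rng):
        n = 20
        base = np.zeros((n, 3))
        base[:, 0] = np.arange(n) * 5.0
        stiff = [base + 0.3 * rng.standard_normal((n, 3)) for _ in range(100)]
        floppy = []
        for _ in range(100):
            steps = rng.standard_normal((n - 1, 3))
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            floppy.append(np.vstack([np.zeros(3),
                                     np.cumsum(steps * 5.0, axis=0)]))
        r_stiff = rmsd_normalized(ConformationEnsemble(np.array(stiff)), n)[1]
        r_floppy = rmsd_normalized(ConformationEnsemble(np.array(floppy)), n)[1]
        assert r_floppy > r_stiff
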