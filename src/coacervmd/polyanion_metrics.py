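"""Single-molecule stability descriptors of polyanions.

Three descriptors rank the coacervation propensity of nucleic-acid
constructs:

* contour length L_c, summing 0.6 nm per single-stranded step and 0.34 nm
  per double-stranded (base-pair) step;
* normalized flexibility RMSD_n = RMSD / N: the ensemble root-mean-square
  deviation of bead positions from the (iteratively superposed) mean
  structure, divided by the monomer count N, removing the linear length
  dependence of the raw RMSD;
* log-normalized mean surface electrostatic potential
  Phi_e_tilde = Phi_e / ln N, where Phi_e is the Coulomb potential
  (relative dielectric constant 2 inside the polyanion) averaged over a
  shell of grid points just outside the probe-inflated molecular surface.
  The ln N normalization removes the length dependence arising from the
  long range of the Coulomb potential.

Atomistic inputs come from PQR files (coordinates, partial charges, radii);
bead-level constructs can be converted to pseudo-atom records for the same
machinery.  Conformational ensembles come from the package's own
single-chain CG sampler or from external extended-XYZ files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from coacervmd.constructs import Construct, count_monomers
from coacervmd.parameters import COULOMB_K

SS_STEP_NM = 0.6
DS_STEP_NM = 0.34


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contour length
# ---------------------------------------------------------------------------

def contour_length(c: Construct) -> float:
    """Contour length in nm: 0.6 per unpaired monomer, 0.34 per base pair."""
    if not c.is_nucleic():
        raise MetricsError("contour length is defined for NA/polyP constructs")
    n_pairs = len(c.pairing)
    n_ss = c.n_beads - 2 * n_pairs
    return SS_STEP_NM * n_ss + DS_STEP_NM * n_pairs


# ---------------------------------------------------------------------------
# normalized RMSD
# ---------------------------------------------------------------------------

@dataclass
class ConformationEnsemble:
    """Frames of bead coordinates for one molecule."""

    frames: np.ndarray  # (F, N, 3)
    source: str = "internal"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise MetricsError("ensemble needs >= 2 frames of equal bead count")


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation mapping centered p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def superpose_frames(frames: np.ndarray, n_iter: int = 10,
                     tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Rigid-body superpose all frames onto an iteratively refined mean.

    Returns (aligned frames, mean structure).
    """
    x = frames - frames.mean(axis=1, keepdims=True)
    ref = x[0]
    for _ in range(n_iter):
        aligned = np.empty_like(x)
        for f in range(len(x)):
            aligned[f] = x[f] @ _kabsch(x[f], ref).T
        new_ref = aligned.mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < tol:
            ref = new_ref
            x = aligned
            break
        ref = new_ref
        x = aligned
    return x, ref


def rmsd_normalized(ens: ConformationEnsemble, n_monomers: int,
                    superpose: bool = True) -> tuple[float, float]:
    """(RMSD, RMSD_n = RMSD/N) of an ensemble about its mean structure.

    Frames are rigid-body superposed onto the iteratively refined mean by
    default, so that only internal (conformational) fluctuations contribute;
    ``superpose=False`` exposes the raw deviation for sensitivity checks.
    """
    frames = ens.frames
    if superpose:
        frames, mean = superpose_frames(frames)
    else:
        mean = frames.mean(axis=0)
    dev = frames - mean
    rmsd = float(np.sqrt(np.mean(np.sum(dev * dev, axis=-1))))
    return rmsd, rmsd / n_monomers


# ---------------------------------------------------------------------------
# PQR input and pseudo-atoms
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    xyz: np.ndarray  # (3,) A
    charge: float  # e
    radius: float  # A


def read_pqr(path) -> list[AtomRecord]:
    """Parse a whitespace-delimited PQR file (ATOM/HETATM records).

    The last two numeric fields of each record are charge and radius; a
    malformed record raises with its line number.
    """
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                x, y, z, q, r = (float(v) for v in rec[-5:])
                name = rec[2]
            except (IndexError, ValueError) as exc:
                raise MetricsError(f"malformed PQR record at line {ln}") from exc
            if r <= 0:
                raise MetricsError(f"nonpositive radius at line {ln}")
            atoms.append(AtomRecord(name, np.array([x, y, z]), q, r))
    if not atoms:
        import warnings

        warnings.warn("no ATOM/HETATM records found", stacklevel=2)
    return atoms


def beads_as_atoms(c: Construct, coords: np.ndarray) -> list[AtomRecord]:
    """Bead-level pseudo-atom records (radius sigma/2) for surface metrics."""
    if coords.shape != (c.n_beads, 3):
        raise MetricsError("coordinate shape does not match construct")
    return [AtomRecord(t, np.asarray(xyz, dtype=float), float(q),
                       float(s) / 2.0)
            for t, xyz, q, s in zip(c.bead_types, coords, c.charges, c.sigmas)]


# ---------------------------------------------------------------------------
# surface grid and potential
# ---------------------------------------------------------------------------

@dataclass
class SurfaceGrid:
    points: np.ndarray  # (M, 3)
    spacing: float
    probe: float


def build_surface_points(atoms: Iterable[AtomRecord], spacing: float = 0.5,
                         probe: float = 1.4) -> SurfaceGrid:
    """Uniform-grid points forming a one-voxel shell on the molecular surface.

    A uniform grid fills the bounding box (padded by max radius + probe +
    spacing); a point p is retained when
    0 <= min_i(|p - x_i| - r_i - probe) <= spacing, i.e. it lies just
    outside the probe-inflated surface and within one grid spacing of it.
    """
    atoms = list(atoms)
    if not atoms:
        raise MetricsError("no atoms")
    if spacing <= 0:
        raise MetricsError("spacing must be positive")
    xyz = np.array([a.xyz for a in atoms])
    radii = np.array([a.radius for a in atoms])
    pad = radii.max() + probe + spacing
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # signed distance to the probe-inflated surface, chunked to bound memory
    keep = np.zeros(len(grid), dtype=bool)
    chunk = 200_000
    for s in range(0, len(grid), chunk):
        g = grid[s:s + chunk]
        d = np.linalg.norm(g[:, None, :] - xyz[None, :, :], axis=-1)
        sd = (d - radii[None, :] - probe).min(axis=1)
        keep[s:s + chunk] = (sd >= 0.0) & (sd <= spacing)
    return SurfaceGrid(points=grid[keep], spacing=spacing, probe=probe)


def mean_surface_potential(atoms: Iterable[AtomRecord], grid: SurfaceGrid,
                           eps: float = 2.0) -> float:
    """Mean Coulomb potential over the surface grid, kcal/(mol e).

    phi_e(p) = sum_i q_i / (4 pi eps0 eps |p - x_i|), with a homogeneous
    relative dielectric constant (default 2, the polyanion interior value);
    Phi_e is the plain average over the retained grid points.
    """
    atoms = list(atoms)
    if len(grid.points) == 0:
        raise MetricsError("empty surface grid")
    if eps <= 0:
        raise MetricsError("dielectric constant must be positive")
    xyz = np.array([a.xyz for a in atoms])
    q = np.array([a.charge for a in atoms])
    radii = np.array([a.radius for a in atoms])
    phi = np.zeros(len(grid.points))
    chunk = 100_000
    for s in range(0, len(grid.points), chunk):
        g = grid.points[s:s + chunk]
        d = np.linalg.norm(g[:, None, :] - xyz[None, :, :], axis=-1)
        if np.any(d < radii[None, :] - 1e-9):
            raise MetricsError("surface grid point inside an atom")
        phi[s:s + chunk] = (COULOMB_K / eps) * np.sum(q[None, :] / d, axis=1)
    return float(phi.mean())


def normalized_surface_potential(phi_e: float, n_monomers: int) -> float:
    """Phi_e_tilde = Phi_e / ln N (undefined below N = 2)."""
    if n_monomers < 2:
        raise MetricsError("ln-normalization needs N >= 2")
    return phi_e / float(np.log(n_monomers))


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

@dataclass
class MetricResult:
    name: str
    l_c_nm: float
    n_monomers: int
    rmsd: float
    rmsd_n: float
    phi_e: float
    phi_e_tilde: float

    @property
    def abs_phi_e_tilde(self) -> float:
        return abs(self.phi_e_tilde)


def metric_result(c: Construct, ens: ConformationEnsemble,
                  eps: float = 2.0, spacing: float = 1.0,
                  probe: float = 1.4) -> MetricResult:
    """Full descriptor triple for one construct from its ensemble.

    The surface potential uses the ensemble mean structure as the reference
    conformation, with beads as pseudo-atoms.
    """
    n = count_monomers(c)
    rmsd, rmsd_n = rmsd_normalized(ens, n)
    _, mean = superpose_frames(ens.frames)
    atoms = beads_as_atoms(c, mean)
    grid = build_surface_points(atoms, spacing=spacing, probe=probe)
    phi = mean_surface_potential(atoms, grid, eps=eps)
    return MetricResult(name=c.name, l_c_nm=contour_length(c), n_monomers=n,
                        rmsd=rmsd, rmsd_n=rmsd_n, phi_e=phi,
                        phi_e_tilde=normalized_surface_potential(phi, n))


def metrics_table(results: Iterable[MetricResult]) -> pd.DataFrame:
    rows = [{"name": r.name, "L_c_nm": r.l_c_nm, "N": r.n_monomers,
             "RMSD_A": r.rmsd, "RMSD_n_A": r.rmsd_n,
             "Phi_e": r.phi_e, "Phi_e_tilde": r.phi_e_tilde,
             "abs_Phi_e_tilde": r.abs_phi_e_tilde} for r in results]
    return pd.DataFrame(rows)
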