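"""Langevin-dynamics engine: slab initialization, BAOAB integration, trajectory I/O.

The engine works in periodic orthorhombic boxes with a Verlet pair list
(rebuilt on a displacement criterion) and a BAOAB-discretized Langevin
thermostat.  Dynamics are reproducible from a single integer seed: thermostat
noise is drawn from per-chunk seeded streams, so results do not depend on
how the run is partitioned into chunks of different stride.

Note that, as in all implicit-solvent CG models of this family, the diffusion
time scale is accelerated relative to experiment; dynamic observables should
be reported relative to a reference species (see
:mod:`coacervmd.condensate_analysis`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from coacervmd import forcefield, parameters
from coacervmd._kernels import compute_forces, integrate_chunk
from coacervmd.constructs import Construct
from coacervmd.forcefield import (
    ElectrostaticsParams,
    ForceFieldConfig,
    Topology,
    build_topology,
    neighbor_pairs,
)
from coacervmd.parameters import AVOGADRO, COULOMB_K, KB, MVSQ2E

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass
class SystemState:
    """Bead coordinates/velocities plus topology, box and thermodynamic state."""

    coords: np.ndarray  # (N, 3) A, unwrapped
    velocities: np.ndarray  # (N, 3) A/fs
    box: np.ndarray  # (3,) A
    T: float  # K
    ionic_strength: float  # mol/L
    topology: Topology

    def wrapped(self) -> np.ndarray:
        w = np.mod(self.coords, self.box)
        return np.where(w >= self.box, 0.0, w)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def kinetic_temperature(self) -> float:
        ke = 0.5 * MVSQ2E * np.sum(self.topology.masses[:, None]
                                   * self.velocities**2)
        return float(2.0 * ke / (3.0 * self.n_beads * KB))

    def concentrations(self) -> dict[str, float]:
        """Global molar concentration per species from box-volume bookkeeping."""
        vol_l = float(np.prod(self.box)) * 1e-27  # A^3 -> L
        out: dict[str, float] = {}
        for name in np.unique(self.topology.species):
            mols = np.unique(self.topology.mol_id[self.topology.species == name])
            out[str(name)] = len(mols) / AVOGADRO / vol_l
        return out


@dataclass
class SimulationConfig:
    """Integration parameters.

    ``dt`` defaults to 10 fs, stable for these masses and stiffnesses; with
    much stiffer user-supplied springs reduce it accordingly.  ``friction``
    is the Langevin collision rate in 1/fs.
    """

    steps: int = 10000
    dt: float = 10.0
    friction: float = 1e-3
    seed: int = 0
    stride: int = 500
    skin: float = 4.0
    rebuild: int = 20
    energy_abort: float = 1e8
    geometry: str = "slab"


@dataclass
class Trajectory:
    """Time-ordered unwrapped bead coordinates with labels and state metadata."""

    frames: np.ndarray  # (F, N, 3)
    times: np.ndarray  # (F,) fs
    box: np.ndarray
    T: float
    ionic_strength: float
    species: np.ndarray
    mol_id: np.ndarray
    bead_types: np.ndarray
    charges: np.ndarray
    aborted: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1] if self.frames.ndim == 3 else 0

    def molecule_coms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame molecular centers of mass (F, M, 3), molecule species
        (M,), and molecule ids (M,) (unwrapped coordinates)."""
        mols, first = np.unique(self.mol_id, return_index=True)
        masses = np.ones(self.n_beads)
        coms = np.empty((self.n_frames, len(mols), 3))
        for k, m in enumerate(mols):
            sel = self.mol_id == m
            w = masses[sel] / masses[sel].sum()
            coms[:, k, :] = np.einsum("fnd,n->fd", self.frames[:, sel, :], w)
        return coms, self.species[first], mols


# ---------------------------------------------------------------------------
# slab initialization
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _walk(n: int, b: float, rng: np.random.Generator,
          start: np.ndarray | None = None,
          direction: np.ndarray | None = None) -> np.ndarray:
    """Persistent random walk with fixed step length (initial coil guess)."""
    pos = np.zeros((n, 3))
    if start is not None:
        pos[0] = start
    d = direction if direction is not None else rng.standard_normal(3)
    d = d / np.linalg.norm(d)
    for k in range(1, n):
        d = d + 0.8 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pos[k] = pos[k - 1] + b * d
    return pos


def template_coords(c: Construct, ff: ForceFieldConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Idealized starting conformation for one molecule, centered at origin.

    Duplex tracts are built as straight parallel rods at the hybridization
    rest separation; unpaired tracts as persistent random walks; hairpin
    loops as arcs.  Residual strain relaxes within the first integration
    steps.
    """
    kind = c.kind
    if kind in ("ss", "pna_ss", "polyp", "peptide"):
        b = {"polyp": ff.r0_polyp, "peptide": ff.r0_peptide}.get(kind, ff.r0_ss)
        pos = _walk(c.n_beads, b, rng)
    elif kind in ("ds", "pna_dna_hybrid"):
        n = len(c.strands[0])
        pos = np.zeros((2 * n, 3))
        z = np.arange(n) * ff.r0_ds
        pos[:n, 2] = z
        pos[n:, 0] = ff.r0_hb
        pos[n:, 2] = z[::-1]  # strand-2 bead j pairs strand-1 bead n-1-j
    elif kind == "hairpin":
        n = c.n_beads
        sl = len(c.pairing)
        pos = np.zeros((n, 3))
        z = np.arange(sl) * ff.r0_ds
        pos[:sl, 2] = z
        pos[n - sl:, 0] = ff.r0_hb
        pos[n - sl:, 2] = z[::-1]
        n_loop = n - 2 * sl
        radius = max((n_loop + 1) * ff.r0_ss / np.pi, ff.r0_hb / 2.0)
        ang = np.pi * (1.0 - (np.arange(1, n_loop + 1) / (n_loop + 1)))
        cx = ff.r0_hb / 2.0
        z0 = (sl - 1) * ff.r0_ds
        pos[sl:n - sl, 0] = cx + radius * np.cos(ang)
        pos[sl:n - sl, 2] = z0 + radius * np.sin(ang)
    elif kind == "half_duplex":
        n1 = len(c.strands[0])
        n2 = len(c.strands[1])
        pos = np.zeros((n1 + n2, 3))
        z = np.arange(n2) * ff.r0_ds
        pos[:n2, 2] = z
        pos[n1:, 0] = ff.r0_hb
        pos[n1:, 2] = z[::-1]
        tail = _walk(n1 - n2 + 1, ff.r0_ss, rng,
                     start=pos[n2 - 1], direction=np.array([0.0, 0.0, 1.0]))
        pos[n2 - 1:n1] = tail
    else:
        raise SimulationError(f"no template rule for kind {c.kind!r}")
    return pos - pos.mean(axis=0)


def _is_rodlike(c: Construct) -> bool:
    return (c.n_beads > 0 and c.paired_mask().mean() >= 0.6
            and c.kbend_ds >= 10.0)


def init_slab(recipe: list[tuple[Construct, int]], T: float,
              ionic_strength: float, seed: int,
              concentrations: dict[str, float] | None = None,
              ff: ForceFieldConfig | None = None,
              aspect: float = 4.0, dense_bead_density: float = 0.005,
              min_xy: float | None = None, orientation: str = "auto",
              max_tries: int = 500) -> SystemState:
    """Place all molecules of the recipe in a central dense slab.

    The box volume is fixed by the target molar ``concentrations`` (per
    construct name); the box is elongated along z (``aspect`` = Lz/Lx).  The
    slab spans the full x-y cross-section with thickness set by
    ``dense_bead_density`` (beads/A^3).  Insertion is random, seeded and
    non-overlapping.  With ``orientation='auto'``, rod-like constructs
    (mostly-paired, stiff) are inserted co-aligned in the slab plane -- the
    standard pre-ordered start for direct-coexistence runs of mesogenic
    species -- while coils are inserted with random orientations; 'random'
    and 'aligned' force either behaviour.
    """
    ff = ff or ForceFieldConfig()
    rng = np.random.default_rng(seed)
    n_beads = sum(c.n_beads * k for c, k in recipe)
    if n_beads == 0:
        raise SimulationError("empty recipe")

    if concentrations:
        vols = []
        for c, count in recipe:
            if c.name in concentrations:
                vols.append(count / (concentrations[c.name] * AVOGADRO * 1e-27))
        if not vols:
            raise SimulationError("concentrations do not match recipe names")
        volume = float(np.mean(vols))
        for v in vols:
            if abs(v - volume) / volume > 0.02:
                warnings.warn("recipe counts deviate >2% from target "
                              "concentrations", stacklevel=2)
    else:
        volume = n_beads / 5e-4

    lx = (volume / aspect) ** (1.0 / 3.0)
    if min_xy is not None and lx < min_xy:
        lx = min_xy
    # the dense region must be a pancake spanning the cross-section (thinner
    # than it is wide), else it breaks up into droplets and the axial
    # profile no longer reads out coexistence
    lx_min_slab = (n_beads / (0.8 * dense_bead_density)) ** (1.0 / 3.0)
    lx = max(lx, lx_min_slab)
    lz = volume / lx**2
    box = np.array([lx, lx, lz])
    if lz / lx < 3.0:
        warnings.warn("slab box aspect below 3:1", stacklevel=2)

    h = min(n_beads / (dense_bead_density * lx * lx), 0.6 * lz)
    z_lo, z_hi = 0.5 * lz - 0.5 * h, 0.5 * lz + 0.5 * h

    total_charge = sum(c.total_charge * k for c, k in recipe)
    if abs(total_charge) > 0.5:
        log.info("recipe is not electro-neutral: net charge %+.0f e", total_charge)

    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    coords_all = np.empty((0, 3))
    for c, count in recipe:
        template = template_coords(c, ff, rng)
        flexible = c.kind in ("ss", "pna_ss", "polyp", "peptide",
                              "half_duplex")
        aligned = (orientation == "aligned"
                   or (orientation == "auto" and _is_rodlike(c)))
        for _ in range(count):
            ok = False
            for _try in range(max_tries):
                if flexible and _try:
                    template = template_coords(c, ff, rng)
                if _try and _try % 100 == 0:
                    # relax the slab packing rather than giving up
                    h = min(1.2 * h, 0.7 * lz)
                    z_lo, z_hi = 0.5 * lz - 0.5 * h, 0.5 * lz + 0.5 * h
                if aligned:
                    # rod axis (template z) along the box x direction,
                    # random azimuth about it
                    phi = rng.uniform(0, 2 * np.pi)
                    about_x = np.array([[1, 0, 0],
                                        [0, np.cos(phi), -np.sin(phi)],
                                        [0, np.sin(phi), np.cos(phi)]])
                    swap = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])
                    rot = about_x @ swap
                else:
                    rot = _random_rotation(rng)
                xyz = template @ rot.T
                center = np.array([rng.uniform(0, lx), rng.uniform(0, lx),
                                   rng.uniform(z_lo, z_hi)])
                xyz = xyz + center
                if tree is not None:
                    w = np.mod(xyz, box)
                    w = np.where(w >= box, 0.0, w)
                    dists, _ = tree.query(w, k=1)
                    if np.min(dists) < 3.0:
                        continue
                placed.append(xyz)
                coords_all = np.concatenate([coords_all, xyz])
                w = np.mod(coords_all, box)
                w = np.where(w >= box, 0.0, w)
                tree = cKDTree(w, boxsize=box)
                ok = True
                break
            if not ok:
                raise SimulationError(
                    f"could not insert {c.name} after {max_tries} tries: slab "
                    f"too dense ({n_beads} beads, slab {h:.0f} A of {lz:.0f} A)")

    topo = build_topology(recipe, ff)
    coords = np.concatenate(placed)
    sigma_v = np.sqrt(KB * T / (topo.masses * MVSQ2E))
    vel = rng.standard_normal((n_beads, 3)) * sigma_v[:, None]
    return SystemState(coords=coords, velocities=vel, box=box, T=T,
                       ionic_strength=ionic_strength, topology=topo)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _chunk_seed(base: int, k: int) -> int:
    return int((base * 2654435761 + k * 40503 + 12345) % 2147483647)


def minimize(state: SystemState, ff: ForceFieldConfig | None = None,
             steps: int = 200, max_disp: float = 0.3) -> None:
    """Displacement-capped steepest descent to relax insertion strain (in place)."""
    ff = ff or ForceFieldConfig()
    es = ElectrostaticsParams.from_state(state.T, state.ionic_strength,
                                         ff.cutoff_elec)
    topo = state.topology
    x = state.coords.copy()
    pairs = None
    for it in range(steps):
        if it % 10 == 0:
            pairs = neighbor_pairs(np.mod(x, state.box), state.box,
                                   ff.max_cutoff + 2.0, topo.exclusion_keys,
                                   topo.n_beads)
        _, f = forcefield.nonbonded_energy_forces(x, state.box, topo, es, ff,
                                                  pairs)
        fb = forcefield.bonded_energy_forces(x, topo.bonded, state.box)[1]
        f += fb
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        step = f * (max_disp / np.maximum(norm, max_disp / 0.02))
        x += step
    state.coords = x


def run_langevin(state: SystemState, ff: ForceFieldConfig | None = None,
                 cfg: SimulationConfig | None = None) -> Trajectory:
    """Integrate BAOAB Langevin dynamics; returns frames at the output stride.

    The pair list is rebuilt whenever any bead has moved more than half the
    skin since the last build.  On an energy blow-up (non-finite or above
    ``cfg.energy_abort``) the run aborts and the trajectory collected so far
    is returned with ``aborted=True``.
    """
    ff = ff or ForceFieldConfig()
    cfg = cfg or SimulationConfig()
    topo = state.topology
    es = ElectrostaticsParams.from_state(state.T, state.ionic_strength,
                                         ff.cutoff_elec)
    box = np.asarray(state.box, dtype=float)
    if np.any(box <= 2.0 * ff.max_cutoff):
        raise SimulationError("box edge must exceed twice the largest cutoff")

    pos = state.coords.astype(np.float64).copy()
    vel = state.velocities.astype(np.float64).copy()
    frc = np.zeros_like(pos)
    inv_meff = 1.0 / (topo.masses * MVSQ2E)
    bfac = float(np.exp(-cfg.friction * cfg.dt))
    sig_v = np.sqrt(KB * state.T * (1.0 - bfac**2) * inv_meff)
    if cfg.friction == 0.0:
        sig_v = np.zeros_like(sig_v)
    coulomb_pref = COULOMB_K / es.eps_r
    bt = topo.bonded

    frames = [pos.copy()]
    times = [0.0]
    last_build = None
    pairs = np.empty((0, 2), dtype=np.int64)
    rmax = ff.max_cutoff + cfg.skin
    aborted = False
    step = 0
    chunk_idx = 0

    def rebuild():
        nonlocal pairs, last_build
        pairs = neighbor_pairs(pos, box, rmax, topo.exclusion_keys,
                               topo.n_beads).astype(np.int64)
        if pairs.ndim != 2:
            pairs = pairs.reshape(-1, 2).astype(np.int64)
        last_build = pos.copy()

    rebuild()
    e0 = compute_forces(pos, frc, box, pairs, topo.charges, topo.lambdas,
                        topo.sigmas, ff.eps_lj, ff.cutoff_sr, es.cutoff,
                        coulomb_pref, es.lambda_d, bt.bond_idx, bt.bond_k,
                        bt.bond_r0, bt.angle_idx, bt.angle_k, bt.angle_theta0,
                        bt.hb_idx, bt.hb_k, bt.hb_r0)
    if not np.isfinite(e0):
        raise SimulationError("overlapping beads in the initial configuration")

    while step < cfg.steps:
        n_sub = min(cfg.rebuild, cfg.steps - step,
                    cfg.stride - step % cfg.stride or cfg.stride)
        disp = np.abs(pos - last_build).max() if last_build is not None else 0.0
        if disp > 0.5 * cfg.skin:
            rebuild()
        energy = integrate_chunk(
            pos, vel, frc, n_sub, cfg.dt, bfac, sig_v, inv_meff, box, pairs,
            topo.charges, topo.lambdas, topo.sigmas, ff.eps_lj, ff.cutoff_sr,
            es.cutoff, coulomb_pref, es.lambda_d, bt.bond_idx, bt.bond_k,
            bt.bond_r0, bt.angle_idx, bt.angle_k, bt.angle_theta0,
            bt.hb_idx, bt.hb_k, bt.hb_r0,
            _chunk_seed(cfg.seed, chunk_idx))
        chunk_idx += 1
        step += n_sub
        if not np.isfinite(energy) or abs(energy) > cfg.energy_abort:
            warnings.warn(f"energy blow-up at step {step}; aborting run",
                          stacklevel=2)
            aborted = True
            break
        if step % cfg.stride == 0 or step == cfg.steps:
            frames.append(pos.copy())
            times.append(step * cfg.dt)

    state.coords = pos
    state.velocities = vel
    return Trajectory(frames=np.array(frames), times=np.array(times), box=box,
                      T=state.T, ionic_strength=state.ionic_strength,
                      species=topo.species.copy(), mol_id=topo.mol_id.copy(),
                      bead_types=topo.bead_types.copy(),
                      charges=topo.charges.copy(), aborted=aborted)


# ---------------------------------------------------------------------------
# trajectory I/O (extended XYZ)
# ---------------------------------------------------------------------------

_PROPS = "species:S:1:pos:R:3:mol:I:1:charge:R:1:construct:S:1"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write an extended-XYZ trajectory (plain text, one block per frame).

    Per-bead columns: bead type, position, molecule id, charge, construct
    name; box, time, temperature and ionic strength live in the comment line.
    Files stay readable as plain XYZ by generic tools.
    """
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            lx, ly, lz = traj.box
            fh.write(
                f'Lattice="{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 '
                f'{lz:.6f}" Properties={_PROPS} time={traj.times[f]:.1f} '
                f"temperature={traj.T:.2f} ionic_strength={traj.ionic_strength:.6g}"
                f" aborted={int(traj.aborted)}\n")
            for a in range(traj.n_beads):
                x, y, z = traj.frames[f, a]
                fh.write(f"{traj.bead_types[a]} {x:.4f} {y:.4f} {z:.4f} "
                         f"{traj.mol_id[a]} {traj.charges[a]:.4f} "
                         f"{traj.species[a]}\n")


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    Malformed or truncated frames raise :class:`SimulationError` naming the
    offending frame.
    """
    frames, times = [], []
    box = np.zeros(3)
    T = 300.0
    ionic = 0.1
    aborted = False
    bead_types: list[str] = []
    species: list[str] = []
    mol_id: list[int] = []
    charges: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    frame_no = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise SimulationError(
                f"frame {frame_no}: bad atom-count line {k + 1}") from exc
        if k + 2 + n > len(lines):
            raise SimulationError(
                f"frame {frame_no}: truncated (expected {n} atom lines)")
        header = lines[k + 1]
        for key in ("time=", "temperature=", "ionic_strength=", "aborted="):
            if key in header:
                val = header.split(key, 1)[1].split()[0]
                if key == "time=":
                    times.append(float(val))
                elif key == "temperature=":
                    T = float(val)
                elif key == "ionic_strength=":
                    ionic = float(val)
                else:
                    aborted = bool(int(val))
        if 'Lattice="' in header:
            lat = [float(v) for v in header.split('Lattice="', 1)[1]
                   .split('"', 1)[0].split()]
            box = np.array([lat[0], lat[4], lat[8]])
        xyz = np.empty((n, 3))
        first = frame_no == 0
        for a in range(n):
            ln = k + 2 + a
            tok = lines[ln].split()
            try:
                xyz[a] = [float(tok[1]), float(tok[2]), float(tok[3])]
                if first:
                    bead_types.append(tok[0])
                    mol_id.append(int(tok[4]))
                    charges.append(float(tok[5]))
                    species.append(tok[6] if len(tok) > 6 else tok[0])
            except (IndexError, ValueError) as exc:
                raise SimulationError(
                    f"frame {frame_no}: malformed atom line {ln + 1}") from exc
        frames.append(xyz)
        if len(times) < len(frames):
            times.append(float(len(frames) - 1))
        k += 2 + n
        frame_no += 1
    return Trajectory(
        frames=np.array(frames) if frames else np.empty((0, 0, 3)),
        times=np.array(times), box=box, T=T, ionic_strength=ionic,
        species=np.array(species), mol_id=np.array(mol_id, dtype=np.int64),
        bead_types=np.array(bead_types), charges=np.array(charges),
        aborted=aborted)
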