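"""Interaction model: energies and analytic forces of the bead-spring system.

One bead per residue in implicit solvent.  Nonbonded terms:

* screened electrostatics between charged beads, Debye-Hueckel form with a
  temperature-dependent water permittivity;
* a short-range Ashbaugh-Hatch pair potential in which the attractive
  Lennard-Jones branch is scaled by the arithmetic-mean hydropathy of the
  two beads (lambda = 0 gives a purely repulsive WCA core, lambda = 1 plain
  Lennard-Jones).

Bonded terms (full-prefactor harmonic convention, U = k x^2):

* stretching between consecutive beads of a strand;
* bending between triplets of consecutive beads, applied only when the
  triplet lies entirely in one stiffness class (all-paired duplex tract or
  all-unpaired tract);
* hybridization springs between hydrogen-bonded partner beads, mirroring the
  construct's pairing map.

1-2 and 1-3 bonded neighbours and hybridized partners are excluded from the
nonbonded sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from coacervmd import parameters
from coacervmd.constructs import Construct
from coacervmd.parameters import AVOGADRO, COULOMB_K, KB


class ForceFieldError(ValueError):
    pass


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def water_permittivity(T: float) -> float:
    """Relative permittivity of water from the standard empirical fit.

    eps_r(T) = 5321/T + 233.76 - 0.9297 T + 1.417e-3 T^2 - 8.292e-7 T^3,
    with T in kelvin; about 78.4 at 298.15 K, monotonically decreasing over
    the liquid range.
    """
    if not 250.0 < T < 400.0:
        raise ForceFieldError(f"temperature {T} K outside the fit's validity range")
    return 5321.0 / T + 233.76 - 0.9297 * T + 1.417e-3 * T**2 - 8.292e-7 * T**3


def debye_length(T: float, ionic_strength: float) -> float:
    """Debye screening length in angstrom for a 1:1 salt.

    lambda_D = sqrt(eps0 eps_r kB T / (2 NA e^2 * 1000 * IS)); with the
    Coulomb constant expressed in kcal A/mol this reduces to
    sqrt(eps_r kB T / (8 pi K NA IS * 1e-27)).
    """
    if ionic_strength <= 0:
        raise ForceFieldError("ionic strength must be positive")
    eps_r = water_permittivity(T)
    # number density of ions (both signs): 2 * IS[mol/L] * NA / 1e27 per A^3
    rho = 2.0 * ionic_strength * AVOGADRO * 1e-27
    return float(np.sqrt(eps_r * KB * T / (4.0 * np.pi * COULOMB_K * rho)))


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Thermodynamic state + derived screening parameters."""

    T: float  # K
    ionic_strength: float  # mol/L
    eps_r: float
    lambda_d: float  # A
    cutoff: float = parameters.CUTOFF_ELEC

    @classmethod
    def from_state(cls, T: float, ionic_strength: float,
                   cutoff: float = parameters.CUTOFF_ELEC) -> "ElectrostaticsParams":
        return cls(T, ionic_strength, water_permittivity(T),
                   debye_length(T, ionic_strength), cutoff)


def pair_energy_dh(r, qi, qj, es: ElectrostaticsParams):
    """Debye-Hueckel pair energy in kcal/mol; zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ForceFieldError("nonpositive pair distance")
    u = COULOMB_K * qi * qj / (es.eps_r * r) * np.exp(-r / es.lambda_d)
    return np.where(r <= es.cutoff, u, 0.0)[()]


def pair_energy_sr(r, sigma: float, eps_lj: float, lam: float,
                   cutoff: float = parameters.CUTOFF_SR):
    """Ashbaugh-Hatch short-range pair energy in kcal/mol.

    For r <= 2^(1/6) sigma: U_LJ(r) + (1 - lambda) eps_lj; beyond the
    minimum: lambda U_LJ(r); zero past the cutoff.  Continuous at the split.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ForceFieldError("nonpositive pair distance")
    if not 0.0 <= lam <= 1.0:
        raise ForceFieldError("hydropathy must lie in [0, 1]")
    sr6 = (sigma / r) ** 6
    ulj = 4.0 * eps_lj * (sr6 * sr6 - sr6)
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    u = np.where(r <= rmin, ulj + (1.0 - lam) * eps_lj, lam * ulj)
    return np.where(r <= cutoff, u, 0.0)[()]


# ---------------------------------------------------------------------------
# configuration and topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceFieldConfig:
    """All force-field constants (shipped defaults, user-overridable)."""

    eps_lj: float = parameters.EPS_LJ
    cutoff_sr: float = parameters.CUTOFF_SR
    cutoff_elec: float = parameters.CUTOFF_ELEC
    k_bond: float = parameters.K_BOND
    k_hb: float = parameters.K_HB
    r0_hb: float = parameters.R0_HB
    theta0: float = parameters.THETA0
    r0_peptide: float = parameters.R0_PEPTIDE
    r0_ss: float = parameters.R0_SS
    r0_ds: float = parameters.R0_DS
    r0_polyp: float = parameters.R0_POLYP

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoff_sr, self.cutoff_elec)

    def echo(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in self.__dict__.items())


@dataclass
class BondedTerms:
    """Bond/angle/hybridization term arrays over global bead indices."""

    bond_idx: np.ndarray  # (B, 2) int
    bond_k: np.ndarray  # (B,)
    bond_r0: np.ndarray  # (B,)
    angle_idx: np.ndarray  # (A, 3) int
    angle_k: np.ndarray  # (A,)
    angle_theta0: np.ndarray  # (A,)
    hb_idx: np.ndarray  # (H, 2) int
    hb_k: np.ndarray  # (H,)
    hb_r0: np.ndarray  # (H,)


@dataclass
class Topology:
    """Per-bead parameters, bonded terms and nonbonded exclusions for a system."""

    n_beads: int
    charges: np.ndarray
    lambdas: np.ndarray
    sigmas: np.ndarray
    masses: np.ndarray
    mol_id: np.ndarray  # molecule index per bead
    species: np.ndarray  # construct name per bead (str array)
    bead_types: np.ndarray  # residue bead-type code per bead
    bonded: BondedTerms
    exclusion_keys: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def pair_key(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        lo = np.minimum(i, j).astype(np.int64)
        hi = np.maximum(i, j).astype(np.int64)
        return lo * self.n_beads + hi


def _construct_bonded(c: Construct, ff: ForceFieldConfig, offset: int
                      ) -> tuple[list, list, list]:
    """Bond/angle/hb term lists for one molecule placed at a bead offset."""
    paired = c.paired_mask()
    alpha: list[str] = []
    for s in c.strands:
        alpha += [s.alphabet] * len(s)

    def bond_r0(a: int, b: int) -> float:
        if alpha[a] == "peptide":
            return ff.r0_peptide
        if alpha[a] == "polyp":
            return ff.r0_polyp
        return ff.r0_ds if paired[a] and paired[b] else ff.r0_ss

    bonds, angles, hbs = [], [], []
    start = 0
    for s in c.strands:
        n = len(s)
        for a in range(start, start + n - 1):
            bonds.append((a + offset, a + 1 + offset, ff.k_bond, bond_r0(a, a + 1)))
        for a in range(start, start + n - 2):
            trip = (a, a + 1, a + 2)
            if all(paired[t] for t in trip):
                k = c.kbend_ds
            elif not any(paired[t] for t in trip):
                k = c.kbend_ss
            else:
                k = 0.0  # mixed stiffness class: no bending term
            if k > 0.0:
                angles.append((a + offset, a + 1 + offset, a + 2 + offset,
                               k, ff.theta0))
        start += n
    for i, j in c.global_pairs():
        hbs.append((i + offset, j + offset, ff.k_hb, ff.r0_hb))
    return bonds, angles, hbs


def build_topology(recipe: list[tuple[Construct, int]],
                   ff: ForceFieldConfig | None = None) -> Topology:
    """Assemble system topology from (construct, copy count) pairs.

    Beads are laid out construct by construct, copy by copy; molecule ids
    are sequential over all copies.
    """
    ff = ff or ForceFieldConfig()
    charges, lambdas, sigmas, masses = [], [], [], []
    mol_id, species, bead_types = [], [], []
    bonds, angles, hbs = [], [], []
    offset = 0
    mol = 0
    for c, count in recipe:
        if count <= 0:
            raise ForceFieldError(f"nonpositive copy count for {c.name}")
        for _ in range(count):
            b, a, h = _construct_bonded(c, ff, offset)
            bonds += b
            angles += a
            hbs += h
            charges.append(c.charges)
            lambdas.append(c.lambdas)
            sigmas.append(c.sigmas)
            masses.append(c.masses)
            mol_id += [mol] * c.n_beads
            species += [c.name] * c.n_beads
            bead_types += list(c.bead_types)
            offset += c.n_beads
            mol += 1

    def arr(rows, ncol):
        if rows:
            return np.array(rows)
        return np.empty((0, ncol))

    barr = arr(bonds, 4)
    aarr = arr(angles, 5)
    harr = arr(hbs, 4)
    bonded = BondedTerms(
        bond_idx=barr[:, :2].astype(np.int64), bond_k=barr[:, 2], bond_r0=barr[:, 3],
        angle_idx=aarr[:, :3].astype(np.int64), angle_k=aarr[:, 3],
        angle_theta0=aarr[:, 4],
        hb_idx=harr[:, :2].astype(np.int64), hb_k=harr[:, 2], hb_r0=harr[:, 3])

    topo = Topology(
        n_beads=offset,
        charges=np.concatenate(charges), lambdas=np.concatenate(lambdas),
        sigmas=np.concatenate(sigmas), masses=np.concatenate(masses),
        mol_id=np.array(mol_id, dtype=np.int64), species=np.array(species),
        bead_types=np.array(bead_types), bonded=bonded)

    # exclusions: 1-2, 1-3 neighbours and hybridized partners
    excl: set[tuple[int, int]] = set()
    for i, j in bonded.bond_idx:
        excl.add((min(i, j), max(i, j)))
    neigh: dict[int, list[int]] = {}
    for i, j in bonded.bond_idx:
        neigh.setdefault(int(i), []).append(int(j))
        neigh.setdefault(int(j), []).append(int(i))
    for j, partners in neigh.items():
        for a in partners:
            for b in partners:
                if a < b:
                    excl.add((a, b))
    for i, j in bonded.hb_idx:
        excl.add((min(i, j), max(i, j)))
    if excl:
        pairs = np.array(sorted(excl), dtype=np.int64)
        topo.exclusion_keys = np.sort(topo.pair_key(pairs[:, 0], pairs[:, 1]))
    return topo


# ---------------------------------------------------------------------------
# energy and force evaluation
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def neighbor_pairs(coords: np.ndarray, box: np.ndarray | None, rmax: float,
                   exclusion_keys: np.ndarray | None = None,
                   n_beads: int | None = None) -> np.ndarray:
    """All bead pairs within rmax (minimum-image), exclusions removed."""
    if box is not None:
        wrapped = np.mod(coords, box)
        # floating-point mod can land exactly on the upper edge
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size and exclusion_keys is not None and exclusion_keys.size:
        n = n_beads if n_beads is not None else len(coords)
        keys = (np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64) * n
                + np.maximum(pairs[:, 0], pairs[:, 1]))
        pos = np.searchsorted(exclusion_keys, keys)
        pos = np.clip(pos, 0, len(exclusion_keys) - 1)
        pairs = pairs[exclusion_keys[pos] != keys]
    return pairs


def nonbonded_energy_forces(coords: np.ndarray, box: np.ndarray | None,
                            topo: Topology, es: ElectrostaticsParams,
                            ff: ForceFieldConfig,
                            pairs: np.ndarray | None = None
                            ) -> tuple[float, np.ndarray]:
    """Short-range + Debye-Hueckel energy and forces over a pair list."""
    if pairs is None:
        pairs = neighbor_pairs(coords, box, ff.max_cutoff,
                               topo.exclusion_keys, topo.n_beads)
    forces = np.zeros_like(coords)
    if pairs.size == 0:
        return 0.0, forces
    i, j = pairs[:, 0], pairs[:, 1]
    d = _min_image(coords[j] - coords[i], box)
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < 1e-12):
        raise ForceFieldError("overlapping beads (r < 1e-6 A)")
    r = np.sqrt(r2)
    inv_r = 1.0 / r
    # -- Ashbaugh-Hatch ------------------------------------------------------
    sig = 0.5 * (topo.sigmas[i] + topo.sigmas[j])
    lam = 0.5 * (topo.lambdas[i] + topo.lambdas[j])
    in_sr = r <= ff.cutoff_sr
    sr6 = np.where(in_sr, (sig * inv_r) ** 6, 0.0)
    ulj = 4.0 * ff.eps_lj * (sr6 * sr6 - sr6)
    dulj = 4.0 * ff.eps_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r
    below = r <= 2.0 ** (1.0 / 6.0) * sig
    u_sr = np.where(below, ulj + (1.0 - lam) * ff.eps_lj, lam * ulj)
    du_sr = np.where(below, dulj, lam * dulj)
    u_sr = np.where(in_sr, u_sr, 0.0)
    du_sr = np.where(in_sr, du_sr, 0.0)
    # -- Debye-Hueckel -------------------------------------------------------
    qq = topo.charges[i] * topo.charges[j]
    in_el = (r <= es.cutoff) & (qq != 0.0)
    pref = COULOMB_K / es.eps_r
    u_dh = np.where(in_el, pref * qq * inv_r * np.exp(-r / es.lambda_d), 0.0)
    du_dh = -u_dh * (inv_r + 1.0 / es.lambda_d)
    energy = float(np.sum(u_sr) + np.sum(u_dh))
    # force on j along +d, on i along -d
    fmag = -(du_sr + du_dh) * inv_r  # F = -dU/dr * unit vector
    fvec = fmag[:, None] * d
    np.add.at(forces, j, fvec)
    np.add.at(forces, i, -fvec)
    return energy, forces


def bonded_energy_forces(coords: np.ndarray, terms: BondedTerms,
                         box: np.ndarray | None = None
                         ) -> tuple[float, np.ndarray]:
    """Harmonic bonds, bends and hybridization springs (U = k x^2)."""
    forces = np.zeros_like(coords)
    energy = 0.0
    for idx, kk, r0 in ((terms.bond_idx, terms.bond_k, terms.bond_r0),
                        (terms.hb_idx, terms.hb_k, terms.hb_r0)):
        if len(idx) == 0:
            continue
        d = _min_image(coords[idx[:, 1]] - coords[idx[:, 0]], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-12):
            raise ForceFieldError("degenerate bond (coincident beads)")
        dr = r - r0
        energy += float(np.sum(kk * dr * dr))
        fvec = (-2.0 * kk * dr / r)[:, None] * d
        np.add.at(forces, idx[:, 1], fvec)
        np.add.at(forces, idx[:, 0], -fvec)
    if len(terms.angle_idx):
        ai, aj, ak = (terms.angle_idx[:, 0], terms.angle_idx[:, 1],
                      terms.angle_idx[:, 2])
        u = _min_image(coords[ai] - coords[aj], box)
        v = _min_image(coords[ak] - coords[aj], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        if np.any(nu < 1e-12) or np.any(nv < 1e-12):
            raise ForceFieldError("degenerate angle (coincident beads)")
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cth = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        th = np.arccos(cth)
        dth = th - terms.angle_theta0
        energy += float(np.sum(terms.angle_k * dth * dth))
        sth = np.sqrt(np.maximum(1.0 - cth * cth, 1e-12))
        # dU/dtheta / sin(theta); finite as theta -> theta0 = pi
        g = 2.0 * terms.angle_k * dth / sth
        fi = (g / nu)[:, None] * (vh - cth[:, None] * uh)
        fk = (g / nv)[:, None] * (uh - cth[:, None] * vh)
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))
    return energy, forces


def bonded_energy(coords: np.ndarray, terms: BondedTerms,
                  box: np.ndarray | None = None) -> float:
    return bonded_energy_forces(coords, terms, box)[0]


def total_energy_forces(coords: np.ndarray, box: np.ndarray | None,
                        topo: Topology, es: ElectrostaticsParams,
                        ff: ForceFieldConfig | None = None,
                        pairs: np.ndarray | None = None
                        ) -> tuple[float, np.ndarray]:
    """Full system energy (kcal/mol) and exact-negative-gradient forces.

    With a periodic box, every edge must exceed twice the largest cutoff so
    the minimum-image convention is valid.
    """
    ff = ff or ForceFieldConfig()
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box <= 2.0 * ff.max_cutoff) and len(coords) > 1:
            raise ForceFieldError("box edge must exceed twice the largest cutoff")
    e_nb, f_nb = nonbonded_energy_forces(coords, box, topo, es, ff, pairs)
    e_b, f_b = bonded_energy_forces(coords, topo.bonded, box)
    return e_nb + e_b, f_nb + f_b
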