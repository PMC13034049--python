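"""Condensate observables: rdf, nematic order, diffusion, exchanges, contacts.

All operations work on :class:`~coacervmd.simulator.Trajectory` objects.
Dynamic quantities are reported in simulation units (A^2/fs); because the
implicit-solvent model accelerates diffusion, ratios to a reference species
(the peptide in an isotropic condensate) are the meaningful quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from coacervmd.simulator import Trajectory

AA_BEAD_TYPES = frozenset("ARNDCQEGHILKMFPSTWYV")


class AnalysisError(ValueError):
    pass


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    w = np.mod(coords, box)
    return np.where(w >= box, 0.0, w)


def _frames_after(traj: Trajectory, discard: float) -> np.ndarray:
    n0 = int(np.floor(discard * traj.n_frames))
    return traj.frames[n0:]


def _species_mask(traj: Trajectory, species) -> np.ndarray:
    if isinstance(species, str):
        species = [species]
    mask = np.isin(traj.species, list(species))
    if not mask.any():
        raise AnalysisError(f"empty selection for species {species}")
    return mask


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, A
    g: np.ndarray
    pair: tuple[str, str]
    n_pairs_used: int = 0


def radial_distribution(traj: Trajectory, species_a: str, species_b: str,
                        rmax: float = 30.0, nbins: int = 60,
                        discard: float = 0.5,
                        exclude_same_molecule: bool = True) -> RDFResult:
    """Standard pair-histogram g(r), normalized by ideal-gas shell counts.

    Intramolecular pairs are excluded by default so the rdf reports the
    intermolecular structure of the fluid.
    """
    box = np.asarray(traj.box, dtype=float)
    if rmax >= 0.5 * box.min():
        raise AnalysisError("rmax must be below half the smallest box edge")
    ma = _species_mask(traj, species_a)
    mb = _species_mask(traj, species_b)
    same = species_a == species_b
    ia = np.where(ma)[0]
    ib = np.where(mb)[0]
    if (same and len(ia) < 2) or (not same and (len(ia) < 1 or len(ib) < 1)):
        raise AnalysisError("selection too small for pair statistics")
    edges = np.linspace(0.0, rmax, nbins + 1)
    hist = np.zeros(nbins)
    volume = float(np.prod(box))
    frames = _frames_after(traj, discard)
    npair_total = 0
    for f in frames:
        w = _wrap(f, box)
        ta = cKDTree(w[ia], boxsize=box)
        if same:
            pairs = ta.query_pairs(rmax, output_type="ndarray")
            gi, gj = ia[pairs[:, 0]], ia[pairs[:, 1]]
        else:
            tb = cKDTree(w[ib], boxsize=box)
            mat = ta.sparse_distance_matrix(tb, rmax, output_type="ndarray")
            gi, gj = ia[mat["i"]], ib[mat["j"]]
        if exclude_same_molecule:
            keep = traj.mol_id[gi] != traj.mol_id[gj]
            gi, gj = gi[keep], gj[keep]
        d = w[gj] - w[gi]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        r = r[r > 0]
        hist += np.histogram(r, bins=edges)[0]
        npair_total += len(r)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_ideal = len(ia) * (len(ia) - 1) / 2.0 / volume * shell
    else:
        n_ideal = len(ia) * len(ib) / volume * shell
    g = hist / (len(frames) * n_ideal)
    return RDFResult(r=0.5 * (edges[:-1] + edges[1:]), g=g,
                     pair=(species_a, species_b), n_pairs_used=npair_total)


# ---------------------------------------------------------------------------
# nematic order
# ---------------------------------------------------------------------------

@dataclass
class OrderResult:
    S: float  # largest Q-tensor eigenvalue, in [-0.5, 1]
    director: np.ndarray  # unit vector
    n_molecules: int
    n_degenerate: int = 0
    axis_mode: str = "gyration"


def molecule_axes(coords: np.ndarray, mol_of: np.ndarray,
                  mode: str = "gyration") -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule long axis (principal gyration eigenvector or end-to-end).

    Returns (axes (M,3) unit vectors, asphericity ratio (M,)); near-spherical
    molecules have ratio close to 1 and a poorly defined axis.
    """
    mols = np.unique(mol_of)
    axes = np.empty((len(mols), 3))
    ratio = np.empty(len(mols))
    for k, m in enumerate(mols):
        x = coords[mol_of == m]
        x = x - x.mean(axis=0)
        if mode == "end_to_end":
            v = x[-1] - x[0]
            n = np.linalg.norm(v)
            axes[k] = v / n if n > 0 else np.array([0.0, 0.0, 1.0])
            ratio[k] = np.inf
            continue
        gyr = x.T @ x / len(x)
        w, v = np.linalg.eigh(gyr)
        axes[k] = v[:, -1]
        ratio[k] = w[-1] / max(w[-2], 1e-12)
    return axes, ratio


def nematic_order(traj: Trajectory, species=None, discard: float = 0.5,
                  mode: str = "gyration",
                  mol_subset: np.ndarray | None = None) -> OrderResult:
    """Nematic order parameter S and director from the orientational Q tensor.

    Q = <(3 u u^T - I)/2> over molecules and frames, with u the molecular
    long axis; S is the largest eigenvalue (0 isotropic, 1 perfectly
    aligned; head-tail symmetric).
    """
    mask = (_species_mask(traj, species) if species is not None
            else np.ones(traj.n_beads, dtype=bool))
    mol_of = traj.mol_id[mask]
    if mol_subset is not None:
        keep = np.isin(mol_of, mol_subset)
        mask = mask.copy()
        mask[np.where(mask)[0][~keep]] = False
        mol_of = traj.mol_id[mask]
    if len(np.unique(mol_of)) < 2:
        raise AnalysisError("nematic order needs at least two molecules")
    frames = _frames_after(traj, discard)
    q_sum = np.zeros((3, 3))
    count = 0
    n_degen = 0
    for f in frames:
        axes, ratio = molecule_axes(f[mask], mol_of, mode)
        n_degen += int(np.sum(ratio < 1.5))
        q_sum += np.einsum("mi,mj->ij", axes, axes) * 3.0 / 2.0
        count += len(axes)
    q = q_sum / count - 0.5 * np.eye(3)
    w, v = np.linalg.eigh(q)
    return OrderResult(S=float(w[-1]), director=v[:, -1],
                       n_molecules=len(np.unique(mol_of)),
                       n_degenerate=n_degen, axis_mode=mode)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    D: float  # A^2/fs, simulation time units
    r_squared: float  # quality of the linear MSD fit
    D_par: float | None = None
    D_perp: float | None = None
    species: str = ""
    lag_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    msd: np.ndarray = field(default_factory=lambda: np.empty(0))


def _msd_multi_origin(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Mean squared displacement over molecules and all time origins.

    ``x``: (F, M, d) unwrapped positions.
    """
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        out[k] = np.mean(np.sum(d * d, axis=-1))
    return out


def diffusion_coefficients(traj: Trajectory, species: str,
                           director: np.ndarray | None = None,
                           fit_window: tuple[float, float] = (0.1, 0.5),
                           discard: float = 0.0,
                           mol_subset: np.ndarray | None = None
                           ) -> DiffusionResult:
    """Einstein-relation diffusion coefficient from the molecular-COM MSD.

    MSD is averaged over multiple time origins; D is the slope of a linear
    fit over the ``fit_window`` fraction of the lag range divided by 6 (by
    2 and 4 for the 1-D parallel / 2-D perpendicular decompositions when a
    director is given).  A low fit R^2 flags sub-linear (caged) motion.
    """
    if traj.n_frames < 100:
        raise AnalysisError("diffusion analysis needs >= 100 frames")
    coms, mol_species, mols = traj.molecule_coms()
    sel = mol_species == species
    if mol_subset is not None:
        sel &= np.isin(mols, mol_subset)
    if not sel.any():
        raise AnalysisError(f"no molecules of species {species!r}")
    n0 = int(np.floor(discard * traj.n_frames))
    x = coms[n0:, sel, :]
    dt_frame = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    nlag = len(x) - 1
    lags = np.unique(np.round(np.linspace(1, nlag, min(60, nlag))).astype(int))
    msd = _msd_multi_origin(x, lags)
    lo = max(int(fit_window[0] * nlag), 1)
    hi = max(int(fit_window[1] * nlag), lo + 2)
    fit_mask = (lags >= lo) & (lags <= hi)
    if fit_mask.sum() < 3:
        fit_mask = slice(None)
    t = lags[fit_mask] * dt_frame
    y = msd[fit_mask]
    slope, icpt = np.polyfit(t, y, 1)
    pred = slope * t + icpt
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    res = DiffusionResult(D=max(float(slope) / 6.0, 0.0), r_squared=float(r2),
                          species=species, lag_times=lags * dt_frame, msd=msd)
    if director is not None:
        u = np.asarray(director, dtype=float)
        u = u / np.linalg.norm(u)
        xpar = np.einsum("fmd,d->fm", x, u)[..., None]
        xperp = x - xpar * u
        mpar = _msd_multi_origin(xpar, lags)[fit_mask]
        mperp = _msd_multi_origin(xperp, lags)[fit_mask]
        res.D_par = max(float(np.polyfit(t, mpar, 1)[0]) / 2.0, 0.0)
        res.D_perp = max(float(np.polyfit(t, mperp, 1)[0]) / 4.0, 0.0)
    return res


# ---------------------------------------------------------------------------
# cluster exchange statistics
# ---------------------------------------------------------------------------

@dataclass
class ExchangeStats:
    in_counts: dict[str, float]  # events per molecule of the species
    out_counts: dict[str, float]
    window_frames: int
    raw_in: dict[str, int] = field(default_factory=dict)
    raw_out: dict[str, int] = field(default_factory=dict)


def _largest_cluster_membership(traj: Trajectory, frame: np.ndarray,
                                cutoff: float) -> np.ndarray:
    """Boolean membership of each molecule in the largest single-linkage
    cluster (inter-molecule minimum bead distance <= cutoff)."""
    box = np.asarray(traj.box, dtype=float)
    w = _wrap(frame, box)
    tree = cKDTree(w, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    mols = np.unique(traj.mol_id)
    m_of = np.searchsorted(mols, traj.mol_id)
    if pairs.size:
        mi = m_of[pairs[:, 0]]
        mj = m_of[pairs[:, 1]]
        keep = mi != mj
        mi, mj = mi[keep], mj[keep]
    else:
        mi = mj = np.empty(0, dtype=int)
    n = len(mols)
    adj = coo_matrix((np.ones(len(mi)), (mi, mj)), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=ncomp)
    return labels == np.argmax(sizes)


def exchange_events(traj: Trajectory, cluster_cutoff: float = 12.0,
                    dwell: int = 5, window: tuple[float, float] = (0.0, 1.0)
                    ) -> ExchangeStats:
    """Count condensate<->supernatant exchange events per species.

    A molecule's membership change in the largest cluster counts as an event
    only if the new state persists for at least ``dwell`` frames; counts are
    normalized by the number of molecules of the species in the box.
    """
    if cluster_cutoff >= 0.5 * min(traj.box[:2]):
        raise AnalysisError("cluster cutoff above half the box edge")
    f0 = int(np.floor(window[0] * traj.n_frames))
    f1 = int(np.ceil(window[1] * traj.n_frames))
    frames = traj.frames[f0:f1]
    if len(frames) < 2:
        raise AnalysisError("exchange window must contain >= 2 frames")
    member = np.array([_largest_cluster_membership(traj, f, cluster_cutoff)
                       for f in frames])  # (F, M)
    mols = np.unique(traj.mol_id)
    first_bead = np.searchsorted(traj.mol_id, mols)
    mol_species = traj.species[first_bead]
    raw_in: dict[str, int] = {}
    raw_out: dict[str, int] = {}
    n_mols: dict[str, int] = {}
    for s in np.unique(mol_species):
        raw_in[str(s)] = 0
        raw_out[str(s)] = 0
        n_mols[str(s)] = int(np.sum(mol_species == s))
    for m in range(member.shape[1]):
        series = member[:, m]
        # collapse runs shorter than the dwell time into the previous state
        state = series[0]
        run_start = 0
        events: list[tuple[bool, bool]] = []
        k = 1
        filtered = [state]
        while k <= len(series):
            if k == len(series) or series[k] != series[run_start]:
                run_len = k - run_start
                new_state = series[run_start]
                if new_state != filtered[-1] and run_len >= dwell:
                    events.append((filtered[-1], new_state))
                    filtered.append(new_state)
                run_start = k
            k += 1
        s = str(mol_species[m])
        for old, new in events:
            if new and not old:
                raw_in[s] += 1
            elif old and not new:
                raw_out[s] += 1
    return ExchangeStats(
        in_counts={s: raw_in[s] / n_mols[s] for s in raw_in},
        out_counts={s: raw_out[s] / n_mols[s] for s in raw_out},
        window_frames=len(frames), raw_in=raw_in, raw_out=raw_out)


# ---------------------------------------------------------------------------
# contacts and bridges
# ---------------------------------------------------------------------------

@dataclass
class ContactProfile:
    n_c: dict[str, float]  # mean NT contacts per amino-acid residue type
    bridges_per_frame: float  # peptides contacting >= 2 distinct NA chains
    cutoff: float


def contact_counts(traj: Trajectory, cutoff: float = 10.0,
                   discard: float = 0.5) -> ContactProfile:
    """Amino-acid--nucleotide contact statistics and peptide-mediated bridges.

    N_c(residue type) is the time-averaged number of NT beads within the
    cutoff of an amino-acid bead of that type, averaged over residue
    instances; a bridge is a peptide simultaneously contacting two or more
    distinct nucleic-acid molecules in a frame.
    """
    is_aa = np.isin(traj.bead_types, list(AA_BEAD_TYPES))
    is_nt = ~is_aa
    if not is_aa.any() or not is_nt.any():
        raise AnalysisError("contact analysis needs a mixed peptide/NA system")
    ia = np.where(is_aa)[0]
    ib = np.where(is_nt)[0]
    box = np.asarray(traj.box, dtype=float)
    frames = _frames_after(traj, discard)
    counts = np.zeros(len(ia))
    bridges = 0
    for f in frames:
        w = _wrap(f, box)
        ta = cKDTree(w[ia], boxsize=box)
        tb = cKDTree(w[ib], boxsize=box)
        mat = ta.sparse_distance_matrix(tb, cutoff, output_type="ndarray")
        np.add.at(counts, mat["i"], 1)
        pep_mol = traj.mol_id[ia[mat["i"]]]
        na_mol = traj.mol_id[ib[mat["j"]]]
        contacts = set(zip(pep_mol.tolist(), na_mol.tolist()))
        per_pep: dict[int, set[int]] = {}
        for pm, nm in contacts:
            per_pep.setdefault(pm, set()).add(nm)
        bridges += sum(1 for v in per_pep.values() if len(v) >= 2)
    counts /= len(frames)
    types = traj.bead_types[ia]
    n_c = {str(t): float(counts[types == t].mean()) for t in np.unique(types)}
    return ContactProfile(n_c=n_c, bridges_per_frame=bridges / len(frames),
                          cutoff=cutoff)
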