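"""Slab-trajectory phase classification and (ionic strength, T) phase diagrams.

The slab (direct-coexistence) readout: bead density is profiled along the
elongated box axis after recentring each frame on the dense cluster, the
dense and dilute coexistence densities are read from the plateau and from
the outer region of the profile, and each state point is labeled

* ``UNI``   -- monophasic: no plateau, or dense/dilute ratio below threshold;
* ``LLPS``  -- biphasic with an orientationally isotropic dense phase;
* ``LLCPS`` -- biphasic with nematic order S above threshold for the
  nucleic-acid species (liquid-crystalline condensate).

The salt-resistance proxy IS_th is the highest sampled ionic strength with a
biphasic label at the reference temperature (298 K).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coacervmd.condensate_analysis import nematic_order
from coacervmd.simulator import Trajectory

REFERENCE_T = 298.0


class PhaseAnalysisError(ValueError):
    pass


@dataclass
class DensityProfile:
    """Per-species bead-number density along the slab axis (beads/A^3)."""

    z: np.ndarray  # bin centers, A
    density: dict[str, np.ndarray]
    box: np.ndarray
    n_frames: int

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.density.values()), axis=0)

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def cross_section(self) -> float:
        return float(self.box[0] * self.box[1])


@dataclass
class PhasePoint:
    ionic_strength: float
    temperature: float
    label: str  # UNI | LLPS | LLCPS
    dilute: dict[str, float] = field(default_factory=dict)
    dense: dict[str, float] = field(default_factory=dict)
    nematic_s: float = float("nan")
    density_ratio: float = float("nan")


@dataclass
class PhaseDiagram:
    points: list[PhasePoint]
    is_th: float | None  # mol/L at the reference temperature
    reference_T: float = REFERENCE_T

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            rows.append({
                "ionic_strength_M": p.ionic_strength, "T_K": p.temperature,
                "label": p.label, "density_ratio": p.density_ratio,
                "nematic_S": p.nematic_s,
                **{f"dilute_{k}": v for k, v in p.dilute.items()},
                **{f"dense_{k}": v for k, v in p.dense.items()}})
        return pd.DataFrame(rows)

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path:
            with open(json_path, "w") as fh:
                json.dump({"is_th_M": self.is_th,
                           "reference_T_K": self.reference_T,
                           "n_points": len(self.points)}, fh, indent=1)


def _recenter_z(z: np.ndarray, lz: float) -> np.ndarray:
    """Shift periodic z so the dense cluster sits at lz/2.

    The cluster position is the maximum of a coarsely smoothed circular
    histogram (robust when a second droplet coexists with the main slab,
    where a global circular mean would land between them), refined by the
    circular center of mass of the beads within a quarter box of the mode.
    """
    nb = 48
    hist, edges = np.histogram(z, bins=nb, range=(0.0, lz))
    win = max(nb // 8, 1)
    kernel = np.ones(2 * win + 1)
    smooth = np.convolve(np.tile(hist, 3), kernel, mode="same")[nb:2 * nb]
    mode = (edges[:-1] + edges[1:])[np.argmax(smooth)] / 2.0
    d = np.mod(z - mode + 0.5 * lz, lz) - 0.5 * lz
    near = np.abs(d) <= 0.25 * lz
    z0 = mode + (d[near].mean() if near.any() else 0.0)
    return np.mod(z - z0 + 0.5 * lz, lz)


def density_profile(traj: Trajectory, species: list[str] | None = None,
                    nbins: int = 60, discard: float = 0.0,
                    recenter: bool = True) -> DensityProfile:
    """Frame-averaged axial density per species, recentred per frame.

    Each frame's dense-cluster position is estimated from the circular mean
    of all bead z coordinates (exact for a single slab, harmless for a
    uniform gas) and shifted to the box center before binning.
    """
    n0 = int(np.floor(discard * traj.n_frames))
    frames = traj.frames[n0:]
    if len(frames) == 0:
        raise PhaseAnalysisError("no analysis frames")
    lz = float(traj.box[2])
    if species is None:
        species = [str(s) for s in np.unique(traj.species)]
    edges = np.linspace(0.0, lz, nbins + 1)
    binvol = traj.box[0] * traj.box[1] * (edges[1] - edges[0])
    hists = {s: np.zeros(nbins) for s in species}
    for f in frames:
        z = np.mod(f[:, 2], lz)
        if recenter:
            z = _recenter_z(z, lz)
        for s in species:
            sel = traj.species == s
            hists[s] += np.histogram(z[sel], bins=edges)[0]
    dens = {s: h / (len(frames) * binvol) for s, h in hists.items()}
    return DensityProfile(z=0.5 * (edges[:-1] + edges[1:]), density=dens,
                          box=np.asarray(traj.box, dtype=float),
                          n_frames=len(frames))


def coexistence_densities(profile: DensityProfile,
                          plateau_fraction: float = 0.25,
                          outer_fraction: float = 0.25
                          ) -> tuple[dict[str, float], dict[str, float], bool]:
    """Dilute and dense coexistence densities per species.

    The slab extent is taken between the half-maximum crossings of the total
    profile; the dense value is the mean over the central
    ``plateau_fraction`` of that extent, the dilute value the mean over the
    outer ``outer_fraction`` of the box.  Returns (dilute, dense, uniform)
    where ``uniform`` flags profiles with no identifiable plateau.
    """
    if len(profile.z) < 40:
        raise PhaseAnalysisError("need >= 40 bins for coexistence analysis")
    total = profile.total
    mean = total.mean()
    peak = total.max()
    uniform = mean == 0.0
    lz = float(profile.box[2])
    z = profile.z
    center = lz / 2.0
    if not uniform:
        above = total >= 0.5 * peak
        # contiguous half-max region containing the center (profiles are
        # recentred, so the slab straddles lz/2)
        ic = int(np.argmin(np.abs(z - center)))
        if not above[ic]:
            ic = int(np.argmax(total))
        lo = ic
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = ic
        while hi < len(z) - 1 and above[hi + 1]:
            hi += 1
        extent = z[hi] - z[lo]
        if extent > 0.9 * lz:
            uniform = True
        z0 = 0.5 * (z[lo] + z[hi])
        dense_mask = np.abs(z - z0) <= 0.5 * plateau_fraction * max(extent,
                                                                    profile.bin_width)
    if uniform:
        dense_mask = np.abs(z - center) <= 0.25 * lz
    # dilute region: the lowest-density quarter of the bins.  For a single
    # recentred slab this coincides with the outer region of the box, and it
    # stays correct when the dense phase occupies several layers.
    n_dilute = max(int(np.ceil(outer_fraction * len(z))), 1)
    dilute_mask = np.zeros(len(z), dtype=bool)
    dilute_mask[np.argsort(total)[:n_dilute]] = True
    dilute = {s: float(d[dilute_mask].mean()) for s, d in profile.density.items()}
    dense = {s: float(d[dense_mask].mean()) for s, d in profile.density.items()}
    # no meaningful partitioning when the emptiest region still holds a
    # substantial share of the mean density (aspect-independent, unlike a
    # peak-to-mean contrast, which fails at high global concentration)
    if mean > 0 and total[dilute_mask].mean() > 0.5 * mean:
        uniform = True
    return dilute, dense, uniform


NA_BEAD_TYPES = frozenset(
    ["DA", "DC", "DG", "DT", "pA", "pC", "pG", "pT", "PO4"])


def isotropic_s_null(n_molecules: int, quantile: float = 0.95,
                     n_draws: int = 500, seed: int = 2024) -> float:
    """Finite-size baseline of the nematic order parameter.

    The largest Q-tensor eigenvalue of M isotropically distributed axes is
    positively biased (~0.27 for M = 10); an LC call on few molecules must
    clear this null.  Frozen axes are assumed (conservative: frame
    averaging of slowly reorienting molecules adds little independence).
    """
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    for k in range(n_draws):
        u = rng.standard_normal((n_molecules, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        q = 1.5 * (u.T @ u) / n_molecules - 0.5 * np.eye(3)
        draws[k] = np.linalg.eigvalsh(q)[-1]
    return float(np.quantile(draws, quantile))


def _nucleic_species(traj: Trajectory) -> list[str]:
    """Species whose beads are nucleotide/polyP types (not amino acids)."""
    return [str(s) for s in np.unique(traj.species)
            if traj.bead_types[traj.species == s][0] in NA_BEAD_TYPES]


def classify_phase_state(traj: Trajectory, na_species: list[str] | None = None,
                         ratio_threshold: float = 5.0,
                         s_threshold: float = 0.3, discard: float = 0.5,
                         nbins: int = 60) -> PhasePoint:
    """Label one slab trajectory UNI / LLPS / LLCPS.

    The first ``discard`` fraction of frames is treated as equilibration.
    The biphasic criterion is a dense/dilute total-density ratio of at least
    ``ratio_threshold``; the liquid-crystal criterion is a nematic order
    parameter of at least ``s_threshold`` for the dense-phase nucleic-acid
    molecules.  Thresholds are conventions of this package, exposed here.
    """
    prof = density_profile(traj, nbins=nbins, discard=discard)
    dilute, dense, uniform = coexistence_densities(prof)
    d_tot = sum(dense.values())
    dil_tot = sum(dilute.values())
    ratio = d_tot / dil_tot if dil_tot > 0 else np.inf
    point = PhasePoint(ionic_strength=traj.ionic_strength, temperature=traj.T,
                       label="UNI", dilute=dilute, dense=dense,
                       density_ratio=float(ratio))
    if uniform or ratio < ratio_threshold:
        return point
    point.label = "LLPS"
    if na_species is None:
        na_species = _nucleic_species(traj)
    if na_species:
        sel = np.isin(traj.species, na_species)
        mols = np.unique(traj.mol_id[sel])
        if sel.any() and len(mols) >= 2:
            dense_mols = _dense_region_molecules(traj, sel, discard)
            if len(dense_mols) >= 2:
                order = nematic_order(traj, species=na_species,
                                      discard=discard,
                                      mol_subset=dense_mols)
                point.nematic_s = order.S
                # the LC call must clear both the fixed threshold and the
                # finite-size isotropic baseline for this molecule count
                null95 = isotropic_s_null(len(dense_mols))
                if order.S >= max(s_threshold, null95):
                    point.label = "LLCPS"
    return point


def _dense_region_molecules(traj: Trajectory, bead_sel: np.ndarray,
                            discard: float) -> np.ndarray:
    """Molecule ids (within the selection) whose mean recentred axial
    position lies inside the half-max extent of the total density slab."""
    prof = density_profile(traj, discard=discard)
    _, _, uniform = coexistence_densities(prof)
    n0 = int(np.floor(discard * traj.n_frames))
    frames = traj.frames[n0:]
    lz = float(traj.box[2])
    mols = np.unique(traj.mol_id[bead_sel])
    if uniform:
        return mols
    total = prof.total
    above = total >= 0.5 * total.max()
    zs = []
    for f in frames:
        z = _recenter_z(np.mod(f[:, 2], lz), lz)
        zs.append([np.mean(z[bead_sel & (traj.mol_id == m)]) for m in mols])
    mean_z = np.mean(zs, axis=0)
    bin_of = np.clip(np.searchsorted(prof.z, mean_z), 0, len(total) - 1)
    return mols[above[bin_of]]


def assemble_phase_diagram(points: list[PhasePoint],
                           reference_T: float = REFERENCE_T,
                           t_tol: float = 2.0) -> PhaseDiagram:
    """Collect state points; IS_th = max biphasic ionic strength at the
    reference temperature (None if no biphasic point is sampled there)."""
    if not points:
        raise PhaseAnalysisError("empty phase-point grid")
    at_ref = [p for p in points if abs(p.temperature - reference_T) <= t_tol]
    if not at_ref:
        raise PhaseAnalysisError(
            f"no state points at the reference temperature {reference_T} K")
    biphasic = [p.ionic_strength for p in at_ref if p.label != "UNI"]
    is_th = max(biphasic) if biphasic else None
    return PhaseDiagram(points=list(points), is_th=is_th,
                        reference_T=reference_T)
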