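"""End-to-end study recipes at reduced scale.

Each recipe orchestrates the library over a named experiment grid:

* ``fig2_ssdna10_diagram`` -- peptide/ssDNA-10 slab states over an ionic
  strength grid at room temperature, with the salt-resistance threshold;
* ``fig3_structures`` -- ssDNA-20 vs dsDNA-20 phase states on a shared
  ionic-strength grid (secondary-structure effect);
* ``fig6_analogs`` -- polyP-20 and the PNA:DNA-20 hybrid;
* ``fig7_dynamics`` -- diffusion / exchange / contact statistics inside
  isotropic (ssDNA-20) and liquid-crystalline (dsDNA-20) condensates;
* ``metrics_fig5`` -- the (L_c, RMSD_n, |Phi_e_tilde|) descriptor table
  over the whole molecule set.

Simulated systems are deliberately small (hundreds to ~1000 beads) and
short (about 1e6 fs) -- enough for the qualitative orderings the package
tests, not for quantitative coexistence curves.  ``scale`` shrinks copy
numbers and step counts further.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from coacervmd import condensate_analysis as ca
from coacervmd import phase_analysis as pa
from coacervmd import polyanion_metrics as pm
from coacervmd.constructs import Construct, canonical_constructs
from coacervmd.forcefield import ForceFieldConfig
from coacervmd.simulator import (
    SimulationConfig,
    SystemState,
    Trajectory,
    init_slab,
    minimize,
    run_langevin,
    write_trajectory,
)

log = logging.getLogger(__name__)

#: simulated stoichiometric concentrations (mol/L): peptide 0.120 M and
#: per-polyanion values chosen for overall charge neutrality of the mixture
SIM_CONCENTRATIONS = {
    "pL22": 0.120,
    "ssDNA-10": 0.080,
    "ssDNA-20": 0.040,
    "dsDNA-20": 0.020,
    "hp5DNA": 0.040,
    "hdsDNA": 0.028,
    "polyP-20": 0.040,
    "PNA:DNA-20": 0.040,
}

#: default molecule counts for the scaled-down slab systems (peptide count
#: fixed; polyanion counts follow the concentration ratios)
N_PEPTIDE = 33

#: recipe-level force field: a single 20 A cutoff for both nonbonded terms
#: keeps the periodic cell compact at these system sizes
RECIPE_FF = ForceFieldConfig(cutoff_sr=20.0, cutoff_elec=20.0)

RECIPE_STEPS = 60_000
RECIPE_DT = 15.0
RECIPE_FRICTION = 3e-4
RECIPE_STRIDE = 400


def _counts_for(polyanion: str, n_pep: int) -> int:
    ratio = SIM_CONCENTRATIONS[polyanion] / SIM_CONCENTRATIONS["pL22"]
    return max(int(round(n_pep * ratio)), 1)


def slab_state_point(constructs: dict[str, Construct], polyanion: str,
                     ionic_strength: float, T: float, seed: int,
                     scale: float = 1.0, steps: int | None = None,
                     ff: ForceFieldConfig | None = None,
                     peptide: str = "pL22",
                     ) -> tuple[pa.PhasePoint, Trajectory, SystemState]:
    """Run one slab simulation and classify its phase state."""
    ff = ff or RECIPE_FF
    n_pep = max(int(round(N_PEPTIDE * scale)), 4)
    n_poly = _counts_for(polyanion, n_pep)
    recipe = [(constructs[peptide], n_pep), (constructs[polyanion], n_poly)]
    conc = {peptide: SIM_CONCENTRATIONS["pL22"],
            polyanion: SIM_CONCENTRATIONS[polyanion]}
    state = init_slab(recipe, T, ionic_strength, seed, concentrations=conc,
                      ff=ff, min_xy=2 * ff.max_cutoff + 2.0,
                      dense_bead_density=0.005)
    minimize(state, ff, steps=100)
    nsteps = steps if steps is not None else max(int(RECIPE_STEPS * scale), 2000)
    cfg = SimulationConfig(steps=nsteps, dt=RECIPE_DT, friction=RECIPE_FRICTION,
                           seed=seed + 1, stride=RECIPE_STRIDE)
    traj = run_langevin(state, ff, cfg)
    point = pa.classify_phase_state(traj)
    log.info("%s @ IS=%g M, T=%g K -> %s (ratio %.1f, S %.2f)", polyanion,
             ionic_strength, T, point.label, point.density_ratio,
             point.nematic_s)
    return point, traj, state


def single_chain_ensemble(c: Construct, seed: int, steps: int = 40_000,
                          stride: int = 200,
                          ff: ForceFieldConfig | None = None) -> pm.ConformationEnsemble:
    """Conformational ensemble of one isolated chain from the CG sampler.

    The chain sits alone in a periodic box comfortably larger than both the
    interaction cutoffs and its own extent (dilute-limit sampling at 298 K,
    0.1 M ionic strength).
    """
    import numpy as np

    from coacervmd.forcefield import build_topology
    from coacervmd.parameters import KB, MVSQ2E
    from coacervmd.simulator import SystemState, template_coords

    ff = ff or RECIPE_FF
    rng = np.random.default_rng(seed)
    template = template_coords(c, ff, rng)
    edge = max(2.0 * ff.max_cutoff + 2.0, 1.5 * float(np.ptp(template)) + 10.0)
    topo = build_topology([(c, 1)], ff)
    coords = template + edge / 2.0
    sigma_v = np.sqrt(KB * 298.0 / (topo.masses * MVSQ2E))
    vel = rng.standard_normal((c.n_beads, 3)) * sigma_v[:, None]
    state = SystemState(coords=coords, velocities=vel, box=np.full(3, edge),
                        T=298.0, ionic_strength=0.1, topology=topo)
    minimize(state, ff, steps=100)  # random-walk starts can self-overlap
    cfg = SimulationConfig(steps=steps, dt=10.0, friction=1e-3, seed=seed + 1,
                           stride=stride)
    traj = run_langevin(state, ff, cfg)
    n0 = traj.n_frames // 4
    return pm.ConformationEnsemble(traj.frames[n0:], source="internal")


# ---------------------------------------------------------------------------
# named recipes
# ---------------------------------------------------------------------------

def _phase_grid(constructs, polyanion, grid_is, T, seed, scale, outdir,
                save_traj=False, kbend_tag="", ff=None):
    points = []
    for k, is_m in enumerate(grid_is):
        point, traj, _ = slab_state_point(constructs, polyanion, is_m, T,
                                          seed + 97 * k, scale=scale, ff=ff)
        points.append(point)
        if save_traj:
            write_trajectory(traj, Path(outdir) /
                             f"{polyanion}{kbend_tag}_IS{int(is_m * 1e3)}mM.xyz")
    return points


def run_recipe(name: str, scale: float = 1.0, seed: int = 1,
               outdir: str | Path = "recipe_out") -> Path:
    """Run one named study recipe; returns the output directory.

    Deterministic for fixed (name, scale, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    constructs = canonical_constructs(seed)
    rng_base = seed

    if name == "fig2_ssdna10_diagram":
        grid = [0.025, 0.100, 0.150]
        points = _phase_grid(constructs, "ssDNA-10", grid, 298.0, rng_base,
                             scale, outdir)
        diagram = pa.assemble_phase_diagram(points)
        diagram.write(outdir / "phase_diagram.tsv", outdir / "summary.json")
    elif name == "fig3_structures":
        grid = [0.025, 0.150]
        summary = {}
        for poly in ("ssDNA-20", "dsDNA-20"):
            pts = _phase_grid(constructs, poly, grid, 298.0, rng_base, scale,
                              outdir)
            d = pa.assemble_phase_diagram(pts)
            d.write(outdir / f"{poly}_diagram.tsv")
            summary[poly] = d.is_th
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"is_th_M": summary}, fh, indent=1)
    elif name == "fig6_analogs":
        summary = {}
        for poly in ("polyP-20", "PNA:DNA-20"):
            pts = _phase_grid(constructs, poly, [0.025], 298.0, rng_base,
                              scale, outdir)
            summary[poly] = pts[0].label
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"label_at_25mM": summary}, fh, indent=1)
    elif name == "fig7_dynamics":
        run_dynamics_comparison(constructs, seed=rng_base, scale=scale,
                                outdir=outdir)
    elif name == "metrics_fig5":
        run_metrics_table(constructs, seed=rng_base, scale=scale,
                          outdir=outdir)
    else:
        raise ValueError(f"unknown recipe {name!r}")
    return outdir


def run_dynamics_comparison(constructs: dict[str, Construct], seed: int,
                            scale: float = 1.0,
                            outdir: str | Path = "recipe_out",
                            low_is: float = 0.025) -> dict:
    """Mobility inside isotropic (ssDNA-20) vs LC (dsDNA-20) condensates.

    Reports diffusion coefficients scaled by D0 (peptide in the isotropic
    condensate), the parallel/perpendicular decomposition for the peptide in
    the LC phase, and normalized exchange counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    pt_iso, traj_iso, _ = slab_state_point(constructs, "ssDNA-20", low_is,
                                           298.0, seed + 11, scale=scale)
    pt_lc, traj_lc, _ = slab_state_point(constructs, "dsDNA-20", low_is,
                                         298.0, seed + 13, scale=scale)
    out["label_ssDNA-20"] = pt_iso.label
    out["label_dsDNA-20"] = pt_lc.label
    out["nematic_S_dsDNA-20"] = pt_lc.nematic_s

    d0 = ca.diffusion_coefficients(traj_iso, "pL22", discard=0.3).D
    d_ss = ca.diffusion_coefficients(traj_iso, "ssDNA-20", discard=0.3).D
    order = ca.nematic_order(traj_lc, species=["dsDNA-20"], discard=0.5)
    d_pep_lc = ca.diffusion_coefficients(traj_lc, "pL22", discard=0.3,
                                         director=order.director)
    d_ds = ca.diffusion_coefficients(traj_lc, "dsDNA-20", discard=0.3).D
    out["D0_pep_iso"] = d0
    out["D_ssDNA_over_D0"] = d_ss / d0 if d0 > 0 else float("nan")
    out["D_dsDNA_over_D0"] = d_ds / d0 if d0 > 0 else float("nan")
    out["D_pep_lc_over_D0"] = d_pep_lc.D / d0 if d0 > 0 else float("nan")
    out["D_pep_lc_par"] = d_pep_lc.D_par
    out["D_pep_lc_perp"] = d_pep_lc.D_perp

    ex_iso = ca.exchange_events(traj_iso, window=(0.5, 1.0))
    ex_lc = ca.exchange_events(traj_lc, window=(0.5, 1.0))
    out["exchange_out_ssDNA_iso"] = ex_iso.out_counts.get("ssDNA-20", 0.0)
    out["exchange_out_pep_iso"] = ex_iso.out_counts.get("pL22", 0.0)
    out["exchange_out_dsDNA_lc"] = ex_lc.out_counts.get("dsDNA-20", 0.0)
    out["exchange_out_pep_lc"] = ex_lc.out_counts.get("pL22", 0.0)

    contacts = ca.contact_counts(traj_lc)
    out["mean_Nc"] = float(np.mean(list(contacts.n_c.values())))
    out["bridges_per_frame"] = contacts.bridges_per_frame
    with open(outdir / "dynamics.json", "w") as fh:
        json.dump(out, fh, indent=1, default=float)
    return out


def run_metrics_table(constructs: dict[str, Construct], seed: int,
                      scale: float = 1.0,
                      outdir: str | Path = "recipe_out",
                      names: list[str] | None = None) -> pd.DataFrame:
    """Descriptor table (L_c, N, RMSD_n, |Phi_e_tilde|) for the molecule set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if names is None:
        names = ["ssDNA-10", "ssDNA-20", "ssDNA-40", "dsDNA-10", "dsDNA-20",
                 "hp5DNA", "hdsDNA", "polyP-20", "PNA:DNA-20"]
    steps = max(int(30_000 * scale), 4000)
    results = []
    for k, nm in enumerate(names):
        ens = single_chain_ensemble(constructs[nm], seed + 31 * k, steps=steps)
        results.append(pm.metric_result(constructs[nm], ens))
    table = pm.metrics_table(results)
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    return table
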