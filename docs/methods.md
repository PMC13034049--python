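# Methods

## Scope

`coacervmd` is a self-contained coarse-grained (CG) toolkit for studying
complex coacervation of short nucleic acids (NAs) and their analogs with a
moderately charged disordered peptide: model construction, slab-geometry
Langevin dynamics over (ionic strength, temperature) grids, phase
classification (monophasic / liquid–liquid / liquid–liquid-crystalline),
and single-molecule stability descriptors.  Everything is text-based and
reproducible from integer seeds.

## The interaction model

One bead per residue (amino acid, nucleotide, or phosphate unit) in
implicit solvent.

**Electrostatics.**  Screened Coulomb (Debye–Hückel) between bead charges
q_i ∈ {0, ±e}:

    U_DH(r) = q_i q_j e² / (4π ε0 ε_r(T) r) · exp(−r/λ_D),

with the relative permittivity of water from the empirical fit
ε_r(T) = 5321/T + 233.76 − 0.9297 T + 1.417·10⁻³ T² − 8.292·10⁻⁷ T³
(≈78.4 at 298.15 K, valid ~250–400 K) and the Debye length λ_D computed
from ε_r, T and the 1:1 ionic strength (λ_D ≈ 9.6 Å at 0.1 M, 298 K).
Ionic strength enters the model only through λ_D — salt is entirely
implicit, so ion partitioning and counterion release are outside the model.

**Short range.**  The Ashbaugh–Hatch form: below the Lennard–Jones minimum
2^(1/6)σ the potential is U_LJ + (1−λ)ε_lj, above it λ·U_LJ, with λ the
arithmetic-mean hydropathy of the pair (λ = 0 is a pure WCA repulsion,
λ = 1 plain LJ).  σ is the arithmetic-mean bead diameter.  ε_lj = 0.2
kcal/mol.

**Residue parameters.**  Amino acids carry the Urry-scale hydropathies and
diameters of the HPS model family; K/R are +e, D/E −e.  Nucleotides carry
−e, σ = 7 Å, and hydropathies equal to an RNA-family table
(A/G 0.65, C/T 0.60) plus a uniform offset +0.05 for DNA's slightly higher
hydrophobicity; the offset and the whole table are user-overridable.  PNA
beads are DNA beads with the charge set to zero.  The polyphosphate bead
has λ = 0 exactly (very hydrophilic), charge −e, σ = 4.5 Å.

**Bonded terms** (full-prefactor convention, U = k·x²; note a ½k x²
convention would correspond to doubled constants):

| term | k | rest value |
|---|---|---|
| backbone bond | 10 kcal/mol/Å² | peptide 3.8 Å, ss-NA 5.0 Å, ds-tract 3.4 Å (B-DNA rise), polyP 3.0 Å |
| bending (triplets) | ds tracts 40 kcal/mol·rad², ss/peptide 0 (configurable) | θ0 = π |
| hybridization spring | 10 kcal/mol/Å² | 13 Å between paired beads |

Bending applies only to triplets lying entirely in one stiffness class
(all-paired or all-unpaired); hybridization springs mirror the construct's
pairing map; 1–2 and 1–3 bonded neighbors and hybridized partners are
excluded from nonbonded sums.  The hybridization rest length of 13 Å plus
the 7 Å bead diameter gives a duplex of ≈2 nm overall diameter.
Nonbonded potentials are plain-truncated (library defaults 20 Å short
range / 35 Å electrostatic; the bundled slab recipes use a single 20 Å
cutoff so the periodic cell stays compact at small system sizes).

## Constructs

All DNA sequences are balanced compositions (equal base counts ±1),
deterministically shuffled from a seed, so that length and hybridization
effects are not confounded with composition.  Topology kinds: ss, full
duplex (paired to the reverse complement), hairpin (stem pairs joining the
5′ and 3′ ends, loop in between), half-duplex (first half paired to a
complementary strand, the rest a free tail), PNA variants, polyP, peptide.
The monomer count 𝒩 counts unpaired residues once and base pairs once.

The peptide `pL22` ships as a documented 18-residue placeholder,
`KGRAKSRLDKGRTKIRQW`: 8 interspersed K/R, one D, net +7, mixed
polar/apolar composition, low sequence charge decoration.  The net charge
+7 is what makes the bundled stoichiometric concentrations (peptide
120 mM against 80/40/28/20 mM for ssDNA-10/ssDNA-20/hdsDNA/dsDNA-20)
electro-neutral, exactly so for hdsDNA.  A user construct file can replace
the placeholder.

## Dynamics

BAOAB-discretized Langevin dynamics in periodic orthorhombic boxes;
forces come from numba-compiled kernels over a Verlet pair list (rebuilt
on a half-skin displacement criterion) that are verified in the test suite
against a plain-numpy reference implementation and against brute-force
minimum-image enumeration.  Thermostat noise is drawn from per-chunk
seeded streams, making trajectories bit-reproducible for a given seed.
Default timestep 10 fs (15 fs in the slab recipes; the stiffest mode, the
backbone bond, has a ≈1.25 ps period); friction 10⁻³ fs⁻¹ (3·10⁻⁴–2·10⁻⁴
in recipes to speed configurational sampling).  As in all
implicit-solvent CG models, absolute diffusion is accelerated; dynamic
observables are therefore reported relative to the peptide in the
isotropic condensate (D/D₀).

**Slab initialization.**  The box volume follows from the target molar
concentrations; the box is elongated along z (aspect ≥ 3 where the bead
count permits).  The cross-section is widened, at fixed volume, until the
dense region is thinner than it is wide (h ≤ 0.8 Lx): a "slab" thicker
than its width is a column that breaks up into droplets and defeats the
axial readout — at the bundled system sizes this brings the aspect to
≈2.2:1, which we accept (with a warning) as the price of a well-formed
slab.  Molecules are inserted without overlap into the central slab at
≈0.005 beads/Å³ (the packing relaxes adaptively when insertion stalls).
Mostly-paired stiff constructs (duplexes) are inserted co-aligned in the
slab plane — the standard pre-ordered start for direct-coexistence studies
of mesogenic species, which probes the *stability* of the ordered dense
phase rather than its spontaneous nucleation (rod reorientation times at
these sizes exceed reachable trajectory lengths in either direction);
coils are inserted with random orientations.  A short displacement-capped
steepest descent removes insertion strain.

## Phase classification

Axial density profiles are computed after per-frame recentring on the
dense cluster — the maximum of a coarsely smoothed circular histogram of
bead z, refined by the local circular center of mass; this stays correct
when a second droplet transiently coexists with the main slab, where a
global circular mean would land between them — discarding the first half
of each trajectory as equilibration.  The dense coexistence density is
the mean over the central quarter of the half-max extent of the main
hump; the dilute density is the mean over the lowest-density quarter of
the bins, which coincides with the outer region of the box for a single
recentred slab and stays correct when the dense phase occupies several
layers.  A state is **UNI** when no plateau is identifiable (the
half-max region spans >90% of the box, or the dilute region still holds
more than half the mean density — an aspect-independent uniformity test;
a peak-to-mean contrast would misread condensates at this study's high
global concentrations, where the dense phase occupies half the box) or
when the dense/dilute ratio is below 5; otherwise **LLPS**; additionally
**LLCPS** when the nematic order parameter S of the dense-region NA
molecules (largest eigenvalue of the molecule-axis Q-tensor, axes from
the gyration-tensor principal eigenvector) exceeds both the fixed
threshold 0.3 and the 95th percentile of the finite-size isotropic null
for the same molecule count (Monte-Carlo, frozen axes: ≈0.45 at 10
molecules, ≈0.2 at 60).  With few molecules the raw Q-tensor eigenvalue
is biased upward, so a fixed threshold alone cannot discriminate.  All
thresholds are package conventions, configurable and reported with every
result.  IS_th is the largest sampled ionic strength with a biphasic
label at 298 K.

## Condensate observables

Standard pair-histogram rdf normalized by ideal-gas shell counts
(intramolecular pairs excluded); Q-tensor nematic order and director;
diffusion from multi-origin molecular-COM MSD slopes (Einstein relation,
6Dt, with 2Dt/4Dt for the ∥/⊥ decomposition against a director); exchange
events as dwell-filtered membership changes of the largest single-linkage
molecular cluster (inter-molecule minimum bead distance ≤ 12 Å, dwell 5
output frames), normalized per molecule; AA–NT contacts within 10 Å per
residue type, and peptide bridges (a peptide touching ≥2 distinct NA
molecules in a frame).  The contact/cluster cutoffs and dwell are
declared conventions, config-exposed.

## Single-molecule descriptors

* **Contour length** L_c = 0.6 nm per unpaired monomer + 0.34 nm per base
  pair.
* **RMSD_n** = RMSD/𝒩: the ensemble RMSD about the iteratively refined
  mean structure after rigid-body (Kabsch) superposition of every frame —
  without superposition, center-of-mass diffusion and tumbling would
  dominate; a no-superposition mode exists for sensitivity checks.
  Ensembles come from the package's own single-chain CG sampler (dilute
  limit, 298 K, 0.1 M) or from external extended-XYZ files.  The ÷𝒩
  normalization removes a linear length dependence; note that for an ideal
  freely-jointed chain the raw RMSD grows only as √𝒩 — the premise of
  linear growth holds for short semiflexible charged strands, not
  universally.
* **Φ̃_e** = Φ_e / ln 𝒩, where Φ_e is the Coulomb potential (homogeneous
  relative dielectric ε = 2, the polyanion-interior value; exterior
  treatment is deliberately the same, the simplest reading of a
  surface-probe construction) averaged over a one-voxel shell of uniform
  grid points just outside the probe-inflated molecular surface (default
  spacing 0.5 Å, probe 1.4 Å).  Inputs are PQR atom records or bead-level
  pseudo-atoms (radius σ/2).  The ln 𝒩 normalization removes the
  logarithmic length growth of the surface-averaged potential of a
  line-like charge distribution.

## Scaled-down study conditions

The bundled recipes reproduce the study design at reduced scale: mixtures
with peptide at 120 mM and polyanions at the electro-neutral
concentrations above, 298 K, ionic-strength grids spanning 25–150 mM.
Slab systems contain ~30–70 peptides and ~10–25 polyanions (≈600–1500
beads) and run ≈1–2·10⁶ fs — sizes chosen so a full grid completes on one
CPU in minutes while still developing (or dissolving) a condensate.  At
these sizes the qualitative orderings are meaningful (condensation at low
vs high salt, ss vs ds salt resistance, LC stability vs bending
stiffness, mobility contrasts); coexistence densities and threshold ionic
strengths are not quantitative, interfaces are a large fraction of the
slab, and states near the phase boundary relax slowly — a state point
near IS_th can appear as a weakly contrasted blob whose classification is
sensitive to the plateau-contrast convention.  The synthetic-data
generator emulates sequence design (balanced compositions, imposed
pairing topologies); it does not predict secondary structure
thermodynamically, so unintended intra-strand pairing that real sequences
might form is absent by construction.

## Known limitations

* Hydropathy parametrization of DNA and polyP geometry use declared
  family-convention defaults, not fitted values; salt resistance is
  therefore expected to be overestimated for strongly paired species.
* Plain-truncated potentials make total energy only approximately
  conserved when pair distances cross a cutoff (irrelevant under a
  thermostat; the zero-friction conservation test uses a molecule shorter
  than the cutoff).
* No explicit ions/solvent, no hydrodynamics, no NPT bulk runs, no
  G-quadruplexes, no RNA.
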