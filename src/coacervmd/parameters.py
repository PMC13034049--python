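"""Default bead parameter tables and physical constants.

Units follow the LAMMPS "real" convention throughout the package:
length in angstrom, energy in kcal/mol, mass in g/mol, time in fs, charge
in units of the elementary charge e.

The residue tables follow the HPS family of one-bead-per-residue models:
each bead carries a charge (0 or +/- e), a hydropathy ``lam`` in [0, 1]
scaling the attractive branch of the short-range pair potential, a diameter
``sigma`` and a mass.  Amino-acid hydropathies are the Urry-scale values
used by that model family; nucleotide hydropathies default to the RNA
values of the same family plus a small uniform offset accounting for the
slightly higher hydrophobicity of DNA (configurable, see
:func:`nucleotide_hydropathy_table`).
"""

from __future__ import annotations

from dataclasses import dataclass

# --- physical constants (CODATA), in package units -------------------------
KB = 0.0019872041  # Boltzmann constant, kcal/mol/K
COULOMB_K = 332.06371  # e^2 / (4 pi eps0), kcal * angstrom / mol
MVSQ2E = 2390.0574  # (g/mol) * (A/fs)^2 -> kcal/mol
AVOGADRO = 6.02214076e23

#: default uniform hydropathy offset of DNA beads relative to the RNA table
DNA_HYDROPATHY_OFFSET = 0.05


@dataclass(frozen=True)
class BeadType:
    """Per-residue bead parameters: charge (e), hydropathy, diameter (A), mass (g/mol)."""

    charge: float
    lam: float
    sigma: float
    mass: float


# Urry-scale hydropathies and van-der-Waals diameters for the 20 amino acids
# (HPS-family convention; glutamate anchors the scale at 0, tryptophan at 1).
AMINO_ACIDS: dict[str, BeadType] = {
    "A": BeadType(0.0, 0.603, 5.04, 71.08),
    "R": BeadType(1.0, 0.559, 6.56, 156.19),
    "N": BeadType(0.0, 0.589, 5.68, 114.10),
    "D": BeadType(-1.0, 0.294, 5.58, 115.09),
    "C": BeadType(0.0, 0.640, 5.48, 103.14),
    "Q": BeadType(0.0, 0.655, 6.02, 128.13),
    "E": BeadType(-1.0, 0.000, 5.92, 129.11),
    "G": BeadType(0.0, 0.579, 4.50, 57.05),
    "H": BeadType(0.0, 0.763, 6.08, 137.14),
    "I": BeadType(0.0, 0.705, 6.18, 113.16),
    "L": BeadType(0.0, 0.721, 6.18, 113.16),
    "K": BeadType(1.0, 0.382, 6.36, 128.17),
    "M": BeadType(0.0, 0.725, 6.18, 131.20),
    "F": BeadType(0.0, 0.802, 6.36, 147.18),
    "P": BeadType(0.0, 0.759, 5.56, 97.12),
    "S": BeadType(0.0, 0.595, 5.18, 87.08),
    "T": BeadType(0.0, 0.600, 5.62, 101.10),
    "V": BeadType(0.0, 0.664, 5.86, 99.13),
    "W": BeadType(0.0, 1.000, 6.78, 186.21),
    "Y": BeadType(0.0, 0.817, 6.46, 163.18),
}

# RNA-family nucleotide hydropathies (purines slightly more hydrophobic).
RNA_HYDROPATHY = {"A": 0.65, "C": 0.60, "G": 0.65, "T": 0.60}

#: nucleotide bead diameter; two hybridized beads at the pairing rest length
#: give a duplex of ~2 nm overall diameter
NUCLEOTIDE_SIGMA = 7.0
NUCLEOTIDE_MASS = {"A": 331.2, "C": 307.2, "G": 347.2, "T": 322.2}


def nucleotide_hydropathy_table(offset: float = DNA_HYDROPATHY_OFFSET) -> dict[str, float]:
    """DNA per-base hydropathy: RNA-family values plus a uniform offset."""
    return {b: lam + offset for b, lam in RNA_HYDROPATHY.items()}


def dna_bead(base: str, offset: float = DNA_HYDROPATHY_OFFSET) -> BeadType:
    """One-bead DNA nucleotide: charge -e, base-dependent hydropathy."""
    return BeadType(-1.0, nucleotide_hydropathy_table(offset)[base],
                    NUCLEOTIDE_SIGMA, NUCLEOTIDE_MASS[base])


def pna_bead(base: str, offset: float = DNA_HYDROPATHY_OFFSET) -> BeadType:
    """PNA nucleotide: identical to the DNA bead with the charge switched off."""
    b = dna_bead(base, offset)
    return BeadType(0.0, b.lam, b.sigma, b.mass)


#: inorganic polyphosphate unit: fully charged, hydropathy exactly 0
#: (very hydrophilic backbone), compact geometry
POLYP_BEAD = BeadType(-1.0, 0.0, 4.5, 79.98)


def default_bead_table(dna_offset: float = DNA_HYDROPATHY_OFFSET) -> dict[str, BeadType]:
    """Full residue-code -> BeadType table.

    Bead type codes: amino acids by one-letter code; DNA bases ``DA DC DG DT``;
    PNA bases ``pA pC pG pT``; polyphosphate ``PO4``.
    """
    table = dict(AMINO_ACIDS)
    for base in "ACGT":
        table["D" + base] = dna_bead(base, dna_offset)
        table["p" + base] = pna_bead(base, dna_offset)
    table["PO4"] = POLYP_BEAD
    return table


# --- bonded-term defaults ---------------------------------------------------
#: harmonic constants use the full-prefactor convention U = k x^2
K_BOND = 10.0  # kcal/mol/A^2
K_HB = 10.0  # hybridization spring, kcal/mol/A^2
R0_HB = 13.0  # paired-bead separation, A
R0_PEPTIDE = 3.8  # CA-CA virtual bond, A
R0_SS = 5.0  # single-stranded intra-strand step, A
R0_DS = 3.4  # double-stranded intra-strand step (B-DNA rise), A
R0_POLYP = 3.0  # polyphosphate step, A
THETA0 = 3.141592653589793  # straight-chain bending reference, rad
K_BEND_DS = 40.0  # default duplex bending constant, kcal/mol/rad^2
K_BEND_SS = 0.0  # single strands / peptides bend freely by default

# --- nonbonded defaults -----------------------------------------------------
EPS_LJ = 0.2  # kcal/mol, depth scale of the short-range pair potential
CUTOFF_SR = 20.0  # short-range cutoff, A
CUTOFF_ELEC = 35.0  # electrostatic cutoff, A
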