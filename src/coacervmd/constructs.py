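"""Molecule builders: sequences, pairing topologies and bead parameter assignment.

This is the package's synthetic-data generator.  It produces every molecule
family of the study deterministically from a seed: balanced-composition
ssDNA 10/20/40/80-mers, their full duplexes, a 5-bp-stem hairpin (hp5DNA),
a half-duplex (a ds 10-mer with a 10-nt unpaired tail, hdsDNA), PNA strands
and PNA:DNA hybrids, polyphosphate 20-mers, a moderately charged 18-residue
peptide standing in for the ribosomal pL22 fragment, and a polylysine-18
control.

Indices are 0-based internally; pairing-map files on disk use 1-based
indices (two integer columns, ``#`` comments).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from coacervmd import parameters
from coacervmd.parameters import BeadType, default_bead_table

WC_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ALPHABETS = {
    "dna": set("ACGT"),
    "pna": set("ACGT"),
    "peptide": set(parameters.AMINO_ACIDS),
    "polyp": {"P"},
}

#: documented placeholder for the pL22 ribosomal fragment: 18 residues,
#: interspersed K/R (8 cationic) with one D, net charge +7, mixed
#: polar/apolar/aromatic composition (the exact sequence is not public).
PL22_PLACEHOLDER = "KGRAKSRLDKGRTKIRQW"


class ConstructError(ValueError):
    """Raised for invalid sequences, pairings or construct parameters."""


@dataclass(frozen=True)
class Sequence:
    """An ordered residue string with its alphabet tag."""

    residues: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ConstructError("empty sequence")
        if self.alphabet not in ALPHABETS:
            raise ConstructError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - ALPHABETS[self.alphabet]
        if bad:
            raise ConstructError(
                f"residues {sorted(bad)} not in {self.alphabet} alphabet")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: Sequence) -> Sequence:
    """Watson-Crick reverse complement of a DNA sequence (an involution)."""
    if seq.alphabet != "dna":
        raise ConstructError(
            f"reverse_complement requires a dna sequence, got {seq.alphabet!r}")
    return Sequence("".join(WC_COMPLEMENT[b] for b in reversed(seq.residues)), "dna")


def design_balanced_sequence(n: int, seed: int) -> Sequence:
    """Length-``n`` DNA sequence with equal base counts (+/-1), seeded shuffle.

    Balanced composition removes sequence-composition effects when strands of
    different lengths are compared; only the arrangement is randomized.
    """
    if n <= 0:
        raise ConstructError("sequence length must be positive")
    rng = np.random.default_rng(seed)
    base = n // 4
    counts = {b: base for b in "ACGT"}
    for b in rng.permutation(list("ACGT"))[: n - 4 * base]:
        counts[b] += 1
    letters = np.array([b for b in "ACGT" for _ in range(counts[b])])
    rng.shuffle(letters)
    return Sequence("".join(letters), "dna")


def _design_hairpin_sequence(n: int, stem_len: int, seed: int) -> Sequence:
    """Balanced sequence whose first and last ``stem_len`` bases are reverse
    complementary (a reshuffle of the balanced composition that folds into a
    hairpin with a ``stem_len``-bp stem)."""
    if 2 * stem_len >= n:
        raise ConstructError("stem too long for the sequence")
    for attempt in range(1000):
        rng = np.random.default_rng((seed, attempt))
        head = "".join(rng.choice(list("ACGT"), size=stem_len))
        tail = "".join(WC_COMPLEMENT[b] for b in reversed(head))
        counts = {b: n // 4 for b in "ACGT"}
        for b in head + tail:
            counts[b] -= 1
        if min(counts.values()) < 0:
            continue
        loop = np.array([b for b in "ACGT" for _ in range(counts[b])])
        rng.shuffle(loop)
        return Sequence(head + "".join(loop) + tail, "dna")
    raise ConstructError("could not draw a balanced hairpin sequence")


@dataclass
class Construct:
    """One molecular species: strands, pairing topology and per-bead parameters.

    Beads are indexed globally, strand 1 first.  ``pairing`` holds 0-based
    (i, j) pairs; for two-strand constructs i indexes strand 1 and j strand 2
    (strand-local), for single-strand hairpins both indices are on strand 1.
    """

    name: str
    kind: str
    strands: tuple[Sequence, ...]
    pairing: list[tuple[int, int]] = field(default_factory=list)
    kbend_ds: float = parameters.K_BEND_DS
    kbend_ss: float = parameters.K_BEND_SS
    bead_types: list[str] = field(default_factory=list)
    charges: np.ndarray = field(default_factory=lambda: np.empty(0))
    lambdas: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigmas: np.ndarray = field(default_factory=lambda: np.empty(0))
    masses: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not 1 <= len(self.strands) <= 2:
            raise ConstructError("a construct has one or two strands")
        self._validate_pairing()
        if not self.bead_types:
            self._assign_beads()

    # -- derived topology ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return sum(len(s) for s in self.strands)

    @property
    def strand_lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.strands)

    def global_pairs(self) -> list[tuple[int, int]]:
        """Pairing as global bead-index pairs."""
        off = len(self.strands[0]) if len(self.strands) == 2 else 0
        return [(i, j + off) for i, j in self.pairing]

    def paired_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_beads, dtype=bool)
        for i, j in self.global_pairs():
            mask[i] = mask[j] = True
        return mask

    def strand_of(self) -> np.ndarray:
        out = np.zeros(self.n_beads, dtype=np.int64)
        if len(self.strands) == 2:
            out[len(self.strands[0]):] = 1
        return out

    @property
    def n_monomers(self) -> int:
        return count_monomers(self)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def is_nucleic(self) -> bool:
        return all(s.alphabet in ("dna", "pna", "polyp") for s in self.strands)

    # -- internals -----------------------------------------------------------
    def _validate_pairing(self) -> None:
        intra = len(self.strands) == 1
        seen_i: set[int] = set()
        seen_j: set[int] = set()
        n1 = len(self.strands[0])
        n2 = len(self.strands[-1])
        for i, j in self.pairing:
            if not (0 <= i < n1 and 0 <= j < n2):
                raise ConstructError(f"pair ({i},{j}) out of range")
            if i in seen_i or j in seen_j or (intra and (i in seen_j or j in seen_i)):
                raise ConstructError(f"index repeated in pairing near ({i},{j})")
            seen_i.add(i)
            seen_j.add(j)
            a = self.strands[0].residues[i]
            b = self.strands[-1].residues[j]
            if {self.strands[0].alphabet, self.strands[-1].alphabet} <= {"dna", "pna"}:
                if WC_COMPLEMENT[a] != b:
                    raise ConstructError(
                        f"pair ({i},{j}) is not Watson-Crick complementary ({a}-{b})")
        if intra and self.pairing:
            # non-crossing nesting for hairpins
            for (i1, j1) in self.pairing:
                for (i2, j2) in self.pairing:
                    if i1 < i2 < j1 < j2:
                        raise ConstructError("crossing intramolecular pairs")

    def _assign_beads(self) -> None:
        table = default_bead_table()
        types: list[str] = []
        for s in self.strands:
            for r in s.residues:
                if s.alphabet == "dna":
                    types.append("D" + r)
                elif s.alphabet == "pna":
                    types.append("p" + r)
                elif s.alphabet == "polyp":
                    types.append("PO4")
                else:
                    types.append(r)
        self.bead_types = types
        beads: list[BeadType] = [table[t] for t in types]
        self.charges = np.array([b.charge for b in beads])
        self.lambdas = np.array([b.lam for b in beads])
        self.sigmas = np.array([b.sigma for b in beads])
        self.masses = np.array([b.mass for b in beads])


def count_monomers(c: Construct) -> int:
    """Monomer count N: unpaired residues count once, base pairs count once.

    For a single strand this is the nucleotide count, for a full duplex the
    base-pair count, and the natural additive combination for partially
    hybridized constructs.
    """
    if not c.is_nucleic():
        raise ConstructError("monomer counting applies to NA/polyP constructs")
    n_pairs = len(c.pairing)
    return c.n_beads - 2 * n_pairs + n_pairs


def compute_scd(c: Construct) -> float:
    """Sequence charge decoration of a peptide chain.

    SCD = (1/N) sum_{i<j} q_i q_j sqrt(j - i); low values indicate
    well-interspersed charges, large positive values charge blockiness.
    """
    if len(c.strands) != 1 or c.strands[0].alphabet != "peptide":
        raise ConstructError("SCD is defined for single-chain peptides")
    q = c.charges
    n = len(q)
    idx = np.arange(n)
    i, j = np.triu_indices(n, k=1)
    return float(np.sum(q[i] * q[j] * np.sqrt(idx[j] - idx[i])) / n)


def assemble_construct(kind: str, *, length: int | None = None,
                       sequence: str | None = None, stem_len: int | None = None,
                       seed: int = 0, name: str | None = None,
                       kbend_ds: float = parameters.K_BEND_DS,
                       kbend_ss: float = parameters.K_BEND_SS) -> Construct:
    """Build a construct of the given topology kind.

    Kinds: ``ss``, ``ds``, ``hairpin``, ``half_duplex``, ``pna_ss``,
    ``pna_dna_hybrid``, ``polyp``, ``peptide``.  DNA sequences are balanced
    compositions drawn deterministically from ``seed`` unless ``sequence``
    is given explicitly.
    """
    def dna_seq(n: int) -> Sequence:
        if sequence is not None:
            return Sequence(sequence, "dna")
        if n is None:
            raise ConstructError(f"kind {kind!r} needs a length or sequence")
        return design_balanced_sequence(n, seed)

    if kind == "ss":
        s = dna_seq(length)
        return Construct(name or f"ssDNA-{len(s)}", kind, (s,), [],
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "ds":
        s = dna_seq(length)
        n = len(s)
        pairs = [(i, n - 1 - i) for i in range(n)]
        return Construct(name or f"dsDNA-{n}", kind, (s, reverse_complement(s)),
                         pairs, kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "hairpin":
        n = length or (len(sequence) if sequence else None)
        if n is None:
            raise ConstructError("hairpin needs a length or sequence")
        sl = stem_len if stem_len is not None else 5
        s = Sequence(sequence, "dna") if sequence else _design_hairpin_sequence(n, sl, seed)
        pairs = [(i, len(s) - 1 - i) for i in range(sl)]
        return Construct(name or f"hp{sl}DNA-{len(s)}", kind, (s,), pairs,
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "half_duplex":
        s = dna_seq(length)
        n = len(s)
        half = n // 2
        comp = reverse_complement(Sequence(s.residues[:half], "dna"))
        pairs = [(i, half - 1 - i) for i in range(half)]
        return Construct(name or "hdsDNA", kind, (s, comp), pairs,
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "pna_ss":
        s = dna_seq(length)
        return Construct(name or f"PNA-{len(s)}", kind,
                         (Sequence(s.residues, "pna"),), [],
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "pna_dna_hybrid":
        s = dna_seq(length)
        n = len(s)
        comp = reverse_complement(s)
        pairs = [(i, n - 1 - i) for i in range(n)]
        return Construct(name or f"PNA:DNA-{n}", kind,
                         (s, Sequence(comp.residues, "pna")), pairs,
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "polyp":
        if length is None:
            raise ConstructError("polyp needs a length")
        return Construct(name or f"polyP-{length}", kind,
                         (Sequence("P" * length, "polyp"),), [],
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if kind == "peptide":
        if sequence is None:
            raise ConstructError("peptide needs an explicit sequence")
        return Construct(name or "peptide", kind,
                         (Sequence(sequence, "peptide"),), [],
                         kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    raise ConstructError(f"unknown construct kind {kind!r}")


def canonical_constructs(seed: int = 0) -> dict[str, Construct]:
    """The study's molecule set, generated deterministically from one seed."""
    out: dict[str, Construct] = {}
    for n in (10, 20, 40, 80):
        out[f"ssDNA-{n}"] = assemble_construct("ss", length=n, seed=seed + n)
    for n in (10, 20, 40):
        out[f"dsDNA-{n}"] = assemble_construct("ds", length=n, seed=seed + n)
    out["hp5DNA"] = assemble_construct("hairpin", length=20, stem_len=5, seed=seed)
    out["hdsDNA"] = assemble_construct("half_duplex", length=20, seed=seed + 20)
    out["PNA-20"] = assemble_construct("pna_ss", length=20, seed=seed + 20)
    out["PNA:DNA-20"] = assemble_construct("pna_dna_hybrid", length=20, seed=seed + 20)
    out["polyP-20"] = assemble_construct("polyp", length=20)
    out["pL22"] = assemble_construct("peptide", sequence=PL22_PLACEHOLDER, name="pL22")
    out["polyK-18"] = assemble_construct("peptide", sequence="K" * 18, name="polyK-18")
    return out


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def construct_to_text(c: Construct) -> str:
    """Stable structured-text serialization (byte-identical for equal inputs)."""
    buf = io.StringIO()
    buf.write(f"construct {c.name}\n")
    buf.write(f"kind {c.kind}\n")
    buf.write(f"kbend_ds {c.kbend_ds:.6g}\n")
    buf.write(f"kbend_ss {c.kbend_ss:.6g}\n")
    for s in c.strands:
        buf.write(f"strand {s.alphabet} {s.residues}\n")
    for i, j in c.pairing:
        buf.write(f"pair {i + 1} {j + 1}\n")
    for t, q, lam, sig, m in zip(c.bead_types, c.charges, c.lambdas,
                                 c.sigmas, c.masses):
        buf.write(f"bead {t} {q:.6g} {lam:.6g} {sig:.6g} {m:.6g}\n")
    return buf.getvalue()


def construct_from_text(text: str) -> Construct:
    name = kind = None
    kbend_ds, kbend_ss = parameters.K_BEND_DS, parameters.K_BEND_SS
    strands: list[Sequence] = []
    pairs: list[tuple[int, int]] = []
    beads: list[tuple[str, float, float, float, float]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "construct":
                name = tok[1]
            elif tok[0] == "kind":
                kind = tok[1]
            elif tok[0] == "kbend_ds":
                kbend_ds = float(tok[1])
            elif tok[0] == "kbend_ss":
                kbend_ss = float(tok[1])
            elif tok[0] == "strand":
                strands.append(Sequence(tok[2], tok[1]))
            elif tok[0] == "pair":
                pairs.append((int(tok[1]) - 1, int(tok[2]) - 1))
            elif tok[0] == "bead":
                beads.append((tok[1], float(tok[2]), float(tok[3]),
                              float(tok[4]), float(tok[5])))
            else:
                raise ConstructError(f"unknown record {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            raise ConstructError(f"malformed construct line {ln}: {line!r}") from exc
    if name is None or kind is None or not strands:
        raise ConstructError("incomplete construct document")
    c = Construct(name, kind, tuple(strands), pairs,
                  kbend_ds=kbend_ds, kbend_ss=kbend_ss)
    if beads:
        c.bead_types = [b[0] for b in beads]
        c.charges = np.array([b[1] for b in beads])
        c.lambdas = np.array([b[2] for b in beads])
        c.sigmas = np.array([b[3] for b in beads])
        c.masses = np.array([b[4] for b in beads])
    return c


def write_construct(c: Construct, path) -> None:
    with open(path, "w") as fh:
        fh.write(construct_to_text(c))


def read_construct(path) -> Construct:
    with open(path) as fh:
        return construct_from_text(fh.read())


def write_fasta(sequences: dict[str, Sequence], path) -> None:
    """Write sequences as FASTA (via Biopython)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.residues), id=name, description=s.alphabet)
               for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path, alphabet: str = "dna") -> dict[str, Sequence]:
    """Read FASTA sequences (via Biopython); alphabet from the description
    field when present, else the given default."""
    from Bio.SeqIO import parse as seqio_parse

    out: dict[str, Sequence] = {}
    for rec in seqio_parse(str(path), "fasta"):
        desc = rec.description.split()
        tag = desc[-1] if desc and desc[-1] in ALPHABETS else alphabet
        out[rec.id] = Sequence(str(rec.seq), tag)
    return out


def write_pairing_map(pairs: list[tuple[int, int]], path) -> None:
    """Two 1-based integer columns, '#' comments."""
    with open(path, "w") as fh:
        fh.write("# pairing map: strand-1 index, partner index (1-based)\n")
        for i, j in pairs:
            fh.write(f"{i + 1} {j + 1}\n")


def read_pairing_map(path) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                i, j = int(tok[0]), int(tok[1])
            except (IndexError, ValueError) as exc:
                raise ConstructError(f"malformed pairing line {ln}: {line!r}") from exc
            pairs.append((i - 1, j - 1))
    return pairs
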