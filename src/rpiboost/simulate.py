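"""Synthetic desk-scale inputs: toy complexes and planted-motif corpora.

Two generators make the whole pipeline testable without downloading a single
structure:

* :func:`generate_toy_complex` lays a protein chain and an RNA chain on
  parallel lines ~30 A apart and swings the side-chain pseudo-atom of chosen
  protein residues to 4-5 A from the RNA, planting exact, known interface
  residues. Geometry is two pseudo-atoms per residue (backbone + side chain);
  nothing about the conformation is physically realistic — it only needs to
  exercise the distance rules.

* :func:`generate_motif_corpus` builds labeled sequence-pair corpora where
  positives carry a planted protein class-motif and RNA motif
  (co-occurrence) over i.i.d. uniform background, and negatives are plain
  background at the same length distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .dataset import PairCorpus, SequencePair
from .propensity import AMINO_ACID_CLASSES
from .structure import (
    AMINO1_TO_3,
    ChainRecord,
    ComplexRecord,
    ResidueRecord,
)

PROTEIN_ALPHABET = sorted("ACDEFGHIKLMNPQRSTVWY")
RNA_ALPHABET = ["A", "C", "G", "U"]

_RNA_Y_OFFSET = 30.0  # separation between the two chain axes, in angstroms


@dataclass(frozen=True)
class ToyComplexSpec:
    protein_length: int = 30
    rna_length: int = 20
    planted_contact_positions: frozenset[int] = frozenset({3, 7})
    spacing: float = 10.0          # > 5 A so unplanted residues stay clear
    seed: int = 0
    contact_residue: str = "R"     # amino acid planted at contact positions
    source_id: str = "TOY"
    resolution: float = 2.0

    def __post_init__(self):
        if self.spacing <= 5.0:
            raise ValueError("spacing must exceed the 5 A interface cutoff")
        bad = [p for p in self.planted_contact_positions
               if not 1 <= p <= self.protein_length]
        if bad:
            raise ValueError(f"planted positions outside protein chain: {bad}")


@dataclass(frozen=True)
class MotifCorpusSpec:
    n_positive: int = 500
    n_negative: int = 500
    protein_motif: str = "00000"   # 5-mer over reduced-alphabet class digits
    rna_motif: str = "UUAGG"       # 5-mer over A/C/G/U
    motif_copies_in_positives: int = 3
    background_length_range: tuple[int, int] = (40, 120)
    seed: int = 0

    def __post_init__(self):
        if not set(self.protein_motif) <= set("0123"):
            raise ValueError("protein_motif must use class digits 0-3")
        if not set(self.rna_motif) <= set("ACGU"):
            raise ValueError("rna_motif must use A/C/G/U")
        lo, hi = self.background_length_range
        if lo < 25 or hi < lo:
            raise ValueError("background lengths must be >= 25 and ordered")


def generate_toy_complex(spec: ToyComplexSpec) -> ComplexRecord:
    """Build a toy complex with planted inter-chain contacts.

    Planted protein residues get a side-chain atom 4-5 A from the nearest
    RNA backbone atom; every other protein atom stays > 8 A from the RNA.
    Raises on infeasible geometry (a planted position beyond the RNA's reach).
    """
    rng = np.random.default_rng(spec.seed)
    planted = sorted(spec.planted_contact_positions)
    if any(p > spec.rna_length for p in planted):
        raise ValueError(
            "infeasible geometry: planted positions exceed the RNA length "
            f"({max(planted)} > {spec.rna_length})"
        )

    # background residue identities (contact positions get contact_residue)
    prot_codes = [str(rng.choice(PROTEIN_ALPHABET)) for _ in range(spec.protein_length)]
    for p in planted:
        prot_codes[p - 1] = spec.contact_residue
    rna_codes = [str(rng.choice(RNA_ALPHABET)) for _ in range(spec.rna_length)]

    def r3(x):  # PDB files carry 3 decimals; keep records identical to disk
        return np.round(x, 3)

    prot_residues = []
    for i, code in enumerate(prot_codes, start=1):
        x = i * spec.spacing
        atoms = [[x, 0.0, 0.0], [x, 0.0, 1.5]]
        if i in spec.planted_contact_positions:
            d = float(rng.uniform(4.2, 4.8))
            atoms[1] = [i * spec.spacing, _RNA_Y_OFFSET - d, 0.0]
        prot_residues.append(
            ResidueRecord(i, code, AMINO1_TO_3[code], False, r3(np.array(atoms)))
        )
    rna_residues = []
    for j, code in enumerate(rna_codes, start=1):
        x = j * spec.spacing
        atoms = np.array([[x, _RNA_Y_OFFSET, 0.0], [x, _RNA_Y_OFFSET, 1.5]])
        rna_residues.append(ResidueRecord(j, code, code, False, r3(atoms)))

    return ComplexRecord(
        source_id=spec.source_id,
        chains=[
            ChainRecord("A", "protein", prot_residues),
            ChainRecord("B", "rna", rna_residues),
        ],
        resolution=spec.resolution,
        method="X-RAY DIFFRACTION",
    )


_PROTEIN_ATOM_NAMES = ("CA", "CB")
_RNA_ATOM_NAMES = ("P", "C1'")


def complex_to_pdb_string(c: ComplexRecord) -> str:
    """Render a ComplexRecord as PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = c.source_id
    if c.resolution:
        st.resolution = c.resolution
    model = gemmi.Model("1")
    for ch in c.chains:
        gch = gemmi.Chain(ch.chain_id)
        names = _PROTEIN_ATOM_NAMES if ch.kind == "protein" else _RNA_ATOM_NAMES
        element = ("C", "C") if ch.kind == "protein" else ("P", "C")
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.raw_code
            gres.seqid = gemmi.SeqId(res.chain_position, " ")
            for k, coords in enumerate(res.atoms):
                atom = gemmi.Atom()
                atom.name = names[min(k, len(names) - 1)]
                atom.element = gemmi.Element(element[min(k, len(element) - 1)])
                atom.pos = gemmi.Position(*coords)
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_toy_complex(spec: ToyComplexSpec, path) -> ComplexRecord:
    c = generate_toy_complex(spec)
    with open(path, "w") as fh:
        fh.write(complex_to_pdb_string(c))
    return c


def _realize_class_motif(motif: str, rng: np.random.Generator) -> str:
    """Turn a class-digit motif into concrete amino acids of those classes."""
    out = []
    for digit in motif:
        group = sorted(AMINO_ACID_CLASSES[int(digit)])
        out.append(str(rng.choice(group)))
    return "".join(out)


def _background(alphabet: list[str], length: int, rng: np.random.Generator) -> list[str]:
    return [str(x) for x in rng.choice(alphabet, size=length)]


def _plant(seq: list[str], motif: str, copies: int, rng: np.random.Generator) -> list[str]:
    """Overwrite `copies` non-overlapping stretches with the motif."""
    k = len(motif)
    slots = len(seq) - k + 1
    taken: set[int] = set()
    placed = 0
    attempts = 0
    while placed < copies and attempts < 1000:
        attempts += 1
        start = int(rng.integers(0, slots))
        if any(abs(start - t) < k for t in taken):
            continue
        seq[start : start + k] = list(motif)
        taken.add(start)
        placed += 1
    if placed < copies:
        raise ValueError("sequence too short to plant all motif copies")
    return seq


def generate_motif_corpus(spec: MotifCorpusSpec) -> PairCorpus:
    """Labeled sequence-pair corpus with a planted motif co-occurrence.

    Positives carry ``motif_copies_in_positives`` copies of the protein class
    motif and of the RNA motif; negatives are motif-free i.i.d. background
    (chance occurrences are possible, as in real null data) at the same
    length distribution.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.background_length_range
    rna_lo = max(15, lo)
    pairs: list[SequencePair] = []
    for i in range(spec.n_positive + spec.n_negative):
        positive = i < spec.n_positive
        plen = int(rng.integers(lo, hi + 1))
        rlen = int(rng.integers(rna_lo, hi + 1))
        prot = _background(PROTEIN_ALPHABET, plen, rng)
        rna = _background(RNA_ALPHABET, rlen, rng)
        if positive:
            prot_motif = _realize_class_motif(spec.protein_motif, rng)
            prot = _plant(prot, prot_motif, spec.motif_copies_in_positives, rng)
            rna = _plant(rna, spec.rna_motif, spec.motif_copies_in_positives, rng)
        tag = f"{'pos' if positive else 'neg'}{i:05d}"
        pairs.append(
            SequencePair(
                rna_id=f"{tag}_R",
                protein_id=f"{tag}_P",
                rna_seq="".join(rna),
                protein_seq="".join(prot),
                label="positive" if positive else "negative",
                source_complex="synthetic",
            )
        )
    return PairCorpus(
        pairs=pairs,
        provenance={"generator": "motif_corpus", **dataclasses.asdict(spec)},
    )
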