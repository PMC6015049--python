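"""Binding-interface detection and amino-acid interaction propensities.

Two distance rules drive everything here, both strict inequalities:

* a protein chain and an RNA chain in the same complex *interact* when any
  pair of their atoms is closer than 8 angstroms (generous enough to span
  bridging waters or ions);
* a residue is an *interface* residue when any of its atoms lies within
  5 angstroms of the partner chain (direct contacts only).

Interface residues are merged into binding-interface segments: up to three
consecutive non-contacting residues are allowed inside a segment provided the
bordering residues contact the partner. The interaction propensity of amino
acid j is

    P_j = (I_j / I_n) / (N_j / N_n)

where I_j counts interface residues of type j (I_n the total) and N_j the
non-contacting residues of type j inside interface segments (N_n the total).
High-propensity residues (R, K, H) anchor the four-class reduced alphabet
used by the sequence encoder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ChainRecord, ComplexRecord, STANDARD_AMINO_ACIDS

logger = logging.getLogger(__name__)

#: The four-class reduced amino-acid alphabet derived from interaction
#: propensities at RNA-protein interfaces: positively charged residues have
#: the highest propensity; aspartate patterns with the hydrophobics through
#: backbone-mediated contacts; cysteine and glutamate have the lowest
#: propensity; the remaining polar residues form the fourth class.
AMINO_ACID_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("RKH"),
    frozenset("DPMFAVLI"),
    frozenset("CE"),
    frozenset("NWSQYGT"),
)

_CLASS_OF = {aa: idx for idx, group in enumerate(AMINO_ACID_CLASSES) for aa in group}


def amino_acid_class(code: str) -> int:
    """Return the reduced-alphabet class (0..3) of a standard amino acid."""
    try:
        return _CLASS_OF[code.upper()]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {code!r}") from None


@dataclass
class ContactMap:
    """Interface residues of one RNA/protein chain pair (5 A rule)."""

    rna_chain_id: str
    protein_chain_id: str
    interface_protein_positions: set[int]
    interface_rna_positions: set[int]
    min_distance: float


@dataclass
class InterfaceSegment:
    """A maximal binding-interface stretch on one chain."""

    chain_id: str
    start: int
    end: int
    interacting_positions: set[int] = field(default_factory=set)

    @property
    def extent(self) -> int:
        return self.end - self.start + 1


@dataclass
class PropensityTable:
    """Interface counts and propensities per amino acid."""

    I: dict[str, int]          # interacting counts per amino acid
    N: dict[str, int]          # non-interacting counts inside segments
    I_n: int
    N_n: int
    P: dict[str, float]

    def to_tsv(self) -> str:
        lines = ["amino_acid\tI_j\tN_j\tP_j\tclass"]
        for aa in sorted(STANDARD_AMINO_ACIDS):
            lines.append(
                f"{aa}\t{self.I.get(aa, 0)}\t{self.N.get(aa, 0)}"
                f"\t{self.P.get(aa, 0.0):.6g}\t{amino_acid_class(aa)}"
            )
        return "\n".join(lines) + "\n"


class UndefinedPropensityError(ValueError):
    """Raised when no interacting or no non-interacting residues exist."""


def _min_chain_distance(a: ChainRecord, b: ChainRecord) -> float:
    xa, xb = a.all_atoms(), b.all_atoms()
    if xa.size == 0:
        raise ValueError(f"chain {a.chain_id} has no atoms")
    if xb.size == 0:
        raise ValueError(f"chain {b.chain_id} has no atoms")
    tree = cKDTree(xb)
    d, _ = tree.query(xa, k=1)
    return float(np.min(d))


def find_interacting_pairs(
    c: ComplexRecord, cutoff: float = 8.0
) -> list[tuple[str, str]]:
    """All (rna_chain_id, protein_chain_id) pairs with any inter-atomic
    distance strictly below ``cutoff``."""
    pairs = []
    for rna in c.rna_chains():
        for prot in c.protein_chains():
            if _min_chain_distance(rna, prot) < cutoff:
                pairs.append((rna.chain_id, prot.chain_id))
    return pairs


def _interface_positions(
    chain: ChainRecord, partner_atoms: np.ndarray, cutoff: float
) -> set[int]:
    tree = cKDTree(partner_atoms)
    positions = set()
    for res in chain.residues:
        d, _ = tree.query(res.atoms, k=1)
        if float(np.min(d)) < cutoff:
            positions.add(res.chain_position)
    return positions


def interface_residues(
    c: ComplexRecord,
    rna_chain_id: str,
    protein_chain_id: str,
    cutoff: float = 5.0,
) -> ContactMap:
    """Interface residues of both chains under the strict 5 A rule.

    A residue is in the interface iff any of its atoms lies within ``cutoff``
    of any atom of the partner chain.
    """
    rna = c.chain(rna_chain_id)
    prot = c.chain(protein_chain_id)
    rna_atoms, prot_atoms = rna.all_atoms(), prot.all_atoms()
    if rna_atoms.size == 0:
        raise ValueError(f"chain {rna_chain_id} has no atoms")
    if prot_atoms.size == 0:
        raise ValueError(f"chain {protein_chain_id} has no atoms")
    return ContactMap(
        rna_chain_id=rna_chain_id,
        protein_chain_id=protein_chain_id,
        interface_protein_positions=_interface_positions(prot, rna_atoms, cutoff),
        interface_rna_positions=_interface_positions(rna, prot_atoms, cutoff),
        min_distance=_min_chain_distance(rna, prot),
    )


def interface_segments(
    interacting_positions: set[int] | list[int],
    max_gap: int = 3,
    chain_id: str = "",
) -> list[InterfaceSegment]:
    """Merge interacting positions into maximal binding-interface segments.

    Consecutive interacting positions are joined when at most ``max_gap``
    non-interacting residues lie between them; segment endpoints are always
    interacting. Interacting at {5, 9} with max_gap 3 therefore yields one
    segment [5, 9] of extent 5 (positions 6-8 admitted though not contacting).
    """
    positions = sorted(set(int(p) for p in interacting_positions))
    if any(p <= 0 for p in positions):
        raise ValueError("positions must be positive 1-based integers")
    if not positions:
        return []
    segments: list[InterfaceSegment] = []
    start = prev = positions[0]
    members = {start}
    for p in positions[1:]:
        if p - prev - 1 <= max_gap:
            members.add(p)
            prev = p
        else:
            segments.append(InterfaceSegment(chain_id, start, prev, members))
            start = prev = p
            members = {p}
    segments.append(InterfaceSegment(chain_id, start, prev, members))
    return segments


def compute_propensities(
    contact_maps: list[ContactMap],
    chains: dict[str, ChainRecord],
    max_gap: int = 3,
) -> PropensityTable:
    """Compute per-amino-acid interaction propensities over a set of
    interfaces.

    I_j counts interface (contacting) amino acids of type j across all contact
    maps; N_j counts the non-contacting amino acids admitted into interface
    segments by the gap rule. ``chains`` maps protein chain IDs to their
    records.
    """
    I: dict[str, int] = {}
    N: dict[str, int] = {}
    for cm in contact_maps:
        chain = chains[cm.protein_chain_id]
        seq = chain.sequence
        contacts = cm.interface_protein_positions
        for p in contacts:
            aa = seq[p - 1]
            if aa in STANDARD_AMINO_ACIDS:
                I[aa] = I.get(aa, 0) + 1
        for seg in interface_segments(contacts, max_gap, cm.protein_chain_id):
            for p in range(seg.start, seg.end + 1):
                if p not in contacts:
                    aa = seq[p - 1]
                    if aa in STANDARD_AMINO_ACIDS:
                        N[aa] = N.get(aa, 0) + 1
    I_n, N_n = sum(I.values()), sum(N.values())
    if I_n == 0 or N_n == 0:
        raise UndefinedPropensityError(
            f"propensity undefined: I_n={I_n}, N_n={N_n}"
        )
    P: dict[str, float] = {}
    for aa in STANDARD_AMINO_ACIDS:
        i_j, n_j = I.get(aa, 0), N.get(aa, 0)
        if i_j == 0:
            P[aa] = 0.0
        elif n_j == 0:
            logger.warning("amino acid %s interacts but never borders: P_j=inf", aa)
            P[aa] = math.inf
        else:
            P[aa] = (i_j / I_n) / (n_j / N_n)
    return PropensityTable(I=I, N=N, I_n=I_n, N_n=N_n, P=P)


def segments_to_tsv(segments: list[InterfaceSegment]) -> str:
    """BED-like report; coordinates are 1-based inclusive."""
    lines = ["# chain\tstart\tend\textent (1-based inclusive coordinates)"]
    for s in segments:
        lines.append(f"{s.chain_id}\t{s.start}\t{s.end}\t{s.extent}")
    return "\n".join(lines) + "\n"
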