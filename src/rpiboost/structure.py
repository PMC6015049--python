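"""Reading and validating RNA-protein complex structures.

Structures come in as PDB or mmCIF files (parsed with gemmi) and are reduced
to plain records: chains of residues with parent-mapped one-letter codes and
atom coordinates. Chain *kind* (protein vs RNA) is decided from residue
chemistry, never from chain labels. Modified residues are mapped to their
standard parent (pseudouridine -> U, selenomethionine -> M, ...) instead of
being dropped or turned into "X".
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel one-letter code for residues whose parent is unknown.
#: Encoding skips any k-mer window containing it.
UNKNOWN_RESIDUE = "?"

STANDARD_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STANDARD_RIBONUCLEOTIDES = set("ACGU")

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO1_TO_3 = {v: k for k, v in AMINO3_TO_1.items()}

# Parent mapping for common modified residues, seeded from the chemical
# component dictionary's parent field. Extensible via the `extra` argument
# of map_modified_residue / parse_complex.
MODIFIED_PARENTS_RNA = {
    "PSU": "U",  # pseudouridine
    "H2U": "U",  # dihydrouridine
    "4SU": "U",  # 4-thiouridine
    "5MU": "U",  # ribothymidine
    "OMU": "U",
    "5MC": "C",  # 5-methylcytidine
    "OMC": "C",
    "1MA": "A",
    "MIA": "A",  # 2-methylthio-N6-isopentenyladenosine
    "6MZ": "A",
    "2MG": "G",
    "M2G": "G",
    "7MG": "G",
    "OMG": "G",
    "QUO": "G",  # queuosine
    "YG":  "G",  # wybutosine
    "G7M": "G",
    "I":   "A",  # inosine (deaminated adenosine)
}
MODIFIED_PARENTS_PROTEIN = {
    "MSE": "M",  # selenomethionine
    "MLY": "K",
    "M3L": "K",
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",
    "CME": "C",
    "OCS": "C",
    "HYP": "P",  # hydroxyproline
    "PCA": "Q",  # pyroglutamate
    "KCX": "K",
    "FME": "M",
}


@dataclass
class ResidueRecord:
    """One residue: chain-ordinal position, parent code, and atom coordinates."""

    chain_position: int           # 1-based ordinal within the chain
    parent_code: str              # one-letter code after parent mapping
    raw_code: str                 # original component name (up to 3 letters)
    is_modified: bool
    atoms: np.ndarray             # (n_atoms, 3) coordinates in angstroms

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)


@dataclass
class ChainRecord:
    chain_id: str
    kind: str                     # "protein" | "rna" | "other"
    residues: list[ResidueRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """Parent-mapped one-letter sequence (unknowns appear as '?')."""
        return "".join(r.parent_code for r in self.residues)

    def all_atoms(self) -> np.ndarray:
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack([r.atoms for r in self.residues])


@dataclass
class ComplexRecord:
    source_id: str
    chains: list[ChainRecord]
    resolution: float | None = None
    method: str = ""
    rejected: bool = False
    rejection_reason: str | None = None

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex {self.source_id}")

    def protein_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.kind == "protein"]

    def rna_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains if c.kind == "rna"]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read or holds no polymer."""


def map_modified_residue(
    raw_code: str, kind: str, extra: dict[str, str] | None = None
) -> str:
    """Map a residue component name to its one-letter parent code.

    Standard residues map to themselves; known modified residues map to the
    standard parent (e.g. PSU -> U); anything unresolvable maps to the
    UNKNOWN_RESIDUE sentinel, which downstream encoding skips.

    Parameters
    ----------
    raw_code : component name, e.g. "ALA", "PSU", "A".
    kind : "protein" or "rna"; controls which parent table and which standard
        alphabet are consulted.
    extra : optional user-supplied additions to the parent table.
    """
    if not raw_code:
        raise ValueError("empty residue code")
    code = raw_code.strip().upper()
    if kind == "protein":
        if code in AMINO3_TO_1:
            return AMINO3_TO_1[code]
        if len(code) == 1 and code in STANDARD_AMINO_ACIDS:
            return code
        table = MODIFIED_PARENTS_PROTEIN
        standard = STANDARD_AMINO_ACIDS
    elif kind == "rna":
        if code in STANDARD_RIBONUCLEOTIDES:
            return code
        if code == "T":  # FASTA files sometimes carry T for U
            return "U"
        table = MODIFIED_PARENTS_RNA
        standard = STANDARD_RIBONUCLEOTIDES
    else:
        raise ValueError(f"kind must be 'protein' or 'rna', got {kind!r}")
    if extra and code in extra:
        return extra[code]
    if code in table:
        return table[code]
    # fall back to gemmi's tabulated parent one-letter codes (lowercase for
    # modified residues)
    info = gemmi.find_tabulated_residue(code)
    if info is not None:
        letter = info.one_letter_code.upper()
        if letter in standard:
            return letter
    logger.warning("unmappable %s residue code %r -> unknown", kind, raw_code)
    return UNKNOWN_RESIDUE


def _classify_residue(name: str) -> str:
    """Classify a component name as amino acid / ribonucleotide / other."""
    code = name.strip().upper()
    if code in AMINO3_TO_1 or code in MODIFIED_PARENTS_PROTEIN:
        return "protein"
    if code in STANDARD_RIBONUCLEOTIDES or code in MODIFIED_PARENTS_RNA:
        return "rna"
    info = gemmi.find_tabulated_residue(code)
    if info is None:
        return "other"
    if info.is_amino_acid():
        return "protein"
    if info.is_nucleic_acid():
        # distinguish ribo from deoxy by the component naming convention
        return "other" if code.startswith("D") else "rna"
    return "other"


def _chain_kind(residue_kinds: list[str]) -> str:
    """A chain's kind is the majority chemistry of its residues."""
    if not residue_kinds:
        return "other"
    counts = {k: residue_kinds.count(k) for k in ("protein", "rna", "other")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else "other"


def parse_complex(
    path: str | Path,
    fmt: str = "auto",
    extra_parents: dict[str, str] | None = None,
) -> ComplexRecord:
    """Parse a PDB or mmCIF file into a ComplexRecord.

    Waters and free ions are excluded; only the first model is used; for
    alternate-location conformers only the first conformation is kept.
    Hydrogens, when present, are retained (they take part in distance checks).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such structure file: {path}")
    if path.stat().st_size == 0:
        raise StructureParseError(f"empty structure file: {path}")
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_ligands_and_waters()

    chains: list[ChainRecord] = []
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    model = st[0]
    for ch in model:
        residue_kinds = [_classify_residue(r.name) for r in ch]
        kind = _chain_kind(residue_kinds)
        residues: list[ResidueRecord] = []
        # author-deposited residue order: seqid number, insertion code after base
        indexed = sorted(
            enumerate(ch),
            key=lambda t: (t[1].seqid.num, t[1].seqid.icode or " ", t[0]),
        )
        pos = 0
        for _, res in indexed:
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res], dtype=float)
            if coords.size == 0:
                continue
            pos += 1
            if kind in ("protein", "rna"):
                parent = map_modified_residue(res.name, kind, extra_parents)
                is_mod = _is_modified(res.name, kind)
            else:
                parent, is_mod = UNKNOWN_RESIDUE, False
            residues.append(
                ResidueRecord(
                    chain_position=pos,
                    parent_code=parent,
                    raw_code=res.name.strip().upper(),
                    is_modified=is_mod,
                    atoms=coords,
                )
            )
        if residues:
            chains.append(ChainRecord(chain_id=ch.name, kind=kind, residues=residues))

    if not chains:
        raise StructureParseError(f"no polymer chains in {path}")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    method = ""
    try:
        method = st.get_info("_exptl.method") or ""
    except Exception:  # pragma: no cover - header oddities
        pass
    return ComplexRecord(
        source_id=st.name or path.stem,
        chains=chains,
        resolution=resolution,
        method=method,
    )


def _is_modified(name: str, kind: str) -> bool:
    code = name.strip().upper()
    if kind == "protein":
        return code not in AMINO3_TO_1
    return code not in STANDARD_RIBONUCLEOTIDES


def validate_complex(
    c: ComplexRecord,
    max_resolution: float = 3.0,
    min_protein_len: int = 25,
    min_rna_len: int = 15,
) -> ComplexRecord:
    """Apply the chain-validity and resolution filters.

    A protein chain is valid at >= ``min_protein_len`` residues, an RNA chain
    at >= ``min_rna_len`` (inclusive minima). The returned copy keeps only
    valid chains. Complexes with resolution above ``max_resolution``, without
    a resolution record, or lacking a valid protein or a valid RNA chain are
    flagged ``rejected`` (rejection is an outcome, not an error).
    """
    out = copy.deepcopy(c)
    if c.resolution is None:
        out.rejected = True
        out.rejection_reason = "no resolution record (not an X-ray crystal structure)"
        return out
    if c.resolution > max_resolution:
        out.rejected = True
        out.rejection_reason = f"resolution {c.resolution:.2f} A > {max_resolution} A"
        return out
    valid = []
    for ch in out.chains:
        if ch.kind == "protein" and len(ch) >= min_protein_len:
            valid.append(ch)
        elif ch.kind == "rna" and len(ch) >= min_rna_len:
            valid.append(ch)
    out.chains = valid
    has_protein = any(ch.kind == "protein" for ch in valid)
    has_rna = any(ch.kind == "rna" for ch in valid)
    if not (has_protein and has_rna):
        out.rejected = True
        out.rejection_reason = "absence of any valid RNA or protein chain"
    else:
        out.rejected = False
        out.rejection_reason = None
    return out


def chains_to_fasta(c: ComplexRecord) -> str:
    """Render the complex's chains as FASTA with parent-mapped sequences."""
    lines = []
    for ch in c.chains:
        lines.append(f">{c.source_id}_{ch.chain_id} {ch.kind}")
        lines.append(ch.sequence)
    return "\n".join(lines) + "\n"
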