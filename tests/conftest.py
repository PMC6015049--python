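"""Shared fixtures: toy complexes, manual complexes, and a small motif corpus."""

from __future__ import annotations

import numpy as np
import pytest

from rpiboost import (
    ChainRecord,
    ComplexRecord,
    MotifCorpusSpec,
    ResidueRecord,
    ToyComplexSpec,
    generate_motif_corpus,
    generate_toy_complex,
    validate_complex,
)


def make_chain(
    chain_id: str,
    kind: str,
    codes: str,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: float = 6.0,
    axis: int = 0,
) -> ChainRecord:
    """A straight-line chain with one atom per residue, for hand-built geometry."""
    residues = []
    for i, code in enumerate(codes, start=1):
        pos = list(origin)
        pos[axis] += i * spacing
        residues.append(
            ResidueRecord(
                chain_position=i,
                parent_code=code,
                raw_code=code,
                is_modified=False,
                atoms=np.array([pos]),
            )
        )
    return ChainRecord(chain_id=chain_id, kind=kind, residues=residues)


def make_complex(chains, source_id="MANUAL", resolution=2.0) -> ComplexRecord:
    return ComplexRecord(
        source_id=source_id, chains=list(chains), resolution=resolution
    )


@pytest.fixture(scope="session")
def toy_complex():
    return generate_toy_complex(
        ToyComplexSpec(planted_contact_positions=frozenset({3, 7}), seed=1)
    )


@pytest.fixture(scope="session")
def toy_structure_corpus():
    """Eight validated monomeric toy complexes with distinct random sequences."""
    out = []
    for i in range(8):
        spec = ToyComplexSpec(
            protein_length=30,
            rna_length=40,
            planted_contact_positions=frozenset({3 + i, 7 + i}),
            seed=200 + i,
            source_id=f"TOY{i}",
        )
        out.append(validate_complex(generate_toy_complex(spec)))
    return out


@pytest.fixture(scope="session")
def small_motif_corpus():
    """Sixty labeled pairs with a strong planted motif (fast learner fixture)."""
    spec = MotifCorpusSpec(
        n_positive=30,
        n_negative=30,
        background_length_range=(30, 60),
        seed=42,
    )
    return generate_motif_corpus(spec)


@pytest.fixture(scope="session")
def small_features(small_motif_corpus):
    from rpiboost.encoding import encode_many

    pairs = [(p.protein_seq, p.rna_seq) for p in small_motif_corpus.pairs]
    y = np.array([1 if p.label == "positive" else 0 for p in small_motif_corpus.pairs])
    return encode_many(pairs), y
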