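"""Window-5 k-mer feature encoding of RNA/protein sequence pairs.

Each molecule is reduced to a 4-letter alphabet (the propensity-derived
four classes for proteins; A/C/G/U for RNA, with modified residues already
mapped to parents) and scanned with a sliding window of five residues — the
minimum structural unit (MSU). Every window packs into a base-4 index
(leftmost residue most significant), giving a 4^5 = 1024-bin histogram per
molecule. The two histograms are min-max scaled into [0, 1] per molecule
and concatenated, protein block first: a 2048-dimensional pair vector with
protein features at indices 0-1023 and RNA features at 1024-2047.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .propensity import _CLASS_OF

logger = logging.getLogger(__name__)

RNA_LETTER_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class AlphabetMap:
    """Residue-to-class maps plus the window size."""

    protein_map: dict[str, int] = field(default_factory=lambda: dict(_CLASS_OF))
    rna_map: dict[str, int] = field(default_factory=lambda: dict(RNA_LETTER_INDEX))
    window: int = 5

    @property
    def block_size(self) -> int:
        return 4 ** self.window


def default_alphabet(window: int = 5) -> AlphabetMap:
    return AlphabetMap(window=window)


def kmer_counts(
    seq: str, mapping: dict[str, int], window: int = 5
) -> np.ndarray:
    """Sliding-window k-mer histogram over a 4-letter reduced alphabet.

    Windows containing a residue missing from ``mapping`` (e.g. the unknown
    sentinel) are skipped. Counts sum to the number of valid windows.
    """
    size = 4 ** window
    counts = np.zeros(size, dtype=np.int64)
    n = len(seq)
    if n < window:
        logger.warning("sequence of length %d shorter than window %d", n, window)
        return counts
    classes = [mapping.get(ch.upper()) for ch in seq]
    powers = [4 ** (window - 1 - i) for i in range(window)]
    for start in range(n - window + 1):
        win = classes[start : start + window]
        if any(c is None for c in win):
            continue
        idx = sum(c * p for c, p in zip(win, powers))
        counts[idx] += 1
    return counts


def normalize_vector(counts: np.ndarray) -> np.ndarray:
    """Scale a count vector into [0, 1] as (v - min) / max.

    With a typical minimum of zero this is plain division by the peak count,
    damping the high absolute frequencies of long chains. An all-zero vector
    is returned unchanged (no division).
    """
    v = np.asarray(counts, dtype=float)
    if np.any(v < 0):
        raise ValueError("counts must be non-negative")
    peak = v.max() if v.size else 0.0
    if peak == 0:
        return np.zeros_like(v)
    return (v - v.min()) / peak


def encode_pair(
    protein_seq: str, rna_seq: str, alphabet: AlphabetMap | None = None
) -> np.ndarray:
    """Encode one RNA/protein pair as the concatenated normalized vector.

    The protein block occupies the first 4^window entries, the RNA block the
    next 4^window. Returns a float vector of length 2 * 4^window (2048 at
    window 5).
    """
    if not protein_seq or not rna_seq:
        raise ValueError("both sequences must be non-empty")
    alphabet = alphabet or default_alphabet()
    p = normalize_vector(kmer_counts(protein_seq, alphabet.protein_map, alphabet.window))
    r = normalize_vector(kmer_counts(rna_seq, alphabet.rna_map, alphabet.window))
    if not p.any() and not r.any():
        warnings.warn(
            "pair encodes to an all-zero vector (sequences too short or all "
            "windows contain unknown residues)",
            stacklevel=2,
        )
    return np.concatenate([p, r])


def encode_many(
    pairs: list[tuple[str, str]], alphabet: AlphabetMap | None = None
) -> np.ndarray:
    """Feature matrix for a list of (protein_seq, rna_seq) pairs."""
    alphabet = alphabet or default_alphabet()
    return np.vstack([encode_pair(p, r, alphabet) for p, r in pairs])
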