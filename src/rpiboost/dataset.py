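"""Positive/negative training-set construction from complex structures.

Positives are the interacting (8 A rule) RNA/protein chain pairs of the
validated complexes, with exact duplicate sequence pairs collapsed. Negatives
are generated by re-pairing chains — cross-complex for monomeric complexes
(one RNA + one protein), the within-complex R1<->P2 swap for multimeric
ones — and then filtered so that no negative is an exact positive, no
negative partner resembles (>= 30% global-alignment identity) a positively
paired partner of the same molecule, and negatives sharing a partner are
mutually dissimilar. A balanced subset matching the positives' unique-chain
ratio is drawn last.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .propensity import find_interacting_pairs
from .structure import ComplexRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequencePair:
    rna_id: str
    protein_id: str
    rna_seq: str
    protein_seq: str
    label: str                  # "positive" | "negative"
    source_complex: str = ""

    def key(self) -> tuple[str, str]:
        return (self.rna_seq, self.protein_seq)


@dataclass
class PairCorpus:
    pairs: list[SequencePair] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def positives(self) -> list[SequencePair]:
        return [p for p in self.pairs if p.label == "positive"]

    def negatives(self) -> list[SequencePair]:
        return [p for p in self.pairs if p.label == "negative"]


def build_positive_set(complexes: list[ComplexRecord]) -> PairCorpus:
    """One positive pair per interacting RNA/protein chain pair, deduplicated.

    Exact duplicate (rna_seq, protein_seq) tuples collapse to the first-seen
    source complex.
    """
    seen: set[tuple[str, str]] = set()
    pairs: list[SequencePair] = []
    for c in complexes:
        if c.rejected:
            continue
        for rna_id, prot_id in find_interacting_pairs(c):
            rna, prot = c.chain(rna_id), c.chain(prot_id)
            key = (rna.sequence, prot.sequence)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                SequencePair(
                    rna_id=f"{c.source_id}_{rna_id}",
                    protein_id=f"{c.source_id}_{prot_id}",
                    rna_seq=rna.sequence,
                    protein_seq=prot.sequence,
                    label="positive",
                    source_complex=c.source_id,
                )
            )
    if not pairs:
        warnings.warn("no interacting RNA/protein pairs found", stacklevel=2)
    return PairCorpus(pairs=pairs, provenance={"n_complexes": len(complexes)})


def generate_negative_candidates(
    positives: PairCorpus, complexes: list[ComplexRecord]
) -> list[SequencePair]:
    """Candidate non-interacting pairs by chain re-pairing.

    Monomeric complexes (exactly one RNA + one protein chain) contribute
    cross-complex pairs: each RNA with every protein of every *other*
    monomeric complex. Multimeric complexes contribute within-complex swaps:
    each RNA with the proteins of the same complex it does not interact with.
    """
    live = [c for c in complexes if not c.rejected]
    monomeric = [c for c in live if len(c.rna_chains()) == 1 and len(c.protein_chains()) == 1]
    multimeric = [c for c in live if c not in monomeric]

    candidates: list[SequencePair] = []

    def add(c_rna, rna, c_prot, prot):
        candidates.append(
            SequencePair(
                rna_id=f"{c_rna.source_id}_{rna.chain_id}",
                protein_id=f"{c_prot.source_id}_{prot.chain_id}",
                rna_seq=rna.sequence,
                protein_seq=prot.sequence,
                label="negative",
                source_complex=f"{c_rna.source_id}|{c_prot.source_id}",
            )
        )

    for ci in monomeric:
        rna = ci.rna_chains()[0]
        for cj in monomeric:
            if cj is ci:
                continue
            add(ci, rna, cj, cj.protein_chains()[0])

    for c in multimeric:
        interacting = set(find_interacting_pairs(c))
        for rna in c.rna_chains():
            for prot in c.protein_chains():
                if (rna.chain_id, prot.chain_id) not in interacting:
                    add(c, rna, c, prot)
    return candidates


_ALIGNERS: dict[str, Align.PairwiseAligner] = {}


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match +1 / mismatch 0 / gap open -10 / gap extend -1
    if "global" not in _ALIGNERS:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        _ALIGNERS["global"] = a
    return _ALIGNERS["global"]


def _molecule_kind(seq: str) -> str:
    return "rna" if set(seq.upper()) <= set("ACGU") else "protein"


def sequence_identity(a: str, b: str, kind: str | None = None) -> float:
    """Global-alignment percent identity (0-100).

    Identity = 100 * matches / alignment length, counting gap columns in the
    length. Both sequences must be the same molecule kind (inferred from the
    alphabet when ``kind`` is not given).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if kind is None:
        ka, kb = _molecule_kind(a), _molecule_kind(b)
        # a short all-ACG protein is indistinguishable from RNA; only flag
        # the unambiguous mismatch
        if ka != kb and not (set(a.upper()) <= set("ACG") or set(b.upper()) <= set("ACG")):
            raise ValueError(f"mixed molecule kinds: {ka} vs {kb}")
    aln = _aligner().align(a.upper(), b.upper())[0]
    matches = aln.counts().identities
    columns = aln.shape[1]
    return 100.0 * matches / columns


def _passes_similarity(
    pair: SequencePair,
    pos_by_rna: dict[str, list[str]],
    pos_by_protein: dict[str, list[str]],
    threshold: float,
) -> bool:
    for pos_prot in pos_by_rna.get(pair.rna_seq, []):
        if sequence_identity(pair.protein_seq, pos_prot, "protein") >= threshold:
            return False
    for pos_rna in pos_by_protein.get(pair.protein_seq, []):
        if sequence_identity(pair.rna_seq, pos_rna, "rna") >= threshold:
            return False
    return True


def filter_negatives(
    candidates: list[SequencePair],
    positives: PairCorpus,
    sim_threshold: float = 30.0,
) -> list[SequencePair]:
    """Keep candidates that satisfy the three negative-set rules.

    1. the pair is not an exact positive;
    2. the candidate's protein has < threshold identity to every protein
       positively paired with the candidate's RNA, and symmetrically for the
       RNA;
    3. within the surviving set, negatives sharing an RNA partner have
       mutually < threshold protein identity (and symmetrically for shared
       proteins) — resolved by a first-kept-wins scan in deterministic order.
    """
    pos_keys = {p.key() for p in positives.positives()}
    pos_by_rna: dict[str, list[str]] = {}
    pos_by_protein: dict[str, list[str]] = {}
    for p in positives.positives():
        pos_by_rna.setdefault(p.rna_seq, []).append(p.protein_seq)
        pos_by_protein.setdefault(p.protein_seq, []).append(p.rna_seq)

    ordered = sorted(
        candidates, key=lambda p: (p.source_complex, p.protein_id, p.rna_id)
    )
    kept: list[SequencePair] = []
    seen: set[tuple[str, str]] = set()
    for cand in ordered:
        if cand.key() in pos_keys or cand.key() in seen:          # rule 1 + dedup
            continue
        if not _passes_similarity(cand, pos_by_rna, pos_by_protein, sim_threshold):
            continue                                              # rule 2
        ok = True                                                 # rule 3
        for k in kept:
            if k.rna_seq == cand.rna_seq:
                if sequence_identity(cand.protein_seq, k.protein_seq, "protein") >= sim_threshold:
                    ok = False
                    break
            if k.protein_seq == cand.protein_seq:
                if sequence_identity(cand.rna_seq, k.rna_seq, "rna") >= sim_threshold:
                    ok = False
                    break
        if ok:
            kept.append(cand)
            seen.add(cand.key())
    return kept


def _unique_ratio(pairs: list[SequencePair]) -> float:
    prot = len({p.protein_seq for p in pairs})
    rna = len({p.rna_seq for p in pairs})
    return prot / rna if rna else float("inf")


def balance_subset(
    negatives: list[SequencePair],
    positives: PairCorpus,
    seed: int,
) -> PairCorpus:
    """Draw |positives| negatives whose unique-protein:unique-RNA ratio tracks
    the positive set's.

    Seeded greedy selection: candidates are shuffled once, then at each step
    the remaining candidate whose inclusion brings the running ratio closest
    to the target is taken (earlier shuffle position breaks ties).
    """
    import random

    n_pos = len(positives.positives())
    target = _unique_ratio(positives.positives())
    if len(negatives) < n_pos:
        warnings.warn(
            f"only {len(negatives)} negatives for {n_pos} positives; returning all",
            stacklevel=2,
        )
        chosen = list(negatives)
    elif len(negatives) == n_pos:
        chosen = list(negatives)
    else:
        rng = random.Random(seed)
        pool = sorted(negatives, key=lambda p: (p.source_complex, p.protein_id, p.rna_id))
        rng.shuffle(pool)
        chosen = []
        prot_seen: set[str] = set()
        rna_seen: set[str] = set()
        remaining = list(pool)
        while len(chosen) < n_pos:
            best_i, best_err = 0, float("inf")
            for i, cand in enumerate(remaining):
                np_ = len(prot_seen | {cand.protein_seq})
                nr_ = len(rna_seen | {cand.rna_seq})
                err = abs(np_ / nr_ - target)
                if err < best_err:
                    best_i, best_err = i, err
            pick = remaining.pop(best_i)
            chosen.append(pick)
            prot_seen.add(pick.protein_seq)
            rna_seen.add(pick.rna_seq)
    prov = dict(positives.provenance)
    prov.update(seed=seed, target_ratio=target, n_selected=len(chosen))
    return PairCorpus(pairs=chosen, provenance=prov)


def audit_negatives(
    negatives: list[SequencePair],
    positives: PairCorpus,
    sim_threshold: float = 30.0,
) -> list[str]:
    """Independently re-check rules 1-3 on a finished negative set.

    Returns a list of human-readable violations (empty when the set is clean).
    """
    violations: list[str] = []
    pos_keys = {p.key() for p in positives.positives()}
    pos_by_rna: dict[str, list[str]] = {}
    pos_by_protein: dict[str, list[str]] = {}
    for p in positives.positives():
        pos_by_rna.setdefault(p.rna_seq, []).append(p.protein_seq)
        pos_by_protein.setdefault(p.protein_seq, []).append(p.rna_seq)

    for n in negatives:
        if n.key() in pos_keys:
            violations.append(f"rule1: {n.rna_id}/{n.protein_id} is a positive pair")
        if not _passes_similarity(n, pos_by_rna, pos_by_protein, sim_threshold):
            violations.append(f"rule2: {n.rna_id}/{n.protein_id} resembles a positive partner")
    for i, a in enumerate(negatives):
        for b in negatives[i + 1:]:
            if a.rna_seq == b.rna_seq and sequence_identity(
                a.protein_seq, b.protein_seq, "protein"
            ) >= sim_threshold:
                violations.append(f"rule3: proteins {a.protein_id}/{b.protein_id} share RNA")
            if a.protein_seq == b.protein_seq and sequence_identity(
                a.rna_seq, b.rna_seq, "rna"
            ) >= sim_threshold:
                violations.append(f"rule3: RNAs {a.rna_id}/{b.rna_id} share protein")
    return violations


def write_corpus(corpus: PairCorpus, out_dir: str | Path, prefix: str = "corpus") -> None:
    """Serialize a corpus as protein FASTA + RNA FASTA + TSV pair table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prot_seen, rna_seen = {}, {}
    rows = ["protein_id\trna_id\tlabel\tsource"]
    for p in corpus.pairs:
        prot_seen.setdefault(p.protein_id, p.protein_seq)
        rna_seen.setdefault(p.rna_id, p.rna_seq)
        rows.append(f"{p.protein_id}\t{p.rna_id}\t{p.label}\t{p.source_complex}")
    (out / f"{prefix}_proteins.fasta").write_text(
        "".join(f">{i}\n{s}\n" for i, s in prot_seen.items())
    )
    (out / f"{prefix}_rnas.fasta").write_text(
        "".join(f">{i}\n{s}\n" for i, s in rna_seen.items())
    )
    (out / f"{prefix}_pairs.tsv").write_text("\n".join(rows) + "\n")
    (out / f"{prefix}_provenance.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in corpus.provenance.items())
    )


def read_corpus(in_dir: str | Path, prefix: str = "corpus") -> PairCorpus:
    """Load a corpus written by :func:`write_corpus`."""
    from Bio import SeqIO

    inp = Path(in_dir)
    prots = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(inp / f"{prefix}_proteins.fasta"), "fasta")
    }
    rnas = {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(inp / f"{prefix}_rnas.fasta"), "fasta")
    }
    pairs = []
    lines = (inp / f"{prefix}_pairs.tsv").read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        prot_id, rna_id, label, source = line.split("\t")
        pairs.append(
            SequencePair(
                rna_id=rna_id,
                protein_id=prot_id,
                rna_seq=rnas[rna_id],
                protein_seq=prots[prot_id],
                label=label,
                source_complex=source,
            )
        )
    prov = {}
    prov_path = inp / f"{prefix}_provenance.txt"
    if prov_path.exists():
        for line in prov_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                prov[k] = v
    return PairCorpus(pairs=pairs, provenance=prov)
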