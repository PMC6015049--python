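# Methods

`rpiboost` predicts whether an RNA and a protein interact from their
sequences alone. The model is a gradient-boosted-tree binary classifier over
k-mer features built on two pieces of structure-derived domain knowledge: a
four-class reduced amino-acid alphabet obtained from interaction propensities
at RNA-protein binding interfaces, and a five-residue window — the minimum
structural unit (MSU) — as the k-mer size. This note records the model, its
assumptions, the tunable parameters, and the numerical choices made where the
design was genuinely open.

## Structure handling

Complexes are read from PDB or mmCIF with gemmi. Only the first model is
used; waters and free ions are discarded; for alternate-location conformers
only the first conformation is kept (an arbitrary but deterministic choice —
altloc pairs are closer to each other than any distance cutoff used here, so
the effect on contact detection is nil in practice). Hydrogens, when present,
participate in distance checks, since the interaction rules are defined over
*any* pair of atoms.

Chain kind (protein vs RNA) is decided from residue chemistry by majority
vote, never from chain identifiers. Modified residues map to their standard
parent (pseudouridine → U, queuosine → G, selenomethionine → M, ...) through
a packaged table seeded from the chemical-component dictionary's parent
field, with gemmi's tabulated one-letter codes as fallback. Codes that
resolve nowhere become the sentinel `?` — never silently A or X — and any
k-mer window containing the sentinel is skipped during encoding. The point of
parent mapping is to keep chemically informative positions in play instead of
masking them.

Validity filters: protein chains need ≥ 25 residues, RNA chains ≥ 15 (both
inclusive); complexes must have crystallographic resolution ≤ 3.0 Å.
Structures without a resolution record (e.g. NMR ensembles) are rejected
because the propensity statistics are defined over X-ray crystal structures.
Rejection is a labeled outcome on the returned record, not an exception.

## Distance rules and propensities

Two cutoffs, both strict `<`:

* **8 Å** decides whether an RNA chain and a protein chain in the same
  complex *interact* (the slack admits water- or ion-bridged contacts);
* **5 Å** decides whether an individual residue is an *interface* residue
  (direct contacts only).

Interface residues are merged into binding-interface segments, allowing at
most three consecutive non-contacting residues between contacting ones;
segment endpoints always contact. Contacts at positions 5 and 9 with nothing
else nearby therefore form one segment of extent five — the observation
behind the MSU window size.

The interaction propensity of amino acid j is

    P_j = (I_j / I_n) / (N_j / N_n)

with I_j the count of interface residues of type j (I_n the total) and N_j
the count of non-contacting residues of type j *inside* interface segments
(N_n the total). Reading N_j as segment-interior residues follows directly
from the gap rule, which is what admits non-contacting residues into the
interface in the first place. Edge cases: I_j = 0 gives P_j = 0; N_j = 0 with
I_j > 0 gives +inf with a warning; I_n = 0 or N_n = 0 raises, because no
propensity is defined without both populations.

Positions in segment logic are 1-based chain ordinals, not author residue
numbers, so a gap always means a sequence gap.

The four-class alphabet packaged here — {R,K,H}, {D,P,M,F,A,V,L,I}, {C,E},
{N,W,S,Q,Y,G,T} — is the canonical propensity-derived grouping: positively
charged residues have the highest propensity, aspartate patterns with the
hydrophobics (its contacts run through backbone atoms), cysteine and
glutamate sit lowest, and the remaining polar residues form the fourth
class. `compute_propensities` lets users recompute P_j on their own corpora,
but regrouping is deliberately a manual/config step: no clustering algorithm
is implied by the grouping, so none is silently applied. Nucleotides keep
their four identities; their propensities are near-uniform, so no reduction
is warranted.

## Sequence encoding

Each molecule is scanned with a stride-1 window of five residues; each window
packs into a base-4 integer with the leftmost residue most significant (any
consistent bijection works; this one is fixed and documented for
reproducibility). That yields a 4^5 = 1024-bin histogram per molecule. Each
histogram is scaled as v' = (v − min v) / max v — in practice v / max v,
since the minimum of a sparse count vector is zero — which bounds every
feature in [0, 1] and damps the raw-count advantage of long chains. The
normalization is per molecule vector, before concatenation: it is the only
variant computable from a single pair without corpus statistics. All-zero
vectors (sequence shorter than the window, or all windows containing the
unknown sentinel) pass through unchanged with a warning.

The pair vector is the protein block followed by the RNA block: 2048
features, protein at indices 0–1023, RNA at 1024–2047.

## Classifier and evaluation

XGBoost, binary-logistic objective, with the published configuration as the
package default: 200 trees, learning rate 0.25, maximum depth 8, L1 penalty
1.12, L2 penalty 18.51, subsample ratio 0.9, decision threshold 0.5 with the
`>=` convention. Models serialize to XGBoost's portable JSON dump and reload
with bit-identical predictions.

Evaluation is stratified 10-fold nested cross-validation: outer folds
estimate generalization; an inner stratified grid search over the (L1, L2)
penalties picks, per outer training set, the pair with the best mean inner
accuracy. Stratification keeps class balance in small corpora; all fold
shuffling and subsampling randomness flows from one seed recorded in the
report. Reported means and standard deviations are across outer folds.

Two grids ship with the package. The full grid is inner 5-fold over
L1 ∈ {0, 0.5, 1.12, 2} × L2 ∈ {1, 10, 18.51, 30}, which contains the
published configuration. Desk-scale runs (the test suite and the acceptance
script) use inner 3-fold over the pair {(1.12, 18.51), (0, 1)} — the
published configuration against a near-unregularized alternative — which
exercises the full nested machinery at ~1/10 the fit count. This is a
problem-size choice for routine runs; the full grid remains one flag away
(`--full-grid`).

Metrics follow the standard confusion-matrix formula block (accuracy,
precision, recall, F-score as the harmonic mean) plus rank-based
(trapezoidal) AUROC. Degenerate denominators (no positive calls, no positive
labels) report 0 with a warning rather than raising, so per-fold tables stay
rectangular.

## Training-set construction

Positives are the interacting (8 Å) RNA/protein chain pairs of the validated
complexes, with exact duplicate (RNA sequence, protein sequence) tuples
collapsed to the first-seen source. Negative candidates come from chain
re-pairing: monomeric complexes (exactly one RNA + one protein) are crossed
with every other monomeric complex, while multimeric complexes contribute
only within-complex swaps (each RNA with the proteins it does not contact).

A candidate survives filtering iff (1) it is not an exact positive pair;
(2) its protein has < 30% identity to every protein positively paired with
its RNA, and symmetrically for the RNA (the same 30% threshold is applied to
RNA — the natural symmetric reading); and (3) within the surviving set,
negatives sharing a partner are mutually < 30% identical, resolved by a
first-kept-wins scan in deterministic order (sorted by source complex and
chain IDs). "Identity" is global-alignment percent identity — matches over
alignment columns, gaps included — under match +1, mismatch 0, gap open −10,
gap extend −1 (Bio.Align.PairwiseAligner). Normalizing by alignment length
rather than the shorter sequence makes the statistic symmetric and penalizes
length mismatch, which is the conservative choice for a filter meant to
exclude look-alikes.

Balancing selects exactly |positives| negatives by seeded greedy search:
candidates are shuffled once, then each step takes the remaining candidate
whose inclusion keeps the running unique-protein:unique-RNA ratio closest to
the positive set's. The procedure is deterministic given the seed and is
recorded in the corpus provenance. An `audit_negatives` operation re-checks
rules 1–3 independently after construction.

## Synthetic fixtures

The toy-complex generator lays both chains on straight parallel lines 30 Å
apart, two pseudo-atoms per residue (backbone + side chain), and swings the
side-chain atom of chosen protein residues to 4.2–4.8 Å from the nearest RNA
backbone atom; every other protein atom stays > 8 Å from the RNA. Residue
spacing must exceed 5 Å so contacts never leak to neighbours. This plants an
exactly known interface — the ground truth for the distance-rule oracles —
while making no claim of physical realism (a stated non-goal).

The motif-corpus generator emulates the learning problem: positives carry
three copies each of a fixed protein class-level 5-mer (default `00000`, an
R/K/H-rich patch — the high-propensity signature of RNA-binding surfaces)
and a fixed RNA 5-mer (default `UUAGG`, the telomeric-repeat flavour),
planted at random non-overlapping positions in i.i.d. uniform background of
length 40–120; negatives are plain background at the same length
distribution, so chance motif hits occur at the background rate (~0.08 per
sequence) exactly as in real null data. What passing tests on this corpus
show is that the encoding preserves planted co-occurrence signal and the
nested-CV machinery recovers it near-perfectly (accuracy ≥ 0.95, AUROC
≥ 0.98) while label-permuted data sits at chance. What they do not show is
real-corpus performance: real positives share no single motif, real
backgrounds are compositionally biased, and real negatives are only putative
non-interactions.

## Problem sizes and limitations

Routine runs use: 500 + 500 pairs for the end-to-end cross-validation, 50
seeded toy complexes for the distance-rule oracle, 8 monomeric complexes for
the negative-set audit, and the desk-scale penalty grid. These sizes make
the self-tests complete in minutes on one CPU while leaving every code path
exercised at full fidelity.

Known limitations: exact tree-level reproducibility across XGBoost versions
is not promised (seeded runs are reproducible within a version); the
permuted-label null of a flexible classifier sits slightly below 0.5 on
finite samples, which is expected overfitting-to-noise behaviour, not a bug;
chain-kind classification by majority chemistry can misclassify heavily
modified chains whose components resolve nowhere; and the sequence-identity
filter is a pairwise global-alignment statistic, not a homology search — it
removes look-alikes, not remote homologs.
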