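# Methods

This note documents the models and procedures `memtype` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Label model

The six membrane types are fixed in the order GPI-anchor (1),
lipid-anchor (2), multi-pass (3), peripheral (4), single-pass type I (5),
single-pass type II (6); every vector, report and index-coded annotation
file uses this order. A protein's annotation is a non-empty label set,
encoded losslessly as a 6-component 0/1 vector. Curated human datasets
carry means of ≈ 1.03 labels per protein and no protein with more than
three types; the synthetic generator reproduces both properties by
default.

Interaction confidences are stored internally on the raw STRING 0–1000
scale; unit-interval inputs are multiplied by 1000 on ingest so the
distance transform has a single domain. A pair is *interactive* iff its
confidence is strictly positive; zero-score rows are dropped on ingest
and self-interactions are excluded throughout (curated STRING extracts
rarely contain them and no stage of the predictor can use them).

## Homology stage

The stage consumes only (bit score, E-value) pairs through a provider
contract, so single-pass BLAST, iterated PSI-BLAST tabular output and the
built-in aligner are interchangeable; PSI-BLAST's profile iteration is
deliberately not reimplemented. The built-in provider is Biopython's
`PairwiseAligner` in local (Smith–Waterman) mode with BLOSUM62 and affine
gap costs 11 (open) / 1 (extend), the first gap residue paying 12 in
total, matching the BLAST convention. Tests hold this path equal to an
independently coded full Gotoh dynamic program.

Approximate E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λ·S_raw)` with the standard gapped BLOSUM62(11,1)
constants λ = 0.267, K = 0.041 and m·n the product of query and subject
lengths (a per-pair search space; BLAST's database-length convention
would scale all E-values by a common factor and shift, not reorder, the
gate). These constants affect only the significance gate, never which
subject ranks best. Bit scores are `(λ·S_raw − ln K)/ln 2`.

Choices the sources leave open, fixed here: "alignment score" is read as
bit score; the best hit is maximal bit score with ties broken by smaller
E-value, then lexicographic subject id (determinism). The default gate is
E ≤ 0.01, balancing accuracy against coverage; the low-complexity filter
is never enabled in emitted external command lines because masking
hydrophobic stretches removes exactly the regions that characterize
membrane proteins. Selenocysteine and pyrrolysine are mapped to C and K
for scoring; B/Z/X use their BLOSUM62 rows.

## Network stage

The vote `p_k = Σ_q w_q·l_qk / Σ_q w_q` is a confidence-weighted mean of
partner label vectors. The sum-of-weights normalizer is the default
(making p_k a fraction in [0,1] and the all-zero output with no partners
well-defined); a no-normalization switch exists for sensitivity checks
and cannot change the ranking, hence never the prediction. The top t
types with *strictly positive* probability are kept — the positivity
requirement stops top-t from emitting unsupported types when fewer than
t have any partner evidence. t defaults to the ceiling of the training
set's mean labels-per-protein (2 for realistic multiplicity profiles) and
is computed once per dataset, not per query. Ties at the t-th rank break
toward the smaller type index, making the prediction invariant to
storage order.

## Shortest-distance stage

Edge length is d = 1000 − w: strictly decreasing in confidence, zero for
a maximal-confidence edge, bounded because STRING scores are. The
alternative d = 1000/w is available behind the `distance_transform`
config key for sensitivity analysis (it compresses high confidences and
blows up weak ones). Distances are exact single-source Dijkstra
(networkx), cross-checked against exhaustive simple-path enumeration in
tests. The query inherits the nearest labelled protein's full label set;
distance ties break by larger direct confidence with the query, then
lexicographic id. A query unreachable from every training protein
receives the most frequent single training type, flagged `fallback=True`
so evaluations can segregate these — the flag exists because the stage's
contract is to never abstain. In leave-one-out the query's *edges remain
in the graph*; only its label knowledge is hidden — evaluation removes
knowledge of types, not of interactions.

## Integrated cascade and RWC

The cascade is strict: homology if any hit passes the gate, else network
if any direct interactive training partner exists, else
shortest-distance. Stage assignment is therefore a partition of any
query set, an invariant the tests and the acceptance script both check.
Sequence-less queries simply skip the homology stage (sequences are
optional on records so network-only data remain usable); with an empty
network the cascade degenerates to homology plus fallback.

RWC fuses the three evidence channels per candidate:
`S = α·ŝ + β·ŵ + γ·(1 − d̂)`, each component min–max normalized over the
candidate set (distance inverted so closer is better), weights default
(1/3, 1/3, 1/3) and configurable. A component undefined for a candidate
(no alignment, no edge, unreachable) contributes its worst normalized
value, 0, keeping S defined for all candidates; when all defined values
of a component are equal they jointly map to 1 (they are at the
candidate-set optimum). Min–max normalization makes the prediction
invariant to positive affine rescaling of any single raw component. RWC
exists as a comparison method: a flat weighted combination of
heterogeneous scores, against which the cascade's "most reliable evidence
first" ordering is evaluated. A strongly connected wrong-type hub can
dominate all three normalized channels and mislead RWC where the
network stage's mass-weighted vote is still correct; the test suite
constructs exactly this situation.

## PseAAC and the nearest-neighbor baseline

The encoder uses five residue property scales (polarity, secondary
structure, molecular volume, codon diversity, electrostatic charge —
Atchley-style factor scores, tabulated in `pseaac.py`). Each column is
standardized to zero mean and unit (population) standard deviation over
the 20 amino acids; the published values are already near-standardized,
so this is an affine no-op up to rounding, but applying it makes the
encoder correct for any replacement property table. Tier-j correlation
factors are mean squared property differences at sequence separation j;
with λ = 50 tiers per property the vector is 20 + 5·50 = 270 components,
jointly normalized to sum to 1. The sequence-order weight defaults to
w = 0.15, the canonical value of the original PseAAC scheme, since
nothing in this problem pins it; λ and w are both config keys.

Sequences not longer than λ are a hard error rather than a silent λ
reduction — silent reduction would change the vector length and break
distance comparability across a dataset; an explicit dataset-wide λ can
be passed instead. Non-standard residues (B, Z, X, U, O) are dropped
from both the frequency and correlation computations with a warning.
The NNA distance is Euclidean by default (cosine available); ties break
by lexicographic id.

## Metrics and leave-one-out protocol

The default accuracy per record is
`|L∩L*|/|L| − |L*\L|/|L*|` ∈ [−1, 1]: a recall-like reward minus a
penalty that vanishes iff no spurious type is predicted. The Jaccard
variant `|L∩L*|/|L∪L*|` ∈ [0, 1] is always computed alongside so results
are interpretable under either reading; both equal 1 exactly when the
prediction equals the truth. Abstentions are excluded from all metric
averages and counted separately as NU — the only accounting under which
an abstaining method's accuracy is meaningful. The c/p/e breakdown
(complete / partial / entirely wrong) is reported per label-multiplicity
group and partitions each group.

Leave-one-out hides one protein's labels at a time. Self-information is
excluded structurally: the aligner never returns self-hits, the vote
never counts the query, the graph search never selects the query as its
own nearest training protein. Pairwise alignment scores are symmetric
and cached across rounds, which changes nothing statistically.

## Synthetic benchmarks

The generator plants known structure: families are point-mutated copies
(substitutions only — no indels, which keeps the brute-force alignment
oracle exact and the divergence dial one-dimensional; an indel rate would
be a config extension) of random ancestor sequences, sharing the family
label set; edges connect label-sharing pairs with probability `p_same`
(default 0.8) and others with `p_diff` (default 0.02); confidences are
uniform integers on [150, 999]. Default sizes: 120 proteins in 30
families of length-120 sequences (long enough for λ = 50), multiplicity
distribution {1: 0.970, 2: 0.027, 3: 0.003} (mean 1.033, so t = 2).
Decoy homologs — copies of a family ancestor at 0.9 per-site divergence
with labels disjoint from the family's — sit at the weak-similarity
level that a loose E-value gate (10) admits and a strict one (0.01)
rejects, reproducing the direction of the accuracy/coverage trade-off.

What the benchmarks show: every pipeline stage is exercised end to end,
planted structure is recovered exactly in the regimes where the method's
assumptions hold (zero mutation ⇒ perfect homology transfer; full
assortativity ⇒ exact network voting), bookkeeping invariants hold, and
the E-value trade-off has the expected direction. What they do not show:
performance on real proteomes — uniform random ancestors lack real
amino-acid composition and domain structure, real interaction networks
are scale-free rather than family-blocked, and real type assortativity
is far from the planted extremes. Accuracies measured on synthetic data
characterize the implementation, not expected biological performance.

## Problem sizes and numerics

Tests and the acceptance script run leave-one-out at n ≤ 200 proteins
(≈ 20,000 cached pairwise alignments), oracle cross-checks at 100 random
sequence pairs (length ≤ 30) and 100 random graphs (≤ 8 nodes, where
exhaustive path enumeration is tractable); the whole suite completes in
a few seconds. Floating-point ties in distances are resolved by the
documented deterministic tie-breaks; PseAAC normalization is checked to
1e-9; alignment scores are exact integers under BLOSUM62 and compared
exactly. All randomness flows from explicit seeds; two runs with the
same seed and config are identical.
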