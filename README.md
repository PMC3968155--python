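# memtype

Multi-label prediction of human membrane protein types from sequence
homology and protein–protein interaction networks.

## The problem

Membrane proteins are conventionally divided into six types by their
intramolecular arrangement and position in the cell:

1. GPI-anchor
2. lipid-anchor
3. multi-pass
4. peripheral
5. single-pass type I
6. single-pass type II

A protein's type constrains its function, but a single protein can carry
more than one type at once (in curated human data up to three), so type
prediction is a *multi-label* problem: the target is a label set
L ⊆ {1..6}, encoded as a 6-component 0/1 vector. `memtype` implements an
integrated predictor for this problem, the evaluation metrics it needs,
and two classical baselines, for computational biologists who want to
annotate uncharacterized membrane proteins or benchmark multi-label
annotation transfer.

## The method

Given a training set S of labelled proteins, an interaction network with
STRING-style confidence scores w ∈ (0, 1000] (a pair is *interactive* iff
w > 0), and a query protein p, the integrated predictor is a three-stage
cascade in which exactly one stage fires:

1. **Homology transfer.** Align p against S (BLAST/PSI-BLAST tabular
   reports are accepted; a built-in Smith–Waterman aligner with BLOSUM62
   and affine gaps 11/1 is the default provider). If any hit passes the
   E-value gate (0.01 by default), copy the label set of the
   highest-scoring subject. High accuracy, but abstains for queries
   without homologs.
2. **Network voting.** Otherwise, if p has interactive training partners,
   score each type k by the confidence-weighted vote
   p_k = Σ_q w_q·l_qk / Σ_q w_q and keep the top t positive types, where
   t = ⌈mean labels-per-protein of S⌉ (t = 2 on curated human sets, whose
   means are ≈ 1.03).
3. **Shortest-distance transfer.** Otherwise, convert confidences to edge
   lengths d = 1000 − w, run Dijkstra from p, and copy the labels of the
   nearest training protein. Never abstains (a fully disconnected query
   falls back, flagged, to the most frequent training type).

Baselines: **NNA/PseAAC** — nearest neighbor over 270-component pseudo
amino acid composition vectors (20 residue frequencies + 5 property
blocks × λ = 50 correlation tiers, sequence-order weight 0.15); and
**RWC** — label transfer from the candidate maximizing the fused score
S = α·ŝ + β·ŵ + γ·(1 − d̂) over min–max-normalized alignment, confidence
and distance components, α = β = γ = 1/3.

Evaluation is leave-one-out with multi-label precision, recall, and an
accuracy that penalizes over-prediction:

    Acc = 1/n · Σ_i [ |L_i ∩ L_i*| / |L_i|  −  |L_i* \ L_i| / |L_i*| ]

(a Jaccard variant is reported alongside), plus unannotated counts (NU),
per-stage annotation counts (NA), and complete/partial/wrong breakdowns
by label multiplicity.

## Worked example

Synthetic benchmarks are built in: point-mutated homologous families
embedded in a label-assortative interaction network. Here 100 proteins in
60 families (so 20 proteins have no homolog) at 35% per-site divergence:

```python
from memtype import SynthConfig, generate_dataset, loo_evaluate

config = SynthConfig(n_proteins=100, n_families=60, mutation_rate=0.35, seed=0)
dataset, interactions, _ = generate_dataset(config)
for method in ("integrated", "homology", "network", "shortest", "nna", "rwc"):
    report = loo_evaluate(dataset, interactions, method=method)
    acc = "  n/a " if report.accuracy is None else f"{report.accuracy:6.3f}"
    print(f"{method:<11} Acc={acc}  NU={report.nu:3d}  "
          f"stages={{{', '.join(f'{s}: {st.na}' for s, st in report.per_stage.items())}}}")
```

prints

```
integrated  Acc= 0.705  NU=  0  stages={homology: 98, network: 2}
homology    Acc= 0.709  NU=  2  stages={homology: 98}
network     Acc= 0.530  NU=  0  stages={network: 100}
shortest    Acc= 0.810  NU=  0  stages={shortest_distance: 100}
nna         Acc=-0.480  NU=  0  stages={nna: 100}
rwc         Acc= 0.930  NU=  0  stages={rwc: 100}
```

Reading this: homology-only annotates 98 of 100 proteins and abstains on
2 (NU); the cascade hands exactly those two to the network vote, so its
per-stage counts partition the dataset. The purely sequence-order-based
NNA baseline collapses on these heavily mutated families (negative Acc
means its wrong predicted types outweigh its correct ones), while
methods that see the assortative network do well.

The same machinery is exposed as a CLI:

```sh
memtype simulate --out fixture --n 30 --families 10 --seed 5
memtype evaluate --fasta fixture/proteins.fasta \
                 --annotations fixture/annotations.tsv \
                 --network fixture/interactions.tsv --method integrated
memtype predict  --fasta fixture/proteins.fasta \
                 --annotations fixture/annotations.tsv \
                 --network fixture/interactions.tsv \
                 --queries queries.txt --method integrated
```

Real data drop into the same three files: FASTA sequences, a
tab-delimited `id<TAB>type[;type...]` annotation table (type names or
1-based indices), and a 3-column STRING-style edge list. Precomputed
BLAST reports are supplied with `--blast-tab hits.tsv` (outfmt 6).

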