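# Methods

## Model

`ncplink` scores candidate cells of a binary bipartite association matrix
`MD` (microbes × diseases) under the guilt-by-association assumption that
similar microbes associate with similar diseases. Similarity is derived
entirely from the network itself, through interaction profiles (a microbe's
row of `MD`, a disease's column):

* **GIP kernel** `K(i,j) = exp(−λ‖p_i − p_j‖²)`, `λ = λ′ / mean_i‖p_i‖²`.
  The normalisation makes the bandwidth scale-free in the number of
  associations; `λ′ = 1` by default, following common practice for GIP
  kernels in link prediction. The mean in the normaliser runs over **all**
  profiles, including zero rows/columns created by cross-validation masking —
  this shifts λ slightly in LOOCV folds but keeps the definition uniform.
* **Cosine similarity**, with the convention 0/0 := 0 for zero profiles,
  including the zero profile's own diagonal entry. A zero profile carries no
  similarity evidence; returning 0 rather than 1 or NaN prevents masked
  degree-1 entities from poisoning the projection.

Each side's two views are fused by an elementwise convex combination
(`α` on the disease side, `β` on the microbe side, both strictly inside
(0, 1); defaults 0.3 and 0.6, the grid-search optimum reported for the
curated benchmark). Endpoint weights are rejected: single-similarity runs
are expressed by passing one matrix through (`microbe_similarity="gip"`
etc.), not by degenerate weights.

Network consistency projection then scores cell (i, j) as

```
NCP(i,j) = ( MD(i,:)·DS(:,j)/|MD(i,:)| + MS(i,:)·MD(:,j)/|MD(:,j)| )
           / ( |DS(:,j)| + |MS(i,:)| )
```

`|·|` is the Euclidean norm throughout. L2 is the natural companion of the
cosine construction; the norm is nevertheless a single policy point
(`norm="l1"`) so sensitivity to this choice can be measured. 0/0 := 0 for
zero rows/columns of `MD`: a microbe whose only association was masked still
receives a finite score through the microbe-space term. Scores are
nonnegative ranking scores, not probabilities; they are not normalised
to [0, 1].

## Parameters that matter

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | disease-side weight on the GIP kernel | 0.3 | (0, 1); grid driver sweeps 0.1–0.9 |
| `beta` | microbe-side weight on the GIP kernel | 0.6 | (0, 1) |
| `lambda_prime` | raw GIP bandwidth, both sides | 1.0 | normalised per side, per fold |
| `norm` | projection vector norm | `l2` | `l1` available for sensitivity analysis |

## Cross-validation protocol

Bandwidths, all four similarity matrices and the fused matrices are
recomputed from the masked training matrix in **every** fold; nothing is
cached across folds, so a held-out association cannot leak through the
kernels. Fold negatives are all cells unknown in the *original* dataset.

The AUC is the fold-matched Mann–Whitney statistic: each fold's held-out
positives are compared with that fold's negative scores, ties count 1/2, and
the pair counts are aggregated across folds. This is threshold-free and is
the de-facto protocol in this literature. 5-fold partitioning is a seeded
uniform shuffle of the positive list into near-equal contiguous blocks,
masked jointly per fold; the repeat count defaults to 100 and the per-repeat
AUCs are summarised by mean ± standard deviation.

For AUPR and the stringency tables the positives are pooled across folds
while each unknown pair contributes its **mean score across folds**, so the
negative class keeps the size and balance of the network itself
(concatenated pooling is also available and is what the permutation-null
comparison uses on the same pooled functional). PR integration is step-wise
(precision summed over recall increments, ties grouped), avoiding the
optimism of linear PR interpolation. Stringency thresholds are realised —
the smallest pooled score whose specificity meets the requested level; no
interpolation — and the achieved specificity is reported. Any ratio with a
zero denominator (including MCC) is reported as 0 so degenerate folds cannot
crash a sweep.

## Synthetic data

The generator emulates the curated benchmark's regime: 292 microbes × 39
diseases, expected density 0.039375 (≈448 expected associations against the
benchmark's 450), heavy-tailed **disease** degrees (the benchmark averages
≈11.5 associations per disease but only ≈1.5 per microbe). Microbes and
diseases are assigned uniformly to 4 + 4 clusters; a cell whose microbe
cluster corresponds to its disease cluster (c ↦ c mod K_d) is sampled with
`intra_cluster_prob = 0.12`, others with `inter_cluster_prob = 0.0125`, each
multiplied by a per-disease Zipf popularity weight (exponent 0.7, mean 1,
randomly assigned). Weights that push any cell probability above 1 are a
configuration error. Isolated entities are retained; an entirely empty draw
is retried with an incremented seed offset (logged).

`degree_skew = 0` yields uniform popularity. This matters for the
signal-free control: with `intra = inter` but skewed popularity, the degree
structure itself remains learnable (measured LOOCV AUC ≈ 0.62), so the
exchangeable null used for calibration checks sets both `intra = inter`
*and* `degree_skew = 0` (measured AUC ≈ 0.50, inside the permutation null's
95% band).

What the generator does **not** emulate: real taxon/disease identities,
literature co-occurrence structure, correlated annotation biases between
related diseases, and the curation process that produced the benchmark.
Passing tests on synthetic data therefore demonstrate correctness of the
algorithms and calibration of the evaluation harness — not the absolute
performance level to expect on curated association databases, where
reported AUCs are substantially higher than on these planted-cluster
networks.

## Numerical choices

* Squared profile distances are computed from the Gram matrix (exact for
  binary profiles), symmetrised, and clipped at 0.
* Similarity matrices are validated at construction: symmetric to 1e-12,
  entries clipped to [0, 1].
* Ranking ties break by ascending microbe index (deterministic output).
* Candidate ranking excludes known associations; the score matrix itself
  keeps them (cross-validation needs them).
* Edge-list export re-emits rows in an order that reproduces the dataset's
  first-appearance entity order, so load → write → load round-trips.

## Problem sizes used by the test suite and acceptance script

Most unit tests run on hand-sized fixtures (≤ 15 × 8) against scalar-loop
oracles. CV behaviour is exercised on an 80 × 16 planted network (~110
associations); signal-recovery and calibration checks run LOOCV on the full
default 292 × 39 network with a 1000-shuffle permutation null. The
acceptance script uses the default network with 5-fold CV at 20 repeats —
enough to estimate the repeat spread to two decimals — and reports every
value alongside the problem size it was computed at.

## Known limitations

* The method is transductive: scores exist only for entities present in the
  fitted network, and a new microbe or disease with no associations has a
  zero profile and an uninformative score row/column.
* Scores are incomparable across datasets (norm denominators scale with
  network size); only within-dataset rankings are meaningful.
* The LOOCV driver refits once per known association; for networks far
  larger than the benchmark regime a blocked or approximate protocol would
  be needed.
* SNF/SKF-style nonlinear fusion is out of scope; the fusion step is a
  single convex combination by design.
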