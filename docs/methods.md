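# Methods notes

## Model and assumptions

All methods operate on undirected weighted gene networks over a fixed,
ordered gene universe; an absent edge is an exact zero and weights are
nonnegative "strength of functional evidence", not distances. Disease
annotations are treated as a positive-only labelling: unannotated genes
are *unknowns*, not confirmed negatives, which is why evaluation is
ranking-based (AUC, precision-at-recall) rather than classification
accuracy, and why top-ranked "false positives" of well-predicted
diseases are read as candidates rather than errors.

Matrices are stored dense (numpy). The target scale is a few thousand
genes; q-step kernel powers densify any sparse input, and at this scale
dense BLAS is both simpler and faster than sparse bookkeeping.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `a` | kernel diagonal shift, `K = (a−1)I + D^(−1/2)WD^(−1/2)` | 2.0 | any `a > 1` is admissible; `a ≥ 2` guarantees positive semidefiniteness because the normalized adjacency spectrum lies in [−1, 1] |
| `q` | random-walk steps (kernel power) | 5 | the usual grid is {1, 2, 3, 5, 10}; 5 steps explore the mesoscale topology without washing out locality |
| `k` | seeds summed by S_kNN | 19 | saturates to the full seed set when `k ≥ |V_M|` |
| `θ` | RWR restart probability | 0.6 | typical grid {0.6, 0.9}; RWR converges geometrically at rate `1−θ` |
| `steps` | RW iterations | 5 | RW run to convergence forgets the seeds (stationary distribution depends only on degrees), so it is deliberately truncated |
| RWR `tol`, `max_iter` | L1 stopping rule | 1e−10, 1000 | the fixed-point residual test in the suite checks the returned state beats `tol` |
| `b` | cap inside the log-γ transform | 0.99 | keeps `log(1−M)` finite when a network's AUC reaches 1 |
| size filter | disease set sizes kept | [5, 200] inclusive | fewer than 5 seeds is too little prior signal; more than 200 is too heterogeneous a class |

Ranking ties are always broken lexicographically on the gene identifier
so every output is deterministic.

## Pipeline order and design choices that were genuinely open

* **Filter before rescale.** Threshold filtering (keep weights ≥ the
  minimum over genes of the per-gene maximum weight, inclusive so the
  no-singleton guarantee holds) precedes [0, 1] rescaling; both are
  optional and independently callable.
* **Rescaling statistics use present edges only.** Including structural
  zeros would pin every network's minimum at 0 and defeat cross-network
  comparability; a degenerate all-equal-weight network rescales to all
  ones so binary networks pass through unchanged.
* **Duplicate edge records keep the maximum weight**; self-edges are
  dropped on read (simple graphs).
* **PUA coverage is gene-level**: a network "contains" a pair iff it
  contains both genes, recorded as a per-network coverage mask at
  alignment time.
* **Weighted integration combines adjacencies, not Gram matrices, when
  given networks.** Building the kernel on the WA-integrated network
  lets walks alternate between sources of evidence; integrating
  per-network q-step Gram matrices instead confines every walk to a
  single source and measurably loses accuracy (0.88 vs 0.94 mean AUC on
  the default benchmark). A collection of `KernelMatrix` objects is
  still integrated elementwise as supplied.
* **Internal γ estimation shares one split per disease across
  networks**, so identical networks provably receive identical weights
  and the network comparison is not confounded by split noise. Exact
  leave-one-out is available (`internal_folds="loo"`, cost
  |seeds|+1 scorings per disease/network); the default is an internal
  5-fold. Either way the weights never read a test-fold label — the
  suite asserts bit-identical γ under sentinel relabelling of the test
  fold.
* **Zero-degree genes** get a 0 entry in `D^(−1/2)` (kernel-isolated,
  self-similarity `a−1`) and a self-transition of 1 in `Q` so
  probability mass is conserved on disconnected networks.
* **Shuffle test at fixed predictions.** The 1000 shuffled AUCs reuse
  the assembled cross-validated score vector; `p = m/n` exactly (the
  add-one estimator is available behind a flag). A shuffle is a uniform
  random gene set of the positive set's size.
* **ECDF percentile convention**: percentile(s) = #{support ≤ s} /
  #support over the pooled (annotated + unannotated) scores ≥ c, where
  c is the weakest annotated gene's score; a top unannotated gene
  scoring below c gets percentile 0 and a `below_support` flag.
* **S_AV self term.** The full score subtracts `½K(i,i)`; the
  simplified form drops it. With a one-step kernel the diagonal is
  constant and the two rankings coincide (asserted in the suite). For
  `q > 1` diagonals track degree, and on planted-set benchmarks —
  where disease genes are exactly the high-degree genes — the full form
  systematically penalizes true positives (measured ≈ 0.89 vs ≈ 0.96
  mean AUC on the informative network). The library default is the
  full form; the benchmark study and the examples use the simplified
  form, which is also the behaviour consistent with S_AV being the
  strongest score in this family.

## What the synthetic benchmark emulates — and what it does not

The generator plants overlapping disease gene sets (5–40 genes each,
mirroring the fact that real annotation vocabularies overlap) and draws
each network's edges with probability `p_in·ι + p_out·(1−ι)` inside
shared-disease pairs against a `p_out` background, with per-network
informativeness `ι ∈ [0, 1]`, multiplicative lognormal weight jitter
(σ = 0.25) and optional per-network gene coverage. Defaults: 500
genes, 20 diseases, three networks at ι = 0.9/0.5/0.0,
`p_in = 0.3`, `p_out = 0.02`. Everything derives from one integer seed
and regenerates byte-identically.

What it does **not** emulate: heavy-tailed degree distributions, edge
weights that themselves carry signal (fixture weights are pure jitter —
which is why the benchmark study skips threshold filtering: deleting
edges by an uninformative weight destroys topology, measured ≈ 0.62 vs
≈ 0.96 mean AUC), correlated noise across networks, ascertainment bias
in annotations, and the sheer scale of real compendia. Passing the
recovery study therefore shows the machinery is correct and that the
protocol can recover planted informativeness orderings — not that any
particular AUC will transfer to real data.

## Benchmark study sizes

The recovery study (tests and `scripts/acceptance.py`) runs ten
replicates of the default 500-gene / 20-disease / 3-network benchmark:
per-network and per-operator cross-validated mean AUCs with five-step
S_AV, nested WA integration, γ-ordering recovery, and 1000-shuffle
p-values on the WA scores. One replicate takes under a second on a
single CPU.

## Known limitations

* Dense storage caps practical use around ~10⁴ genes on ordinary RAM.
* WAP materializes one integrated matrix per disease per fold; with
  hundreds of diseases prefer WA (which the evidence favours anyway —
  per-disease weights overfit).
* GBA and the score functions are scale-sensitive: comparing integrated
  variants is only meaningful after rescaling to a common range.
* The permutation p-value has resolution 1/n_shuffles and is 0 (not
  "< 1/n") when no shuffle wins; use the add-one flag for downstream
  multiplicity corrections that dislike zeros.
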