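# Methods

## The two-step model

**Step 1 — connectivity regression.** For a cell line with a labeled CDKO
screen, each gene's SL connectivity `c(g)` is its number of SL partners
(pairs with GI score strictly below −3). Validated SL networks are
scale-free, so `c` is heavy-tailed; the regression runs on `y = log(1+c)`
and predictions are mapped back with `expm1`, clipped at zero. The encoder
stack is:

* *Gene encoder.* Population-scope features (profiles across cell lines:
  expression, essentiality, copy number) and cell-specific features
  (including per-gene mutation counts) are encoded by separate one-layer
  ReLU branches into `d`-dimensional embeddings, concatenated, and linearly
  fused back to `d`. A missing scope is replaced by a learned constant
  vector (with a warning), not an error.
* *Multiview graph encoder.* Per network view (physical PPI, genetic
  interaction, pathway), `L` rounds of `H ← ReLU(Â H W + b)` with
  `Â = D^{-1/2}(A+I)D^{-1/2}`; self-connections mean isolated genes
  propagate their own features with weight one. View outputs are
  concatenated and projected to `d`.
* *Transformer encoder.* Standard post-norm multihead self-attention over
  all gene tokens (no positional encoding — the gene set is unordered),
  residual connections, parameter-free layer normalization, and a
  `d → 2d → d` ReLU feed-forward sublayer. Attention is dense over all N
  genes, which is the point: hubs are visible from global topology that
  `L`-hop message passing cannot reach.
* *MLP head.* Dropout, a `d → d` ReLU layer, and a linear map to the scalar
  `ŷ(g)`.

Training is full-batch Adam on MSE over training-gene rows (gene counts are
small enough that minibatching buys nothing). Dropout is applied after each
encoder stage (rate `dropout_encoder`) and before the head
(`dropout_predictor`).

**Step 2 — pair classification.** A pair's features are the order-invariant
`(min(ĉ_a, ĉ_b), max(ĉ_a, ĉ_b), ĉ_a·ĉ_b)` — min/max preserve asymmetry that
averaging would destroy, and the product captures the both-hubs interaction;
`sum` and `|difference|` are available as alternatives. Features are
standardized with training statistics and fed to an L2-penalized logistic
regression with balanced class weights. The penalty is parameterized
per-sample (objective `mean log-loss + 0.5·α·‖w‖²`, default `α = 1e-4`), so
the fit is invariant to duplicating the training data. Step 2 is fitted on
the *predicted* connectivities of training genes — the quantities available
at prediction time — against training-pair labels.

## Leakage control

Three separate leakage paths are closed:

1. **Split-level.** The evaluation of record is the nonoverlap split: genes
   are partitioned, test pairs need both endpoints among test genes, and
   cross pairs are discarded outright (assigning them to training would let
   test genes influence the fit).
2. **Supervision-level.** Connectivity targets for training genes are
   computed from training-side pairs only, and evaluation targets for test
   genes from test pairs only; using all pairs would leak test labels into
   step-1 supervision.
3. **Input-level.** Feature standardization (median imputation + z-scoring)
   uses training-gene statistics only, and `remove_leakage_edges` deletes
   screened pairs from genetic-interaction network views before encoding.

Early stopping needs a validation signal: training genes are split 80/20
into a fit subset and a monitor subset (seeded from `ModelConfig.seed`), and
the returned model carries the weights of the epoch with minimal monitor
MSE. Both subsets' targets come from training-side pairs.

## Hyperparameters

| parameter | default | role |
| --- | --- | --- |
| `embed_dim` | 64 | width of every embedding stage |
| `n_graph_layers` | 2 | message-passing rounds per view |
| `n_attention_heads` / `n_transformer_layers` | 4 / 1 | attention geometry (`embed_dim` must divide by heads) |
| `dropout_encoder` / `dropout_predictor` | 0.5 / 0.7 | regularization between encoder stages and before the head |
| `learning_rate` | 5e-5 | Adam step size; deliberately low for convergent screen-scale training |
| `max_epochs` / `early_stop_patience_epochs` | 1000 / 200 | schedule bounds |
| `target_transform` | log1p | count-scale stabilization |

`ModelConfig.small()` is the desk-scale preset used throughout the tests and
the acceptance script: `embed_dim` 16, one graph layer, two heads, dropout
0.1/0.1, learning rate 1e-2, 400 epochs with 60-epoch patience. The raised
learning rate and shortened schedule exist because a 16-dimensional model on
a few hundred genes converges in minutes of CPU, not hours of GPU; the
schedule was sized so runs end by early stopping rather than at the epoch
cap. Dense N×N attention bounds usable N to a few thousand genes; the
supported scaling path is restricting the gene universe (screened genes plus
neighbors), not sparse-attention approximation.

## The synthetic benchmark

The generator produces the statistical structure the method assumes, at desk
scale and with known ground truth:

* **SL graph.** Barabási–Albert preferential attachment (`n_genes`,
  `attachment_m`): each new node attaches to `m` nodes with probability
  proportional to degree, giving `m(n−m)` edges and a degree-density
  power-law exponent near 3 — the qualitative shape of validated SL
  networks. No claim is made about the true exponent of any real screen;
  `attachment_m` is exposed rather than fixed to a "true" value.
* **GI scores.** Every unordered pair gets a score: true SL pairs from
  `N(−5, σ)`, non-SL from `N(0, σ)`, so the −3 labeling threshold sits
  between classes. With `σ = 1` the mislabeling probabilities are `Φ(−2)`
  for SL pairs and `Φ(−3)` for non-SL pairs (the threshold is 2 and 3 sds
  from the respective means).
* **Features.** Each column is `s·z + (1−s)·ε` with `z` the standardized
  `log(1+c)` and `ε` iid standard normal; the population correlation with
  `z` is `s/√(s²+(1−s)²)`. Default blocks: one population table and one
  cell-specific table of 10 features each; an optional mutation block
  Poisson-thins the latent (`rate = exp(clip(latent)−1)`) into sparse
  nonnegative counts.
* **Network views.** Three independently rewired copies of the SL graph;
  each edge is replaced by a uniform random non-edge with probability
  `network_rewire_prob`, preserving edge count.

Defaults (`n=500`, `m=2`, `signal=0.7`, `rewire=0.2`, `σ=1`, three views)
are the package's standing study conditions. Every generator is a pure
function of the master seed via deterministically spawned per-component
substreams, so bundles are byte-identical across repeat calls.

What the generator does *not* emulate: real omics marginals (CCLE-like
skew, batch structure), correlated noise across features, BioGRID's topology
beyond degree coupling, or biological pathway structure. Passing
recovery tests therefore shows the pipeline extracts connectivity signal
that is present in the stated form — not that real screens carry signal of
that strength or shape.

## Evaluation conventions

* **AUC-ROC** is the rank statistic `P(score⁺ > score⁻) + ½P(tie)`.
* **AUPR** is the step-wise precision–recall area with tie grouping
  (average precision), *not* trapezoidal interpolation, which overestimates
  PR areas; all-tied scores give the prevalence.
* **Precision@k%** takes the top `ceil(k/100·N)` items under a stable sort
  with a deterministic secondary key (the gene pair, else input index), so
  ties resolve identically on every platform.
* Repeated evaluation uses split seeds `0..n_runs−1` (overridable) and
  reports mean ± sd with the n−1 denominator; a single run reports sd 0
  with a flag.
* The ablation harness replaces disabled omics sources with shape-matched
  standard-normal features and disabled network views with uniform random
  edge sets of equal size, and can bypass the transformer stage, leaving
  everything else bit-identical.
* Screen comparison uses the Pearson chi-square without continuity
  correction (the motivating counts are in the hundreds); Yates correction
  is available by flag. Hub rankings break ties alphabetically. A pair's
  pathway stratum is the unordered pair of its genes' pathways; genes with
  multiple annotations take the first mapping in file order, with a warning.

## Numerical and implementation choices

* The encoder stack runs on a minimal in-package reverse-mode autodiff
  engine over numpy float64 (dense matmul, ReLU, row softmax, parameter-free
  layer norm, dropout masks, batched attention matmuls, row gathering,
  Adam). All gradients are verified against central finite differences in
  the test suite; attention rows are checked to be probability vectors.
* Glorot-uniform initialization; biases start at zero; all randomness
  (init, dropout, gene splits) comes from substreams of `ModelConfig.seed`,
  making trained parameters and histories exactly reproducible.
* GI labeling is strict (`score < −3`); a score exactly at the threshold is
  non-SL. Pairs are canonicalized to `(min, max)` lexicographic order
  everywhere, so every operation is order-invariant; self-pairs and
  conflicting duplicate records are integrity errors.
* Constant features standardize to zero rather than dividing by zero;
  degenerate strata report `N/A` metrics rather than failing; an all-zero
  connectivity vector still yields a deterministic (alphabetical) hub
  ranking, with a warning.
* "Not expressed" for cell-line network filtering means expression ≤ 0
  after log-scale loading — strictly positive expression is required for a
  node to survive.

## Known limitations

* Dense attention and dense normalized adjacencies are O(N²) memory; the
  package targets screen-scale gene universes (hundreds to a few thousand
  genes), not genome-wide prediction.
* Step 2 uses connectivity-derived features only; feeding raw embeddings
  alongside them is a plausible extension the current design deliberately
  omits to keep the second step interpretable.
* Real-data ingestion is format-level only (TSV screens, feature tables,
  edge lists, pathway maps); no downloaders and no gene-symbol
  harmonization beyond exact matching.
* The desk-scale preset trades capacity for speed; its absolute metric
  values on synthetic benchmarks say nothing quantitative about real-screen
  performance.
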