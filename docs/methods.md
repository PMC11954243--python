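# Methods

This note documents the modelling choices, defaults and numerical
conventions behind `amogel`, and what the synthetic benchmark does and does
not establish.

## Inputs and identifier handling

The pipeline consumes three per-omics numeric matrices (samples × features),
a sample→subtype label table, a STRING-style PPI table (`gene_a`, `gene_b`,
`combined_score` on the 0–1000 scale) and DAVID-style annotation charts
(`term`, `p_value`, comma-separated gene list) for KEGG and GO. Gene symbols
are upper-cased and whitespace-stripped before any cross-source matching.
Features are assumed to already be gene-level symbols; no probe-to-gene
mapping is performed. A symbol present in two omics layers is kept twice
under `<omics>:<symbol>` unique ids; prior-knowledge matching strips the
prefix and matches on the raw symbol, bridging mRNA and methylation layers.
miRNA nodes never receive PPI edges (protein networks do not cover them);
term channels match any node whose symbol appears in a term's gene list.
Duplicated samples or features are aggregated by mean at load time; a
feature with any missing value is dropped rather than imputed — with
thousands of candidate features per omics, imputation buys little and risks
leaking structure.

## Preprocessing

* **Variance filter** keeps features with population variance strictly
  above 0.001 (applied per omics).
* **ANOVA-F selection** keeps the k largest one-way F statistics per omics
  (defaults scale with the cohort; miRNA defaults to "all" since that layer
  is narrow). Selection runs per omics *before* concatenation; an
  alternative post-concatenation mode exists for the feature-selection
  ablations. The stratified split is drawn first and the F statistics are
  computed on training rows only, so every fitted quantity — selected
  features, cutpoints, rule statistics, model weights — derives from the
  training split alone.
* **PC1 diagnostic**: after selection the first principal component of the
  standardized matrix should explain < 50% of variance; the pipeline warns,
  but does not fail, above that.
* **Split**: stratified 7:3 with `round(0.7 · class size)` training samples
  per class, seeded; repeated over the trial seeds.
* **Discretization**: per-feature cutpoints are the 33.33rd and 66.67th
  percentiles (linear interpolation) of the *training* values — three
  labels map naturally onto training tertiles; an equal-width variant is
  available by config. `level = low if v ≤ c1, medium if c1 < v ≤ c2, else
  high`; constant training features map everything to low (such features
  are normally removed by the variance filter first). Test rows reuse
  training cutpoints, keeping discretization leakage-free and monotone.

## Rule mining

Transactions are per-class training samples; every transaction carries one
(feature, level) item per feature. Closed frequent itemsets (no proper
superset with equal support) are mined by a levelwise Apriori enumeration
over a boolean transaction matrix; closure is decided by the one-item
extension test, which is exact even under the antecedent-length cap
(default ≤ 3 items, for tractability at hundreds of features — observed
rule sets are dominated by short antecedents anyway). The minimum support
starts at 0.9 and decreases by 0.05 until the closed-itemset count reaches
the per-class budget (default: the top-k size) or the floor 0.1; a
`1 − 1/n`-scaled initial support is available by config. Searching per
class keeps rule counts balanced across subtypes of unequal prevalence.

Confidence is computed over the full training database (per-class
confidence would be identically 1). The interestingness score
`log₂(infogain) + log₂(correlation) + log₂(confidence)` uses antecedent
means of two per-gene statistics computed on training rows:

* **infogain**: empirical mutual information (bits) between the 3-level
  feature and the subtype label;
* **correlation**: the largest absolute Pearson correlation between the
  0/1/2 level code and a one-vs-rest class indicator, clipped to [0, 1].

A zero component makes the score −∞; such rules sort after every finite
score. Ties break by support (descending) then lexicographic antecedent,
making the selection a total order. The default rule budget k is 1000 per
class; the scaled-down synthetic runs use 150. Database-coverage (CBA-style)
pruning is exposed only as an interface stub.

## Graph

Channel 0 (information) links every gene pair co-occurring in a kept rule
with weight `(infogainᵢ + infogainⱼ + corrᵢ + corrⱼ)/4`, zeroed at ≤ 0.3.
Channel 1 (PPI) is `combined_score/1000` for pairs with score ≥ 500 (the
threshold is inclusive); two nodes carrying the same symbol in different
omics layers are linked with weight 1.0 when that symbol occurs in the
retained network. Channels 2–3 (KEGG, GO) are binary co-membership in a
term with p < 0.05. The prior channels are scaled by λ = mean of the
*nonzero* information weights: averaging over all m² entries would shrink λ
toward zero as the graph grows and extinguish the priors, contradicting
their auxiliary role; the all-entries mean remains available by config.
All adjacencies are symmetric with zero diagonals; an edge exists wherever
any channel is nonzero, and a graph with no information edges is an error
(λ undefined).

## Model

Both branches are trained jointly on a small numpy reverse-mode autodiff
engine shipped with the package (`amogel.autodiff`), gradient-checked
against central finite differences in the test suite.

* **Graph branch.** Node features are one-hot low/medium/high. An input
  projection (3 → hidden) is followed by two attention layers. Each layer
  updates `h'_μ = α_μμ Θ_s h_μ + Σ_ν α_μν Θ_t h_ν` with logits
  `LeakyReLU(a_dst·Θ_s h_μ + a_src·msg_ν + a_e·W_e e_μν)` softmax-normalized
  over the closed neighborhood {μ} ∪ N(μ). The learned projection `W_e` of
  the 4-channel edge attribute is the point of the multi-channel graph; a
  config flag drops the edge term for a plain endpoint-only attention.
  Two layers are used — deeper stacks oversmooth — with ELU activations,
  concatenated skip connections (input ‖ layer 1 ‖ layer 2), global mean
  pooling over nodes and a shallow dense block. Self-loops carry a zero
  edge attribute.
* **Global branch.** The graph encoder only sees 3-level codes; the global
  branch feeds the continuous, training-standardized values of the same
  genes through a feed-forward network, recovering the amplitude
  information discretization discards.
* **Head.** Branch embeddings are concatenated and classified by a dense
  softmax layer; ablations disable either branch (at least one must stay).
* **Training.** Full-batch categorical cross-entropy under Adam with
  coupled L2 weight decay 1e-3. Paper-scale defaults are lr 5e-5 for 500
  epochs; the synthetic benchmark uses lr 0.01 for 100 epochs because
  full-batch training takes exactly one optimizer step per epoch, two
  orders of magnitude fewer steps than a mini-batched run at the same
  epoch count. Hidden width 32 (16 in the scaled-down runs), 4 heads,
  dropout 0.2, LeakyReLU slope 0.2. Seeded initialization and dropout make
  runs bit-reproducible on one device; a non-finite loss aborts with the
  epoch index.

## Gene ranking

Attention is recorded head-averaged per layer, sample and directed edge.
A gene's score is the *incoming* attention mass
`mean over samples of Σ_{j≠i} (α¹_ji + α²_ji)/2`. Summing a node's own
outgoing softmax row instead is vacuous — every row sums to 1 by
normalization — so the incoming reading is the default and the outgoing
one is kept only behind a flag for audit. Self-coefficients measure
self-retention, not gene–gene interaction, and are excluded. Ties break
lexicographically. When several trials are run, the biomarker list comes
from the best trial (highest test accuracy, ties by macro F1 then seed
order).

## Evaluation

Accuracy, macro F1 (per-class F1 = 0 when precision + recall = 0) and
one-vs-rest macro AUROC with midrank tie handling; classes absent from the
test labels are skipped with a warning. The repeated-split protocol runs
the whole pipeline once per seed and reports mean and population STD.

## Synthetic benchmark

The generator emulates the *shape* of real cohorts: three omics layers of
unequal width (default 100/70/30), Gaussian background noise, per-class
mean shifts of `effect_size` SDs on a few planted features spread across
all layers, and prior tables wiring a configurable fraction of planted
genes (PPI scores uniform in [500, 1000]; enriched terms p < 0.05) next to
decoy edges and terms that every threshold must reject (including a fixed
PPI row at score 400 and a term at p = 0.2). Default study conditions:
3 classes × 50 samples, 5 planted features per class, effect size 3,
prior overlap 0.5.

What passing these conditions shows: the mining, graph, training and
ranking machinery recover strong, clean planted signal end to end, and
every filter and threshold acts as specified. What it does not show:
performance on real TCGA-scale data — the generator has no correlated
background structure, batch effects, label noise, heavy-tailed marginals
or class imbalance, so real-data accuracy claims cannot be transferred.

## Numerical conventions and limitations

* All tie-breaks (ANOVA ranks, rule order, gene ranking) are lexicographic
  by feature uid — reproducibility over arbitrariness.
* Support comparisons use a 1e-9 slack against the count threshold to
  absorb float rounding of `min_support · n`.
* Softmax and log-softmax subtract detached per-group maxima for stability.
* Duplicate PPI pairs collapse to their maximum score.
* The Apriori miner is exact but enumerative; it is sized for the
  hundreds-of-features regime that follows ANOVA selection, not for raw
  20k-gene matrices.
* The staged CLI recomputes upstream stages deterministically from the data
  directory and seed rather than deserializing model checkpoints; stage
  artifacts (rules, graph bundles, splits, reports) are plain JSON/TSV.
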