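# Methods

`atrokg` implements a four-stage analysis that goes from gene-expression
matrices to ranked candidate drug–disease links. This note records the
models behind each stage, the tunable parameters and their defaults, what
the synthetic study systems do and do not emulate, and the numerical and
design choices that were genuinely open.

## Stage 1 — gene-pair inference

**Pearson selection.** For every unordered gene pair the sample correlation
r is computed over the n samples and converted to a two-sided p-value via
the t transform `t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of freedom.
Pairs with `p < 5×10⁻⁷` (the default threshold) are selected; selection is
two-sided, so strong negative correlation qualifies. Zero-variance genes
are excluded before testing (their correlation is undefined) and logged.

The p-value cutoff and an `|r| ≥ 0.9` cutoff select the same pairs only at
one sample size. `equivalence_sample_size()` computes it: for each n the
p-threshold corresponds to an |r| cutoff `r_c(n) = t_c/sqrt(n−2+t_c²)`,
which is monotone decreasing in n; the function returns the n whose r_c is
closest to 0.9. With the default thresholds this is **n\* = 18**
(r_c = 0.8958). At any other n the two rules genuinely disagree, so the
equivalence is a property of the sample size, not of the data.

**IAMB.** The Markov blanket of a gene — its parents, children and spouses
in the generating Bayesian network — is recovered by the incremental
association grow/shrink procedure. Conditional independence on continuous
expression data is assessed by the partial-correlation Fisher-z test: the
partial correlation of x and y given S comes from the inverse of the
correlation submatrix over {x, y} ∪ S, and `z = atanh(r)·sqrt(n−|S|−3)` is
referred to a standard normal. The grow phase repeatedly adds the candidate
with the smallest p-value below `alpha` (default 0.01) given the current
blanket; the shrink phase removes members that become independent given the
rest. Conditioning sets are capped at n−4 so the z statistic stays defined.
The test is exact for the linear-Gaussian systems the generator produces;
on real expression data it is the standard Gaussian approximation.

Per-dataset extraction then union across datasets is the default (sample
concatenation across small heterogeneous datasets invites batch artifacts);
the merged list keeps one canonical record per pair with the originating
method tags.

## Synthetic study systems

**Expression.** `simulate_expression` draws from a linear-Gaussian
structural equation model over a user-specified acyclic network: each gene
is its parents' coefficient-weighted sum plus independent Gaussian noise,
sampled in topological order. The implied covariance `(I−C)⁻¹D(I−C)⁻ᵀ` is
available in closed form and is what the variance/correlation tests check
against. `random_regulatory_network` draws random DAGs with coefficient
magnitudes in [0.6, 1.4] — bounded away from zero so conditional
dependences remain detectable (faithfulness in practice). Gaussian noise is
a modeling choice; nothing in the pipeline depends on it beyond the CI
test's exactness. What this does **not** emulate: counts/over-dispersion,
normalization artifacts, batch effects, or measurement error correlated
across genes. Passing tests therefore show correctness of the inference
machinery under its own assumptions, not robustness to RNA-seq noise.

**Gene–disease graph (GDKG scale).** 473 genes × 100 diseases. Each gene
receives a target degree from a capped Pareto draw
(`base_degree·(1−u)^(−attachment_exponent)`, clipped to [1, n_diseases];
defaults 4 and 1.0), producing the heavy-tailed gene-degree profile with
span from 1 up to the disease count. Disease partners are sampled without
replacement by preferential attachment (weight = current disease degree
+ 1) modulated by community structure: genes and diseases carry one of
`n_blocks = 4` block labels and within-block partners get
`block_affinity = 4.0` times the weight. A `holdout_fraction` (0.2,
mirroring the 80/20 gene-disease split) of edges is withheld as planted
positives such that no node is isolated. These conditions — popularity bias
plus blocks — were fixed once as the study conditions for all evaluations.

**Disease–drug graph (DDKG scale).** 100 diseases × 98 drugs; every
disease is linked to exactly `drugs_per_disease = 10` distinct drugs drawn
with a Zipf popularity bias (`usage_weight ∝ rank⁻¹`) and the same block
affinity; each drug's popularity weight is stored on the node as the
generator's notion of "how commonly used" a drug is. Drugs never link to
drugs or genes. Because every disease has degree exactly k, every drug
node's neighborhood connectivity equals k in the full construction — the
structural invariant the acceptance suite checks exactly. The holdout
default for this graph is 0.4 (60/40 split). Unused drugs are wired in by
swapping one edge away from a well-connected drug, preserving per-disease
counts. The generators do not emulate real disease vocabularies, curated
drug-database identifiers, or multi-relational edge types.

## Stage 2 — graph measures

Graphs are undirected and typed; every edge joins different types.
Node-level measures: degree; neighborhood connectivity (mean neighbor
degree; undefined → NaN for isolated nodes); eigenvector centrality by
power iteration to 1e−8 on A + I (the shift leaves the principal
eigenvector unchanged while suppressing the −λ₁ oscillation that stalls
power iteration on bipartite graphs), per connected component, each
component normalized to unit Euclidean norm; subgraph centrality
`Σ_k (Aᵏ)_vv / k!`, evaluated exactly through the symmetric
eigendecomposition `Σ_j U²_vj e^{λ_j}` (the tests cross-check a truncated
power series). Graph-level: density `2|E|/(|V|(|V|−1))`, average neighbor
count `2|E|/|V|`, and spectral gap. **Spectral-gap convention:** λ₁ − λ₂ of
the adjacency matrix, eigenvalues sorted descending. Other conventions
(normalized-Laplacian gap, λ₁ − |λ₂| with signed second eigenvalue) exist;
users comparing against externally reported values should check which
convention those used.

## Stage 3 — features

**Walks.** Second-order biased random walks: step weights are the edge
weights divided by `p` for returning to the previous node, unchanged for
moving to a neighbor of the previous node, divided by `q` otherwise, then
renormalized. `p = q = 1` reduces exactly to the first-order transition
model `P = T⁻¹A`, which the goodness-of-fit test checks empirically. Walk
defaults used throughout the evaluations: 4 walks per node of length 30.
The classic feature-learning settings (10 walks of length 80, window 10,
dimension 128) remain available through the config; the smaller corpus is
adequate for graphs of a few hundred nodes and keeps repeated
cross-validation affordable.

**Embeddings.** Skip-gram with negative sampling over walk windows,
implemented vectorised in numpy: per-token shrunk windows, 5 negatives
from the unigram^0.75 noise distribution, linearly decaying learning rate
(0.025), minibatches of 16384 pairs. Within a minibatch, per-row gradient
sums are applied with the row's step norm capped at 0.5: frequent nodes
appear thousands of times per batch, and uncapped summed steps diverge on
larger corpora. Defaults: dimension 64, window 5, 3 epochs. A single seeded
generator drives initialisation, window draws, shuffling and negative
sampling, so a fixed seed reproduces the table bit for bit.

**Edge features.** Two node vectors are combined by the elementwise mean
(default), hadamard product, absolute difference, or concatenation
(order-sensitive, doubles the dimension). The mean is the default because
it is symmetric, dimension-preserving, and — unlike the hadamard product —
keeps the information carried by each endpoint's vector on its own: on
popularity-dominated bipartite graphs the hadamard product of two
skip-gram vectors turned out to be nearly uninformative (a linear probe
scores ~0.5 there, against ~0.7 for mean), and it also squares shared
features, losing their sign.

**Node centrality features** for the tree learners: degree, eigenvector
centrality, log subgraph centrality (logged because the raw value spans
many orders of magnitude), neighborhood connectivity (0 for isolated
nodes so tables stay finite).

## Stage 4 — link prediction

**Labeled sets.** Positives are graph edges; negatives are sampled
uniformly from cross-type non-edges of the full graph (same-type pairs are
never candidates), 1:1 by default, disjoint between splits and re-drawn
per fold with the fold seed. Graph-derived inputs — centrality tables,
walk corpora, embeddings, and the GCN's normalized adjacency — are always
computed on the training graph with test positives removed, so no label
information leaks through the graph structure.

**Learners.** Random forest: 500 trees of depth ≤ 15. Gradient boosting:
learning rate 0.2, 100 stages. MLP ("GNN"): ten ReLU hidden layers of 100
units trained by L-BFGS on embedding edge features; inputs are
standardized first — without scaling, gradients vanish through the deep
ReLU stack and the quasi-Newton line search fails at the first step.
Preferential attachment: the score |Γ(u)|·|Γ(v)|; only its ordering enters
AUROC, with min-max scaling available for probability-style reporting.

**GCN.** Two propagation layers
`H(l+1) = σ(D̄^(−1/2)(A+I)D̄^(−1/2) H(l) W(l))` with 32 then 16 units, ReLU
between, identity + node-type one-hot input features (the standard
featureless choice; it keeps the method structure-driven). A pair is
scored by the logistic squashing of the inner product of its two 16-d
output embeddings. A ReLU output cannot produce values bounded by 1, so
probabilities come from the logistic function; this is the package's
documented reading of an output layer that must emit probabilities. Loss
is binary cross-entropy over the labeled pairs; optimisation is full-batch
Adam (learning rate 0.03, 2000 epochs). The L2 weight decay is selected
from a small config ladder (1e−4, 1e−3, 1e−2) because how much the
per-node identity weights need to be regularised scales with graph size.
Selection is internal: 10% of the labeled training pairs are held out, and
— crucially — their positive edges are also removed from the
message-passing graph during fitting, otherwise a memorising model reads
them off the adjacency and wins selection without generalising. The kept
checkpoint is the best validation AUROC within the winning run (evaluated
every 50 epochs); a run's quality is its mean validation AUROC over the
second half of training, a steadier estimate than any single checkpoint.
Training passes through two regimes — a degree-dominated plateau and a
later escape that picks up community structure — which is why checkpoint
selection matters. The validation split never touches held-out test pairs.

**Evaluation.** AUROC uses the rank (Mann–Whitney) formulation with ties
counting one half; it equals the concordant-pair fraction, which the tests
verify by brute force. Cross-validation partitions edges into k = 10
folds; each fold's positives are withheld from training and from the
message-passing graph, matched negatives are drawn with the fold seed, and
the aggregate is the **mean of fold AUROCs** (the per-fold values are also
reported). Ranked novel-link tables exclude existing edges, sort by
descending probability with lexicographic tie-breaks, and apply reporting
cutoffs of 0.8 (gene–disease) and 0.7 (disease–drug).

## Problem sizes used by the test and acceptance runs

Planted-link recovery runs at the full graph scale (473 × 100, 20%
holdout) over 5 generator seeds with single train/test splits; blanket
recovery uses 50 replicate datasets × 10 targets at n = 2000; the
determinism check runs the complete pipeline twice on a reduced
configuration (50 × 14 gene–disease, 14 × 12 disease–drug, 2 folds).
These sizes were chosen to exercise every component at meaningful scale
while keeping a full run of the suite in the minutes range.

## Known limitations

- The Gaussian CI test and the linear SEM match each other; neither claims
  fidelity to RNA-seq noise.
- The graph generators plant popularity and block structure only; real
  knowledge graphs carry typed multi-relational evidence the learners here
  never see.
- The GCN is single-relation and CPU-bound by design; no sparse-minibatch
  or GPU path exists.
- Preferential attachment is a strong baseline on popularity-driven graphs;
  margins of learned methods over it on such synthetic graphs are real but
  modest, concentrated in the planted community signal. On the small
  disease-drug graph the learned methods do not beat it at all (PA median
  ~0.73 against ~0.62-0.71 for the learners over five seeds): with only
  ~1200 training pairs and popularity dominating the generative law, direct
  access to degrees is worth more than anything the models infer. The
  gene-disease graph, ten times larger, is where the GCN's community signal
  pays off and the learned ordering emerges.
- With identical scores on all candidates (e.g. isolated nodes), AUROC's
  tie convention yields 0.5 by construction, not by learning.
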