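# Methods

## Knowledge graphs and layer assignment

Pathway relations are read as parent→child pairs (Reactome dialect). The
relation graph must be a DAG; a directed cycle aborts parsing with one
cycle named. Each pathway's layer is **1 + the longest directed path to a
leaf**, so layer 1 holds the most specific processes and every parent sits
strictly above all of its children. This choice makes the rule "a gene
connects to the lowest pathway level containing it" well defined and gives
every retained edge the parent-one-layer-up structure the masks need.
Layering depends only on descendants, so graphs with several roots need no
special handling beyond reporting all roots.

Two situations break the strict one-layer-up structure and are repaired
with **copy-through nodes** — synthetic nodes named `<pathway>::copy@<k>`
whose single incoming weight is frozen at 1, whose bias is frozen at 0 and
whose activation is the identity, making them exact pass-throughs:

* a hierarchy edge that skips layers (parent more than one layer above its
  child) carries the child upward through a frozen chain; when the parent
  lies above the retained depth `n_layers`, the chain still carries the
  child to the top retained layer so no branch dead-ends;
* a gene whose deepest membership sits at layer ℓ > 1 enters through a
  chain at layer 1 (the entry node aggregates the member genes with
  trainable weights; the chain above it is frozen).

Genes with no usable membership are dropped with a logged warning (strict
mode raises); they would be dead inputs. Mask row/column identifiers are
sorted lexicographically within each layer so masks are independent of
input file row order. Pathway masks are {0,1}; the regulatory mask stores
the curated signs {−1,+1}.

## Network, regulatory layer and heads

The Gene Input Layer maps the concatenated modality channels (modality ×
gene, modality-major) onto one node per gene through a block mask; the
hidden activation (default tanh; ReLU and linear available) applies to
every non-copy node. The regulatory layer is square over genes: column *t*
of its mask collects TF *t*'s targets plus a +1 self-link; its input is
the GIL output and its output is added element-wise to the GIL output
before the first pathway layer. Nodes without incoming regulatory edges
produce exactly zero (their bias is frozen at 0), so an empty regulon
reproduces the regulatory-free model parameter-for-parameter.

Signed entries constrain learning by default: effective weight =
sign · softplus(raw), so an activating edge can shrink toward zero but
never flip to repression (``signed_mode="free"`` lifts the constraint and
uses the sign only at initialization). Binary entries use the raw weight;
zero entries contribute nothing and receive identically zero gradient, so
sparsity is exact at every training step rather than approximately
enforced.

Every maskable layer (GIL, regulatory when present, each pathway layer)
carries an affine head producing one logit; the combined prediction is the
convex combination of head logits with weights ω = softmax of a per-head
scalar (a clamped-linear normalization is available). Initialization is
fan-in-scaled uniform restricted to nonzero mask positions, fixed per
seed.

## Training

The loss is the mean of the per-head binary cross-entropies plus the
cross-entropy of the combined logit — equal per-head weights, so every
pathway level receives direct gradient signal and its head is a meaningful
layer-local predictor. Optimization is Adam (default learning rate 1e-3),
full-batch or minibatch; with a validation fraction set, early stopping
restores the best state after a patience of 10 evaluations. Class
imbalance is handled by inverse-frequency sample weights. Dropout
(default 0.1) applies to pathway-layer outputs during training only.
All randomness flows through seeded NumPy generators; a fixed seed gives
bitwise-identical parameters single-threaded. Cross-validation is
stratified k-fold (10 by default; tests and the benchmark use 2–3 to keep
problem sizes small), and AUC-ROC is computed by the rank-sum formula with
average ranks, i.e. ties count one half.

Gradients are hand-derived and verified against central finite differences
in the test suite (reverse mode for parameters and inputs, forward mode
for the directional derivatives conductance needs).

## Attribution

Integrated Gradients integrates ∂F/∂x along the straight line from a
baseline to the sample, scaled by (x − baseline); the default target F is
the combined logit and the default baseline all-zeros (absence/reference
for mutation and expression encodings). Quadrature is the midpoint rule
with 64 steps by default (Gauss–Legendre optional); a linear model is
exact at one step, and on toy networks the completeness identity
Σ attr = F(x) − F(baseline) holds to 1% relative + 1e-6 absolute at 128
steps. Layer conductance scores hidden node *j* by
∫ (∂F/∂h_j) · (dh_j/dα) dα. Because earlier heads bypass deeper layers, a
layer's conductances sum exactly to F(x) − F(baseline) only when the layer
is a full cut between input and target — always true for the gene layer
and the combined logit, or for any layer when targeting a downstream
head's logit (per-head targets are exposed). Per-node importance is the
mean of absolute per-sample conductances; all evaluated samples are used,
not only correctly classified ones.

## Stability statistics

Top-N Jaccard stability averages the pairwise Jaccard index of the N
highest-importance node identifiers over all unordered run pairs, ties
broken by (score descending, node id ascending) for determinism; N
defaults to 20. SNR is mean over runs divided by ddof-1 standard
deviation; zero-variance nodes are reported as missing and excluded from
layerwise statistics with a logged count. Layerwise Z standardizes SNR
within each layer (genes form their own layer), and p-values are the
one-sided upper tail of the standard normal — the convention that
reproduces published Z/p pairs for this statistic, where two-sided tails
do not.

## Synthetic data

The generator emulates the curated inputs end to end: a balanced rooted
tree of configurable depth and branching (a DAG variant adds extra
parents), genes dealt to leaves so every gene has at least one membership
with overlap from leftover slots, and a regulon of randomly chosen TF
genes with equiprobable activation/repression signs. Cohorts carry two
modalities by default — one standard-normal continuous channel (an
expression-like signal) and one Bernoulli(0.1) binary channel (a
mutation-like signal) — with the member genes of randomly chosen causal
leaf pathways receiving a common log-odds effect through both channels;
labels are logistic draws with optional flip noise. Files are emitted in
the exact dialects the parsers read, byte-identical per seed.

The benchmark study conditions are 200 genes in 20 disjoint leaves of 10
(branching 5 × 4), one causal leaf — hence exactly 10 causal genes — with
effect 1.5, 600 samples and 5 independently seeded trainings of ~1000
minibatch Adam steps each; top-20 recovery is tested against a
permutation null of random 20-gene sets and pathway-node SNR dominance by
a one-sided rank-sum test over the 25 pathway nodes. These sizes keep a
full benchmark under a minute on one CPU while leaving the planted signal
strong enough that the Bayes-optimal classifier is far from chance.

What the generator deliberately does not model: expression covariance
between genes, batch effects, per-modality effect heterogeneity (a switch
exists but the default ties effects across modalities), copy-number-like
channels, or realistic pathway-size distributions. Passing the planted
benchmark therefore shows that the pipeline recovers causal structure it
is architecturally aligned with — not that it would rank genes correctly
under correlated, confounded real cohorts.

## Numerical and design notes

* Combined-logit BCE uses the log-sum-exp form; probabilities never
  saturate to exactly 0/1 in the loss.
* The softmax weighting subtracts its maximum; a clamped-linear weighting
  falls back to uniform when every scalar is non-positive.
* Mask serialization is a sparse triplet CSV plus a JSON index sidecar
  (row/column order, frozen positions, pass-through columns); round-trips
  are bit-exact, and checkpoints (masks + parameter arrays + YAML config)
  reproduce forward passes bit-identically on the saving platform.
* A possible residual connection adding gene representations directly
  into higher pathway layers is not implemented; the per-layer heads
  already give genes shortcut influence on the prediction, and the
  masks stay interpretable as pure hierarchy edges.
* The random-sparse baseline redraws each mask's nonzero positions
  uniformly without replacement and permutes the original entry values,
  preserving per-layer connection counts exactly; the gene-set baseline
  keeps curated gene→set membership in its first layer and matches later
  layers' connection counts to a reference stack.

## Known limitations

* Single binary outcome only (no multi-class or survival heads).
* The NumPy implementation is single-threaded and CPU-bound; it is sized
  for cohorts of hundreds to a few thousand samples and up to a few
  thousand genes, not genome-wide inputs with deep hierarchies.
* Importance SNR contrasts assume several independent runs (≥ 2, 5+
  recommended); with two runs the ddof-1 estimate is very noisy.
* Conductance on intermediate layers under the combined target measures
  routed — not total — contribution; use per-head targets for strict
  completeness on deep layers.
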