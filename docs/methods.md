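# Methods

## Model

A gene-superset autoencoder maps a logTPM expression profile
`x ∈ R^G` (G genes) through two encoder layers and back:

```
gene-set layer:   h = ReLU(b₁ + W₁ᵀ x),   W₁ ⊙ (1 − M) = 0
superset layer:   z = ReLU(b₂ + W₂ᵀ h)
decoder:          x̂ = b₄ + W₄ᵀ ReLU(b₃ + W₃ᵀ z)
```

`M` is the binary gene × gene-set membership mask, so each gene-set node
sees only its member genes; its activation is that sample's *gene-set
score*, and each latent node's activation is a *superset score* — a
learned, data-driven combination of gene sets. The decoder is fully
connected (the prior-knowledge constraint applies only to the first
layer). In classifier mode the decoder is replaced by a softmax layer
over class labels. Losses: mean squared error over genes (autoencoder)
or categorical cross-entropy (classifier).

Assumptions worth stating: expression is nonnegative logTPM
(log2(TPM+1)); gene symbols match the collection's naming
case-sensitively; ReLU activations are read as graded "pathway activity"
scores, which is meaningful only for reasonably large cohorts (hundreds
of samples) — single-sample scoring is out of scope.

## Training

Mini-batch SGD with Nesterov momentum and Keras-1.x decay semantics
(`lr_t = lr₀ / (1 + decay · t)`, t the update counter). After **every**
parameter update the first-layer weights and their momentum buffer are
re-multiplied by the mask, so masked-out weights are exactly zero at all
times — this is the whole sparsity mechanism, verified to machine
precision in the tests. Weights start He-uniform
(`±√(6/fan_in)`), biases at zero. A validation split (stratified in
classifier mode, drawn with the run seed) drives early stopping: stop
after `patience` epochs without a strictly better validation loss, keep
the final-epoch weights, record the best epoch. Training is a pure
function of (data, config, seed).

Stock defaults follow the historical recipe (superset layer 200,
lr 0.05, decay 10⁻⁶, momentum 0.9, Nesterov, 5% validation split,
patience 3); batch size 64 and a 200-epoch cap are this package's
defaults where the recipe is silent. That recipe was tuned for
~10⁴ × ~10⁴ matrices. Because MSE gradients scale as 1/G, the same
learning rate is ~40× hotter on a 400-gene cohort and destroys the
network, while a 5% validation split of 300 samples makes early stopping
fire inside the initial optimization plateau.
`NetworkConfig.small_cohort()` is the package's recipe for
desk-scale cohorts: lr 0.01, patience 50, 10% validation, 2000-epoch
cap, 20 supersets (classifier variant: lr 0.005, patience 100 — the
cross-entropy loss has a different gradient scale). All of these are
ordinary config fields.

### Selective activation (important limitation)

With symmetric He initialization and all-positive inputs, roughly half
of the gene-set nodes start with negative expected pre-activation, and
training settles into optima where ~40–60% of nodes are permanently
inactive (output 0 for every sample). This is not an implementation
artifact: it persists across learning rates 10⁻⁴–5·10⁻², momentum
0–0.9, any batch size, and thousands of epochs, and the gradient was
verified numerically. It is intrinsic to ReLU + nonnegative data +
redundant sets: the network can reconstruct a dead set's information
through overlapping active sets (or absorb the loss when it cannot), and
a fully dead node receives zero gradient forever.

Consequences for analysis: a dead gene-set node has gsScore exactly 0
and can never rank highly; a planted signature whose nodes all die in a
given run is invisible to that run. Which nodes survive depends on the
initialization seed, so multi-run ensembles (medians over seeds, or
frequency of appearance across runs) are the recommended reading of any
per-gene-set ranking; the acceptance script reports seed-ensemble
medians for exactly this reason.

## Gene-set preparation

Sets outside the 15–500 member window are dropped (the classic
enrichment-analysis window). Similarity between two sets is Cohen's
kappa of their membership indicator vectors over the collection's gene
universe (the union of all member genes, making the result independent
of any particular expression matrix). Significance is a one-sided
z-test of H0: κ = 0 using the large-sample null standard error computed
from the 2×2 table's marginals (Fleiss):

```
Var₀(κ) = [p_e + p_e² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)] / [n (1 − p_e)²]
```

Pairs with κ > 0 and P < 10⁻⁷ become graph edges; clusters are connected
components (the minimal assumption for "clustered"); each cluster is
represented by its largest member, ties broken toward the
lexicographically smaller name.

## Subtype analysis

Superset scores are embedded with t-SNE (perplexity 30; an optional PCA
projection first, meant for raw logTPM inputs) and clustered with
HDBSCAN (`min_cluster_size = max(10, 1% of samples)` by default); noise
samples are excluded from every downstream comparison. For a chosen
cluster ("group 1") versus the union of the other clusters ("group 2"),
each superset is tested with a one-tailed Mann–Whitney U test with
location shift μ in both directions; μ sets the stringency and must be
chosen relative to the score scale (≈9 for TCGA-scale gene-set scores;
0.5 is appropriate for this package's synthetic fixtures, whose superset
scores have spread ~1–3). Exact enumeration is used when both groups
have ≤ 8 tie-free observations, otherwise the tie-corrected normal
approximation. No multiple-testing correction is applied across
supersets (raw P < 0.01), matching the original protocol.

Within a significant superset *j*, gene set *i* is scored
`gsScore_ij = (μ₁⁽ⁱ⁾ − μ₂⁽ⁱ⁾) · w_ij` (group means of the gene-set
score × the learned gene-set→superset weight). High-impact sets lie
beyond 2 standard deviations of the superset's gsScore distribution
(right tail for up-supersets, left for down). The PScore column is
−log₁₀ of a gene-set-level Mann–Whitney p-value with location shift 0.5,
taken in the direction of the observed mean difference.

## Survival analysis

Each node's score dichotomizes the cohort at its median (ties go to the
low group; a split with > 90% ties is refused) and the two halves are
compared with the standard two-sided Mantel–Haenszel log-rank test
(lifelines). Survival records are censored administratively at 1825
days; an event exactly at the horizon remains an event. Prognostic
screening keeps nodes with P below α (0.001 for the headline screen,
0.05 inside the reproducibility protocol) ranked by p-value. For a
prognostic superset, the two groups entering the gsScore formula are the
median-split halves of that superset's own score (high half = group 1).

The reproducibility experiment: simple random 60/40 split with the run
seed, autoencoder trained on the 60% only, both splits encoded and
screened independently, per layer (supersets, gene sets) the Jaccard
index of the two significant lists and the overlap proportion
|train ∩ test| / |train|, and a one-sided pooled two-proportion z-test
of "superset proportion > gene-set proportion". Layers with zero
train-significant nodes report missing proportions rather than a number.

## Synthetic cohorts

The generators emulate the *shape* of preprocessed bulk RNA-seq, not any
real cohort's marginals: baseline logTPM is `max(0, N(2, 1))` per gene
(so every gene passes the μ > 1, σ > 0.5 filter at cohort sizes of
interest), and every gene set behaves as a co-expression module — its
member genes share a per-sample N(0, 1) activity factor. The module
factors matter: without them the only shared signal is the subtype
indicator, the autoencoder has no reason to keep redundant set nodes
alive, and the latent collapses. Planted structure:

- **Subtype cohorts** — k balanced groups; each group's planted sets
  (disjoint, reserved gene blocks that background sets never touch) are
  shifted up by δ (default 2 logTPM) in that group.
- **Prognostic cohorts** — a latent per-sample program score u ~ N(0,1)
  is added (scaled by 1 logTPM/SD) to the member genes of 3 reserved
  sets, and event times are exponential with hazard
  `λ₀ exp(β·u)` (λ₀ = ln2/900 per day, β = 1), independent exponential
  censoring tuned to ~30% and the 1825-day horizon on top.
- **Background sets** draw members at random (incidental overlap only)
  unless a chained `overlap_fraction` is requested for redundancy
  experiments.

What passing tests on these cohorts shows: the statistics are correct
(they match brute-force oracles), the pipeline recovers planted signals
of realistic effect size, and screens are calibrated under the null.
What they do not show: robustness to real-data features the generator
omits — heavy-tailed and gene-specific marginals, correlated hazards,
batch effects, annotation errors, and collection sizes in the thousands.

## Numerical choices and degenerate inputs

- Gene filter inequalities are strict; sd uses the n−1 denominator.
- Kappa is refused for empty sets or sets equal to the whole universe.
- Mann–Whitney refuses all-tied inputs; differential testing skips such
  supersets with a warning.
- Log-rank requires ≥ 1 event; zero-event tables are an error, never a
  silent p-value.
- Cluster centers are component-wise medians; within-cluster spread is
  the mean distance to center (a radius, so Dunn's ratio compares like
  with like). Median centers make Dunn/IID exactly invariant under
  translation, reflection and axis permutation but only approximately
  under general rotation; the silhouette (macro-averaged over clusters,
  singleton silhouette = 0) is fully rotation invariant.
- The two-proportion z-test is pooled, without continuity correction,
  and refuses pooled proportions of 0 or 1.
- Classifier ties resolve to the lowest class index; argmax on softmax.
- Model archives round-trip encode() bit-identically (exact float
  storage, no compression of values).

## Known limitations

Selective activation (above) is the main one. Others: no gene-identifier
mapping (symbols must match the GMT), no GPU path (pure numpy — fine for
desk-scale, slow for 10⁴×10⁴ cohorts), no Cox models or multivariate
adjustment in the survival layer, and t-SNE/HDBSCAN hyperparameters are
exposed but not auto-tuned.
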