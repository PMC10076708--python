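# Methods

## Problem setting

Given a binary disease×microbe association matrix `A` (nd diseases, nm
microbes), the task is to score every unobserved pair so that true but
unrecorded associations rank ahead of non-associations.  There are no
verified negative pairs in this domain; all unknown cells are treated as
the negative class, both during training and during evaluation.

## Similarity views

Two profile-based views need nothing beyond `A`:

* **GIP kernel** `exp(−λ‖p_i − p_j‖²)` with `λ = 1 / mean(‖p‖²)` over the
  axis.  For binary profiles the squared Euclidean norm equals the row
  sum, so no ℓ1/ℓ2 ambiguity arises (asserted in tests).  An all-zero
  matrix has no defined bandwidth and is rejected.
* **cosine** of association profiles.  A zero profile has no evidence of
  similarity to anything, including itself: its entries (and diagonal) are
  0 rather than NaN.

Two knowledge-based views use optional auxiliary inputs:

* **disease functional similarity (DFS)** from annotated gene sets
  `G_i`, averaging each gene's best match in the other set.  The pairwise
  gene score is 1 for identical genes and the min–max-normalised LLS for
  interacting genes.  Non-interacting gene pairs score 0: absence of an
  edge is absence of evidence, consistent with the normalisation's lower
  bound.  Diseases without annotation score 0 against every other disease
  (diagonal forced to 1) and are reported in a warning, so annotation
  coverage stays visible.  A degenerate network whose LLS values are all
  equal cannot be normalised and raises an error.
* **microbe functional similarity (MFS)** through the diseases each
  microbe associates with, using Wang-style DAG semantic similarity: the
  contribution of an ancestor to a disease decays by 0.5 per generation
  along the best path (`SC(dt) = 1`, `SC(a) = max 0.5·SC(child)` over the
  children inside the ancestor set), and two diseases are compared by
  shared-ancestor contributions normalised by their semantic values.  The
  recursion is evaluated with memoisation over the ancestor-induced
  subgraph only.  Diseases missing from the ontology count as isolated
  nodes — similar only to themselves, a conservative default.

Views fuse by unweighted elementwise mean.  When an auxiliary input is
absent the fusion averages the available views only (the divisor is the
number of included views); the default pipeline uses all three per axis.
The fused blocks and `A` assemble into the heterogeneous network
`Y = [[DS, A], [Aᵀ, MS]]`, diseases indexed first.

## Generator, critic, and training objective

The generator input features are the rows of `Y` itself — each node is
described by its similarity-and-association profile.  (A seeded Gaussian
noise input is retained as an ablation switch, `noise_input=True`.)

Layers: `F^l = ReLU(Ỹ F^{l−1} W^{l−1})` with `Ỹ = D^{−1/2}(Y+I)D^{−1/2}`.
Self-loops are added before normalisation by default; similarity diagonals
are already 1, so degrees are positive either way, but the flag protects
association-only ablations.  The aggregated embedding is

    h = Y P + Σ_{l=1..L} w_l F^l,    w_l = 1/L,

where `P` is a learned projection (needed because the input width n and
the embedding width differ).  The cross-level weights make the embedding
an average over receptive-field depths rather than the deepest layer
alone, which is what keeps depth-4 stacks from over-smoothing (the
depth-robustness check in the acceptance suite measures exactly this).
Pair scores are the bilinear decoder `S = h_d h_mᵀ` over the disease and
microbe row blocks; a sigmoid is applied for reporting only, never for
ranking.

Training follows the weight-clipped Wasserstein recipe.  The critic — one
ReLU hidden layer, affine output, no output nonlinearity — receives rows
of the real `Y` and rows of the reconstruction `h hᵀ`; per epoch it takes
`critic_steps = 5` RMSProp ascent steps on `mean c(real) − mean c(fake)`
with all weights clipped to ±0.01 afterwards, then the generator takes one
descent step on

    L_G = −α · mean c(h hᵀ) + β · BCE(σ(S), A_train),

with adversarial weight α = 2 and reconstruction weight β = 1.  The BCE
term is an addition beyond the plain adversarial objective: with a few
hundred positives, the critic alone is weak supervision.  The adversarial
term, in turn, is the effective regulariser — it pushes the whole
reconstruction toward the similarity structure of `Y`, and removing it
(critic_steps=0) measurably overfits.  All generator weights carry an L2
penalty (`weight_decay = 0.02`); with the learned skip `Y P`, node rows of
`Y` are nearly orthogonal and each node otherwise has enough free capacity
to memorise its own training row, which generalises poorly.

Both networks are trained with RMSProp (ρ = 0.9) at learning rate 2e-3.
RMSProp's normalised step means roughly `lr × epochs` total parameter
movement; at the package default of 200 epochs, 2e-3 is the rate at which
training converges without divergence, and together with the decay and
adversarial weights above it was fixed once as the package default.  All
gradients are hand-derived and verified against central finite differences
in the test suite.

Everything is float64 NumPy on one thread; a fixed `random_state` makes
training bit-for-bit reproducible, which the tests assert at the byte
level on exported score files.

## Cross-validation protocol

Known positives are split into k balanced folds (sizes differ by at most
one).  Per fold, the test positives are zeroed in the training matrix and
**all similarity views are recomputed from the masked matrix** — computing
them once from the full matrix would leak each test edge into the features
of its endpoints.  A `static_similarity` flag reproduces the leaky variant
for comparison only.  Held-out positives are then scored against every
pair unknown in the *full* matrix; training-fold positives are excluded
from test scoring.  Two controls guard the protocol: a leakage canary
(scoring with the masked training matrix itself) must sit at AUC 0.5, and
a cheat oracle (scoring with the held-out truth) must reach 1.0.

AUC is the trapezoidal area under the TPR/FPR threshold sweep, with tied
scores sharing a threshold, so it equals the tie-corrected Mann–Whitney
rank statistic; the test suite checks that identity exactly against an
O(n²) pairwise-count oracle.  Ranked candidate lists exclude known
positives and break score ties lexicographically by microbe identifier so
rankings are stable across runs.  A degree-product baseline
(`score(d,m) = rowdeg(d)·coldeg(m)`) provides the popularity-only
reference.

## Synthetic study conditions

The default fixture is 40 diseases × 60 microbes in 4 matched blocks,
within-block association probability 0.25 over a 0.01 background — a few
hundred positives, the scale class of small curated databases.  Draws are
regenerated wholesale (not patched) until every row and column has a
positive; this conditioning inflates the positive count slightly above the
unconditional binomial expectation at the default sparse background (~5%),
which is accepted as the cost of a clean cell distribution.  The gene
fixture gives each block a disjoint core gene pool; a disease takes each
core gene with probability `annotation_overlap = 0.8` and foreign genes
with a small leak probability, over an Erdős–Rényi gene graph
(48 genes, edge probability 0.15, LLS uniform on [0.5, 5]).  The DAG
fixture hangs one spine node per block under a shared root before fanning
into `dag_branching = 2` anchors; the shared spine guarantees within-block
semantic similarity strictly exceeds the cross-block value regardless of
anchor assignment.  Under these defaults the fused disease similarity
separates blocks (Mann–Whitney p < 0.01 over 20 seeds) — that separation
*is* the learnable signal.

What the fixtures deliberately do not emulate: real taxonomies and
ontology depth heterogeneity, hub diseases with hundreds of associations,
annotation noise and database biases, and the literature-level correlation
between views.  A passing suite therefore shows that the pipeline recovers
*planted block structure* under leak-free evaluation; it does not certify
AUC levels on any real database.

## Numerical and degenerate-input choices

* Symmetry of similarity matrices is enforced at 1e-12; the GIP Gram
  expansion clips tiny negative squared distances from rounding.
* `normalize_graph` rejects zero-degree nodes (naming them) unless
  self-loops repair the degree.
* `roc_auc` requires both classes; one-class input is an error, not NaN.
* Non-finite activations, reconstructions, or losses abort training with
  the epoch index rather than propagating silently.
* `k` beyond the number of positives, empty input files, malformed rows
  (named by line number), cycles in the ontology (one cycle listed), and
  non-numeric LLS scores are all hard errors; duplicate scored gene edges
  keep the last score with a warning, self-loop gene edges are skipped
  with a warning.
* Identifier matching is exact-string and case-sensitive; entities present
  only in auxiliary files are ignored with a warning.

## Known limitations

* An edge-list round trip preserves association content and disease order
  exactly, but the microbe registry can be permuted: with first-appearance
  ordering, no pair ordering can reproduce both registries in general
  (e.g. registries d1<d2 and m1<m2 with pairs {(d1,m2),(d2,m1)}).  One
  write/load cycle reaches a byte-stable fixed point.
* The critic sees node rows; whole-matrix flattening is available but
  untuned.
* Scores are relative ranks, not calibrated probabilities; the sigmoid
  reporting squash is monotone, nothing more.
* Problem sizes in the tests and the acceptance script (40×60 fixture,
  200 epochs, 5 folds, 3 fixture seeds) are the package's default study
  conditions; larger inputs run, but hyperparameters were fixed at this
  scale.
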