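# Methods

## Connectome construction

A subject's recording is a T × N matrix of ROI mean time series (T ≥ 3
timepoints, N ROIs; columns with zero variance are rejected as degenerate).
Functional connectivity is the Pearson correlation of every ROI pair,
variance-stabilised by the Fisher z-transform (arctanh). The diagonal is
excluded before the transform and fixed at zero. A perfect off-diagonal
correlation makes arctanh infinite; because synthetic fixtures can
legitimately contain duplicated signals, correlations are clipped to
±(1 − 1e−7) before the transform by default (`clip_perfect=True`), which
caps |z| at ≈ 8.41. With clipping disabled, |r| = 1 raises an error naming
the ROI pair.

Graphs retain the top M% of candidate edges. Candidates are the N(N−1)/2
upper-triangle entries; the number kept is round(M/100 × candidates),
half-up, so N = 200 and M = 25 give exactly 4975 edges. The ranking key is
|z| under the `abs` and `signed` conventions and z under `positive_only`
(negative entries are removed from the candidate pool first; if fewer
positive entries exist than the target count, all are kept and a warning is
issued). Under `signed`, ranking by magnitude — rather than by the signed
value — is a deliberate choice: ranking signed values would silently discard
every strong negative connection, defeating the purpose of a convention
whose point is to retain both connectivity signs. Ties at the density cutoff
are broken by (key descending, i ascending, j ascending), so graphs are
bit-reproducible across runs. Edge weights stay real-valued after
thresholding (they multiply neighbour messages in the GIN update; the graph
is never binarised). ROI ids are 1-based in every file format and public
table, 0-based in arrays.

## The classifier

Node features are one-hot ROI identities (input dimension N), in parcellation
file row order. Layer k of the GIN computes, for every node v,

    h_v(k) = MLP_k( (1 + eps_k) h_v(k−1) + Σ_{u∈N(v)} w_uv h_u(k−1) ),

i.e. in matrix form MLP_k(((1+eps_k) I + A_w) H). Because H(0) = I, the
first aggregation is formed directly as (1+eps) I + A_w without a product.
`eps` is per-layer: frozen at 0 (GIN-0, the default) or one learnable scalar
per layer initialised at 0.1 (GIN-eps). The two modes share initialisation,
so GIN-eps with `epsilon_init=0` reproduces GIN-0 exactly.

Each MLP has depth 2 (configurable): Linear → batch norm → ReLU → Linear →
ReLU. The activation inside the GIN MLPs is not dictated by the problem;
ReLU is the GIN convention and is used here. Batch normalisation (over all
node rows in the batch, momentum 0.1, eps 1e−5) follows the same convention
and can be switched off (`batch_norm=False`); it is set-invariant over
nodes, so it preserves permutation invariance.

Attention pooling applies a learned linear gate f_gate: R^d → R^d to every
node embedding and normalises with a softmax **across nodes, independently
per feature dimension**, so every gate column sums to one over nodes; the
graph embedding is the gate-weighted elementwise sum. The vector-valued gate
is the primary reading (f_gate maps into R^d); a scalar-gate variant
(`gate_mode="scalar"`, one weight per node) is provided for sensitivity
analysis. The readout applies one linear map per layer to that layer's
pooled embedding and sums the class scores over layers (`readout="concat"`
concatenates the pooled embeddings into a single linear map instead).
Dropout (rate 0.2) acts on each pooled embedding before its readout map, at
training time only.

Parameters are Glorot-uniform initialised from a seeded generator. All
forward/backward passes are hand-written numpy; gradients of every block
(aggregation, linear, batch norm, ReLU, softmax gate, dropout, readout,
cross-entropy) are verified against central finite differences in the test
suite to ~1e−7. One caveat of that verification, documented because it is
easy to mistake for a backward-pass defect: at a freshly initialised model,
biases are zero and a node whose hidden activations are all ReLU-killed
produces a pre-ReLU value of exactly zero downstream, so numeric
differencing straddles the ReLU kink and disagrees with any valid
subgradient; the check therefore nudges biases off zero first.

Model state (config JSON + parameter and batch-norm buffer arrays, schema
version field) round-trips through a single-file checkpoint bit-exactly.

## Training and evaluation

Stratified k-fold cross-validation (default k = 10, stratified by diagnosis;
with ~30 subjects per held-out fold, unstratified splits would make fold
metrics needlessly noisy under class imbalance). Each fold trains a fresh
model with Adam (lr 0.005, betas 0.9/0.999, weight decay 0 by default) on
the softmax cross-entropy, mini-batches of 32, for a fixed epoch budget with
no early stopping (default 200 epochs; a fixed budget keeps runs
deterministic). Non-finite losses abort with a diagnostic. Predictions are
argmax of the logits with exact ties resolved to the control class.
Accuracy, precision, recall, specificity and F1 are computed per fold from
the confusion counts with the case class positive; a ratio with a zero
denominator is reported as 0 and flagged, never NaN. Graph construction uses
global, label-blind settings, and all learned state derives from training
indices only, so there is no test-set leakage; the zero-effect cohort's
chance-level accuracy is the operational check of that property.

Per-fold seeds derive deterministically from the run seed, so a (seed,
config) pair reproduces per-fold metrics exactly on the same platform.

## Saliency

For each fold, layer, and diagnostic group, node scores are the two-stage
mean of the post-softmax gates of the fold's trained model run once in
inference mode over the group's **training** subjects: mean over feature
dimensions per subject, then mean over subjects. The top q = ⌈N/4⌉ ROIs per
fold (50 of 200) are recorded, and a ROI is salient for a (layer, group)
when selected in strictly more than half the folds (> 5 of 10). The
vector-valued gate has no canonical scalarisation; the mean over feature
dimensions is one defensible choice among several (max or L2 norm would
also be defensible) and is used consistently. Network proportions divide a
salient set across the seven canonical functional systems of the
parcellation.

## Synthetic cohorts

Subjects are zero-mean multivariate normal time series. The correlation
structure mimics a 7-network parcellation: ROIs partition into seven
near-equal contiguous blocks with within-block correlation r0 = 0.2 and zero
between blocks. Case subjects get +delta on every pair inside a planted ROI
subset (default: ROIs 1–20, delta = 0.25, i.e. localised
hyperconnectivity); both target covariances are checked for positive
definiteness at construction. Defaults emulate the reference cohort shape:
150 subjects per group, 200 ROIs, 200 timepoints (a typical resting-state
acquisition length), unit noise SD. The defaults were chosen so that 10-fold
cross-validation sits comfortably above chance without the task being
trivial at smaller sample sizes.

What the generator does **not** emulate: hemodynamic (autocorrelated) BOLD
noise, site effects, head-motion artefacts, hypo-connectivity or distributed
(non-block) effects, and inter-subject variability in the connectivity
structure itself (all subjects in a group share one target covariance).
Passing the end-to-end checks therefore demonstrates that the pipeline
recovers a planted covariance signal through graph construction, training
and attention consolidation — not that any particular accuracy is attainable
on clinical resting-state data, where effect sizes are far smaller and
heteroscedastic.

## Problem sizes used in the shipped checks

The end-to-end checks and `scripts/acceptance.py` run the default cohort
(300 subjects, 200 ROIs, T = 200) with M = 25% absolute-value graphs,
10-fold cross-validation at 50 epochs, and hidden width 32 in float32.
Fifty epochs and a 32-unit width are ample on these cohorts (training
accuracy saturates well before epoch 50) while keeping a full double-cohort
run around ten minutes on a single core; the library defaults (hidden 64,
200 epochs, float64) remain the recommended starting point for real data.

Under the zero-effect (permuted-label) null, the consolidated salient sets
are governed by the top-q selection: were folds independent, a ROI's
selection count would be Bin(10, q/N) and its inclusion probability the
exact tail P(X ≥ 6) ≈ 0.020. Folds share ~8/9 of their training subjects,
which correlates per-fold selections and inflates the empirical inclusion
rate above that tail; it remains far below both the per-fold top-q rate
(q/N = 0.25) and the planted-recovery signal, and the null sets are
unstable across seeds.

## Known limitations

- Batches are dense (B × N × N) adjacency stacks; memory grows quadratically
  in N. Fine for parcellations up to ~1000 ROIs, inappropriate for
  voxel-level graphs.
- All graphs in a cohort must share the node count (a fixed parcellation).
- Binary classification only; the readout generalises to more classes but
  the metrics module assumes one positive class.
- Whether the original 10-fold protocol stratified by site as well as by
  diagnosis is unknown; this implementation stratifies by diagnosis only.
- The `positive_only` convention can retain fewer edges than requested when
  positive connectivity is scarce; this is logged, not padded.
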