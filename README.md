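# connectogin

Classification of functional brain connectomes with an edge-weighted Graph
Isomorphism Network (GIN), including attention-based identification of the
brain regions that drive the decision.

## Who this is for

Neuroimaging groups who have per-subject ROI mean time series (or precomputed
connectivity matrices) from resting-state fMRI, a binary diagnostic label per
subject, and want (i) a cross-validated graph-level classifier that respects
the network structure of the connectome and (ii) an interpretable ranking of
regions of interest (ROIs) rather than a black-box score. The package also
ships a synthetic-cohort generator with planted group differences, so the
entire pipeline can be exercised and validated without any imaging data.

## The model

Each subject's connectome is an N × N matrix of Fisher-z transformed Pearson
correlations between ROI time series (N = 200 in the reference setting). The
matrix is sparsified by keeping the top *M*% of candidate edges (default
M = 25, giving 4975 of the 19 900 possible edges) and becomes a weighted,
undirected graph whose node features are one-hot ROI identities. Three
edge-weight conventions are supported: absolute connectivity |z| (default),
positive-only, and signed.

The classifier stacks L = 4 GIN layers. Layer *k* updates node *v* by

```
h_v(k) = MLP_k( (1 + ε_k) · h_v(k−1) + Σ_{u∈N(v)} w_uv · h_u(k−1) )
```

with w_uv the retained edge weights and ε_k either frozen at zero (GIN-0,
default) or a learnable per-layer scalar (GIN-ε). Each layer's node
embeddings x_i(k) are collapsed by gated attention pooling

```
g(k) = Σ_i softmax(f_gate(x_i(k))) · x_i(k)
```

where the learned linear gate is normalised by a softmax **across nodes**, so
every gate column sums to one and a node's gate value is directly a measure
of how much the classifier attends to that ROI. A readout maps each g(k)
through its own linear layer to class scores and sums the scores over layers;
training minimises cross-entropy with Adam (lr = 0.005, dropout 0.2 on the
pooled embeddings) under stratified 10-fold cross-validation, reporting
accuracy, precision, recall, specificity and F1 (mean ± SD over folds).

**Salient ROIs.** Per fold, layer and diagnostic group, node attention
scores are the mean gate value over feature dimensions and over the group's
training subjects. A ROI is *salient* for a (layer, group) pair when it
ranks in the top quarter of ROIs (top 50 of 200) in strictly more than half
of the folds. Salient sets are annotated with the seven canonical functional
networks (visual, somatomotor, dorsal/ventral attention, limbic,
frontoparietal control, default mode).

The network forward/backward passes are implemented directly in numpy with
hand-coded gradients (verified against finite differences in the test
suite); there is no deep-learning framework dependency.

## Worked example

```python
from connectogin import (SimConfig, make_fc_cohort, build_graph,
                         ModelConfig, TrainConfig, run_cv, consolidate)

# synthetic cohort: 150+150 subjects, 200 ROIs, a 20-ROI block whose
# within-block correlation is raised by 0.25 in the case group
fcs, truth = make_fc_cohort(SimConfig(seed=7))
graphs = [build_graph(fc, label, density_m=25, case="abs")
          for fc, label in fcs]

result = run_cv(graphs,
                TrainConfig(n_epochs=50, n_folds=10, seed=7),
                ModelConfig(input_dim=200, hidden_dim=32, dtype="float32"))
print({m: round(result.report.mean(m), 2)
       for m in ("acc", "pre", "rec", "spe", "f1")})

sets = consolidate(result.gate_records, q=50)
planted = set(truth.planted_rois)
for (layer, group), s in sorted(sets.items()):
    if group == "case":
        hit = len(planted & s.roi_ids) / len(planted)
        print(f"layer {layer}: {len(s.roi_ids)} salient ROIs, "
              f"planted recovery {hit:.2f}")
```

prints

```
{'acc': 100.0, 'pre': 100.0, 'rec': 100.0, 'spe': 100.0, 'f1': 100.0}
layer 1: 20 salient ROIs, planted recovery 1.00
layer 2: 20 salient ROIs, planted recovery 1.00
layer 3: 20 salient ROIs, planted recovery 1.00
layer 4: 21 salient ROIs, planted recovery 1.00
```

i.e. the planted effect is large enough that held-out classification is
perfect and the attention gates concentrate exactly on the 20 planted ROIs.
On a zero-effect cohort (`delta=0`) the same pipeline stays at chance
(mean accuracy ≈ 50%), confirming there is no leakage anywhere in the
cross-validation.

The same pipeline is available from the shell:

```
connectogin simulate     --out data/sim1/
connectogin build-graphs --manifest data/sim1/manifest.csv --density 25 \
                         --case abs --out graphs/
connectogin train        --graphs graphs/ --out runs/run1/
connectogin evaluate     --run runs/run1/
connectogin saliency     --run runs/run1/ \
                         --parcellation data/sim1/parcellation.csv \
                         --out runs/run1/saliency/
connectogin report       --run runs/run1/
```

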