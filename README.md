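# rnmfnet

Graph-regularized non-negative matrix factorization for predicting
functional properties of nodes in **sparsely labeled interaction
networks**.

The motivating setting is protein–protein interaction (PPI) networks:
each protein carries a non-negative attribute vector and, for a small
fraction of proteins (2–10%), known functional classes. Because so few
nodes are labeled, most unlabeled proteins have no labeled interaction
partner and classical label propagation or collective classification
starves. `rnmfnet` instead:

1. builds **latent graphs** — the observed interaction graph, an
   even-step random-walk-with-restart graph capturing shared-partner
   (level-2) similarity, and a classifier-confidence cosine graph;
2. **integrates** them with simplex weights **w** learned on the labeled
   nodes by minimizing ‖Σᵢ wᵢ Ē⁽ⁱ⁾ − ȲᵀȲ‖²_F + λ‖w‖² (an exact
   active-set QP solver);
3. fits a **label- and graph-regularized NMF**: with X the M × N feature
   matrix, Y the q × N partial label matrix, W a confidence mask
   (0.01 at known memberships, 1 at known absences, 0 for unlabeled
   nodes) and L = D − Ê the Laplacian of the integrated graph Ê,

       O = ‖X − UVᵀ‖² + α Σᵢⱼ Wᵢⱼ(Y − BVᵀ)²ᵢⱼ + β Tr(VᵀLV)

   is minimized by multiplicative updates (defaults α = 10, β = 5,
   K = q), with labeled rows of V re-imposed as one-hot after every
   pass;
4. reads predictions straight off V: class argmax for single-label
   tasks, per-node class rankings for multi-label tasks (evaluated by
   coverage and ranking loss), and node-pair interaction strength as
   the cosine of two V rows.

A synthetic planted-partition generator with class-correlated indicator
features (and a preset at the scale of the classic KDD Cup 2001 yeast
benchmark: 1,243 nodes, ~1,806 edges, 14 classes) makes every stage
testable without downloads. See `docs/methods.md` for the model,
parameter meanings, and known limitations.

## Worked example

```python
import numpy as np
from rnmfnet import (
    SyntheticConfig, generate, split_labels,
    ppi_latent_graph, erwr_latent_graph, ErwrParams,
    restrict_to_labeled, learn_weights, integrate,
    RnmfParams, rnmf_fit, predict_single_label, accuracy,
    interaction_similarity,
)

dataset = generate(SyntheticConfig(seed=1))        # 300 nodes, 3 classes
split = split_labels(dataset, label_ratio=0.05, seed=0)   # 15 labeled

graphs = [ppi_latent_graph(split), erwr_latent_graph(split, ErwrParams())]
restricted, ybar = restrict_to_labeled(graphs, split)
weights = learn_weights(restricted, ybar.T @ ybar, smoothing=0.01)
latent = integrate(graphs, weights)

state = rnmf_fit(split, latent, RnmfParams(seed=0))
pred = predict_single_label(state, split)
truth = np.argmax(dataset.labels, axis=0)
acc = accuracy(pred, truth, ~split.labeled_mask)

print(f"combination weights: ppi={weights.w[0]:.3f}, erwr={weights.w[1]:.3f}")
print(f"iterations: {len(state.objective_trace)}, "
      f"final objective: {state.objective_trace[-1]:.1f}")
print(f"accuracy on {int((~split.labeled_mask).sum())} unlabeled nodes: {acc:.3f}")
print(f"interaction similarity of nodes 0 and 1: "
      f"{interaction_similarity(state, 0, 1):.3f}")
```

Output:

```
combination weights: ppi=0.752, erwr=0.248
iterations: 126, final objective: 923.9
accuracy on 285 unlabeled nodes: 0.930
interaction similarity of nodes 0 and 1: 0.686
```

The learner puts three quarters of the weight on the observed
interaction graph and the rest on the level-2 walk graph; the
factorization converges in ~126 passes and classifies 93% of the 285
unlabeled nodes correctly from only 15 labels — against a class-prior
baseline of ~0.33. The interaction-similarity readout scores how
interrelated two nodes' learned representations are (0 = independent,
1 = strongly interrelated).

## Command line

The same pipeline is scriptable:

```sh
rnmfnet generate --seed 3 --out data/ --n-nodes 300 --n-classes 3
rnmfnet graphs      --data data/ --out graphs/  --label-ratio 0.05
rnmfnet fit-predict --data data/ --out run/     --label-ratio 0.05 --verbose
rnmfnet evaluate    --data data/ --out report.tsv --seed 2
```

`generate` writes TSV edge/feature/label files plus a manifest
(seed, config hash); `graphs` exports the latent graphs as MatrixMarket;
`fit-predict` writes U/B/V, an objective log, and per-node predictions;
`evaluate` sweeps label ratios with repeated splits and reports
mean ± sd per metric. A YAML `--config` file (flat keys) sets any
parameter; command-line flags override it.

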