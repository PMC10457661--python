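# metastab

Cross-modality graph contrastive learning for molecular **metabolic-stability
classification**.

Metabolic stability — how quickly a compound is degraded by liver-microsome
enzymes — is a key property in early drug discovery: unstable leads are
cleared before they can act. `metastab` predicts a binary stability label
(1 = stable) directly from a SMILES string by fusing two views of the same
molecule:

* **Sequence view.** The SMILES token sequence is embedded with pretrained
  skip-gram token vectors (Z ∈ ℝ^{m×d₁}), encoded by a bidirectional GRU
  (hₜ = [GRU→(zₜ), GRU←(zₜ)], H ∈ ℝ^{m×d₂}), and pooled with multihead
  additive attention, αᵢ = Softmax[MLP(H)], sᵢ = FC(Σⱼ αᵢⱼ hⱼ).
* **Graph view.** The heavy-atom molecular graph G = {V, E} with 84-dim
  binary atom features is encoded by a K-layer graph isomorphism network,
  h_v^{(k)} = MLP((1+ε)·h_v^{(k−1)} + Σ_{u∈N(v)} h_u^{(k−1)}), and pooled as
  pᵢ = CONCAT(max-pool, mean-pool).
* **Inter-view contrastive learning.** During training each graph is
  augmented into a local subgraph Ĝ by a random-walk substructure sample
  (|V̂| ≤ k·|V|, k = 0.4). The pooled vectors (zᵢ, ẑᵢ) form a positive pair
  in a temperature-scaled NT-Xent loss (τ = 0.2) against the other 2(Q−1)
  in-batch representations.
* **Predictor.** ŷᵢ = σ(FC[CONCAT(zᵢ, sᵢ)]) with widths 768 → 256 → 1; the
  training objective is L = L_C + λ·L_CL with summed binary cross-entropy
  L_C and λ = 0.1, optimized with Adam (lr 5·10⁻⁴).

Two interpretability procedures expose what the model relies on: attention
weights mapped from tokens to atoms and bonds (a bond's weight is the mean
of its atoms'), and per-bond Shapley values estimated by Monte-Carlo
permutation sampling of an edge-coalition game.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
import metastab as ms

# synthetic benchmark: scaffolds with planted stabilizing groups
# (acetylene, trifluoromethyl, chlorophenyl) vs destabilizing groups
# (ester, amide, methoxy, hydroxyl), 5% label noise, 64% positives
ds, truth = ms.generate_dataset(ms.SynthSpec(n=2000, noise=0.05, seed=10))
y = ds.labels
tr, te = train_test_split(np.arange(len(y)), test_size=0.2, stratify=y,
                          random_state=0)

est = ms.StabilityClassifier(epochs=30, batch_size=64, seed=0)
est.fit([ds.molecules[i] for i in tr], y[tr])
scores = est.predict_proba([ds.molecules[i] for i in te])[:, 1]
print(ms.evaluate_scores(y[te], scores))
# MetricsReport(auc=0.954, accuracy=0.958, f1=0.967, mcc=0.908, n=400, ...)
```

Held-out AUC ≈ 0.95 sits near the ceiling imposed by the 5% label noise:
the model has essentially learned the planted functional-group rule.
Explaining a prediction:

```python
expl = ms.attention_explanation(est, ds.molecules[te[0]])
expl.atom_weights          # length-N simplex over atoms
expl.bond_weights          # bond -> mean of its two atom weights
shap = ms.edge_shapley(est, ds.molecules[te[0]], n_samples=1000,
                       rng=np.random.default_rng(0))
shap.edge_shapley          # bond -> Shapley value of the model score
```

The same workflows are available from the shell:

```bash
metastab synth --n 2000 --noise 0.05 --seed 10 --out data.csv
metastab train --data data.csv --out run/ --epochs 30
metastab predict --model run/model.joblib --data data.csv --out preds.csv
metastab crossval --data data.csv --folds 10
metastab cluster-eval --data data.csv --clusters 5
metastab explain --model run/model.joblib --data data.csv --method shapley --out explain/
```

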