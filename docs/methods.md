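# Methods

## Problem and model

`metastab` casts metabolic stability as binary classification: given a
compound's SMILES string, predict whether it meets a liver-microsome
half-life criterion (label 1 = stable). The model assumes stability is
largely determined by local functional groups and their structural context,
and therefore encodes each molecule twice:

1. **Sequence branch.** SMILES tokens (atoms, bonds, ring digits, branches;
   `Cl`/`Br` and bracket atoms are single tokens) are mapped to pretrained
   d₁-dimensional vectors and passed through a bidirectional GRU whose
   per-position states are the concatenation of a forward and a backward
   recurrence (d₂ = 2 × hidden size). A multihead additive attention scores
   every position with vᵀtanh(W hₜ + b), normalizes with a softmax over
   positions, averages the head contexts and maps them through a ReLU fully
   connected layer to the sequence vector sᵢ (d_s). Attention over atoms is
   a probability simplex by construction, which is what makes the weights
   usable as explanations.
2. **Graph branch.** The implicit-hydrogen heavy-atom graph carries an
   84-dimensional binary feature per atom: element symbol (50-way one-hot
   over 49 symbols plus "unknown"), degree (0–10), attached hydrogens
   (0–10), implicit valence (0–10), and an aromaticity flag. K GIN layers
   update atoms by MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u) with a learnable ε per
   layer (initialized 0) and an MLP of linear → batch-norm → ReLU → linear.
   The molecule vector pᵢ concatenates global max- and mean-pooling of the
   final layer, so d₃ = 2·d_g.
3. **Contrastive regularizer.** Each training graph is augmented into a
   connected local subgraph by a random walk stopped at ⌈ratio·N⌉ distinct
   nodes (features copied; induced edges kept; walks never leave the start
   component). Original and subgraph vectors form positive pairs in the
   temperature-scaled NT-Xent loss with cosine similarity; the other
   2(Q−1) in-batch vectors act as negatives. Three alternative
   augmentations (node dropping, edge perturbation, attribute masking with
   the dataset-mean feature row) are provided for ablations.
4. **Predictor and objective.** ŷᵢ = σ(FC[CONCAT(zᵢ, sᵢ)]); the head emits
   a logit and the sigmoid lives inside the loss for numerical stability.
   L = L_C + λ·L_CL, where L_C is the *summed* binary cross-entropy over
   the mini-batch, optimized with Adam.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| d₁ | 100 | token-embedding width |
| d₂ | 200 | BiGRU output width (two directions of 100) |
| d_s | 256 | sequence vector width (so fused width is 768) |
| d_g | 256 | GIN layer width; pooled graph vector d₃ = 512 |
| K | 2 | GIN layers (receptive field = 2-hop neighborhoods) |
| heads | 4 | attention heads, mean-aggregated |
| predictor | 768→256→1 | fully connected head |
| τ | 0.2 | NT-Xent temperature |
| ratio | 0.4 | substructure-sampling fraction (0.2/0.4/0.4 for the ablation augmentations) |
| λ | 0.1 | contrastive-loss weight; a sweep utility covers {0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1, 1.5, 2} |
| epochs / lr | 200 / 5·10⁻⁴ | Adam, fixed-epoch protocol (no early stopping) |
| batch Q | 128 | also the number of contrastive positives per batch |

Choices the architecture leaves open were fixed as package decisions: four
attention heads with mean aggregation and a 100-unit (64 in tests) scoring
layer; a linear+ReLU map FCs after pooling; contrastive vectors are the
pooled pᵢ used directly (a projection head exists behind a flag, default
off, since the same zᵢ feeds the predictor); the NT-Xent denominator runs
over the other 2Q−1 rows including the positive; token embeddings are
trained by skip-gram with negative sampling (window 5, 10 epochs, 5
negatives, unigram^0.75 noise) on the training-split SMILES themselves,
with a pluggable external table; out-of-vocabulary tokens receive a vector
hashed deterministically from (token, seed), uniform on (−0.05, 0.05).

## Evaluation protocols

Metrics are AUC (rank statistic), Accuracy, F1 and MCC at threshold 0.5.
`crossval` runs repeated stratified k-fold (default 10-fold);
`leave_one_cluster_out` clusters molecules by K-means on the rows of the
ECFP4 (radius-2, 2048-bit) Tanimoto similarity matrix (default five
clusters) and holds out each structural cluster once, skipping single-class
clusters with a warning — a proxy for generalization to novel chemotypes.
Tanimoto scores bin into dissimilar (≤0.5), moderately similar (0.5–0.7]
and highly similar (>0.7).

## Interpretability

*Attention explanations* average the per-head attention over tokens, assign
zero atom mass to non-atom tokens (digits, bonds, branches) and renormalize
over atom tokens; SMILES token order matches RDKit atom order, and a
mismatch (e.g. explicit hydrogens removed during sanitization) raises an
alignment error rather than guessing. A bond's weight is the mean of its
two atoms' weights.

*Edge Shapley values* treat each bond as a player in a coalition game whose
value f(S) is the model's sigmoid score when only the edge subset S is
present (node features and the sequence branch held fixed; edges outside S
are deleted before encoding — deletion is deterministic, unlike stochastic
masking). Estimation uses Monte-Carlo permutation sampling: each sampled
ordering contributes one marginal per edge, so the per-permutation totals
telescope and the efficiency axiom Σφ = f(E) − f(∅) holds exactly; per-edge
standard errors (shrinking as 1/√n) are reported. The frequency report
collects, over an evaluation set, bonds with φ above 0.2 plus their
neighbor bonds, canonicalizes the induced fragment SMILES, and counts the
top-10 substructures separately for predicted-stable and predicted-unstable
molecules, with a small SMARTS dictionary used only to attach human names.

## Synthetic benchmark

The generator emulates the *shape* of a curated liver-microsome dataset:
valid SMILES, binary labels at roughly 64/36 class balance, and labels
driven by functional groups. Each molecule is a random scaffold (alkane
chain of 2–6 carbons, cyclohexane, benzene or pyridine) with one planted
motif appended at a valid attachment point — stabilizing: acetylene `C#C`,
trifluoromethyl `C(F)(F)F`, chlorophenyl; destabilizing: ester, amide,
methoxy, hydroxyl — and the clean label is the motif class, flipped with
probability `noise`. String-template assembly guarantees parseability, and
because RDKit preserves SMILES atom order, the planted atoms are exactly
the final heavy atoms, giving atom-level ground truth for explanation
tests.

What it does *not* emulate: realistic chemical diversity (the scaffold ×
motif space is small, so molecules repeat), competing or interacting
functional groups, stereochemistry, salts, or any relationship between
structure and assay noise. Passing the recovery tests therefore shows that
the architecture, losses and explanation machinery work end-to-end on a
planted-rule task — not that the model attains any particular accuracy on
real microsomal data, which requires the real labelled sets.

The end-to-end checks train the default architecture on n = 2000 molecules
with 5% label noise for 30 epochs at batch 64 (three seeds) — problem sizes
chosen to exercise the full pipeline at desk scale; note the 5% label-flip
noise caps attainable held-out AUC at about 0.94–0.95 because flipped
duplicates are exact score ties. The motif-recovery check counts a molecule
as recovered when at least one planted-motif atom ranks in the top 30% of
attention weights — "the group is flagged" — rather than requiring every
motif atom to rank highly, which would penalize large motifs like
chlorophenyl.

## Numerical choices and edge cases

* All training runs in float32 on a small numpy reverse-mode autodiff
  engine (`metastab.nn`); the GRU recurrence and the sparse neighbor-sum
  are single fused tape nodes with hand-written backward passes. Oracle
  comparisons can run the same modules in float64.
* Batch norm falls back to running statistics when batch statistics are
  undefined (single-row batches) and always uses them at evaluation.
* Softmaxes subtract the row maximum before exponentiation; masked (padded)
  positions are excluded from attention normalization; cosine similarities
  add 1e-12 to norms, and zero-norm contrastive rows are rejected.
* Batches with a single molecule skip the contrastive term (a positive pair
  needs at least two molecules for negatives).
* Single-node graphs have an empty neighbor sum (zero vector); max- and
  mean-pool halves then coincide.
* Determinism: all randomness (embedding pretraining, weight init, batch
  shuffling, augmentation walks) derives from one seed via spawned
  `SeedSequence` streams; identical seed + data + config reproduce losses,
  metrics and files bit-for-bit on the same platform.
* Duplicate molecules are removed by canonical SMILES (first occurrence
  wins) when reading datasets; unparseable rows are skipped and counted.

## Known limitations

* No bond-type features in the GIN (aggregation is over unlabeled edges);
  no stereochemistry; no 3-D information.
* The contrastive term's effectiveness depends on batch size Q (more
  in-batch negatives); very small batches weaken it.
* Attention explanations are renormalized over atom tokens, so importance
  carried by pure-symbol tokens (e.g. `#`) is redistributed
  proportionally, not attributed to neighboring atoms.
* Attention-based explanations are seed-dependent. Because every BiGRU
  state carries global context, attending to a single summary position
  (typically token 0, whose backward state has seen the whole molecule) is
  as good for classification as attending to the causal atoms; some
  training seeds converge to this collapsed solution and then localize
  nothing, while others place their mass on the discriminative group. On
  the synthetic benchmark two of three seeds recover the planted groups in
  100% of correctly classified positives and one collapses (~6%), and the
  collapse persists with longer training. Edge-Shapley values do not share
  this failure mode — they probe the graph branch causally by deleting
  bonds — which is a practical reason to prefer them when the two methods
  disagree.
* Training is CPU-bound pure numpy; it is sized for datasets of thousands,
  not millions, of molecules.
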