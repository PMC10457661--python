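"""Fused stability predictor: estimator, training loop, metrics and evaluation.

:class:`StabilityClassifier` is a scikit-learn style estimator.  ``fit``
takes SMILES strings and binary labels (1 = metabolically stable) and
trains the full cross-modality model: pretrained token embeddings feed an
attention-BiGRU sequence encoder (s_i), the molecular graph feeds a GIN
encoder (z_i), and a sigmoid MLP head scores CONCAT(z_i, s_i).  During
training each graph is also augmented into a local subgraph and the two
pooled graph vectors are tied together by an NT-Xent contrastive loss, so
the total objective is  L = L_C + lambda * L_CL  with L_C the summed binary
cross-entropy over the mini-batch.

Default hyperparameters: d1=100, d2=200, d_s=256, d_g=256 (fused predictor
widths 768 -> 256 -> 1), K=2 GIN layers, temperature 0.2, sampling ratio
0.4, lambda=0.1, Adam with learning rate 5e-4 for 200 epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.metrics import (accuracy_score, f1_score, matthews_corrcoef,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import chemio
from .chemio import LabelledDataset, Molecule, ecfp_matrix, tanimoto_matrix
from .contrastive import AUGMENT_METHODS, augment, contrastive_loss_t
from .embeddings import EmbeddingTable, embed_sequence, train_atom_embeddings
from .graph_encoder import GINEncoder, batch_graphs
from .nn import Adam, MLP, Tensor, bce_with_logits_sum, concat, no_grad
from .nn.layers import Linear
from .seq_encoder import SequenceEncoder, pad_batch

LAMBDA_GRID = (0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)


# ---------------------------------------------------------------------------
# config / report containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the fused model (defaults are the recommended ones)."""

    d1: int = 100
    d2: int = 200
    d_s: int = 256
    d_g: int = 256
    gin_layers: int = 2
    heads: int = 4
    att_dim: int = 100
    predictor_hidden: int = 256
    tau: float = 0.2
    aug_method: str = "substructure"
    aug_ratio: float = 0.4
    contrastive_weight: float = 0.1
    epochs: int = 200
    learning_rate: float = 5e-4
    batch_size: int = 128
    seed: int = 0
    use_sequence: bool = True
    embed_window: int = 5
    embed_epochs: int = 10
    projection_head: bool = False

    def __post_init__(self):
        if self.contrastive_weight < 0:
            raise ValueError("contrastive weight (lambda) must be >= 0")
        if self.aug_method not in AUGMENT_METHODS:
            raise ValueError(f"unknown augmentation {self.aug_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Prediction:
    id: str
    score: float
    label: Optional[int] = None


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    f1: float
    mcc: float
    n: int = 0
    fold: Optional[str] = None

    def to_dict(self):
        return {"auc": self.auc, "accuracy": self.accuracy, "f1": self.f1,
                "mcc": self.mcc, "n": self.n, "fold": self.fold}


def aggregate_reports(reports: Sequence[MetricsReport]) -> Dict[str, Dict[str, float]]:
    """mean +/- sd across folds/repeats for each metric."""
    out = {}
    for metric in ("auc", "accuracy", "f1", "mcc"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        out[metric] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


# ---------------------------------------------------------------------------
# losses and metrics
# ---------------------------------------------------------------------------

def _bce_sum(logits: np.ndarray, labels: np.ndarray) -> float:
    """Summed binary cross-entropy on logits (stable closed form)."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    sp = np.maximum(logits, 0.0) + np.log1p(np.exp(-np.abs(logits)))
    return float(np.sum(sp - y * logits))


def total_loss(logits, labels, contrastive: float, lam: float) -> Tuple[float, float, float]:
    """(L, L_C, L_CL) with L = L_C + lam * L_CL, composed exactly as written."""
    l_c = _bce_sum(logits, labels)
    return l_c + lam * contrastive, l_c, contrastive


def evaluate_scores(y_true, scores, threshold: float = 0.5,
                    fold: Optional[str] = None) -> MetricsReport:
    """AUC (rank statistic), Accuracy/F1/MCC at the decision threshold."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation requires both classes present")
    pred = (scores >= threshold).astype(int)
    return MetricsReport(
        auc=float(roc_auc_score(y_true, scores)),
        accuracy=float(accuracy_score(y_true, pred)),
        f1=float(f1_score(y_true, pred)),
        mcc=float(matthews_corrcoef(y_true, pred)),
        n=len(y_true), fold=fold)


def evaluate(preds: Sequence[Prediction], threshold: float = 0.5) -> MetricsReport:
    labels = [p.label for p in preds]
    if any(l is None for l in labels):
        raise ValueError("all predictions need labels for evaluation")
    return evaluate_scores(np.array(labels), np.array([p.score for p in preds]),
                           threshold=threshold)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class StabilityClassifier(BaseEstimator, ClassifierMixin):
    """Cross-modality metabolic-stability classifier (sequence + graph views).

    Parameters mirror :class:`ModelConfig`; see the module docstring for the
    architecture.  ``contrastive_weight=0`` disables the contrastive branch
    (the "without graph contrastive learning" ablation) and
    ``use_sequence=False`` drops the sequence encoder (the "graph only"
    ablation).
    """

    def __init__(self, d1=100, d2=200, d_s=256, d_g=256, gin_layers=2,
                 heads=4, att_dim=100, predictor_hidden=256, tau=0.2,
                 aug_method="substructure", aug_ratio=0.4,
                 contrastive_weight=0.1, epochs=200, learning_rate=5e-4,
                 batch_size=128, seed=0, use_sequence=True, embed_window=5,
                 embed_epochs=10, projection_head=False,
                 embedding_table=None, verbose=0):
        self.d1 = d1
        self.d2 = d2
        self.d_s = d_s
        self.d_g = d_g
        self.gin_layers = gin_layers
        self.heads = heads
        self.att_dim = att_dim
        self.predictor_hidden = predictor_hidden
        self.tau = tau
        self.aug_method = aug_method
        self.aug_ratio = aug_ratio
        self.contrastive_weight = contrastive_weight
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.use_sequence = use_sequence
        self.embed_window = embed_window
        self.embed_epochs = embed_epochs
        self.projection_head = projection_head
        self.embedding_table = embedding_table
        self.verbose = verbose

    # -- plumbing ---------------------------------------------------------
    @classmethod
    def from_config(cls, config: ModelConfig, **extra) -> "StabilityClassifier":
        return cls(**asdict(config), **extra)

    @staticmethod
    def _parse_inputs(X) -> List[Molecule]:
        if isinstance(X, LabelledDataset):
            return X.molecules
        mols = []
        for i, item in enumerate(X):
            if isinstance(item, Molecule):
                mols.append(item)
            else:
                mols.append(chemio.parse_molecule(str(item), mol_id=str(i)))
        return mols

    def _embed(self, mol: Molecule) -> np.ndarray:
        return embed_sequence(mol.tokens, self.embedding_table_).astype(np.float32)

    # -- core forward pieces ---------------------------------------------
    def _fused_logits(self, mols: List[Molecule], Zs: List[np.ndarray]):
        """Returns (logits Tensor (B,), z Tensor (B, d3))."""
        gb = batch_graphs([m.graph for m in mols])
        z = self.gin_(gb)
        if self.use_sequence:
            X, mask, lengths = pad_batch(Zs)
            _, _, s = self.seq_(Tensor(X), mask, lengths)
            fused = concat([z, s], axis=1)
        else:
            fused = z
        logits = self.predictor_(fused).reshape(len(mols))
        return logits, z

    def _batch_loss(self, mols, Zs, y, aug_rng):
        logits, z = self._fused_logits(mols, Zs)
        l_c = bce_with_logits_sum(logits, y)
        lam = self.contrastive_weight
        if lam > 0 and len(mols) >= 2:
            aug = [augment(m.graph, self.aug_method, self.aug_ratio, aug_rng,
                           mask_vector=self.feature_mean_) for m in mols]
            z_hat = self.gin_(batch_graphs(aug))
            if self.projection_head:
                z_c, z_hat_c = self.proj_(z), self.proj_(z_hat)
            else:
                z_c, z_hat_c = z, z_hat
            l_cl = contrastive_loss_t(z_c, z_hat_c, self.tau)
            loss = l_c + lam * l_cl
            return loss, float(l_c.data), float(l_cl.data)
        return l_c, float(l_c.data), 0.0

    # -- fit / predict ----------------------------------------------------
    def fit(self, X, y=None, eval_set=None):
        mols = self._parse_inputs(X)
        if isinstance(X, LabelledDataset) and y is None:
            y = X.labels
        y = np.asarray(y, dtype=np.int64)
        if len(mols) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires both classes present (AUC undefined otherwise)")

        ss = np.random.SeedSequence(self.seed)
        s_embed, s_init, s_shuffle, s_aug = ss.spawn(4)
        init_rng = np.random.default_rng(s_init)
        shuffle_rng = np.random.default_rng(s_shuffle)
        aug_rng = np.random.default_rng(s_aug)

        # token embeddings: pluggable, by default pretrained on the training SMILES
        if self.embedding_table is not None:
            self.embedding_table_ = self.embedding_table
            if self.embedding_table_.d1 != self.d1:
                raise ValueError("embedding table dimension != d1")
        else:
            self.embedding_table_ = train_atom_embeddings(
                [m.tokens for m in mols], d1=self.d1, window=self.embed_window,
                epochs=self.embed_epochs,
                seed=int(s_embed.generate_state(1)[0] % (2 ** 31)))
        Zs = [self._embed(m) for m in mols]

        in_dim = mols[0].graph.node_features.shape[1]
        self.gin_ = GINEncoder(in_dim=in_dim, d_g=self.d_g,
                               num_layers=self.gin_layers, rng=init_rng)
        pred_in = self.gin_.d3
        if self.use_sequence:
            self.seq_ = SequenceEncoder(self.d1, self.d2, self.d_s,
                                        heads=self.heads, att_dim=self.att_dim,
                                        rng=init_rng)
            pred_in += self.d_s
        else:
            self.seq_ = None
        self.predictor_ = MLP([pred_in, self.predictor_hidden, 1], init_rng)
        modules = [self.gin_, self.predictor_] + ([self.seq_] if self.seq_ else [])
        if self.projection_head:
            self.proj_ = Linear(self.gin_.d3, self.gin_.d3, init_rng)
            modules.append(self.proj_)
        params = [p for m in modules for p in m.parameters()]
        opt = Adam(params, lr=self.learning_rate)

        self.feature_mean_ = np.concatenate(
            [m.graph.node_features for m in mols]).mean(axis=0)

        n = len(mols)
        self.history_ = []
        for m in modules:
            m.train(True)
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            tot = tot_c = tot_cl = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch_mols = [mols[i] for i in idx]
                batch_Z = [Zs[i] for i in idx]
                loss, l_c, l_cl = self._batch_loss(batch_mols, batch_Z, y[idx], aug_rng)
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += float(loss.data)
                tot_c += l_c
                tot_cl += l_cl
            entry = {"epoch": epoch, "loss": tot, "cls_loss": tot_c,
                     "contrastive_loss": tot_cl}
            if eval_set is not None:
                ev_scores = self._scores(self._parse_inputs(eval_set[0]))
                entry["eval"] = evaluate_scores(eval_set[1], ev_scores).to_dict()
                for m in modules:
                    m.train(True)
            self.history_.append(entry)
            if self.verbose:
                print(f"epoch {epoch:3d}  loss {tot:.3f}  "
                      f"cls {tot_c:.3f}  contr {tot_cl:.3f}")
        for m in modules:
            m.eval()
        return self

    def _scores(self, mols: List[Molecule]) -> np.ndarray:
        self.gin_.eval()
        self.predictor_.eval()
        if self.seq_ is not None:
            self.seq_.eval()
        out = np.empty(len(mols), dtype=np.float64)
        with no_grad():
            for start in range(0, len(mols), self.batch_size):
                chunk = mols[start:start + self.batch_size]
                Zs = [self._embed(m) for m in chunk]
                logits, _ = self._fused_logits(chunk, Zs)
                out[start:start + len(chunk)] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        return out

    def predict_proba(self, X) -> np.ndarray:
        mols = self._parse_inputs(X)
        p1 = self._scores(mols)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def predictions(self, X, y=None) -> List[Prediction]:
        mols = self._parse_inputs(X)
        scores = self._scores(mols)
        labels = [None] * len(mols) if y is None else list(np.asarray(y))
        return [Prediction(id=m.id or str(i), score=float(s), label=l)
                for i, (m, s, l) in enumerate(zip(mols, scores, labels))]

    # -- hooks used by the interpretability module ------------------------
    def sequence_attention(self, mol: Molecule):
        """Per-head attention vectors (each length m) and s_i for one molecule."""
        if self.seq_ is None:
            raise ValueError("model was trained without the sequence encoder")
        out = self.seq_.encode_one(self._embed(mol))
        return out.attention, out.seq_rep

    def score_graph_variants(self, variants, s_vec: Optional[np.ndarray]) -> np.ndarray:
        """Sigmoid scores of one molecule under alternative edge sets.

        The sequence representation is held fixed at ``s_vec`` (ignored when
        the model has no sequence branch).
        """
        with no_grad():
            z = self.gin_(batch_graphs(list(variants)))
            if self.use_sequence:
                s = np.tile(np.asarray(s_vec, dtype=np.float32), (len(variants), 1))
                fused = concat([z, Tensor(s)], axis=1)
            else:
                fused = z
            logits = self.predictor_(fused).data.ravel().astype(np.float64)
        return 1.0 / (1.0 + np.exp(-logits))


# ---------------------------------------------------------------------------
# training / evaluation protocols
# ---------------------------------------------------------------------------

def train(dataset: LabelledDataset, config: ModelConfig,
          eval_set=None, verbose: int = 0) -> StabilityClassifier:
    """Fit a :class:`StabilityClassifier` on a labelled dataset."""
    est = StabilityClassifier.from_config(config, verbose=verbose)
    return est.fit(dataset, dataset.labels, eval_set=eval_set)


def crossval(X, y=None, estimator: Optional[StabilityClassifier] = None,
             folds: int = 10, repeats: int = 1, seed: int = 0):
    """Repeated stratified k-fold cross-validation.

    Returns ``(reports, aggregate)`` where reports is a list of
    :class:`MetricsReport` (one per fold and repeat) and aggregate holds
    mean +/- sd per metric.
    """
    from sklearn.base import clone
    if isinstance(X, LabelledDataset):
        y = X.labels
        X = X.molecules
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds smallest class count {counts.min()}")
    base = estimator if estimator is not None else StabilityClassifier()
    reports = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            est = clone(base)
            est.set_params(seed=base.seed + rep)
            est.fit([X[i] for i in tr], y[tr])
            scores = est.predict_proba([X[i] for i in te])[:, 1]
            reports.append(evaluate_scores(y[te], scores, fold=f"rep{rep}_fold{k}"))
    return reports, aggregate_reports(reports)


def cluster_molecules(smiles: Sequence[str], n_clusters: int = 5,
                      seed: int = 0) -> np.ndarray:
    """K-means over rows of the ECFP-Tanimoto similarity matrix."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    sim = tanimoto_matrix(ecfp_matrix(list(smiles)))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(sim)


def leave_one_cluster_out(X, y=None, estimator: Optional[StabilityClassifier] = None,
                          n_clusters: int = 5, seed: int = 0):
    """Hold out each structural cluster once; returns (reports dict, labels).

    Clusters whose test molecules are single-class are skipped with a warning.
    """
    from sklearn.base import clone
    if isinstance(X, LabelledDataset):
        y = X.labels
        X = X.molecules
    y = np.asarray(y)
    smiles = [m.smiles if isinstance(m, Molecule) else str(m) for m in X]
    labels = cluster_molecules(smiles, n_clusters=n_clusters, seed=seed)
    base = estimator if estimator is not None else StabilityClassifier()
    reports: Dict[int, MetricsReport] = {}
    for c in range(n_clusters):
        te = np.where(labels == c)[0]
        tr = np.where(labels != c)[0]
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn(f"cluster {c} skipped: single-class train or test split")
            continue
        est = clone(base)
        est.fit([X[i] for i in tr], y[tr])
        scores = est.predict_proba([X[i] for i in te])[:, 1]
        reports[c] = evaluate_scores(y[te], scores, fold=f"cluster{c}")
    return reports, labels


def sweep_lambda(X, y=None, estimator: Optional[StabilityClassifier] = None,
                 grid: Sequence[float] = LAMBDA_GRID, test_size: float = 0.2,
                 seed: int = 0):
    """Evaluate the contrastive-weight grid on one stratified split."""
    if isinstance(X, LabelledDataset):
        y = X.labels
        X = X.molecules
    y = np.asarray(y)
    idx_tr, idx_te = train_test_split(np.arange(len(y)), test_size=test_size,
                                      stratify=y, random_state=seed)
    from sklearn.base import clone
    base = estimator if estimator is not None else StabilityClassifier()
    rows = []
    for lam in grid:
        est = clone(base)
        est.set_params(contrastive_weight=lam)
        est.fit([X[i] for i in idx_tr], y[idx_tr])
        scores = est.predict_proba([X[i] for i in idx_te])[:, 1]
        rep = evaluate_scores(y[idx_te], scores, fold=f"lambda={lam}")
        rows.append({"lambda": lam, **{k: getattr(rep, k) for k in
                                       ("auc", "accuracy", "f1", "mcc")}})
    import pandas as pd
    return pd.DataFrame(rows)
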