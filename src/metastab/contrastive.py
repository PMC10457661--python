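"""Graph augmentations and the inter-view NT-Xent contrastive loss.

The default augmentation draws a connected local subgraph by a seeded
random walk (substructure sampling); three alternatives used for ablations
are node dropping, edge perturbation and attribute masking.  The loss
contrasts each molecule's pooled graph vector z_i with the vector of its
augmented subgraph z_i-hat: the pair is pulled together while the remaining
2(Q-1) in-batch graph/subgraph vectors act as negatives, with cosine
similarity scaled by a temperature tau (0.2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np

from .chemio import MolGraph
from .nn import Tensor

AUGMENT_METHODS = ("substructure", "node_dropping", "edge_perturbation",
                   "attribute_masking")


@dataclass
class AugmentedPair:
    original: MolGraph
    augmented: MolGraph
    method: str
    ratio: float


@dataclass
class ContrastiveBatch:
    """2Q x d stacked representations: rows [0, Q) originals, [Q, 2Q) subgraphs."""

    reps: np.ndarray
    tau: float = 0.2

    @property
    def Q(self) -> int:
        return self.reps.shape[0] // 2


def _components(adj, n):
    comp = np.full(n, -1, dtype=np.int64)
    c = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = c
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    return comp


def _induced(graph: MolGraph, keep) -> MolGraph:
    keep = sorted(keep)
    remap = {old: new for new, old in enumerate(keep)}
    edges = [(remap[u], remap[v]) for u, v in graph.edges
             if u in remap and v in remap]
    return MolGraph(graph.node_features[keep].copy(), edges, len(keep))


def sample_substructure(graph: MolGraph, ratio: float, rng) -> MolGraph:
    """Node-induced subgraph over a seeded random walk of ceil(ratio*N) nodes.

    The walk starts at a random node and restarts from an already visited
    node on dead ends; it never leaves the start's connected component, so
    for a disconnected molecule the sample lives in one component.
    Features are copied unchanged.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must be in (0, 1]")
    n = graph.num_nodes
    if n == 1:
        return _induced(graph, [0])
    adj = graph.neighbors()
    start = int(rng.integers(n))
    comp = _components(adj, n)
    comp_size = int((comp == comp[start]).sum())
    target = min(max(1, ceil(ratio * n)), comp_size)
    visited = {start}
    cur = start
    steps = 0
    limit = 200 * max(target, 1)
    while len(visited) < target and steps < limit:
        steps += 1
        if adj[cur]:
            cur = adj[cur][int(rng.integers(len(adj[cur])))]
            visited.add(cur)
        else:  # isolated within walk (cannot happen for comp_size>1, but be safe)
            break
        if len(visited) < target and not adj[cur]:
            cur = sorted(visited)[int(rng.integers(len(visited)))]
    if len(visited) < target:
        # deterministic completion: breadth-first fill from the visited frontier
        frontier = sorted(visited)
        while len(visited) < target and frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in visited:
                        visited.add(v)
                        nxt.append(v)
                        if len(visited) >= target:
                            break
                if len(visited) >= target:
                    break
            frontier = nxt
    return _induced(graph, visited)


def _node_dropping(graph: MolGraph, ratio: float, rng) -> MolGraph:
    n = graph.num_nodes
    n_drop = min(ceil(ratio * n), n - 1)  # always keep at least one node
    drop = set(rng.choice(n, size=n_drop, replace=False).tolist())
    return _induced(graph, [v for v in range(n) if v not in drop])


def _edge_perturbation(graph: MolGraph, ratio: float, rng) -> MolGraph:
    n = graph.num_nodes
    edges = [tuple(sorted(e)) for e in graph.edges]
    n_pert = ceil(ratio * len(edges))
    keep_idx = set(range(len(edges)))
    if n_pert and edges:
        removed = rng.choice(len(edges), size=n_pert, replace=False)
        keep_idx -= set(removed.tolist())
    kept = [edges[i] for i in sorted(keep_idx)]
    existing = set(edges)
    candidates = [(u, v) for u in range(n) for v in range(u + 1, n)
                  if (u, v) not in existing]
    n_add = min(n_pert, len(candidates))
    if n_add:
        added_idx = rng.choice(len(candidates), size=n_add, replace=False)
        kept.extend(candidates[i] for i in sorted(added_idx.tolist()))
    return MolGraph(graph.node_features.copy(), kept, n)


def _attribute_masking(graph: MolGraph, ratio: float, rng,
                       mask_vector: Optional[np.ndarray]) -> MolGraph:
    n = graph.num_nodes
    n_mask = min(ceil(ratio * n), n)
    masked = rng.choice(n, size=n_mask, replace=False)
    feats = graph.node_features.copy()
    if mask_vector is None:
        mask_vector = graph.node_features.mean(axis=0)
    feats[masked] = mask_vector
    return MolGraph(feats, list(graph.edges), n)


def augment(graph: MolGraph, method: str, ratio: float, rng,
            mask_vector: Optional[np.ndarray] = None) -> MolGraph:
    """Apply one augmentation; ``mask_vector`` is the dataset-mean feature row
    used by attribute masking (falls back to the graph's own mean)."""
    if method == "substructure":
        return sample_substructure(graph, ratio, rng)
    if method == "node_dropping":
        return _node_dropping(graph, ratio, rng)
    if method == "edge_perturbation":
        return _edge_perturbation(graph, ratio, rng)
    if method == "attribute_masking":
        return _attribute_masking(graph, ratio, rng, mask_vector)
    raise ValueError(f"unknown augmentation method {method!r}; "
                     f"expected one of {AUGMENT_METHODS}")


# ---------------------------------------------------------------------------
# NT-Xent loss
# ---------------------------------------------------------------------------

def _check_reps(reps: np.ndarray):
    if reps.ndim != 2 or reps.shape[0] % 2 or reps.shape[0] < 4:
        raise ValueError("reps must be a 2Q x d matrix with 2Q >= 4")
    norms = np.linalg.norm(reps, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm representation row")
    return norms


def ntxent_pair_loss(reps: np.ndarray, i: int, tau: float = 0.2) -> float:
    """Loss of one anchor row i against its positive (row (i+Q) mod 2Q).

    -log( exp(cos(z_i, pos_i)/tau) / sum_{k != i} exp(cos(z_i, z_k)/tau) );
    the denominator runs over the other 2Q-1 rows including the positive.
    """
    reps = np.asarray(reps, dtype=np.float64)
    norms = _check_reps(reps)
    two_q = reps.shape[0]
    q = two_q // 2
    pos = i + q if i < q else i - q
    unit = reps / norms[:, None]
    sims = unit @ unit[i]
    logits = np.exp(sims / tau)
    denom = logits.sum() - logits[i]
    return float(-np.log(logits[pos] / denom))


def contrastive_loss(reps, tau: float = 0.2) -> float:
    """Batch NT-Xent loss: mean over all 2Q anchor rows of the pair loss."""
    if isinstance(reps, ContrastiveBatch):
        tau = reps.tau
        reps = reps.reps
    reps = np.asarray(reps, dtype=np.float64)
    norms = _check_reps(reps)
    two_q = reps.shape[0]
    q = two_q // 2
    unit = reps / norms[:, None]
    sims = unit @ unit.T / tau
    np.fill_diagonal(sims, -np.inf)
    pos = np.concatenate([np.arange(q, two_q), np.arange(q)])
    logZ = np.log(np.exp(sims).sum(axis=1))
    return float(np.mean(logZ - sims[np.arange(two_q), pos]))


def contrastive_loss_t(z: Tensor, z_hat: Tensor, tau: float = 0.2) -> Tensor:
    """Differentiable NT-Xent loss on stacked [z; z_hat] rows (training path)."""
    from .nn import concat
    reps = concat([z, z_hat], axis=0)
    two_q = reps.shape[0]
    q = two_q // 2
    norms = ((reps * reps).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    unit = reps / norms
    sims = (unit @ unit.T) * (1.0 / tau)
    mask = (1.0 - np.eye(two_q, dtype=reps.data.dtype))
    off_diag = np.where(np.eye(two_q, dtype=bool), -np.inf, sims.data)
    shift = off_diag.max(axis=1, keepdims=True)
    e = (sims - shift).exp() * mask
    logZ = e.sum(axis=1).log() + Tensor(shift.ravel())
    pos = np.concatenate([np.arange(q, two_q), np.arange(q)])
    pos_sims = sims[np.arange(two_q), pos]
    return (logZ - pos_sims).mean()
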