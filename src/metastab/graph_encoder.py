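"""Graph isomorphism network (GIN) encoder over molecular graphs.

Per layer, each atom's representation is updated as
``MLP((1 + eps) * h_v + sum_{u in N(v)} h_u)`` with a learnable per-layer
eps (initialized at 0) and an MLP of the form linear -> batch-norm -> ReLU
-> linear.  After K layers (default 2) the molecule representation p_i is
the concatenation of global max-pooling and global mean-pooling over the
final node representations, so d3 = 2 * d_g.

Batching stacks all node-feature rows of a batch block-diagonally and keeps
a graph-id per node; pooling is a segment reduction over graph ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .chemio import MolGraph
from .nn import (Module, Parameter, Tensor, concat, no_grad, segment_max,
                 segment_mean)
from .nn.layers import BatchNorm1d, Linear

__all__ = ["GraphBatch", "GINLayer", "GINEncoder", "GraphEncoderOutput",
           "gin_layer", "encode_graph", "batch_graphs"]


@dataclass
class GraphBatch:
    """Block-diagonal batch of graphs."""

    features: np.ndarray     # n_total x d
    edge_index: np.ndarray   # 2 x 2E directed
    graph_ids: np.ndarray    # n_total
    num_graphs: int
    num_nodes: int
    _adj: object = None      # cached sparse adjacency

    def adjacency(self):
        """Sparse symmetric adjacency used for neighbor-sum aggregation."""
        if self._adj is None:
            from scipy import sparse
            src, dst = self.edge_index
            self._adj = sparse.csr_matrix(
                (np.ones(len(src), dtype=np.float32), (dst, src)),
                shape=(self.num_nodes, self.num_nodes))
        return self._adj


def batch_graphs(graphs: Sequence[MolGraph],
                 features: Optional[Sequence[np.ndarray]] = None) -> GraphBatch:
    feats, edges, gids = [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        f = g.node_features if features is None else features[gi]
        if f.shape[0] != g.num_nodes:
            raise ValueError("feature row count does not match node count")
        feats.append(f)
        ei = g.edge_index()
        edges.append(ei + offset)
        gids.append(np.full(g.num_nodes, gi, dtype=np.int64))
        offset += g.num_nodes
    return GraphBatch(
        features=np.concatenate(feats, axis=0),
        edge_index=np.concatenate(edges, axis=1) if edges else np.zeros((2, 0), np.int64),
        graph_ids=np.concatenate(gids),
        num_graphs=len(graphs),
        num_nodes=offset,
    )


def _aggregate(x: Tensor, batch: "GraphBatch", eps: Tensor) -> Tensor:
    """(1 + eps) * h_v + sum of neighbor rows (zero vector for isolated nodes)."""
    if batch.edge_index.size:
        src, dst = batch.edge_index
        if src.max(initial=-1) >= batch.num_nodes or dst.max(initial=-1) >= batch.num_nodes:
            raise ValueError("edge index out of range")
        from .nn.tensor import spmm
        return (1.0 + eps) * x + spmm(batch.adjacency(), x)
    return (1.0 + eps) * x


class GINLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng):
        super().__init__()
        self.eps = Parameter(np.zeros(1, dtype=np.float32))
        self.lin1 = Linear(in_dim, out_dim, rng)
        self.bn = BatchNorm1d(out_dim)
        self.lin2 = Linear(out_dim, out_dim, rng)

    def forward(self, x: Tensor, batch: "GraphBatch") -> Tensor:
        agg = _aggregate(x, batch, self.eps)
        return self.lin2(self.bn(self.lin1(agg)).relu())


@dataclass
class GraphEncoderOutput:
    node_reps: np.ndarray    # N x d_g (final layer)
    graph_rep: np.ndarray    # d3 = 2 * d_g (max-pool ++ mean-pool)


class GINEncoder(Module):
    """K stacked GIN layers + max/mean readout producing p_i of width 2*d_g."""

    def __init__(self, in_dim: int = 84, d_g: int = 256, num_layers: int = 2,
                 rng=None):
        super().__init__()
        if num_layers < 1:
            raise ValueError("need at least one GIN layer")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.layers = [GINLayer(in_dim if k == 0 else d_g, d_g, rng)
                       for k in range(num_layers)]
        self.d_g = d_g
        self.d3 = 2 * d_g

    def node_forward(self, batch: GraphBatch, x: Optional[Tensor] = None) -> Tensor:
        h = x if x is not None else Tensor(batch.features)
        for layer in self.layers:
            h = layer(h, batch)
        return h

    def forward(self, batch: GraphBatch) -> Tensor:
        """num_graphs x d3 pooled representations."""
        h = self.node_forward(batch)
        mx = segment_max(h, batch.graph_ids, batch.num_graphs)
        mn = segment_mean(h, batch.graph_ids, batch.num_graphs)
        return concat([mx, mn], axis=1)

    def encode_one(self, graph: MolGraph) -> GraphEncoderOutput:
        with no_grad():
            batch = batch_graphs([graph])
            h = self.node_forward(batch)
            mx = segment_max(h, batch.graph_ids, 1)
            mn = segment_mean(h, batch.graph_ids, 1)
        return GraphEncoderOutput(node_reps=h.data,
                                  graph_rep=np.concatenate([mx.data[0], mn.data[0]]))


# -- functional forms ------------------------------------------------------

def gin_layer(graph: MolGraph, features: np.ndarray, epsilon: float,
              mlp: Optional[Callable[[np.ndarray], np.ndarray]] = None) -> np.ndarray:
    """One GIN aggregation step on plain numpy features.

    ``mlp`` is any callable applied to the aggregated matrix (identity when
    omitted).  This is the reference entry point used by the batched
    :class:`GINLayer` under the hood of training; it accepts arbitrary
    feature widths.
    """
    if features.shape[0] != graph.num_nodes:
        raise ValueError("feature row count does not match node count")
    with no_grad():
        batch = batch_graphs([graph], features=[np.asarray(features, dtype=np.float64)])
        agg = _aggregate(Tensor(batch.features), batch,
                         Tensor(np.float64(epsilon))).data
    return mlp(agg) if mlp is not None else agg


def encode_graph(graph: MolGraph, encoder: GINEncoder) -> np.ndarray:
    """Molecule representation p_i for a single graph."""
    return encoder.encode_one(graph).graph_rep
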