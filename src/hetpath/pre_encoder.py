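"""Type-specific feature projection and single-layer relational convolution.

Every node type is first mapped into a shared d-dimensional latent space by
its own linear projection (when a type carries no feature matrix, one-hot
inputs are assumed, which makes the projection a table of learnable per-node
vectors).  A single relational graph-convolution layer then mixes first-order
neighborhoods with one weight matrix per *directed* relation, normalizing
messages by the receiver's per-relation degree:

    h_v' = sigma( W_0 h_v + sum_r sum_{u in N_r(v)} (1 / |N_r(v)|) W_r h_u )

Isolated nodes reduce to ``sigma(W_0 h_v)``.  The ablation that removes this
stage simply feeds the projected features downstream unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import nn
from .schema import GraphSchema, HeteroGraph


def directed_relations(schema: GraphSchema) -> list[tuple[str, str]]:
    """Directed relation keys: each undirected cross-type relation expands to
    forward and reverse; same-type relations stay single with symmetric
    adjacency."""
    keys = []
    for rel in sorted(schema.relations):
        a, b = schema.relations[rel]
        if a == b:
            keys.append((rel, "sym"))
        else:
            keys.append((rel, "fwd"))
            keys.append((rel, "rev"))
    return keys


def type_offsets(graph: HeteroGraph) -> tuple[dict[str, int], int]:
    """Global contiguous indexing: types in sorted order."""
    offsets: dict[str, int] = {}
    total = 0
    for t in sorted(graph.schema.node_types):
        offsets[t] = total
        total += graph.num_nodes(t)
    return offsets, total


def relation_operators(graph: HeteroGraph) -> dict[tuple[str, str], sp.csr_matrix]:
    """Row-normalized global adjacency per directed relation.

    ``A[(rel, dir)][recv, send] = 1 / deg_rel(recv)`` so that ``A @ H`` is the
    mean of sender embeddings — the 1/c_r normalizer with c_r = |N_r(v)|.
    """
    offsets, total = type_offsets(graph)
    ops: dict[tuple[str, str], sp.csr_matrix] = {}
    for rel, direction in directed_relations(graph.schema):
        a, b = graph.schema.relations[rel]
        rows, cols = [], []
        for u, v in graph.edges[rel]:
            if direction == "sym":
                rows += [offsets[a] + u, offsets[a] + v]
                cols += [offsets[a] + v, offsets[a] + u]
            elif direction == "fwd":  # receivers of type b
                rows.append(offsets[b] + v)
                cols.append(offsets[a] + u)
            else:  # receivers of type a
                rows.append(offsets[a] + u)
                cols.append(offsets[b] + v)
        mat = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(total, total)
        )
        deg = np.asarray(mat.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        ops[(rel, direction)] = sp.diags(inv) @ mat
    return ops


@dataclass
class ProjectionParams:
    """One (d x d_T) weight matrix per node type; shared output dimension d."""

    weights: dict[str, nn.Tensor]
    dim: int

    @classmethod
    def init(cls, graph: HeteroGraph, dim: int, rng: np.random.Generator) -> "ProjectionParams":
        weights = {}
        for t in sorted(graph.schema.node_types):
            d_t = graph.features[t].shape[1] if t in graph.features else graph.num_nodes(t)
            d_t = max(d_t, 1)
            weights[t] = nn.glorot(rng, (dim, d_t))
        return cls(weights=weights, dim=dim)


def project_features(graph: HeteroGraph, params: ProjectionParams) -> nn.Tensor:
    """Stacked h^(0): rows are nodes in global order, columns the latent dims.

    For a type with features X (n x d_T): ``H = X @ W_T^T``.  Without
    features the inputs are one-hot, so ``H = W_T^T`` directly.
    """
    blocks = []
    for t in sorted(graph.schema.node_types):
        w = params.weights[t]
        n = graph.num_nodes(t)
        if t in graph.features:
            x = graph.features[t]
            if x.shape[1] != w.shape[1]:
                raise ValueError(
                    f"type {t!r}: feature width {x.shape[1]} != W_T width {w.shape[1]}"
                )
            blocks.append(nn.matmul(nn.Tensor(x), nn.transpose(w)))
        else:
            if w.shape[1] != n:
                raise ValueError(
                    f"type {t!r}: one-hot projection expects width {n}, got {w.shape[1]}"
                )
            blocks.append(nn.transpose(w))
    return nn.concat(blocks, axis=0)


@dataclass
class RgcnParams:
    """Self weight plus one weight per directed relation; LeakyReLU default."""

    w_self: nn.Tensor
    w_rel: dict[tuple[str, str], nn.Tensor]
    slope: float = 0.01
    activation: str = "leaky_relu"  # or "identity"

    @classmethod
    def init(cls, schema: GraphSchema, dim: int, rng: np.random.Generator) -> "RgcnParams":
        w_self = nn.glorot(rng, (dim, dim))
        w_rel = {key: nn.glorot(rng, (dim, dim)) for key in directed_relations(schema)}
        return cls(w_self=w_self, w_rel=w_rel)


def rgcn_layer(
    graph: HeteroGraph,
    h: nn.Tensor,
    params: RgcnParams,
    operators: dict[tuple[str, str], sp.csr_matrix] | None = None,
) -> nn.Tensor:
    """One relational convolution over the stacked embedding table."""
    h = nn.as_tensor(h)
    if operators is None:
        operators = relation_operators(graph)
    out = nn.matmul(h, nn.transpose(params.w_self))
    for key in directed_relations(graph.schema):
        msg = nn.spmm(operators[key], h)
        out = nn.add(out, nn.matmul(msg, nn.transpose(params.w_rel[key])))
    if params.activation == "identity":
        return out
    return nn.leaky_relu(out, params.slope)
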