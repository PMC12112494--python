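"""Three-layer nested metapath encoder.

Per metapath class the pipeline is:

1. instance encoding — each instance is the mean of the embeddings of *all*
   nodes on the path (endpoints included) mapped through the class weight
   ``W_P``;
2. intra-class aggregation — arithmetic mean by default, or instance
   attention ``alpha = softmax(LeakyReLU(theta . h_i))``;
3. inter-class aggregation — sample-wise multiplicative self-attention over
   the M class vectors of a sample, yielding a fused vector and per-class
   weights ``beta`` that sum to one.

Because steps 1 and 2 are linear in the node embeddings when the intra mode
is the mean, they are folded into one precomputed sparse row-stochastic
operator per class (node-embedding table in, per-anchor/per-pair mean
instance embedding out), which is what makes full-batch CPU training cheap.
The inter-class step is batch independent by construction: each sample's
attention involves only its own M class vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import nn
from .metapath import (
    InstanceStore,
    MetaPathInstance,
    MetaPathType,
    anchor_instances,
    pair_instances,
)
from .schema import HeteroGraph

NEG_INF = -1e30


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class InstanceEncoderParams:
    """One (d x d) weight matrix per metapath type."""

    weights: dict[MetaPathType, nn.Tensor]

    @classmethod
    def init(cls, types, dim: int, rng: np.random.Generator) -> "InstanceEncoderParams":
        return cls(
            weights={
                t: nn.glorot(rng, (dim, dim))
                for t in sorted(types, key=lambda t: t.name)
            }
        )


@dataclass
class IntraAggParams:
    mode: str = "mean"  # "mean" | "attention"
    theta: nn.Tensor | None = None  # (d,) attention vector
    slope: float = 0.01
    activation: str = "leaky_relu"  # sigma applied to the aggregate

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator, mode: str = "mean") -> "IntraAggParams":
        return cls(mode=mode, theta=nn.Tensor(rng.normal(0, 0.1, size=dim), requires_grad=True))


@dataclass
class InterAggParams:
    """Sample-wise self-attention over class vectors (plus the batch-additive
    alternative used by one ablation)."""

    w1: nn.Tensor  # (d, d')
    b1: nn.Tensor  # (d',)
    wq: nn.Tensor  # (d', dk)
    wk: nn.Tensor  # (d', dk)
    wv: nn.Tensor  # (d', dk)
    w2: nn.Tensor  # (dk, 1)
    q_add: nn.Tensor  # (d',) additive-attention query (ablation only)
    dk: int
    normalize: bool = True  # softmax the raw class weights

    @classmethod
    def init(
        cls, dim: int, rng: np.random.Generator, d_hidden: int | None = None, dk: int | None = None
    ) -> "InterAggParams":
        d_hidden = d_hidden or dim
        dk = dk or max(dim // 2, 1)
        return cls(
            w1=nn.glorot(rng, (dim, d_hidden)),
            b1=nn.Tensor(np.zeros(d_hidden), requires_grad=True),
            wq=nn.glorot(rng, (d_hidden, dk)),
            wk=nn.glorot(rng, (d_hidden, dk)),
            wv=nn.glorot(rng, (d_hidden, dk)),
            w2=nn.glorot(rng, (dk, 1)),
            q_add=nn.Tensor(rng.normal(0, 0.1, size=d_hidden), requires_grad=True),
            dk=dk,
        )


# ---------------------------------------------------------------------------
# per-instance / per-list operations (contract-level API)
# ---------------------------------------------------------------------------

def encode_instance(rows, h, w_p) -> nn.Tensor:
    """``W_P @ mean(h[rows])`` for one instance given its global row indices."""
    rows = np.asarray(rows, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("empty metapath instance")
    picked = nn.gather(nn.as_tensor(h), rows)
    m = nn.mean(picked, axis=0, keepdims=True)  # (1, d)
    return nn.reshape(nn.matmul(m, nn.transpose(nn.as_tensor(w_p))), (-1,))


def _apply_sigma(x: nn.Tensor, params: IntraAggParams) -> nn.Tensor:
    if params.activation == "identity":
        return x
    return nn.leaky_relu(x, params.slope)


def aggregate_intra(encoded, params: IntraAggParams, return_weights: bool = False):
    """Aggregate a non-empty list of instance encodings into one class vector."""
    encoded = [nn.as_tensor(e) for e in encoded]
    if not encoded:
        raise ValueError("cannot aggregate an empty instance list")
    stackd = nn.stack(encoded, axis=0)  # (m, d)
    if params.mode == "mean":
        out = _apply_sigma(nn.mean(stackd, axis=0), params)
        alpha = np.full(len(encoded), 1.0 / len(encoded))
    elif params.mode == "attention":
        scores = nn.leaky_relu(
            nn.matmul(stackd, nn.reshape(params.theta, (-1, 1))), params.slope
        )  # (m, 1)
        alpha_t = nn.softmax(nn.reshape(scores, (1, -1)), axis=-1)  # (1, m)
        out = _apply_sigma(nn.reshape(nn.matmul(alpha_t, stackd), (-1,)), params)
        alpha = nn.reshape(alpha_t, (-1,))
    else:
        raise ValueError(f"unknown intra mode {params.mode!r}")
    if return_weights:
        return out, alpha
    return out


def aggregate_inter(class_vectors, params: InterAggParams):
    """Sample-wise multiplicative self-attention.

    ``class_vectors`` is (M, d) for a single sample or (B, M, d) batched.
    Returns (fused vector(s), beta weights).  Each sample's computation uses
    only its own rows, so results are independent of batch composition.
    """
    H = nn.as_tensor(class_vectors)
    single = H.ndim == 2
    if single:
        H = nn.reshape(H, (1,) + H.shape)
    X = nn.tanh(nn.add(nn.matmul(H, params.w1), params.b1))  # (B, M, d')
    Q = nn.matmul(X, params.wq)
    K = nn.matmul(X, params.wk)
    V = nn.matmul(X, params.wv)
    A = nn.softmax(
        nn.mul(nn.matmul(Q, nn.transpose(K, (0, 2, 1))), 1.0 / np.sqrt(params.dk)),
        axis=-1,
    )  # (B, M, M)
    beta_raw = nn.matmul(nn.matmul(A, V), params.w2)  # (B, M, 1)
    beta_flat = nn.reshape(beta_raw, beta_raw.shape[:-1])  # (B, M)
    beta = nn.softmax(beta_flat, axis=-1) if params.normalize else beta_flat
    weighted = nn.mul(nn.reshape(beta, beta.shape + (1,)), H)
    fused = nn.sum_(weighted, axis=-2)  # (B, d)
    if single:
        return nn.reshape(fused, fused.shape[1:]), nn.reshape(beta, beta.shape[1:])
    return fused, beta


def aggregate_inter_additive(class_vectors, params: InterAggParams):
    """Batch-based additive attention (ablation): one weight vector shared by
    the whole batch, computed from batch-mean class scores."""
    H = nn.as_tensor(class_vectors)  # (B, M, d)
    if H.ndim != 3:
        raise ValueError("additive aggregation expects a (B, M, d) batch")
    X = nn.tanh(nn.add(nn.matmul(H, params.w1), params.b1))  # (B, M, d')
    scores = nn.matmul(X, nn.reshape(params.q_add, (-1, 1)))  # (B, M, 1)
    mean_scores = nn.mean(nn.reshape(scores, scores.shape[:-1]), axis=0)  # (M,)
    beta = nn.softmax(nn.reshape(mean_scores, (1, -1)), axis=-1)  # (1, M)
    weighted = nn.mul(nn.reshape(beta, (1, -1, 1)), H)
    return nn.sum_(weighted, axis=-2), nn.reshape(beta, (-1,))


# ---------------------------------------------------------------------------
# folded sparse operators for the (default) mean intra mode
# ---------------------------------------------------------------------------

def _instance_rows(
    inst: MetaPathInstance, types: tuple[str, ...], offsets: dict[str, int]
) -> list[int]:
    return [offsets[t] + i for t, i in zip(types, inst)]


def mean_operator(
    keys,
    instance_lists,
    mptype_node_types_per_key,
    offsets: dict[str, int],
    total: int,
) -> sp.csr_matrix:
    """Row k = mean over instances of the mean over path-node rows.

    ``instance_lists[k]`` must be non-empty (fallback guarantees it);
    ``mptype_node_types_per_key[k]`` gives the type sequence matching each
    instance (fallback instances are shorter than the full type sequence).
    """
    rows, cols, vals = [], [], []
    for k, (instances, type_seqs) in enumerate(
        zip(instance_lists, mptype_node_types_per_key)
    ):
        m = len(instances)
        for inst, types in zip(instances, type_seqs):
            w = 1.0 / (m * len(inst))
            for r in _instance_rows(inst, types, offsets):
                rows.append(k)
                cols.append(r)
                vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(keys), total))


def node_class_operator(
    graph: HeteroGraph,
    store: InstanceStore,
    mptype: MetaPathType,
    offsets: dict[str, int],
    total: int,
) -> sp.csr_matrix:
    """Folded operator over *all* nodes of the class's anchor type."""
    anchor_type = mptype.node_types[0]
    n = graph.num_nodes(anchor_type)
    instance_lists, type_seqs = [], []
    for v in range(n):
        insts = anchor_instances(store, v, mptype)
        instance_lists.append(insts)
        type_seqs.append(
            [mptype.node_types if len(i) > 1 else (anchor_type,) for i in insts]
        )
    return mean_operator(range(n), instance_lists, type_seqs, offsets, total)


def pair_class_operator(
    pairs,
    store: InstanceStore,
    mptype: MetaPathType,
    offsets: dict[str, int],
    total: int,
) -> sp.csr_matrix:
    """Folded operator over candidate pairs, with target-edge exclusion and
    the (u, v) fallback applied."""
    instance_lists, type_seqs = [], []
    for u, v in pairs:
        insts = pair_instances(store, u, v, mptype)
        instance_lists.append(insts)
        type_seqs.append(
            [
                mptype.node_types
                if len(i) == len(mptype.node_types)
                else ("miRNA", "disease")
                for i in insts
            ]
        )
    return mean_operator(pairs, instance_lists, type_seqs, offsets, total)


def class_vectors_mean(
    operator: sp.csr_matrix,
    h: nn.Tensor,
    w_p: nn.Tensor,
    intra: IntraAggParams,
) -> nn.Tensor:
    """Vectorized Eq-8 + mean Eq-10 for one class: sigma((S h) W_P^T)."""
    pooled = nn.spmm(operator, h)
    return _apply_sigma(nn.matmul(pooled, nn.transpose(w_p)), intra)


# ---------------------------------------------------------------------------
# ragged attention intra mode (ablation "+iattn")
# ---------------------------------------------------------------------------

@dataclass
class RaggedInstances:
    """Padded layout of per-key instance lists for vectorized attention."""

    operator: sp.csr_matrix  # (n_instances, total): per-instance node means
    pad_index: np.ndarray  # (n_keys, max_m) into instance rows (+dummy last)
    mask: np.ndarray  # (n_keys, max_m) 1 for real instances

    @classmethod
    def build(cls, instance_lists, type_seqs, offsets, total) -> "RaggedInstances":
        rows, cols, vals = [], [], []
        counts = []
        r = 0
        for insts, seqs in zip(instance_lists, type_seqs):
            counts.append(len(insts))
            for inst, types in zip(insts, seqs):
                w = 1.0 / len(inst)
                for c in _instance_rows(inst, types, offsets):
                    rows.append(r)
                    cols.append(c)
                    vals.append(w)
                r += 1
        op = sp.csr_matrix((vals, (rows, cols)), shape=(r, total))
        max_m = max(counts) if counts else 1
        pad = np.full((len(counts), max_m), r, dtype=np.intp)  # r = dummy row
        mask = np.zeros((len(counts), max_m))
        start = 0
        for k, m in enumerate(counts):
            pad[k, :m] = np.arange(start, start + m)
            mask[k, :m] = 1.0
            start += m
        return cls(operator=op, pad_index=pad, mask=mask)


def class_vectors_attention(
    ragged: RaggedInstances,
    h: nn.Tensor,
    w_p: nn.Tensor,
    intra: IntraAggParams,
) -> nn.Tensor:
    """Instance attention per key: alpha = softmax(LeakyReLU(theta . h_i))."""
    inst = nn.matmul(nn.spmm(ragged.operator, h), nn.transpose(w_p))  # (n_inst, d)
    d = inst.shape[1]
    dummy = nn.Tensor(np.zeros((1, d)))
    padded = nn.concat([inst, dummy], axis=0)
    n_keys, max_m = ragged.pad_index.shape
    flat = ragged.pad_index.reshape(-1)
    gathered = nn.reshape(nn.gather(padded, flat), (n_keys, max_m, d))
    scores = nn.leaky_relu(
        nn.matmul(gathered, nn.reshape(intra.theta, (-1, 1))), intra.slope
    )  # (n_keys, max_m, 1)
    scores = nn.reshape(scores, (n_keys, max_m))
    masked = nn.add(scores, nn.Tensor((1.0 - ragged.mask) * NEG_INF))
    alpha = nn.softmax(masked, axis=-1)  # (n_keys, max_m)
    weighted = nn.mul(nn.reshape(alpha, (n_keys, max_m, 1)), gathered)
    return _apply_sigma(nn.sum_(weighted, axis=1), intra)
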