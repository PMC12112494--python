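"""Full forward pass and the structure-guided link decoder.

The decoder scores a candidate pair from three vectors: the two secondary
(node-specific metapath) embeddings and the common-metapath embedding of the
pair.  The logit is

    y = f( f1(h_u ⊙ h_v) + beta_dec * f2(h_uv) )

with f, f1, f2 small MLPs (linear + layer norm + LeakyReLU) and ``beta_dec``
a learnable scalar scaling the structural-evidence term; setting it to zero
(or the ``use_link=False`` ablation) removes the common-metapath guidance
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import nn
from .metapath import InstanceStore, MetaPathType, anchor_instances, pair_instances
from .metapath_encoder import (
    InstanceEncoderParams,
    InterAggParams,
    IntraAggParams,
    RaggedInstances,
    aggregate_inter,
    aggregate_inter_additive,
    class_vectors_attention,
    class_vectors_mean,
    node_class_operator,
    pair_class_operator,
)
from .pre_encoder import (
    ProjectionParams,
    RgcnParams,
    project_features,
    relation_operators,
    rgcn_layer,
    type_offsets,
)
from .schema import HeteroGraph


class MLP:
    """Linear -> (LayerNorm) -> LeakyReLU -> Linear."""

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        d_out: int,
        rng: np.random.Generator,
        use_layer_norm: bool = True,
        slope: float = 0.01,
    ):
        self.w1 = nn.glorot(rng, (d_in, d_hidden))
        self.b1 = nn.Tensor(np.zeros(d_hidden), requires_grad=True)
        self.w2 = nn.glorot(rng, (d_hidden, d_out))
        self.b2 = nn.Tensor(np.zeros(d_out), requires_grad=True)
        self.use_layer_norm = use_layer_norm
        self.slope = slope
        if use_layer_norm:
            self.gamma = nn.Tensor(np.ones(d_hidden), requires_grad=True)
            self.beta = nn.Tensor(np.zeros(d_hidden), requires_grad=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        z = nn.add(nn.matmul(x, self.w1), self.b1)
        if self.use_layer_norm:
            z = nn.layer_norm(z, self.gamma, self.beta)
        z = nn.leaky_relu(z, self.slope)
        return nn.add(nn.matmul(z, self.w2), self.b2)

    def parameters(self) -> list[nn.Tensor]:
        out = [self.w1, self.b1, self.w2, self.b2]
        if self.use_layer_norm:
            out += [self.gamma, self.beta]
        return out


@dataclass
class DecoderParams:
    f1: MLP  # d -> d
    f2: MLP  # d -> d
    f: MLP  # d -> 1
    beta_dec: nn.Tensor  # learnable scalar, init 1.0

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator, use_layer_norm: bool = True) -> "DecoderParams":
        return cls(
            f1=MLP(dim, dim, dim, rng, use_layer_norm),
            f2=MLP(dim, dim, dim, rng, use_layer_norm),
            f=MLP(dim, dim, 1, rng, use_layer_norm),
            beta_dec=nn.Tensor(np.array(1.0), requires_grad=True),
        )

    def parameters(self) -> list[nn.Tensor]:
        return self.f1.parameters() + self.f2.parameters() + self.f.parameters() + [self.beta_dec]


@dataclass
class PairScore:
    mirna: str
    disease: str
    logit: float
    probability: float
    label: int | None = None


def decode_logits(
    h_u: nn.Tensor, h_v: nn.Tensor, h_uv: nn.Tensor | None, params: DecoderParams, use_link: bool = True
) -> nn.Tensor:
    """Batched decoder: (B, d) inputs -> (B,) logits."""
    z = params.f1(nn.mul(h_u, h_v))
    if use_link:
        if h_uv is None:
            raise ValueError("use_link=True requires the common-metapath embedding")
        z = nn.add(z, nn.mul(params.beta_dec, params.f2(h_uv)))
    out = params.f(z)
    return nn.reshape(out, (out.shape[0],))


def score_pair(u, v, h_u, h_v, h_uv, params: DecoderParams, use_link: bool = True, label=None) -> PairScore:
    """Score a single candidate pair from its three d-vectors."""
    hu = nn.reshape(nn.as_tensor(h_u), (1, -1))
    hv = nn.reshape(nn.as_tensor(h_v), (1, -1))
    huv = None if h_uv is None else nn.reshape(nn.as_tensor(h_uv), (1, -1))
    logit = float(decode_logits(hu, hv, huv, params, use_link=use_link).data[0])
    prob = 1.0 / (1.0 + np.exp(-logit))
    return PairScore(mirna=str(u), disease=str(v), logit=logit, probability=prob, label=label)


# ---------------------------------------------------------------------------
# model configuration and state
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    dim: int = 64
    d_hidden: int | None = None  # d' of the inter-class attention
    dk: int | None = None
    intra_mode: str = "mean"  # "mean" | "attention"   (+iattn ablation)
    inter_mode: str = "self"  # "self" | "additive"    (-attn ablation)
    use_link: bool = True  # False = -link ablation
    use_pre_encoder: bool = True  # False = drop the relational pre-encoding
    normalize_beta: bool = True
    rgcn_layers: int = 1
    use_layer_norm: bool = True


@dataclass
class ModelState:
    projection: ProjectionParams
    rgcn: RgcnParams
    instance: InstanceEncoderParams
    intra: IntraAggParams
    inter: InterAggParams
    decoder: DecoderParams

    def parameters(self) -> list[nn.Tensor]:
        params = list(self.projection.weights.values())
        params.append(self.rgcn.w_self)
        params += list(self.rgcn.w_rel.values())
        params += list(self.instance.weights.values())
        if self.intra.theta is not None:
            params.append(self.intra.theta)
        inter = self.inter
        params += [inter.w1, inter.b1, inter.wq, inter.wk, inter.wv, inter.w2, inter.q_add]
        params += self.decoder.parameters()
        return params


@dataclass
class PairBatch:
    """Precomputed evidence layout for a fixed list of candidate pairs."""

    pairs: list[tuple[int, int]]
    labels: np.ndarray
    mirna_rows: np.ndarray  # per-pair miRNA index (within type)
    disease_rows: np.ndarray
    mirna_ops: dict[MetaPathType, sp.csr_matrix]  # all-miRNA folded operators
    disease_ops: dict[MetaPathType, sp.csr_matrix]
    common_ops: dict[MetaPathType, sp.csr_matrix]  # per-pair folded operators
    mirna_ragged: dict[MetaPathType, RaggedInstances] = field(default_factory=dict)
    disease_ragged: dict[MetaPathType, RaggedInstances] = field(default_factory=dict)
    common_ragged: dict[MetaPathType, RaggedInstances] = field(default_factory=dict)


class LinkPredictor:
    """End-to-end model: projection, relational pre-encoding, nested metapath
    aggregation and the structure-guided decoder."""

    def __init__(
        self,
        graph: HeteroGraph,
        node_specific_types,
        common_types,
        config: ModelConfig,
        seed: int = 0,
    ):
        self.graph = graph
        self.config = config
        self.node_specific_types = sorted(node_specific_types, key=lambda t: t.name)
        self.common_types = sorted(common_types, key=lambda t: t.name)
        self.mirna_classes = [t for t in self.node_specific_types if t.node_types[0] == "miRNA"]
        self.disease_classes = [t for t in self.node_specific_types if t.node_types[0] == "disease"]
        rng = np.random.default_rng(seed)
        dim = config.dim
        self.state = ModelState(
            projection=ProjectionParams.init(graph, dim, rng),
            rgcn=RgcnParams.init(graph.schema, dim, rng),
            instance=InstanceEncoderParams.init(
                self.node_specific_types + self.common_types, dim, rng
            ),
            intra=IntraAggParams.init(dim, rng, mode=config.intra_mode),
            inter=InterAggParams.init(dim, rng, d_hidden=config.d_hidden, dk=config.dk),
        decoder=DecoderParams.init(dim, rng, use_layer_norm=config.use_layer_norm),
        )
        self.state.inter.normalize = config.normalize_beta
        self._rel_ops = relation_operators(graph)
        self._offsets, self._total = type_offsets(graph)

    # -- batch preparation ---------------------------------------------
    def prepare_batch(self, store: InstanceStore, pairs, labels=None) -> PairBatch:
        pairs = list(pairs)
        labels = np.zeros(len(pairs)) if labels is None else np.asarray(labels, dtype=np.float64)
        offsets, total = self._offsets, self._total
        batch = PairBatch(
            pairs=pairs,
            labels=labels,
            mirna_rows=np.array([m for m, _ in pairs], dtype=np.intp),
            disease_rows=np.array([d for _, d in pairs], dtype=np.intp),
            mirna_ops={},
            disease_ops={},
            common_ops={},
        )
        attention = self.config.intra_mode == "attention"
        for mptype in self.mirna_classes:
            batch.mirna_ops[mptype] = node_class_operator(self.graph, store, mptype, offsets, total)
            if attention:
                batch.mirna_ragged[mptype] = self._node_ragged(store, mptype)
        for mptype in self.disease_classes:
            batch.disease_ops[mptype] = node_class_operator(self.graph, store, mptype, offsets, total)
            if attention:
                batch.disease_ragged[mptype] = self._node_ragged(store, mptype)
        for mptype in self.common_types:
            batch.common_ops[mptype] = pair_class_operator(pairs, store, mptype, offsets, total)
            if attention:
                batch.common_ragged[mptype] = self._pair_ragged(store, mptype, pairs)
        return batch

    def _node_ragged(self, store: InstanceStore, mptype: MetaPathType) -> RaggedInstances:
        anchor_type = mptype.node_types[0]
        lists, seqs = [], []
        for v in range(self.graph.num_nodes(anchor_type)):
            insts = anchor_instances(store, v, mptype)
            lists.append(insts)
            seqs.append([mptype.node_types if len(i) > 1 else (anchor_type,) for i in insts])
        return RaggedInstances.build(lists, seqs, self._offsets, self._total)

    def _pair_ragged(self, store: InstanceStore, mptype: MetaPathType, pairs) -> RaggedInstances:
        lists, seqs = [], []
        for u, v in pairs:
            insts = pair_instances(store, u, v, mptype)
            lists.append(insts)
            seqs.append(
                [
                    mptype.node_types if len(i) == len(mptype.node_types) else ("miRNA", "disease")
                    for i in insts
                ]
            )
        return RaggedInstances.build(lists, seqs, self._offsets, self._total)

    # -- forward --------------------------------------------------------
    def encode_nodes(self) -> nn.Tensor:
        h = project_features(self.graph, self.state.projection)
        if self.config.use_pre_encoder:
            for _ in range(self.config.rgcn_layers):
                h = rgcn_layer(self.graph, h, self.state.rgcn, operators=self._rel_ops)
        return h

    def _class_stack(self, h, classes, ops, ragged) -> nn.Tensor:
        vectors = []
        for mptype in classes:
            w_p = self.state.instance.weights[mptype]
            if self.config.intra_mode == "attention":
                vectors.append(class_vectors_attention(ragged[mptype], h, w_p, self.state.intra))
            else:
                vectors.append(class_vectors_mean(ops[mptype], h, w_p, self.state.intra))
        return nn.stack(vectors, axis=1)  # (n_keys, M, d)

    def _aggregate(self, stacked: nn.Tensor):
        if self.config.inter_mode == "additive":
            return aggregate_inter_additive(stacked, self.state.inter)
        return aggregate_inter(stacked, self.state.inter)

    def forward(self, batch: PairBatch):
        """Return (logits tensor, diagnostics dict with beta weights)."""
        h = self.encode_nodes()
        mirna_stack = self._class_stack(h, self.mirna_classes, batch.mirna_ops, batch.mirna_ragged)
        disease_stack = self._class_stack(
            h, self.disease_classes, batch.disease_ops, batch.disease_ragged
        )
        h_mirna, beta_m = self._aggregate(mirna_stack)  # (n_miRNA, d)
        h_disease, beta_d = self._aggregate(disease_stack)
        h_u = nn.gather(h_mirna, batch.mirna_rows)
        h_v = nn.gather(h_disease, batch.disease_rows)
        h_uv, beta_c = None, None
        if self.config.use_link:
            common_stack = self._class_stack(h, self.common_types, batch.common_ops, batch.common_ragged)
            h_uv, beta_c = self._aggregate(common_stack)
        logits = decode_logits(h_u, h_v, h_uv, self.state.decoder, use_link=self.config.use_link)
        diagnostics = {
            "beta_common": None if beta_c is None else np.array(beta_c.data),
            "beta_mirna": np.array(beta_m.data),
            "beta_disease": np.array(beta_d.data),
        }
        return logits, diagnostics

    def predict(self, batch: PairBatch) -> np.ndarray:
        """Probabilities for the batch (no gradient bookkeeping needed)."""
        logits, _ = self.forward(batch)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def score_pairs(self, batch: PairBatch) -> list[PairScore]:
        logits, _ = self.forward(batch)
        out = []
        for (m, d), z, y in zip(batch.pairs, logits.data, batch.labels):
            out.append(
                PairScore(
                    mirna=self.graph.nodes["miRNA"][m],
                    disease=self.graph.nodes["disease"][d],
                    logit=float(z),
                    probability=float(1.0 / (1.0 + np.exp(-z))),
                    label=int(y),
                )
            )
        return out

    def parameters(self) -> list[nn.Tensor]:
        """Parameters active under the current configuration."""
        cfg = self.config
        params = list(self.state.projection.weights.values())
        if cfg.use_pre_encoder:
            params.append(self.state.rgcn.w_self)
            params += list(self.state.rgcn.w_rel.values())
        for mptype, w in self.state.instance.weights.items():
            if mptype.category == "common" and not cfg.use_link:
                continue
            params.append(w)
        if cfg.intra_mode == "attention":
            params.append(self.state.intra.theta)
        inter = self.state.inter
        params += [inter.w1, inter.b1]
        if cfg.inter_mode == "additive":
            params.append(inter.q_add)
        else:
            params += [inter.wq, inter.wk, inter.wv, inter.w2]
        dec = self.state.decoder
        params += dec.f1.parameters() + dec.f.parameters()
        if cfg.use_link:
            params += dec.f2.parameters() + [dec.beta_dec]
        return params
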