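# hetpath

Metapath-guided heterogeneous-graph link prediction for miRNA–disease
association (MDA) networks, with a strictly leakage-safe protocol.

The pipeline couples semantic and structural evidence in four stages:

1. **Metapath discovery** — enumerate metapath types over an 8-node-type
   biological schema (miRNA, disease, mRNA, lncRNA, circRNA, protein, drug,
   microbe; 17 undirected relations): 12 *node-specific* types (length-2
   paths anchored at miRNA or disease) and 13 *common* types (miRNA→disease
   paths of length 2–3 plus the alternating miRNA–disease–miRNA–disease
   pattern), then materialize concrete node-level instances on the
   **training graph only**.
2. **Relational pre-encoding** — type-specific feature projection followed
   by a single relational graph-convolution layer (one weight matrix per
   directed relation, mean-normalized neighborhoods).
3. **Nested metapath encoding** — per-instance encoding (mean of all path
   node embeddings through a per-class weight), intra-class aggregation
   (mean by default, instance attention optionally) and inter-class
   *sample-wise* multiplicative self-attention producing per-class weights
   `beta` that are batch independent and sum to 1.
4. **Structure-guided decoding** — `y = f(f1(h_u ⊙ h_v) + β · f2(h_uv))`,
   where `h_uv` aggregates the pair's common-metapath evidence; a learnable
   scalar scales the structural term and candidate pairs never see their own
   target edge (target-edge exclusion plus node-simple instances).

Leakage safety: validation/test target edges are removed from the graph
before any instance is materialized or any message passed; negatives are
sampled once from non-edges, disjointly across splits.

A stochastic-block synthetic generator (`hetpath.synthgraph`) plants
cluster-mediated MDA structure so the whole pipeline is testable offline;
`direct` / `mediated` / `mixed` modes control whether the recoverable signal
lives in the target relation, the shared intermediates, or both.

Everything trains on one CPU: the model runs on a small vectorized
reverse-mode autodiff engine (`hetpath.nn`, numpy + scipy.sparse only), and
the default mean intra-class mode folds instance aggregation into
precomputed sparse operators.

## CLI

```bash
# generate a planted-signal fixture (edges.tsv + clusters.tsv)
hetpath synth --seed 0 --mode mixed --out data/

# print the metapath catalogue (12 node-specific + 13 common types)
hetpath enumerate

# splits, training graph and instance stores from an edge list
hetpath prepare data/edges.tsv --seed 0 --out prep/

# multi-seed protocol: metrics JSON + per-pair attention-weight export
hetpath train data/edges.tsv --config config.yaml --out run/

# score explicit candidate pairs
hetpath predict data/edges.tsv --pairs pairs.tsv --out scores.tsv
```

A YAML config mirrors `hetpath.train_eval.TrainConfig`, e.g.:

```yaml
seeds: [0, 1, 2, 3, 4]
epochs: 150
patience: 30
lr: 0.005
weight_decay: 0.0001
model:
  dim: 64
  use_link: true      # false = drop the structural decoder term
  intra_mode: mean    # "attention" for intra-class instance attention
  inter_mode: self    # "additive" for batch-based additive attention
```

Edge TSV format: `src_type  src_id  relation  dst_type  dst_id` (UTF-8,
`#` comments). Split TSV: `split  label  miRNA_id  disease_id`.

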