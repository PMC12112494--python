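"""Typed heterogeneous-graph container, edge-list I/O and leakage-safe splits.

A graph is described by a :class:`GraphSchema` (node types plus undirected,
labelled relations between type pairs) and realized as a :class:`HeteroGraph`
(per-type node-id registries, per-relation edge lists, optional per-type
feature matrices).  Edges are stored undirected with a canonical orientation:
endpoint types sorted lexicographically, and for same-type relations the
smaller node index first — which makes duplicate detection well defined.

Split construction for the target relation lives here too, because the
anti-leakage contract (validation/test edges never visible to training) is a
property of the data layer, not of any model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Node types of the biological fixture network.
BIO_NODE_TYPES = (
    "miRNA",
    "disease",
    "mRNA",
    "lncRNA",
    "circRNA",
    "protein",
    "drug",
    "microbe",
)

#: Undirected relations of the biological fixture network (17 relations:
#: the association-source table plus the miRNA-disease target relation and
#: the miRNA-circRNA relation required by the metapath catalogue).
BIO_RELATIONS = {
    "miRNA-disease": ("disease", "miRNA"),
    "miRNA-mRNA": ("mRNA", "miRNA"),
    "miRNA-drug": ("drug", "miRNA"),
    "miRNA-circRNA": ("circRNA", "miRNA"),
    "miRNA-lncRNA": ("lncRNA", "miRNA"),
    "miRNA-protein": ("miRNA", "protein"),
    "disease-mRNA": ("disease", "mRNA"),
    "disease-drug": ("disease", "drug"),
    "disease-circRNA": ("circRNA", "disease"),
    "disease-lncRNA": ("disease", "lncRNA"),
    "disease-microbe": ("disease", "microbe"),
    "drug-microbe": ("drug", "microbe"),
    "drug-mRNA": ("drug", "mRNA"),
    "drug-protein": ("drug", "protein"),
    "lncRNA-mRNA": ("lncRNA", "mRNA"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "mRNA-protein": ("mRNA", "protein"),
}

#: Name of the target relation whose links are predicted.
TARGET_RELATION = "miRNA-disease"


class SchemaViolation(ValueError):
    """A row or edge refers to a type/relation not present in the schema."""


class ParseError(ValueError):
    """A TSV row could not be parsed."""


class CapacityError(ValueError):
    """Not enough non-edges to sample the requested number of negatives."""


@dataclass(frozen=True)
class GraphSchema:
    """Node-type set and labelled undirected relation set.

    ``relations`` maps a relation label to its (canonically sorted) pair of
    endpoint types.
    """

    node_types: frozenset[str]
    relations: dict[str, tuple[str, str]]

    def __post_init__(self):
        fixed = {}
        for name, (a, b) in self.relations.items():
            if a not in self.node_types or b not in self.node_types:
                raise SchemaViolation(
                    f"relation {name!r} endpoint types {(a, b)} not in node types"
                )
            fixed[name] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "relations", fixed)

    def relations_between(self, a: str, b: str) -> list[str]:
        """Relation labels whose endpoint pair is {a, b}."""
        key = (a, b) if a <= b else (b, a)
        return sorted(n for n, pair in self.relations.items() if pair == key)

    def relations_touching(self, t: str) -> list[str]:
        return sorted(n for n, (a, b) in self.relations.items() if t in (a, b))

    def other_endpoint(self, relation: str, t: str) -> str:
        a, b = self.relations[relation]
        if t == a:
            return b
        if t == b:
            return a
        raise SchemaViolation(f"type {t!r} is not an endpoint of relation {relation!r}")


def bio_schema() -> GraphSchema:
    """The 8-type / 17-relation biological fixture schema."""
    return GraphSchema(frozenset(BIO_NODE_TYPES), dict(BIO_RELATIONS))


class HeteroGraph:
    """Typed node registries plus per-relation undirected edge lists.

    Node ids are opaque strings mapped to contiguous per-type indices in
    registration order.  Edges are pairs of per-type indices stored in the
    canonical orientation of their relation.
    """

    def __init__(self, schema: GraphSchema):
        self.schema = schema
        self.nodes: dict[str, list[str]] = {t: [] for t in sorted(schema.node_types)}
        self._index: dict[str, dict[str, int]] = {t: {} for t in schema.node_types}
        self.edges: dict[str, set[tuple[int, int]]] = {r: set() for r in schema.relations}
        self.features: dict[str, np.ndarray] = {}
        self._adj_cache: dict[tuple[str, str], dict[int, list[int]]] | None = None

    # -- nodes ----------------------------------------------------------
    def add_node(self, node_type: str, node_id: str) -> int:
        if node_type not in self.schema.node_types:
            raise SchemaViolation(f"unknown node type {node_type!r}")
        idx = self._index[node_type].get(node_id)
        if idx is None:
            idx = len(self.nodes[node_type])
            self.nodes[node_type].append(node_id)
            self._index[node_type][node_id] = idx
            self._adj_cache = None
        return idx

    def node_index(self, node_type: str, node_id: str) -> int:
        try:
            return self._index[node_type][node_id]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r} of type {node_type!r}") from None

    def num_nodes(self, node_type: str) -> int:
        return len(self.nodes[node_type])

    def set_features(self, node_type: str, mat: np.ndarray) -> None:
        mat = np.asarray(mat, dtype=np.float64)
        if mat.shape[0] != self.num_nodes(node_type):
            raise ValueError(
                f"feature matrix for {node_type!r} has {mat.shape[0]} rows, "
                f"expected {self.num_nodes(node_type)}"
            )
        self.features[node_type] = mat

    # -- edges ----------------------------------------------------------
    def canonical_edge(self, relation: str, src_type: str, src: int, dst_type: str, dst: int):
        a, b = self.schema.relations[relation]
        if (src_type, dst_type) == (a, b):
            u, v = src, dst
        elif (src_type, dst_type) == (b, a):
            u, v = dst, src
        else:
            raise SchemaViolation(
                f"edge types {(src_type, dst_type)} do not match relation {relation!r}"
            )
        if a == b and u > v:
            u, v = v, u
        return u, v

    def add_edge(self, relation: str, src_type: str, src_id: str, dst_type: str, dst_id: str) -> bool:
        """Register the edge; returns False when it was a duplicate."""
        if relation not in self.schema.relations:
            raise SchemaViolation(f"unknown relation {relation!r}")
        si = self.add_node(src_type, src_id)
        di = self.add_node(dst_type, dst_id)
        if src_type == dst_type and src_id == dst_id:
            raise SchemaViolation(f"self-loop on {src_type}:{src_id} is not allowed")
        edge = self.canonical_edge(relation, src_type, si, dst_type, di)
        if edge in self.edges[relation]:
            return False
        self.edges[relation].add(edge)
        self._adj_cache = None
        return True

    def has_edge(self, relation: str, src_type: str, src: int, dst_type: str, dst: int) -> bool:
        return self.canonical_edge(relation, src_type, src, dst_type, dst) in self.edges[relation]

    def num_edges(self, relation: str | None = None) -> int:
        if relation is not None:
            return len(self.edges[relation])
        return sum(len(e) for e in self.edges.values())

    # -- adjacency ------------------------------------------------------
    def _adjacency(self) -> dict[tuple[str, str], dict[int, list[int]]]:
        """adjacency[(relation, from_type)][node_idx] -> sorted neighbor indices."""
        if self._adj_cache is not None:
            return self._adj_cache
        adj: dict[tuple[str, str], dict[int, list[int]]] = {}
        for rel, (a, b) in self.schema.relations.items():
            fwd: dict[int, list[int]] = {}
            rev: dict[int, list[int]] = {}
            for u, v in self.edges[rel]:
                fwd.setdefault(u, []).append(v)
                rev.setdefault(v, []).append(u)
                if a == b:
                    fwd.setdefault(v, []).append(u)
                    rev.setdefault(u, []).append(v)
            for d in (fwd, rev):
                for k in d:
                    d[k].sort()
            adj[(rel, a)] = fwd
            adj[(rel, b)] = fwd if a == b else rev
        self._adj_cache = adj
        return adj

    def neighbors(self, relation: str, node_type: str, node: int) -> list[int]:
        """Neighbor indices of ``node`` (of ``node_type``) under ``relation``."""
        a, b = self.schema.relations[relation]
        if node_type not in (a, b):
            raise SchemaViolation(
                f"type {node_type!r} is not an endpoint of relation {relation!r}"
            )
        return self._adjacency()[(relation, node_type)].get(node, [])

    # -- validation and copies ------------------------------------------
    def validate(self) -> None:
        for rel, edge_set in self.edges.items():
            a, b = self.schema.relations[rel]
            na, nb = self.num_nodes(a), self.num_nodes(b)
            for u, v in edge_set:
                if not (0 <= u < na and 0 <= v < nb):
                    raise SchemaViolation(f"edge ({u},{v}) of {rel!r} out of range")
                if a == b and u == v:
                    raise SchemaViolation(f"self-loop ({u},{v}) in relation {rel!r}")

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph(self.schema)
        g.nodes = {t: list(ids) for t, ids in self.nodes.items()}
        g._index = {t: dict(m) for t, m in self._index.items()}
        g.edges = {r: set(e) for r, e in self.edges.items()}
        g.features = {t: m.copy() for t, m in self.features.items()}
        return g

    def edge_rows(self):
        """Canonicalized rows (src_type, src_id, relation, dst_type, dst_id)."""
        rows = []
        for rel in sorted(self.edges):
            a, b = self.schema.relations[rel]
            for u, v in sorted(self.edges[rel]):
                rows.append((a, self.nodes[a][u], rel, b, self.nodes[b][v]))
        return rows


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def load_edges(edge_files, schema: GraphSchema) -> HeteroGraph:
    """Read edge TSVs (``src_type  src_id  relation  dst_type  dst_id``).

    Unknown node ids are registered on first sight; duplicate undirected rows
    are collapsed with a logged count.  Lines beginning with ``#`` are
    comments.
    """
    graph = HeteroGraph(schema)
    duplicates = 0
    for path in edge_files:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ParseError(
                        f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                    )
                src_type, src_id, rel, dst_type, dst_id = parts
                if src_type not in schema.node_types:
                    raise SchemaViolation(f"{path}:{lineno}: unknown node type {src_type!r}")
                if dst_type not in schema.node_types:
                    raise SchemaViolation(f"{path}:{lineno}: unknown node type {dst_type!r}")
                if rel not in schema.relations:
                    raise SchemaViolation(f"{path}:{lineno}: unknown relation {rel!r}")
                if not graph.add_edge(rel, src_type, src_id, dst_type, dst_id):
                    duplicates += 1
    if duplicates:
        logger.warning("collapsed %d duplicate edge rows", duplicates)
    graph.duplicate_rows = duplicates
    return graph


def write_edges(graph: HeteroGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# src_type\tsrc_id\trelation\tdst_type\tdst_id\n")
        for row in graph.edge_rows():
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class EdgeSplit:
    """Train/valid/test positives and 1:1 negatives over the target relation.

    All pairs are (miRNA index, disease index) tuples.
    """

    train_pos: list[tuple[int, int]]
    valid_pos: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]
    valid_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    seed: int
    relation: str = TARGET_RELATION

    def positives(self):
        return self.train_pos + self.valid_pos + self.test_pos

    def negatives(self):
        return self.train_neg + self.valid_neg + self.test_neg

    def pairs(self, part: str):
        pos = getattr(self, f"{part}_pos")
        neg = getattr(self, f"{part}_neg")
        return pos + neg, np.array([1] * len(pos) + [0] * len(neg))


def _target_pairs(graph: HeteroGraph, relation: str) -> list[tuple[int, int]]:
    """Target-relation edges as (miRNA idx, disease idx), sorted."""
    a, b = graph.schema.relations[relation]  # canonical = (disease, miRNA)
    out = []
    for u, v in graph.edges[relation]:
        if a == "miRNA":
            out.append((u, v))
        else:
            out.append((v, u))
    return sorted(out)


def make_splits(
    graph: HeteroGraph,
    ratios: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
    relation: str = TARGET_RELATION,
) -> EdgeSplit:
    """Partition target-relation positives and sample 1:1 negatives.

    Counts are floor-partitioned with the remainder assigned to train;
    negatives are drawn uniformly without replacement from non-edge
    miRNA x disease pairs and are disjoint across splits.  Deterministic
    given ``seed``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    positives = _target_pairs(graph, relation)
    if not positives:
        raise ValueError(f"target relation {relation!r} has no edges")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    n = len(positives)
    n_valid = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_valid - n_test
    shuffled = [positives[i] for i in order]
    train_pos = sorted(shuffled[:n_train])
    valid_pos = sorted(shuffled[n_train : n_train + n_valid])
    test_pos = sorted(shuffled[n_train + n_valid :])

    n_mirna = graph.num_nodes("miRNA")
    n_disease = graph.num_nodes("disease")
    pos_set = set(positives)
    non_edges = [
        (m, d)
        for m in range(n_mirna)
        for d in range(n_disease)
        if (m, d) not in pos_set
    ]
    if len(non_edges) < n:
        raise CapacityError(
            f"need {n} negatives but only {len(non_edges)} non-edges exist"
        )
    chosen = rng.choice(len(non_edges), size=n, replace=False)
    negatives = [non_edges[i] for i in chosen]
    return EdgeSplit(
        train_pos=train_pos,
        valid_pos=valid_pos,
        test_pos=test_pos,
        train_neg=sorted(negatives[:n_train]),
        valid_neg=sorted(negatives[n_train : n_train + n_valid]),
        test_neg=sorted(negatives[n_train + n_valid :]),
        seed=seed,
        relation=relation,
    )


def resplit_train_valid(split: EdgeSplit, seed: int) -> EdgeSplit:
    """Re-shuffle train/valid membership while keeping the test set fixed.

    Used by the multi-seed protocol: each run sees a different train/valid
    partition but the identical held-out test set.
    """
    rng = np.random.default_rng(seed)

    def repartition(a, b):
        pool = a + b
        order = rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        return sorted(shuffled[: len(a)]), sorted(shuffled[len(a) :])

    train_pos, valid_pos = repartition(split.train_pos, split.valid_pos)
    train_neg, valid_neg = repartition(split.train_neg, split.valid_neg)
    return EdgeSplit(
        train_pos=train_pos,
        valid_pos=valid_pos,
        test_pos=list(split.test_pos),
        train_neg=train_neg,
        valid_neg=valid_neg,
        test_neg=list(split.test_neg),
        seed=seed,
        relation=split.relation,
    )


def build_training_graph(graph: HeteroGraph, split: EdgeSplit) -> HeteroGraph:
    """Copy of ``graph`` whose target relation holds exactly the train positives.

    Validation and test positives are removed before any model (or metapath
    materialization) ever sees the graph; every other relation is untouched.
    """
    g = graph.copy()
    a, _ = g.schema.relations[split.relation]
    edges = set()
    for m, d in split.train_pos:
        edges.add((d, m) if a == "disease" else (m, d))
    g.edges[split.relation] = edges
    g._adj_cache = None
    return g


# ---------------------------------------------------------------------------
# split TSV I/O
# ---------------------------------------------------------------------------

def write_splits(split: EdgeSplit, graph: HeteroGraph, path) -> None:
    """Persist as ``split  label  miRNA_id  disease_id`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# split\tlabel\tmiRNA_id\tdisease_id\n")
        for part in ("train", "valid", "test"):
            for label, pairs in ((1, getattr(split, f"{part}_pos")), (0, getattr(split, f"{part}_neg"))):
                for m, d in pairs:
                    fh.write(
                        f"{part}\t{label}\t{graph.nodes['miRNA'][m]}\t{graph.nodes['disease'][d]}\n"
                    )


def read_splits(graph: HeteroGraph, path, seed: int = 0) -> EdgeSplit:
    parts: dict[tuple[str, int], list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            part, label, mid, did = fields
            pair = (graph.node_index("miRNA", mid), graph.node_index("disease", did))
            parts.setdefault((part, int(label)), []).append(pair)
    return EdgeSplit(
        train_pos=sorted(parts.get(("train", 1), [])),
        valid_pos=sorted(parts.get(("valid", 1), [])),
        test_pos=sorted(parts.get(("test", 1), [])),
        train_neg=sorted(parts.get(("train", 0), [])),
        valid_neg=sorted(parts.get(("valid", 0), [])),
        test_neg=sorted(parts.get(("test", 0), [])),
        seed=seed,
    )
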