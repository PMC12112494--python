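"""Metapath type enumeration and node-level instance materialization.

Two catalogues are produced from a schema:

* node-specific types — length-2 paths ``A-X-A`` anchored at the miRNA or
  disease type, capturing homogeneous-neighbor semantics;
* common types — miRNA-to-disease paths of length 2 or 3 whose intermediate
  types exclude miRNA and disease, plus the alternating
  ``miRNA-disease-miRNA-disease`` pattern (shared-association structure on
  the bipartite target graph).

Instances are concrete node-index paths over the *training* graph only.
When instances are served for a candidate pair, any instance that traverses
the candidate edge itself is dropped (target-edge exclusion) and an empty
class falls back to the degenerate instance made of the pair (or anchor)
itself, so every class always contributes exactly one vector downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .schema import GraphSchema, HeteroGraph

ANCHOR_TYPES = ("miRNA", "disease")


@dataclass(frozen=True)
class MetaPathType:
    """A node-type sequence joined by a relation sequence."""

    node_types: tuple[str, ...]
    relations: tuple[str, ...]
    category: str  # "node_specific" | "common"

    def __post_init__(self):
        if len(self.relations) != len(self.node_types) - 1:
            raise ValueError("relation sequence length must be node sequence length - 1")
        if self.category not in ("node_specific", "common"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def name(self) -> str:
        return "-".join(self.node_types)

    @property
    def length(self) -> int:
        return len(self.relations)

    def validate_against(self, schema: GraphSchema) -> None:
        for (a, b), rel in zip(zip(self.node_types, self.node_types[1:]), self.relations):
            if rel not in schema.relations:
                raise ValueError(f"relation {rel!r} not in schema")
            pair = (a, b) if a <= b else (b, a)
            if schema.relations[rel] != pair:
                raise ValueError(
                    f"relation {rel!r} does not join types {a!r} and {b!r}"
                )

    def seed_key(self) -> int:
        return zlib.crc32("|".join(self.node_types + self.relations).encode())


def enumerate_node_specific_types(schema: GraphSchema) -> set[MetaPathType]:
    """All length-2 type paths ``A-X-A`` with A in {miRNA, disease}."""
    out: set[MetaPathType] = set()
    for anchor in ANCHOR_TYPES:
        if anchor not in schema.node_types:
            raise ValueError(f"anchor type {anchor!r} missing from schema")
        for rel in schema.relations_touching(anchor):
            x = schema.other_endpoint(rel, anchor)
            out.add(MetaPathType((anchor, x, anchor), (rel, rel), "node_specific"))
    return out


def enumerate_common_types(schema: GraphSchema, max_len: int = 3) -> set[MetaPathType]:
    """miRNA-to-disease type paths with non-anchor intermediates, plus the
    alternating miRNA-disease-miRNA-disease pattern when a target relation
    exists."""
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    for anchor in ANCHOR_TYPES:
        if anchor not in schema.node_types:
            raise ValueError(f"anchor type {anchor!r} missing from schema")
    out: set[MetaPathType] = set()

    def extend(types: tuple[str, ...], rels: tuple[str, ...]):
        cur = types[-1]
        if len(rels) >= 1:
            for rel in schema.relations_between(cur, "disease"):
                out.add(MetaPathType(types + ("disease",), rels + (rel,), "common"))
        if len(rels) + 1 >= max_len:
            return
        for rel in schema.relations_touching(cur):
            nxt = schema.other_endpoint(rel, cur)
            if nxt in ANCHOR_TYPES:
                continue
            extend(types + (nxt,), rels + (rel,))

    for rel in schema.relations_touching("miRNA"):
        x = schema.other_endpoint(rel, "miRNA")
        if x in ANCHOR_TYPES:
            continue
        extend(("miRNA", x), (rel,))

    for rel in schema.relations_between("miRNA", "disease"):
        out.add(
            MetaPathType(
                ("miRNA", "disease", "miRNA", "disease"),
                (rel, rel, rel),
                "common",
            )
        )
    return out


# ---------------------------------------------------------------------------
# instances
# ---------------------------------------------------------------------------

#: An instance is a tuple of per-type node indices following its type sequence.
MetaPathInstance = tuple[int, ...]


@dataclass
class InstanceStore:
    """Mapping (anchor, metapath type) -> capped instance list.

    Node-specific entries are keyed by the anchor's per-type index; common
    entries by the (miRNA index, disease index) pair.
    """

    cap: int
    seed: int
    data: dict[tuple[object, MetaPathType], list[MetaPathInstance]]

    def get(self, key, mptype: MetaPathType) -> list[MetaPathInstance]:
        return self.data.get((key, mptype), [])


def _walk(graph: HeteroGraph, mptype: MetaPathType, start: int) -> list[MetaPathInstance]:
    """Exhaustive node-simple DFS from ``start`` along the type sequence."""
    types, rels = mptype.node_types, mptype.relations
    results: list[MetaPathInstance] = []
    path = [start]
    visited = {(types[0], start)}

    def recurse(depth: int):
        if depth == len(rels):
            results.append(tuple(path))
            return
        cur_type = types[depth]
        for nxt in graph.neighbors(rels[depth], cur_type, path[-1]):
            key = (types[depth + 1], nxt)
            if key in visited:
                continue
            visited.add(key)
            path.append(nxt)
            recurse(depth + 1)
            path.pop()
            visited.discard(key)

    recurse(0)
    return results


def _subsample(
    instances: list[MetaPathInstance],
    cap: int,
    seed: int,
    mptype: MetaPathType,
    key_ints: Sequence[int],
) -> list[MetaPathInstance]:
    if cap <= 0 or len(instances) <= cap:
        return instances
    instances = sorted(instances)
    rng = np.random.default_rng([seed, mptype.seed_key(), *key_ints])
    idx = rng.choice(len(instances), size=cap, replace=False)
    return [instances[i] for i in sorted(idx)]


def materialize_instances(
    graph: HeteroGraph,
    mptype: MetaPathType,
    anchors: Iterable,
    cap: int = 32,
    seed: int = 0,
) -> dict[tuple[object, MetaPathType], list[MetaPathInstance]]:
    """Depth-first expansion of ``mptype`` over the training graph.

    ``anchors`` is a set of per-type node indices (node-specific types) or
    of (miRNA idx, disease idx) pairs (common types).  Per-key lists longer
    than ``cap`` are uniformly subsampled under a key-stable seeded RNG, so
    results do not depend on anchor iteration order.
    """
    mptype.validate_against(graph.schema)
    entries: dict[tuple[object, MetaPathType], list[MetaPathInstance]] = {}
    if mptype.category == "node_specific":
        for anchor in sorted(anchors):
            found = _walk(graph, mptype, anchor)
            entries[(anchor, mptype)] = _subsample(found, cap, seed, mptype, (anchor,))
    else:
        pair_set = set(anchors)
        by_start: dict[int, list[int]] = {}
        for m, d in pair_set:
            by_start.setdefault(m, []).append(d)
        for m in sorted(by_start):
            wanted = set(by_start[m])
            grouped: dict[int, list[MetaPathInstance]] = {d: [] for d in wanted}
            for inst in _walk(graph, mptype, m):
                if inst[-1] in wanted:
                    grouped[inst[-1]].append(inst)
            for d in sorted(wanted):
                entries[((m, d), mptype)] = _subsample(
                    grouped[d], cap, seed, mptype, (m, d)
                )
    return entries


def build_store(
    graph: HeteroGraph,
    node_types_catalog: Iterable[MetaPathType],
    common_types_catalog: Iterable[MetaPathType],
    pairs: Iterable[tuple[int, int]],
    cap: int = 32,
    seed: int = 0,
) -> InstanceStore:
    """Materialize every catalogue entry over the training graph.

    Node-specific types are materialized for *all* nodes of their anchor
    type; common types for the supplied candidate pairs.
    """
    data: dict[tuple[object, MetaPathType], list[MetaPathInstance]] = {}
    for mptype in sorted(node_types_catalog, key=lambda t: t.name):
        anchor_type = mptype.node_types[0]
        anchors = range(graph.num_nodes(anchor_type))
        data.update(materialize_instances(graph, mptype, anchors, cap=cap, seed=seed))
    pairs = sorted(set(pairs))
    for mptype in sorted(common_types_catalog, key=lambda t: t.name):
        data.update(materialize_instances(graph, mptype, pairs, cap=cap, seed=seed))
    return InstanceStore(cap=cap, seed=seed, data=data)


def _traverses_target_edge(
    inst: MetaPathInstance, mptype: MetaPathType, u: int, v: int
) -> bool:
    """True when a consecutive step of ``inst`` is the edge (u, v) itself."""
    types = mptype.node_types
    for i in range(len(inst) - 1):
        a, b = types[i], types[i + 1]
        if (a, b) == ("miRNA", "disease") and inst[i] == u and inst[i + 1] == v:
            return True
        if (a, b) == ("disease", "miRNA") and inst[i] == v and inst[i + 1] == u:
            return True
    return False


def pair_instances(
    store: InstanceStore, u: int, v: int, mptype: MetaPathType
) -> list[MetaPathInstance]:
    """Instances for candidate pair (u, v) with target-edge exclusion.

    Any stored instance that steps across the (u, v) edge itself is removed;
    if nothing survives, the degenerate fallback instance ``(u, v)`` is
    returned so the class still contributes.
    """
    if mptype.category != "common":
        raise ValueError("pair_instances requires a common metapath type")
    kept = [
        inst
        for inst in store.get((u, v), mptype)
        if not _traverses_target_edge(inst, mptype, u, v)
    ]
    if not kept:
        return [(u, v)]
    return kept


def anchor_instances(store: InstanceStore, v: int, mptype: MetaPathType) -> list[MetaPathInstance]:
    """Node-specific instances for anchor ``v``; falls back to ``(v,)``."""
    if mptype.category != "node_specific":
        raise ValueError("anchor_instances requires a node-specific metapath type")
    found = store.get(v, mptype)
    if not found:
        return [(v,)]
    return found


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def catalogue_to_json(types: Iterable[MetaPathType]) -> list[dict]:
    return [
        {
            "name": t.name,
            "node_types": list(t.node_types),
            "relations": list(t.relations),
            "category": t.category,
        }
        for t in sorted(types, key=lambda t: (t.category, t.name))
    ]


def write_store(store: InstanceStore, graph: HeteroGraph, path) -> None:
    """Persist as ``anchor(s)  metapath_name  node_id_1 ... node_id_k``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# anchor\tmetapath\tnodes...\n")
        for (key, mptype), instances in sorted(
            store.data.items(), key=lambda kv: (kv[0][1].name, str(kv[0][0]))
        ):
            if mptype.category == "node_specific":
                anchor_repr = graph.nodes[mptype.node_types[0]][key]
            else:
                m, d = key
                anchor_repr = f"{graph.nodes['miRNA'][m]},{graph.nodes['disease'][d]}"
            for inst in instances:
                ids = [
                    graph.nodes[t][i] for t, i in zip(mptype.node_types, inst)
                ]
                fh.write(f"{anchor_repr}\t{mptype.name}\t" + "\t".join(ids) + "\n")

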