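"""Metapath type enumeration and instance materialization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_instances
from hetpath.metapath import (
    MetaPathType,
    anchor_instances,
    build_store,
    enumerate_common_types,
    enumerate_node_specific_types,
    materialize_instances,
    pair_instances,
)
from hetpath.schema import GraphSchema, HeteroGraph

# Published catalogue for the biological schema
NODE_SPECIFIC_NAMES = {
    "miRNA-mRNA-miRNA",
    "miRNA-drug-miRNA",
    "miRNA-circRNA-miRNA",
    "miRNA-lncRNA-miRNA",
    "miRNA-protein-miRNA",
    "miRNA-disease-miRNA",
    "disease-mRNA-disease",
    "disease-drug-disease",
    "disease-circRNA-disease",
    "disease-lncRNA-disease",
    "disease-microbe-disease",
    "disease-miRNA-disease",
}
COMMON_NAMES = {
    "miRNA-drug-disease",
    "miRNA-mRNA-disease",
    "miRNA-lncRNA-disease",
    "miRNA-circRNA-disease",
    "miRNA-disease-miRNA-disease",
    "miRNA-drug-mRNA-disease",
    "miRNA-drug-microbe-disease",
    "miRNA-mRNA-drug-disease",
    "miRNA-mRNA-lncRNA-disease",
    "miRNA-protein-drug-disease",
    "miRNA-protein-mRNA-disease",
    "miRNA-protein-lncRNA-disease",
    "miRNA-lncRNA-mRNA-disease",
}


class TestEnumeration:
    def test_bio_node_specific_catalogue(self, schema):
        types = enumerate_node_specific_types(schema)
        assert {t.name for t in types} == NODE_SPECIFIC_NAMES
        assert len(types) == 12

    def test_bio_common_catalogue(self, schema):
        types = enumerate_common_types(schema)
        assert {t.name for t in types} == COMMON_NAMES
        assert len(types) == 13

    def test_toy_schema_node_specific(self, toy_schema):
        names = {t.name for t in enumerate_node_specific_types(toy_schema)}
        assert names == {
            "miRNA-X-miRNA",
            "miRNA-disease-miRNA",
            "disease-X-disease",
            "disease-miRNA-disease",
        }

    def test_toy_schema_common(self, toy_schema):
        names = {t.name for t in enumerate_common_types(toy_schema)}
        assert names == {"miRNA-X-disease", "miRNA-disease-miRNA-disease"}

    def test_toy_schema_without_target_relation(self):
        schema = GraphSchema(
            frozenset({"miRNA", "disease", "X"}),
            {"miRNA-X": ("miRNA", "X"), "disease-X": ("X", "disease")},
        )
        names = {t.name for t in enumerate_common_types(schema)}
        assert names == {"miRNA-X-disease"}

    def test_no_anchor_edges_gives_empty_node_specific(self):
        schema = GraphSchema(
            frozenset({"miRNA", "disease", "X", "Y"}), {"XY": ("X", "Y")}
        )
        assert enumerate_node_specific_types(schema) == set()

    def test_missing_anchor_type_errors(self):
        schema = GraphSchema(frozenset({"X", "Y"}), {"XY": ("X", "Y")})
        with pytest.raises(ValueError):
            enumerate_node_specific_types(schema)

    def test_max_len_below_two_errors(self, schema):
        with pytest.raises(ValueError):
            enumerate_common_types(schema, max_len=1)


# -- brute-force oracle over the type graph ---------------------------------

def oracle_node_specific(schema):
    out = set()
    for anchor in ("miRNA", "disease"):
        for rel, (a, b) in schema.relations.items():
            if anchor == a:
                out.add(((anchor, b, anchor), (rel, rel)))
            if anchor == b:
                out.add(((anchor, a, anchor), (rel, rel)))
    return out


def oracle_common(schema):
    """Exhaustive DFS over the type graph, then the stated filters."""
    adj = []
    for rel, (a, b) in schema.relations.items():
        adj.append((a, b, rel))
        adj.append((b, a, rel))
    out = set()

    def dfs(types, rels):
        if len(rels) in (2, 3) and types[-1] == "disease":
            if all(t not in ("miRNA", "disease") for t in types[1:-1]):
                out.add((tuple(types), tuple(rels)))
        if len(rels) >= 3:
            return
        for a, b, rel in adj:
            if a == types[-1]:
                dfs(types + [b], rels + [rel])

    dfs(["miRNA"], [])
    for rel, pair in schema.relations.items():
        if set(pair) == {"miRNA", "disease"}:
            out.add((("miRNA", "disease", "miRNA", "disease"), (rel, rel, rel)))
    return out


@st.composite
def random_schemas(draw):
    extra = draw(st.integers(0, 6))
    types = ["miRNA", "disease"] + [f"T{i}" for i in range(extra)]
    pairs = [(a, b) for i, a in enumerate(types) for b in types[i:] if (a, b) != (b, a) or a != b]
    pairs = [(a, b) for i, a in enumerate(types) for b in types[i + 1 :]]
    chosen = draw(st.lists(st.sampled_from(pairs), unique=True, max_size=12)) if pairs else []
    relations = {f"{a}--{b}": (a, b) for a, b in chosen}
    return GraphSchema(frozenset(types), relations)


@given(random_schemas())
@settings(max_examples=60, deadline=None)
def test_enumeration_matches_brute_force(schema):
    got_ns = {(t.node_types, t.relations) for t in enumerate_node_specific_types(schema)}
    assert got_ns == oracle_node_specific(schema)
    got_co = {(t.node_types, t.relations) for t in enumerate_common_types(schema)}
    assert got_co == oracle_common(schema)


# -- instance materialization ------------------------------------------------

def _toy_graph(toy_schema):
    g = HeteroGraph(toy_schema)
    for nid in ("m1", "m2", "m3"):
        g.add_node("miRNA", nid)
    for nid in ("d1", "d2"):
        g.add_node("disease", nid)
    for nid in ("x1", "x2"):
        g.add_node("X", nid)
    g.add_edge("miRNA-X", "miRNA", "m1", "X", "x1")
    g.add_edge("miRNA-X", "miRNA", "m2", "X", "x1")
    g.add_edge("miRNA-X", "miRNA", "m3", "X", "x2")
    g.add_edge("disease-X", "X", "x1", "disease", "d1")
    g.add_edge("disease-X", "X", "x2", "disease", "d2")
    g.add_edge("miRNA-disease", "miRNA", "m1", "disease", "d1")
    g.add_edge("miRNA-disease", "miRNA", "m2", "disease", "d1")
    return g


MXM = MetaPathType(("miRNA", "X", "miRNA"), ("miRNA-X", "miRNA-X"), "node_specific")
MXD = MetaPathType(("miRNA", "X", "disease"), ("miRNA-X", "disease-X"), "common")
MDMD = MetaPathType(
    ("miRNA", "disease", "miRNA", "disease"),
    ("miRNA-disease",) * 3,
    "common",
)


class TestMaterialize:
    def test_exhaustive_traversal(self, toy_schema):
        g = _toy_graph(toy_schema)
        entries = materialize_instances(g, MXM, anchors={0}, cap=0)
        assert entries[(0, MXM)] == [(0, 0, 1)]  # m1-x1-m2

    def test_empty_for_isolated_anchor(self, toy_schema):
        g = _toy_graph(toy_schema)
        entries = materialize_instances(g, MXM, anchors={2}, cap=0)
        # m3-x2 has no second miRNA
        assert entries[(2, MXM)] == []

    def test_cap_subsample_deterministic(self, toy_schema):
        g = HeteroGraph(toy_schema)
        for i in range(6):
            g.add_node("miRNA", f"m{i}")
        g.add_node("X", "x0")
        for i in range(6):
            g.add_edge("miRNA-X", "miRNA", f"m{i}", "X", "x0")
        a = materialize_instances(g, MXM, anchors={0}, cap=2, seed=9)[(0, MXM)]
        b = materialize_instances(g, MXM, anchors={0}, cap=2, seed=9)[(0, MXM)]
        assert a == b
        assert len(a) == 2
        full = materialize_instances(g, MXM, anchors={0}, cap=0)[(0, MXM)]
        assert len(full) == 5
        assert set(a) <= set(full)

    def test_invalid_type_for_schema_errors(self, toy_schema):
        g = _toy_graph(toy_schema)
        bad = MetaPathType(("miRNA", "Y", "miRNA"), ("r", "r"), "node_specific")
        with pytest.raises(ValueError):
            materialize_instances(g, bad, anchors={0})

    def test_instances_validate_against_graph(self, small_graph):
        graph, _ = small_graph
        schema = graph.schema
        for mptype in sorted(
            enumerate_node_specific_types(schema) | enumerate_common_types(schema),
            key=lambda t: t.name,
        )[:6]:
            if mptype.category == "node_specific":
                anchors = range(graph.num_nodes(mptype.node_types[0]))
                entries = materialize_instances(graph, mptype, anchors, cap=4, seed=0)
            else:
                pairs = [(m, d) for m in range(4) for d in range(4)]
                entries = materialize_instances(graph, mptype, pairs, cap=4, seed=0)
            for (_, t), instances in entries.items():
                for inst in instances:
                    for i, rel in enumerate(t.relations):
                        a = graph.neighbors(rel, t.node_types[i], inst[i])
                        assert inst[i + 1] in a

    def test_matches_brute_force_enumeration(self, small_graph):
        graph, _ = small_graph
        mptype = sorted(enumerate_common_types(graph.schema), key=lambda t: t.name)[0]
        pairs = [(m, d) for m in range(3) for d in range(3)]
        entries = materialize_instances(graph, mptype, pairs, cap=0)
        for m in range(3):
            oracle = brute_force_instances(graph, mptype, m)
            for d in range(3):
                expected = {p for p in oracle if p[-1] == d}
                assert set(entries[((m, d), mptype)]) == expected

    def test_monotonicity_under_edge_addition(self, toy_schema):
        g = _toy_graph(toy_schema)
        before = len(materialize_instances(g, MXD, anchors={(0, 1)}, cap=0)[((0, 1), MXD)])
        g.add_edge("disease-X", "X", "x1", "disease", "d2")
        after = len(materialize_instances(g, MXD, anchors={(0, 1)}, cap=0)[((0, 1), MXD)])
        assert after >= before


class TestPairInstances:
    def _store(self, g, pairs):
        return build_store(
            g,
            enumerate_node_specific_types(g.schema),
            enumerate_common_types(g.schema),
            pairs,
            cap=0,
            seed=0,
        )

    def test_mediated_paths_returned(self, toy_schema):
        g = _toy_graph(toy_schema)
        g.add_edge("miRNA-X", "miRNA", "m1", "X", "x2")
        store = self._store(g, [(0, 1)])
        got = pair_instances(store, 0, 1, MXD)  # m1 -> x2 -> d2
        assert got == [(0, 1, 1)]

    def test_target_edge_exclusion_then_fallback(self, toy_schema):
        # only alternating path for (m1, d1) would traverse its own edge
        g = HeteroGraph(toy_schema)
        g.add_node("miRNA", "m1")
        g.add_node("disease", "d1")
        g.add_edge("miRNA-disease", "miRNA", "m1", "disease", "d1")
        store = self._store(g, [(0, 0)])
        assert pair_instances(store, 0, 0, MDMD) == [(0, 0)]

    def test_no_connectivity_fallback(self, toy_schema):
        g = _toy_graph(toy_schema)
        store = self._store(g, [(2, 0)])  # m3 only reaches d2
        assert pair_instances(store, 2, 0, MXD) == [(2, 0)]

    def test_served_instances_never_traverse_target_edge(self, toy_schema):
        g = _toy_graph(toy_schema)
        store = self._store(g, [(0, 0), (1, 0)])
        for (m, d) in [(0, 0), (1, 0)]:
            for inst in pair_instances(store, m, d, MDMD):
                if len(inst) < len(MDMD.node_types):
                    continue  # degenerate (u, v) fallback, not a traversal
                for i in range(len(inst) - 1):
                    step_types = MDMD.node_types[i : i + 2]
                    step = (inst[i], inst[i + 1])
                    assert not (
                        step_types == ("miRNA", "disease") and step == (m, d)
                    ) and not (step_types == ("disease", "miRNA") and step == (d, m))

    def test_wrong_category_errors(self, toy_schema):
        g = _toy_graph(toy_schema)
        store = self._store(g, [(0, 0)])
        with pytest.raises(ValueError):
            pair_instances(store, 0, 0, MXM)
        with pytest.raises(ValueError):
            anchor_instances(store, 0, MXD)


class TestAnchorInstances:
    def test_fallback_single_node(self, toy_schema):
        g = _toy_graph(toy_schema)
        store = build_store(g, [MXM], [], [], cap=0, seed=0)
        assert anchor_instances(store, 2, MXM) == [(2,)]

    def test_real_instances_served(self, toy_schema):
        g = _toy_graph(toy_schema)
        store = build_store(g, [MXM], [], [], cap=0, seed=0)
        assert anchor_instances(store, 0, MXM) == [(0, 0, 1)]


def test_store_determinism(small_graph):
    graph, _ = small_graph
    schema = graph.schema
    pairs = [(m, d) for m in range(5) for d in range(5)]
    kwargs = dict(
        node_types_catalog=enumerate_node_specific_types(schema),
        common_types_catalog=enumerate_common_types(schema),
        pairs=pairs,
        cap=8,
        seed=3,
    )
    s1 = build_store(graph, **kwargs)
    s2 = build_store(graph, **kwargs)
    assert s1.data == s2.data
    for (key, t), instances in s1.data.items():
        assert len(instances) <= 8
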