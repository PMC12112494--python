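"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own traversal/aggregation
code paths: instance enumeration scans raw edge sets, and metric oracles are
literal double loops / threshold sweeps.
"""

from __future__ import annotations

import numpy as np
import pytest

from hetpath.schema import GraphSchema, HeteroGraph, bio_schema, make_splits
from hetpath.synthgraph import SynthConfig, generate

SMALL_COUNTS = {
    "miRNA": 30,
    "disease": 30,
    "mRNA": 40,
    "lncRNA": 20,
    "circRNA": 10,
    "protein": 30,
    "drug": 20,
    "microbe": 5,
}

TINY_COUNTS = {
    "miRNA": 6,
    "disease": 6,
    "mRNA": 8,
    "lncRNA": 4,
    "circRNA": 3,
    "protein": 5,
    "drug": 4,
    "microbe": 2,
}


@pytest.fixture(scope="session")
def schema():
    return bio_schema()


@pytest.fixture()
def toy_schema():
    """Three types with relations M-X, X-D and M-D (the spec-style toy)."""
    return GraphSchema(
        frozenset({"miRNA", "disease", "X"}),
        {
            "miRNA-X": ("miRNA", "X"),
            "disease-X": ("X", "disease"),
            "miRNA-disease": ("miRNA", "disease"),
        },
    )


@pytest.fixture(scope="session")
def small_graph():
    """~185-node planted fixture reused by training smoke tests."""
    graph, clusters = generate(SynthConfig(counts=dict(SMALL_COUNTS), seed=7))
    return graph, clusters


@pytest.fixture(scope="session")
def small_split(small_graph):
    graph, _ = small_graph
    return make_splits(graph, seed=7)


@pytest.fixture(scope="session")
def tiny_graph():
    """~38-node fixture for exact forward-pass oracles."""
    graph, clusters = generate(
        SynthConfig(counts=dict(TINY_COUNTS), clusters=2, p_in=0.5, p_out=0.05, seed=3)
    )
    return graph, clusters


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_instances(graph: HeteroGraph, mptype, start: int):
    """All node-simple instances of ``mptype`` from ``start``, found by
    scanning raw edge sets step by step (no adjacency indices)."""
    types, rels = mptype.node_types, mptype.relations
    paths = [(start,)]
    for depth, rel in enumerate(rels):
        a, b = graph.schema.relations[rel]
        t_cur, t_nxt = types[depth], types[depth + 1]
        nxt_paths = []
        for path in paths:
            cur = path[-1]
            for u, v in graph.edges[rel]:
                candidates = []
                if (t_cur, t_nxt) == (a, b) and u == cur:
                    candidates.append(v)
                if (t_cur, t_nxt) == (b, a) and v == cur:
                    candidates.append(u)
                if a == b and t_cur == a:
                    if u == cur:
                        candidates.append(v)
                    if v == cur:
                        candidates.append(u)
                for nxt in candidates:
                    # node-simple: same (type, index) may not repeat
                    if any(
                        types[i] == t_nxt and path[i] == nxt for i in range(len(path))
                    ):
                        continue
                    nxt_paths.append(path + (nxt,))
        paths = nxt_paths
    return set(paths)


def auc_double_loop(scores, labels) -> float:
    """Literal pairwise AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s in pos:
        for t in neg:
            if s > t:
                total += 1.0
            elif s == t:
                total += 0.5
    return total / (len(pos) * len(neg))


def ap_threshold_sweep(scores, labels) -> float:
    """Trapezoidal PR area over the distinct-score thresholds, anchored at
    recall 0 with the highest threshold's precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = int(np.sum(labels == 1))
    points = []
    for th in thresholds:
        pred = scores >= th
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        points.append((tp / n_pos, tp / (tp + fp)))
    points = [(0.0, points[0][1])] + points
    total = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        total += (r1 - r0) * (p0 + p1) / 2.0
    return total
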