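"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from netreg.network_model import GeneSet, Interaction, InteractionNetwork

NODE_CLASSES = ["ligand", "receptor", "kinase", "transcription_factor", "generic"]


@pytest.fixture
def chain_net() -> InteractionNetwork:
    """Five-node all-activating cascade L -> R -> K -> TF -> T."""
    net = InteractionNetwork()
    net.set_node_class("L", "ligand")
    net.set_node_class("R", "receptor")
    net.set_node_class("K", "kinase")
    net.set_node_class("TF", "transcription_factor")
    net.set_node_class("T", "generic")
    net.add_interaction(Interaction("L", "R", "activation", "other"))
    net.add_interaction(Interaction("R", "K", "activation", "other"))
    net.add_interaction(Interaction("K", "TF", "activation", "other"))
    net.add_interaction(
        Interaction("TF", "T", "activation", "transcription_regulation")
    )
    return net


@pytest.fixture
def chain_targets() -> GeneSet:
    return GeneSet("targets", {"T"})


def random_tiny_network(seed: int, max_nodes: int = 12) -> InteractionNetwork:
    """A small random signed network with node classes, for brute-force checks.

    Occasionally emits parallel records between the same ordered pair with a
    different (effect, mechanism) combination, as the data model allows.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    net = InteractionNetwork()
    names = [f"v{i}" for i in range(n)]
    for v in names:
        net.set_node_class(v, NODE_CLASSES[int(rng.integers(len(NODE_CLASSES)))])
    n_edges = int(rng.integers(n, 3 * n))
    for _ in range(n_edges):
        src, tgt = rng.choice(n, size=2, replace=False)
        effect = ["activation", "inhibition", "unspecified"][int(rng.integers(3))]
        mechanism = ["other", "transcription_regulation"][int(rng.integers(2))]
        edge = Interaction(names[src], names[tgt], effect, mechanism)
        try:
            net.add_interaction(edge)
        except ValueError:
            pass  # duplicate record; skip
    return net


# -- independent oracles -------------------------------------------------


def hypergeom_tail_enumeration(r: int, R: int, n: int, N: int) -> float:
    """P(X >= r) by exhaustive enumeration of all C(N, R) draws.

    The population is N items of which the first n are successes; every
    R-subset is equally likely.  Exact rational arithmetic.
    """
    population = [1] * n + [0] * (N - n)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), R):
        total += 1
        if sum(population[i] for i in draw) >= r:
            hits += 1
    if total == 0:
        return 1.0
    return float(Fraction(hits, total))


def build_bipartite_probe_net(seed: int = 7, n_nodes: int = 50, n_edges: int = 120):
    """Random network whose gene set has no internal edges.

    Nodes split into set members (10) and others (40); edges never join two
    set members, so the interactions touching the set are exactly the sum
    of member degrees (symbol n), which makes the analytic statistic agree
    with a draw-R-of-N-interactions resampling null.
    """
    rng = np.random.default_rng(seed)
    members = [f"m{i}" for i in range(10)]
    others = [f"o{i}" for i in range(n_nodes - 10)]
    net = InteractionNetwork()
    for v in members + others:
        net.add_node(v)
    added = 0
    while added < n_edges:
        if rng.random() < 0.12:
            src = members[int(rng.integers(len(members)))]
            tgt = others[int(rng.integers(len(others)))]
        else:
            src = others[int(rng.integers(len(others)))]
            if rng.random() < 0.12:
                tgt = members[int(rng.integers(len(members)))]
            else:
                tgt = others[int(rng.integers(len(others)))]
        if tgt in members and src in members:
            continue
        if src == tgt:
            continue
        effect = "inhibition" if rng.random() < 0.2 else "activation"
        try:
            net.add_interaction(Interaction(src, tgt, effect, "other"))
        except ValueError:
            continue
        added += 1
    return net, GeneSet("members", members)


def permutation_pvalue(net, node, geneset, n_reps=10_000, seed=7):
    """Degree-preserving resampling null: the node's R interactions are a
    uniform draw of R from all N interaction records."""
    edges = net.interactions
    touching = np.array(
        [e.source in geneset or e.target in geneset for e in edges], dtype=int
    )
    R = net.node_degree(node)
    r_obs = net.links_to_set(node, geneset)
    rng = np.random.default_rng(seed)
    draws = rng.random((n_reps, len(edges))).argsort(axis=1)[:, :R]
    counts = touching[draws].sum(axis=1)
    return float((counts >= r_obs).mean())


def brute_force_path_index(
    net: InteractionNetwork,
    targets: set[str],
    parity: str = "even",
    max_len: int = 6,
    exclude_unspecified: bool = False,
):
    """Exhaustive enumerator of admissible shortest paths (forward DFS).

    Generates ALL simple directed edge sequences of length <= max_len from
    every source, filters by (terminal TR-from-TF edge, inhibition parity,
    terminal in targets), then keeps the minimal-length paths per
    (source, target) pair.  Returns the list of node tuples, one per
    admissible shortest path (edge-sequence resolution: parallel records
    yield repeated node tuples).
    """
    want = 0 if parity == "even" else 1
    edges = [
        e
        for e in net.interactions
        if not (exclude_unspecified and e.effect == "unspecified")
    ]
    out: dict[str, list] = {}
    for e in edges:
        out.setdefault(e.source, []).append(e)

    found: dict[tuple[str, str], list[tuple[int, tuple[str, ...]]]] = {}

    def dfs(node, path_nodes, n_inhib, depth):
        for e in out.get(node, ()):
            if e.target in path_nodes:
                continue
            inhib = n_inhib + (1 if e.effect == "inhibition" else 0)
            nodes = path_nodes + (e.target,)
            if (
                e.target in targets
                and e.mechanism == "transcription_regulation"
                and net.node_class.get(e.source) == "transcription_factor"
                and inhib % 2 == want
            ):
                found.setdefault((nodes[0], e.target), []).append((depth + 1, nodes))
            if depth + 1 < max_len:
                dfs(e.target, nodes, inhib, depth + 1)

    for source in net.nodes:
        dfs(source, (source,), 0, 0)

    paths = []
    for (_src, _tgt), candidates in found.items():
        best = min(d for d, _ in candidates)
        paths.extend(nodes for d, nodes in candidates if d == best)
    return paths
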