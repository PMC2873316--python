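"""Connected subnetwork construction with hypergeometric enrichment scoring.

Two builders: per-receptor shortest-path regulatory networks (receptor ->
directly-regulating TFs -> their targets in the list of interest) and
greedy expansion networks grown around a transcription factor to a fixed
node budget.  Both are scored by the tail probability of drawing at least
the observed number of list members in a node sample of the subnetwork's
size from the network's node universe, and sorted ascending.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from collections.abc import Iterable
from pathlib import Path

from .network_model import (
    GeneSet,
    HypergeomParams,
    Interaction,
    InteractionNetwork,
    write_tsv_report,
)
from .overconnectivity import hypergeom_tail

__all__ = [
    "Subnetwork",
    "select_direct_tfs",
    "select_receptors_by_ligand",
    "build_receptor_network",
    "expand_tf_network",
    "enrichment_pvalue",
    "rank_networks",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Subnetwork:
    seed: str
    nodes: frozenset[str]
    edges: tuple[Interaction, ...]
    kind: str  # receptor_series | tf_expansion
    enrichment_p: float = 1.0
    r: int = 0  # list-of-interest members inside

    def __post_init__(self) -> None:
        if self.seed not in self.nodes:
            raise ValueError("subnetwork seed must be among its nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def write_edges(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\teffect\tmechanism\n")
            for e in sorted(
                self.edges, key=lambda e: (e.source, e.target, e.effect, e.mechanism)
            ):
                fh.write(f"{e.source}\t{e.target}\t{e.effect}\t{e.mechanism}\n")


def _induced_edges(net: InteractionNetwork, nodes: set[str]) -> tuple[Interaction, ...]:
    return tuple(
        e for e in net.interactions if e.source in nodes and e.target in nodes
    )


def select_direct_tfs(net: InteractionNetwork, geneset: GeneSet) -> set[str]:
    """TFs with >=1 outgoing transcription_regulation edge into the set."""
    if not len(geneset):
        raise ValueError("gene set of interest is empty")
    tfs = {
        e.source
        for e in net.interactions
        if e.is_tr
        and e.target in geneset
        and net.node_class.get(e.source) == "transcription_factor"
    }
    if not tfs:
        logger.warning("no transcription factor directly regulates the set")
    return tfs


def select_receptors_by_ligand(net: InteractionNetwork, geneset: GeneSet) -> set[str]:
    """Receptors with >=1 incoming edge from a ligand-class set member."""
    if not len(geneset):
        raise ValueError("gene set of interest is empty")
    receptors = {
        e.target
        for e in net.interactions
        if e.source in geneset
        and net.node_class.get(e.source) == "ligand"
        and net.node_class.get(e.target) == "receptor"
    }
    if not receptors:
        logger.warning("no receptor has a ligand in the set")
    return receptors


def _all_shortest_path_nodes(
    net: InteractionNetwork, source: str, sinks: set[str], max_len: int
) -> tuple[dict[str, set[str]], set[tuple[str, str]]]:
    """Nodes and edges on all shortest paths from ``source`` to each sink.

    Standard BFS shortest-path DAG accounting: walking shortest-path
    predecessors back from a sink visits exactly the nodes (and predecessor
    edges) lying on at least one shortest source->sink path.  Returns the
    per-sink node sets and the union of traversed (u, v) edge pairs.
    """
    dist = {source: 0}
    preds: dict[str, set[str]] = {source: set()}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        d = dist[v]
        if d == max_len:
            continue
        for u in sorted(net.successors(v)):
            if u not in dist:
                dist[u] = d + 1
                preds[u] = {v}
                queue.append(u)
            elif dist[u] == d + 1:
                preds[u].add(v)

    result: dict[str, set[str]] = {}
    path_edges: set[tuple[str, str]] = set()
    for sink in sinks:
        if sink not in dist:
            continue
        on_path = {sink}
        frontier = deque([sink])
        while frontier:
            v = frontier.popleft()
            for u in preds[v]:
                path_edges.add((u, v))
                if u not in on_path:
                    on_path.add(u)
                    frontier.append(u)
        result[sink] = on_path
    return result, path_edges


def build_receptor_network(
    net: InteractionNetwork,
    receptor: str,
    tfs: set[str],
    geneset: GeneSet,
    max_len: int = 6,
    all_targets: bool = False,
) -> Subnetwork | None:
    """Shortest-path network from one receptor to regulating TFs and targets.

    Nodes are the receptor, every node on any directed shortest path
    (<= max_len hops) from the receptor to a reachable TF, and the TR
    targets of those reached TFs restricted to the list of interest
    (``all_targets=True`` lifts the restriction).  Returns None when no TF
    is reachable.
    """
    if receptor not in net.nodes:
        raise KeyError(f"unknown node {receptor!r}")
    if net.node_class.get(receptor) != "receptor":
        raise ValueError(f"{receptor!r} is not receptor-class")

    per_sink, path_edges = _all_shortest_path_nodes(net, receptor, set(tfs), max_len)
    if not per_sink:
        logger.info("receptor %s reaches no selected TF; skipped", receptor)
        return None

    nodes: set[str] = {receptor}
    for on_path in per_sink.values():
        nodes |= on_path
    target_edges: set[Interaction] = set()
    for tf in per_sink:
        for e in net.out_edges(tf):
            if e.is_tr and (all_targets or e.target in geneset):
                nodes.add(e.target)
                target_edges.add(e)

    # edges are restricted to the shortest-path DAG plus the TF->target
    # layer (not the full induced subgraph), so each edge is auditable
    edges = tuple(
        sorted(
            {
                e
                for e in net.interactions
                if (e.source, e.target) in path_edges
            }
            | target_edges,
            key=lambda e: (e.source, e.target, e.effect, e.mechanism),
        )
    )
    return Subnetwork(
        seed=receptor,
        nodes=frozenset(nodes),
        edges=edges,
        kind="receptor_series",
    )


def expand_tf_network(
    net: InteractionNetwork,
    tf: str,
    geneset: GeneSet,
    size: int = 50,
) -> Subnetwork:
    """Grow a subnetwork greedily around a transcription factor.

    Starting from {tf}, repeatedly admits the frontier node (any in- or
    out-neighbor of the current set) that ranks best by: list-of-interest
    membership first, then most links into the current set, then
    lexicographic id — until ``size`` nodes or frontier exhaustion.
    Deterministic by construction.
    """
    if tf not in net.nodes:
        raise KeyError(f"unknown node {tf!r}")
    if net.node_class.get(tf) != "transcription_factor":
        raise ValueError(f"{tf!r} is not transcription_factor-class")
    if size < 1:
        raise ValueError("size must be >= 1")

    nodes: set[str] = {tf}
    while len(nodes) < size:
        frontier = set()
        for v in nodes:
            frontier |= net.neighbors(v)
        frontier -= nodes
        if not frontier:
            break
        best = min(
            frontier,
            key=lambda v: (
                0 if v in geneset else 1,
                -net.links_to_set(v, frozenset(nodes)),
                v,
            ),
        )
        nodes.add(best)

    return Subnetwork(
        seed=tf,
        nodes=frozenset(nodes),
        edges=_induced_edges(net, nodes),
        kind="tf_expansion",
    )


def enrichment_pvalue(
    subnet: Subnetwork, geneset: GeneSet, universe: InteractionNetwork
) -> float:
    """Tail probability of the subnetwork's list-member content.

    N = universe node count, n = list members in the universe,
    R = subnetwork node count, r = list members inside the subnetwork.
    """
    if not subnet.nodes <= universe.nodes:
        raise ValueError("subnetwork nodes must lie within the universe network")
    N = len(universe.nodes)
    n = len(geneset.members & universe.nodes)
    R = subnet.n_nodes
    r = len(subnet.nodes & geneset.members)
    return hypergeom_tail(HypergeomParams(r=r, R=R, n=n, N=N).validate())


def score_networks(
    subnets: Iterable[Subnetwork], geneset: GeneSet, universe: InteractionNetwork
) -> list[Subnetwork]:
    """Attach enrichment p-values and member counts in place."""
    scored = []
    for sn in subnets:
        sn.enrichment_p = enrichment_pvalue(sn, geneset, universe)
        sn.r = len(sn.nodes & geneset.members)
        scored.append(sn)
    return scored


def rank_networks(subnets: Iterable[Subnetwork]) -> list[Subnetwork]:
    """Sort ascending by enrichment p, ties by larger r then seed id."""
    return sorted(subnets, key=lambda sn: (sn.enrichment_p, -sn.r, sn.seed))


def write_summary(subnets: list[Subnetwork], path: str | Path) -> None:
    rows = [
        {
            "rank": i,
            "seed": sn.seed,
            "kind": sn.kind,
            "n_nodes": sn.n_nodes,
            "r": sn.r,
            "enrichment_p": sn.enrichment_p,
        }
        for i, sn in enumerate(subnets, start=1)
    ]
    write_tsv_report(
        rows, path, columns=["rank", "seed", "kind", "n_nodes", "r", "enrichment_p"]
    )
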