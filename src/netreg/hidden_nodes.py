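"""Multi-step regulator significance via transcription-activation shortest paths.

A transcription-activation shortest path is a minimal-hop directed simple
path from any network node to a transcription-regulated target whose final
edge is a transcription_regulation edge out of a transcription-factor node
and whose inhibition-edge count has the configured sign parity (default
even, i.e. net-activating; edges with effect 'unspecified' count as
non-inhibiting).  A node over-represented on the paths that lead to the
genes of interest, relative to its share of all such paths, is a
significant hidden regulator:

    r = paths to genes of interest containing the node
    R = paths to genes of interest
    n = all indexed paths containing the node
    N = all indexed paths
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict, deque
from collections.abc import Callable, Iterable
from pathlib import Path

from .network_model import GeneSet, HypergeomParams, InteractionNetwork
from .overconnectivity import RankedEntry, RankedList, hypergeom_tail

__all__ = [
    "ActivationPathIndex",
    "transcription_regulated_targets",
    "build_path_index",
    "hidden_node_pvalue",
    "rank_hidden_nodes",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ActivationPathIndex:
    """Enumerated admissible shortest paths with per-node containment counts.

    A node appearing in a path (source, intermediates and terminal target
    alike) counts once per path.
    """

    paths: list[tuple[str, ...]]
    parity: str
    max_len: int
    node_counts: Counter = dataclasses.field(default_factory=Counter)
    target_counts: Counter = dataclasses.field(default_factory=Counter)
    node_target_counts: dict[str, Counter] = dataclasses.field(
        default_factory=lambda: defaultdict(Counter)
    )

    def __post_init__(self) -> None:
        if not self.node_counts and self.paths:
            for path in self.paths:
                target = path[-1]
                self.target_counts[target] += 1
                for node in set(path):
                    self.node_counts[node] += 1
                    self.node_target_counts[node][target] += 1

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def terminals(self) -> set[str]:
        return set(self.target_counts)

    def paths_containing(self, node: str) -> int:
        return self.node_counts.get(node, 0)

    def paths_to(self, targets: Iterable[str]) -> int:
        return sum(self.target_counts.get(t, 0) for t in set(targets))

    def paths_to_containing(self, node: str, targets: Iterable[str]) -> int:
        counts = self.node_target_counts.get(node)
        if not counts:
            return 0
        return sum(counts.get(t, 0) for t in set(targets))

    def write_paths(self, path: str | Path) -> None:
        """Audit dump: one path per line, comma-joined node ids."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for p in sorted(self.paths):
                fh.write(",".join(p) + "\n")


def transcription_regulated_targets(net: InteractionNetwork) -> set[str]:
    """Nodes with at least one incoming TR edge from a transcription factor."""
    return {
        e.target
        for e in net.interactions
        if e.is_tr and net.node_class.get(e.source) == "transcription_factor"
    }


def build_path_index(
    net: InteractionNetwork,
    targets: GeneSet | Iterable[str],
    parity: str = "even",
    max_len: int = 6,
    exclude_unspecified: bool = False,
) -> ActivationPathIndex:
    """Enumerate all admissible shortest paths into each eligible target.

    For every ordered (source, target) pair with source != target, all
    directed simple paths of minimal hop count (<= ``max_len``) that end
    with a transcription_regulation edge out of a transcription_factor node
    and whose inhibition count matches ``parity`` are indexed.  Targets
    without an incoming TR edge from a TF are skipped with a diagnostic.
    """
    if parity not in {"even", "odd"}:
        raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    want_parity = 0 if parity == "even" else 1

    members = targets.members if isinstance(targets, GeneSet) else set(targets)
    eligible = members & transcription_regulated_targets(net)
    skipped = {t for t in members if t in net.nodes} - eligible
    if skipped:
        logger.info(
            "%d targets without incoming TF transcription_regulation edges skipped",
            len(skipped),
        )

    # Reverse adjacency: target node -> [(source node, inhibition bit, is_tr,
    # source_is_tf)]; optionally drop 'unspecified' edges entirely.
    rev: dict[str, list[tuple[str, int, bool, bool]]] = defaultdict(list)
    for e in net.interactions:
        if exclude_unspecified and e.effect == "unspecified":
            continue
        rev[e.target].append(
            (
                e.source,
                1 if e.is_inhibition else 0,
                e.is_tr,
                net.node_class.get(e.source) == "transcription_factor",
            )
        )

    all_paths: list[tuple[str, ...]] = []
    for target in sorted(eligible):
        all_paths.extend(
            _shortest_admissible_paths(rev, target, want_parity, max_len)
        )

    if not all_paths:
        logger.warning("no admissible transcription-activation paths found")
    return ActivationPathIndex(paths=all_paths, parity=parity, max_len=max_len)


def _reverse_reach(
    rev: dict[str, list[tuple[str, int, bool, bool]]], target: str, max_len: int
) -> set[str]:
    """Nodes that can reach ``target`` within ``max_len`` hops (sign-blind)."""
    dist = {target: 0}
    queue = deque([target])
    while queue:
        v = queue.popleft()
        d = dist[v]
        if d == max_len:
            continue
        for u, _, _, _ in rev.get(v, ()):
            if u not in dist:
                dist[u] = d + 1
                queue.append(u)
    return set(dist)


def _shortest_admissible_paths(
    rev: dict[str, list[tuple[str, int, bool, bool]]],
    target: str,
    want_parity: int,
    max_len: int,
) -> list[tuple[str, ...]]:
    """All minimal-hop admissible simple paths source -> ... -> target.

    Backward depth-first enumeration from the target.  The first backward
    step is restricted to TR edges out of TF nodes (the path's final edge);
    every admissible prefix encountered en route is a candidate path for
    its source node, and candidates are reduced to minimal hop count per
    source afterwards.
    """
    reachable = _reverse_reach(rev, target, max_len)
    # per-source: (best_length, [paths reversed])
    best: dict[str, tuple[int, list[tuple[str, ...]]]] = {}

    # stack entries: (node, depth, inhibition parity, visited tuple)
    # 'visited' is the reversed path: target first, current node last.
    stack: list[tuple[str, int, int, tuple[str, ...]]] = []
    for u, inhib, is_tr, src_is_tf in rev.get(target, ()):
        if is_tr and src_is_tf and u != target and u in reachable:
            stack.append((u, 1, inhib, (target, u)))

    while stack:
        node, depth, par, visited = stack.pop()
        if par == want_parity:
            entry = best.get(node)
            if entry is None or depth < entry[0]:
                best[node] = (depth, [visited])
            elif depth == entry[0]:
                entry[1].append(visited)
        if depth == max_len:
            continue
        seen = set(visited)
        for u, inhib, _, _ in rev.get(node, ()):
            if u in seen or u not in reachable:
                continue
            stack.append((u, depth + 1, par ^ inhib, visited + (u,)))

    paths: list[tuple[str, ...]] = []
    for _, (_, revpaths) in sorted(best.items()):
        for rp in revpaths:
            paths.append(tuple(reversed(rp)))
    return paths


def hidden_node_pvalue(
    idx: ActivationPathIndex,
    node: str,
    targets: GeneSet | Iterable[str],
) -> float:
    """Hypergeometric tail for over-representation on target-bound paths."""
    members = targets.members if isinstance(targets, GeneSet) else set(targets)
    params = hidden_node_params(idx, node, members)
    if params is None:
        return 1.0
    return hypergeom_tail(params)


def hidden_node_params(
    idx: ActivationPathIndex,
    node: str,
    targets: Iterable[str],
) -> HypergeomParams | None:
    """(r, R, n, N) for the path statistic; None when degenerate (p = 1)."""
    members = set(targets)
    N = idx.n_paths
    if N == 0:
        return None
    n = idx.paths_containing(node)
    if n == 0:
        return None
    R = idx.paths_to(members)
    r = idx.paths_to_containing(node, members)
    return HypergeomParams(r=r, R=R, n=n, N=N)


def rank_hidden_nodes(
    net: InteractionNetwork,
    targets: GeneSet,
    candidate_filter: str | Callable[[str], bool] | Iterable[str],
    parity: str = "even",
    max_len: int = 6,
    index: ActivationPathIndex | None = None,
) -> RankedList:
    """Rank candidates by the hidden-node path statistic.

    The path index universe is the full network: paths to every
    transcription-regulated node are enumerated once, and each candidate is
    scored against the paths bound for ``targets``.  A prebuilt ``index``
    may be passed to amortize enumeration across rankings.
    """
    from .overconnectivity import _resolve_candidates

    candidates = _resolve_candidates(net, candidate_filter)
    if not candidates:
        raise ValueError("candidate set is empty")
    if index is None:
        universe = transcription_regulated_targets(net)
        index = build_path_index(net, universe, parity=parity, max_len=max_len)

    members = targets.members & index.terminals
    entries = []
    for v in sorted(candidates):
        params = hidden_node_params(index, v, members)
        if params is None:
            entries.append(
                RankedEntry(node=v, p_value=1.0, r=0, R=index.paths_to(members),
                            n=0, N=index.n_paths)
            )
        else:
            entries.append(
                RankedEntry(
                    node=v,
                    p_value=hypergeom_tail(params),
                    r=params.r,
                    R=params.R,
                    n=params.n,
                    N=params.N,
                )
            )
    return RankedList(entries=entries)
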