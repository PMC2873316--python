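"""Direct-neighbor enrichment: hypergeometric overconnectivity ranking.

A node is overconnected with a gene set when it has more direct
interactions with set members than expected by chance given its degree.
The one-sided p-value is P(X >= r) for X ~ Hypergeom(N, n, R) with
r = links from the node into the set, R = node degree, n = sum of set
member degrees, N = total interaction records in the network.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Iterable

from scipy.stats import hypergeom

from .network_model import GeneSet, HypergeomParams, InteractionNetwork

__all__ = [
    "RankedEntry",
    "RankedList",
    "hypergeom_tail",
    "overconnection_params",
    "overconnection_pvalue",
    "rank_overconnected",
]


def hypergeom_tail(params: HypergeomParams) -> float:
    """Upper-tail P(X >= r) of the hypergeometric distribution.

    Population N with n successes, R draws without replacement.
    """
    params.validate()
    if params.r == 0:
        return 1.0
    # sf(r-1) == P(X >= r)
    p = float(hypergeom.sf(params.r - 1, params.N, params.n, params.R))
    return min(max(p, 0.0), 1.0)


@dataclasses.dataclass(frozen=True, slots=True)
class RankedEntry:
    node: str
    p_value: float
    r: int = 0
    R: int = 0
    n: int = 0
    N: int = 0
    weight: float | None = None


@dataclasses.dataclass
class RankedList:
    """Nodes ordered by ascending p-value with deterministic tie-breaking.

    Ties on p are broken by larger observed success count r, then by
    lexicographic node id.
    """

    entries: list[RankedEntry]

    def __post_init__(self) -> None:
        nodes = [e.node for e in self.entries]
        if len(nodes) != len(set(nodes)):
            raise ValueError("duplicate node in ranked list")
        self.entries = sorted(
            self.entries, key=lambda e: (e.p_value, -e.r, e.node)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def nodes(self) -> list[str]:
        return [e.node for e in self.entries]

    @property
    def p_values(self) -> list[float]:
        return [e.p_value for e in self.entries]

    def top(self, k: int) -> "RankedList":
        return RankedList(entries=list(self.entries[:k]))

    def rank_of(self, node: str) -> int:
        """1-based rank; raises KeyError if absent."""
        for i, e in enumerate(self.entries, start=1):
            if e.node == node:
                return i
        raise KeyError(node)

    def to_rows(
        self,
        node_class: dict[str, str] | None = None,
        with_q: bool = False,
    ) -> list[dict]:
        """Report rows; ``with_q`` adds a BH-adjusted column (raw p-values
        remain the ranking key)."""
        qvals = None
        if with_q and self.entries:
            from statsmodels.stats.multitest import multipletests

            qvals = multipletests(self.p_values, method="fdr_bh")[1]
        rows = []
        for rank, e in enumerate(self.entries, start=1):
            row = {
                "rank": rank,
                "node": e.node,
                "p_value": e.p_value,
                "r": e.r,
                "R": e.R,
                "n": e.n,
                "N": e.N,
            }
            if qvals is not None:
                row["q_value"] = float(qvals[rank - 1])
            if node_class is not None:
                row["class"] = node_class.get(e.node, "generic")
            rows.append(row)
        return rows


def overconnection_params(
    net: InteractionNetwork, node: str, geneset: GeneSet
) -> HypergeomParams:
    """Assemble (r, R, n, N) for the direct-link statistic.

    The node's own degree stays inside n when it belongs to the set;
    pass ``exclude_self_from_population=True`` to
    :func:`overconnection_pvalue` for the alternative convention.
    """
    r = net.links_to_set(node, geneset)
    R = net.node_degree(node)
    n = net.set_degree_sum(geneset)
    N = net.n_interactions
    return HypergeomParams(r=r, R=R, n=min(n, N), N=N)


def overconnection_pvalue(
    net: InteractionNetwork,
    node: str,
    geneset: GeneSet,
    exclude_self_from_population: bool = False,
) -> float:
    """One-sided overconnectivity p-value of ``node`` against ``geneset``."""
    if not len(geneset):
        raise ValueError("gene set of interest is empty")
    if net.n_interactions == 0:
        raise ValueError("network has no interactions")
    params = overconnection_params(net, node, geneset)
    if exclude_self_from_population and node in geneset:
        n = max(params.n - params.R, 0)
        params = HypergeomParams(r=min(params.r, n), R=params.R, n=n, N=params.N)
    if params.R == 0:
        # isolated node can never be overconnected
        return 1.0
    return hypergeom_tail(params)


def rank_overconnected(
    net: InteractionNetwork,
    geneset: GeneSet,
    candidate_filter: str | Callable[[str], bool] | Iterable[str],
    exclude_self_from_population: bool = False,
) -> RankedList:
    """Rank candidate nodes by ascending overconnectivity p-value.

    ``candidate_filter`` is a node-class name, a predicate on node ids, or
    an explicit iterable of node ids.
    """
    candidates = _resolve_candidates(net, candidate_filter)
    if not candidates:
        raise ValueError("candidate set is empty")
    entries = []
    for v in sorted(candidates):
        params = overconnection_params(net, v, geneset)
        p = overconnection_pvalue(
            net, v, geneset, exclude_self_from_population=exclude_self_from_population
        )
        entries.append(
            RankedEntry(node=v, p_value=p, r=params.r, R=params.R, n=params.n, N=params.N)
        )
    return RankedList(entries=entries)


def _resolve_candidates(
    net: InteractionNetwork,
    candidate_filter: str | Callable[[str], bool] | Iterable[str],
) -> set[str]:
    if isinstance(candidate_filter, str):
        return net.nodes_of_class(candidate_filter)
    if callable(candidate_filter):
        return {v for v in net.nodes if candidate_filter(v)}
    candidates = set(candidate_filter)
    unknown = candidates - net.nodes
    if unknown:
        raise KeyError(f"unknown candidate nodes: {sorted(unknown)[:5]}")
    return candidates
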