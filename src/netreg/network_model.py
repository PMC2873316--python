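"""Signed directed interaction networks, node attributes and gene sets.

The network is the analysis universe for every topology statistic: the
total interaction count ``N``, node degrees ``R`` and set-link counts ``r``
defined here feed the hypergeometric tests in the other modules.

Conventions
-----------
* Interactions are directed records ``source -> target`` with an effect
  sign (``activation`` / ``inhibition`` / ``unspecified``) and a mechanism
  (``transcription_regulation`` / ``other``).  Undirected binding data must
  be encoded as two reciprocal records by the producer.
* Parallel edges between the same ordered pair are allowed only when they
  differ in (effect, mechanism); each stored record counts once everywhere.
* Degree counts each stored record once regardless of direction, so
  ``sum(deg) == 2 * N`` always holds.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from collections.abc import Iterable, Mapping
from pathlib import Path

__all__ = [
    "EFFECTS",
    "MECHANISMS",
    "NODE_CLASSES",
    "Interaction",
    "GeneSet",
    "HypergeomParams",
    "InteractionNetwork",
    "NetworkParseError",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "write_tsv_report",
]

EFFECTS = frozenset({"activation", "inhibition", "unspecified"})
MECHANISMS = frozenset({"transcription_regulation", "other"})
NODE_CLASSES = frozenset(
    {"ligand", "receptor", "kinase", "transcription_factor", "generic"}
)


class NetworkParseError(ValueError):
    """Malformed edge/attribute/GMT file content."""


@dataclasses.dataclass(frozen=True, slots=True)
class Interaction:
    """One directed, signed, mechanism-typed interaction record."""

    source: str
    target: str
    effect: str = "activation"
    mechanism: str = "other"

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def is_inhibition(self) -> bool:
        # 'unspecified' is treated as non-inhibiting for sign parity.
        return self.effect == "inhibition"

    @property
    def is_tr(self) -> bool:
        return self.mechanism == "transcription_regulation"


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of node identifiers (a 'list of interest')."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name.strip())
        object.__setattr__(
            self, "members", frozenset(m.strip() for m in members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, node: str) -> bool:
        return node in self.members

    def __iter__(self):
        return iter(sorted(self.members))


@dataclasses.dataclass(frozen=True, slots=True)
class HypergeomParams:
    """Parameters of a one-sided hypergeometric enrichment test.

    r: observed successes among the draws; R: number of draws;
    n: successes in the population; N: population size.
    """

    r: int
    R: int
    n: int
    N: int

    def validate(self) -> "HypergeomParams":
        r, R, n, N = self.r, self.R, self.n, self.N
        if not all(isinstance(v, int) for v in (r, R, n, N)):
            raise ValueError("hypergeometric parameters must be integers")
        if r < 0 or R < 0 or n < 0 or N < 0:
            raise ValueError(f"negative parameter in {self}")
        if R > N or n > N:
            raise ValueError(f"R and n must not exceed N: {self}")
        if r > min(R, n):
            raise ValueError(f"r must not exceed min(R, n): {self}")
        return self


class InteractionNetwork:
    """A signed directed interaction network with typed nodes.

    Nodes are opaque string identifiers.  ``n_interactions`` is the number
    of stored interaction records (symbol ``N`` of the direct-link
    statistic); ``n_unique_pairs`` counts distinct ordered endpoint pairs
    and is exposed for users comparing counting conventions.
    """

    def __init__(
        self,
        interactions: Iterable[Interaction] = (),
        node_class: Mapping[str, str] | None = None,
        extra_nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ):
        self._edges: list[Interaction] = []
        self._edge_set: set[Interaction] = set()
        self._out: dict[str, list[Interaction]] = defaultdict(list)
        self._in: dict[str, list[Interaction]] = defaultdict(list)
        self.nodes: set[str] = set()
        self.node_class: dict[str, str] = {}
        self.allow_self_loops = allow_self_loops

        for node, cls in (node_class or {}).items():
            self.set_node_class(node, cls)
        for node in extra_nodes:
            self.add_node(node)
        for edge in interactions:
            self.add_interaction(edge)

    # -- construction ----------------------------------------------------

    def add_node(self, node: str, cls: str | None = None) -> None:
        self.nodes.add(node)
        if cls is not None:
            self.set_node_class(node, cls)
        else:
            self.node_class.setdefault(node, "generic")

    def set_node_class(self, node: str, cls: str) -> None:
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown node class {cls!r} for node {node!r}")
        self.nodes.add(node)
        self.node_class[node] = cls

    def add_interaction(self, edge: Interaction) -> None:
        if edge.source == edge.target and not self.allow_self_loops:
            raise ValueError(f"self-loop rejected: {edge.source!r}")
        if edge in self._edge_set:
            raise ValueError(
                "duplicate interaction record "
                f"{edge.source}->{edge.target} ({edge.effect}, {edge.mechanism})"
            )
        self.add_node(edge.source)
        self.add_node(edge.target)
        self._edges.append(edge)
        self._edge_set.add(edge)
        self._out[edge.source].append(edge)
        self._in[edge.target].append(edge)

    # -- queries ---------------------------------------------------------

    @property
    def interactions(self) -> tuple[Interaction, ...]:
        return tuple(self._edges)

    @property
    def n_interactions(self) -> int:
        """Total number of stored interaction records (symbol N)."""
        return len(self._edges)

    @property
    def n_unique_pairs(self) -> int:
        return len({(e.source, e.target) for e in self._edges})

    def has_node(self, node: str) -> bool:
        return node in self.nodes

    def _require_node(self, node: str) -> None:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")

    def out_edges(self, node: str) -> list[Interaction]:
        self._require_node(node)
        return list(self._out.get(node, ()))

    def in_edges(self, node: str) -> list[Interaction]:
        self._require_node(node)
        return list(self._in.get(node, ()))

    def successors(self, node: str) -> set[str]:
        self._require_node(node)
        return {e.target for e in self._out.get(node, ())}

    def predecessors(self, node: str) -> set[str]:
        self._require_node(node)
        return {e.source for e in self._in.get(node, ())}

    def neighbors(self, node: str) -> set[str]:
        return self.successors(node) | self.predecessors(node)

    def node_degree(self, node: str) -> int:
        """Interactions incident to ``node`` (in + out), each record once."""
        self._require_node(node)
        deg = len(self._out.get(node, ())) + len(self._in.get(node, ()))
        if self.allow_self_loops:
            deg -= sum(1 for e in self._out.get(node, ()) if e.target == node)
        return deg

    def links_to_set(self, node: str, geneset: GeneSet | frozenset[str]) -> int:
        """Count interactions of ``node`` whose other endpoint is in the set."""
        self._require_node(node)
        members = geneset.members if isinstance(geneset, GeneSet) else geneset
        count = sum(1 for e in self._out.get(node, ()) if e.target in members)
        count += sum(1 for e in self._in.get(node, ()) if e.source in members)
        return count

    def nodes_of_class(self, cls: str) -> set[str]:
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown node class {cls!r}")
        return {v for v, c in self.node_class.items() if c == cls}

    def set_degree_sum(self, geneset: GeneSet | frozenset[str]) -> int:
        """Sum of member degrees: symbol n of the direct-link statistic."""
        members = geneset.members if isinstance(geneset, GeneSet) else geneset
        return sum(self.node_degree(v) for v in members if v in self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.node_class == other.node_class
            and self._edge_set == other._edge_set
        )


# -- file I/O ------------------------------------------------------------

_EDGE_HEADER = ["source", "target", "effect", "mechanism"]
_ATTR_HEADER = ["node", "class"]


def read_network(
    edge_path: str | Path,
    attr_path: str | Path | None = None,
    allow_self_loops: bool = False,
) -> InteractionNetwork:
    """Load a network from an edge-list TSV plus optional node-attribute TSV.

    The edge file must carry the header ``source  target  effect
    mechanism``; unknown effect or mechanism strings raise
    :class:`NetworkParseError` naming the offending line.  Node classes not
    listed in the attribute file default to ``generic``.
    """
    edge_path = Path(edge_path)
    net = InteractionNetwork(allow_self_loops=allow_self_loops)

    if attr_path is not None:
        attr_path = Path(attr_path)
        with attr_path.open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if [h.strip() for h in header[:2]] != _ATTR_HEADER:
                raise NetworkParseError(
                    f"{attr_path}: expected header {_ATTR_HEADER!r}, got {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise NetworkParseError(
                        f"{attr_path}:{lineno}: expected 2 fields, got {len(fields)}"
                    )
                node, cls = fields[0].strip(), fields[1].strip()
                if cls not in NODE_CLASSES:
                    cls = "generic"
                net.set_node_class(node, cls)

    with edge_path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header[:4]] != _EDGE_HEADER:
            raise NetworkParseError(
                f"{edge_path}: expected header {_EDGE_HEADER!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 4:
                raise NetworkParseError(
                    f"{edge_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            source, target, effect, mechanism = fields[:4]
            if effect not in EFFECTS:
                raise NetworkParseError(
                    f"{edge_path}:{lineno}: unknown effect {effect!r}"
                )
            if mechanism not in MECHANISMS:
                raise NetworkParseError(
                    f"{edge_path}:{lineno}: unknown mechanism {mechanism!r}"
                )
            try:
                net.add_interaction(Interaction(source, target, effect, mechanism))
            except ValueError as exc:
                raise NetworkParseError(f"{edge_path}:{lineno}: {exc}") from exc
    return net


def write_network(
    net: InteractionNetwork,
    edge_path: str | Path,
    attr_path: str | Path | None = None,
) -> None:
    edge_path = Path(edge_path)
    with edge_path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in sorted(
            net.interactions,
            key=lambda e: (e.source, e.target, e.effect, e.mechanism),
        ):
            fh.write(f"{e.source}\t{e.target}\t{e.effect}\t{e.mechanism}\n")
    if attr_path is not None:
        attr_path = Path(attr_path)
        with attr_path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(_ATTR_HEADER) + "\n")
            for node in sorted(net.nodes):
                fh.write(f"{node}\t{net.node_class.get(node, 'generic')}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT dialect: name, description, then members."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            members = [f for f in fields[2:] if f.strip()]
            sets.append(GeneSet(fields[0], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.members)]) + "\n")


def write_tsv_report(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: list[str] | None = None,
) -> None:
    """Write dict rows as a TSV with a stable header and column order."""
    rows = list(rows)
    path = Path(path)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in columns) + "\n")


def _fmt(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)
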