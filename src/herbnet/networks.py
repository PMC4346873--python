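"""Bipartite network construction, degree topology and Cytoscape export.

The pipeline analyzes four bipartite graphs: drug-target (D-T),
ingredient-target (I-T), target-pathway (T-P) and target-disease (T-D).
The topology of interest is degree-level: mean degree over all nodes
(2|E|/|V|), per-partition means (|E|/|partition|), and hubs — nodes whose
degree exceeds the all-node mean (strictly, by default; a multiplier can
raise the bar). Graphs are backed by :mod:`networkx`; node ids are
namespaced ``role:id`` inside the graph so a gene symbol can appear in both
partitions of different networks without collision, and exports (SIF,
GraphML, node-attribute TSV) round-trip node and edge sets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "BipartiteNetwork",
    "DegreeSummary",
    "build_bipartite",
    "degree_summary",
    "find_hubs",
    "shared_targets",
    "map_targets_to_pathways",
    "export_network",
    "import_network",
    "write_node_attributes",
]


@dataclass
class BipartiteNetwork:
    """A typed two-partition graph with deterministic node ordering."""

    name: str
    left_role: str
    right_role: str
    left: tuple[str, ...]
    right: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        left_set, right_set = set(self.left), set(self.right)
        for u, v in self.edges:
            if u not in left_set or v not in right_set:
                raise ValueError(
                    f"{self.name}: edge ({u!r}, {v!r}) has an endpoint outside "
                    f"its declared partition ({self.left_role}/{self.right_role})"
                )

    def degree(self, node: str, partition: str) -> int:
        if partition == "left":
            return sum(1 for u, _ in self.edges if u == node)
        return sum(1 for _, v in self.edges if v == node)

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph(name=self.name)
        for node in self.left:
            graph.add_node(f"{self.left_role}:{node}", role=self.left_role, bipartite=0)
        for node in self.right:
            graph.add_node(f"{self.right_role}:{node}", role=self.right_role, bipartite=1)
        for u, v in sorted(self.edges):
            graph.add_edge(f"{self.left_role}:{u}", f"{self.right_role}:{v}")
        return graph


@dataclass(frozen=True)
class DegreeSummary:
    """Degree map plus the mean degrees used by the hub rule.

    ``mean_degree_all`` is 2|E|/|V| over all nodes; the partition means are
    |E|/|partition|. Computed exactly from integer counts and rounded only at
    presentation.
    """

    per_node: Mapping[tuple[str, str], int]  # (partition, node) -> degree
    mean_degree_all: float
    mean_degree_left: float
    mean_degree_right: float


def build_bipartite(
    edges: Iterable[tuple[str, str]],
    left_role: str,
    right_role: str,
    left_nodes: Optional[Iterable[str]] = None,
    right_nodes: Optional[Iterable[str]] = None,
    name: str = "",
) -> BipartiteNetwork:
    """Build a deduplicated bipartite network.

    When node lists are declared explicitly, every edge endpoint must belong
    to them (an endpoint of the wrong role is an error naming the edge) and
    isolated declared nodes are kept with degree 0. Without declared nodes
    the partitions are inferred from the edge list.
    """
    edge_set = frozenset((str(u), str(v)) for u, v in edges)
    if left_nodes is None:
        left = tuple(sorted({u for u, _ in edge_set}))
    else:
        left = tuple(dict.fromkeys(str(n) for n in left_nodes))
    if right_nodes is None:
        right = tuple(sorted({v for _, v in edge_set}))
    else:
        right = tuple(dict.fromkeys(str(n) for n in right_nodes))
    return BipartiteNetwork(
        name=name or f"{left_role}-{right_role}",
        left_role=left_role,
        right_role=right_role,
        left=left,
        right=right,
        edges=edge_set,
    )


def degree_summary(network: BipartiteNetwork) -> DegreeSummary:
    """Degree statistics. Handshake invariant: the degree sum is 2|E|."""
    n_nodes = len(network.left) + len(network.right)
    if n_nodes == 0:
        raise ValueError(f"{network.name}: cannot summarize an empty node set")
    per_node: dict[tuple[str, str], int] = {}
    for node in network.left:
        per_node[("left", node)] = 0
    for node in network.right:
        per_node[("right", node)] = 0
    for u, v in network.edges:
        per_node[("left", u)] += 1
        per_node[("right", v)] += 1
    n_edges = len(network.edges)
    return DegreeSummary(
        per_node=per_node,
        mean_degree_all=2 * n_edges / n_nodes,
        mean_degree_left=n_edges / len(network.left) if network.left else 0.0,
        mean_degree_right=n_edges / len(network.right) if network.right else 0.0,
    )


def find_hubs(
    network: BipartiteNetwork,
    partition: str = "left",
    multiplier: float = 1.0,
    partition_mean: bool = False,
) -> list[tuple[str, int]]:
    """Nodes of one partition whose degree strictly exceeds the mean degree.

    The default bar is the all-node mean 2|E|/|V| (the reading under which
    the reference statistics arise); ``partition_mean=True`` compares against
    that partition's own mean instead, and ``multiplier`` scales the bar.
    Results are sorted by degree descending, then id.
    """
    if partition not in ("left", "right"):
        raise ValueError(f"unknown partition {partition!r}; use 'left' or 'right'")
    summary = degree_summary(network)
    if partition_mean:
        mean = (
            summary.mean_degree_left if partition == "left" else summary.mean_degree_right
        )
    else:
        mean = summary.mean_degree_all
    bar = multiplier * mean
    hubs = [
        (node, deg)
        for (part, node), deg in summary.per_node.items()
        if part == partition and deg > bar
    ]
    return sorted(hubs, key=lambda item: (-item[1], item[0]))


def _target_partition(network: BipartiteNetwork) -> tuple[str, ...]:
    if network.left_role == "targets":
        return network.left
    if network.right_role == "targets":
        return network.right
    raise ValueError(f"{network.name}: no partition has role 'targets'")


def shared_targets(net_a: BipartiteNetwork, net_b: BipartiteNetwork) -> list[str]:
    """Ordered intersection of the two networks' target partitions."""
    return sorted(set(_target_partition(net_a)) & set(_target_partition(net_b)))


def map_targets_to_pathways(
    targets: Sequence[str], pathway_table: Mapping[str, Iterable[str]]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Edge list (target, pathway) from a membership table, plus the targets
    with zero memberships (unmapped report). An empty table maps nothing."""
    memberships = {name: set(members) for name, members in pathway_table.items()}
    edges: list[tuple[str, str]] = []
    unmapped: list[str] = []
    for target in targets:
        hits = sorted(name for name, members in memberships.items() if target in members)
        if hits:
            edges.extend((target, name) for name in hits)
        else:
            unmapped.append(target)
    return edges, unmapped


# ---------------------------------------------------------------------------
# export / import


def export_network(network: BipartiteNetwork, path, fmt: str = "sif") -> None:
    """Write a Cytoscape-ingestible file.

    ``sif``: tab-separated ``source  interaction  target`` lines with the
    relation named ``<left_role>-<right_role>``; ``graphml`` via networkx.
    Node ids are namespaced ``role:id`` in both formats.
    """
    path = Path(path)
    if fmt == "sif":
        relation = f"{network.left_role}-{network.right_role}"
        lines = [
            f"{network.left_role}:{u}\t{relation}\t{network.right_role}:{v}"
            for u, v in sorted(network.edges)
        ]
        isolated = [
            f"{role}:{n}"
            for role, nodes in (
                (network.left_role, network.left),
                (network.right_role, network.right),
            )
            for n in nodes
            if not any(n == (u if role == network.left_role else v) for u, v in network.edges)
        ]
        path.write_text("\n".join(lines + isolated) + "\n", encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'sif' or 'graphml'")


def import_network(path, fmt: str = "sif", name: str = "") -> BipartiteNetwork:
    """Re-read an exported network; round-trips node and edge sets exactly."""
    path = Path(path)
    if fmt == "sif":
        edges: list[tuple[str, str]] = []
        isolated: list[str] = []
        left_role = right_role = None
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                isolated.append(parts[0])
                continue
            source, _, target = parts
            left_role = source.split(":", 1)[0]
            right_role = target.split(":", 1)[0]
            edges.append((source.split(":", 1)[1], target.split(":", 1)[1]))
        left_extra = [
            n.split(":", 1)[1] for n in isolated if n.split(":", 1)[0] == left_role
        ]
        right_extra = [
            n.split(":", 1)[1] for n in isolated if n.split(":", 1)[0] != left_role
        ]
        if left_role is None and isolated:
            roles = sorted({n.split(":", 1)[0] for n in isolated})
            left_role = roles[0]
            right_role = roles[-1]
            left_extra = [n.split(":", 1)[1] for n in isolated if n.startswith(left_role + ":")]
            right_extra = [
                n.split(":", 1)[1]
                for n in isolated
                if not n.startswith(left_role + ":")
            ]
        return build_bipartite(
            edges,
            left_role or "left",
            right_role or "right",
            left_nodes=sorted({u for u, _ in edges} | set(left_extra)),
            right_nodes=sorted({v for _, v in edges} | set(right_extra)),
            name=name or path.stem,
        )
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        roles = nx.get_node_attributes(graph, "role")
        parts = nx.get_node_attributes(graph, "bipartite")
        left_nodes = sorted(n for n in graph if parts.get(n) == 0)
        right_nodes = sorted(n for n in graph if parts.get(n) != 0)
        left_role = roles[left_nodes[0]] if left_nodes else "left"
        right_role = roles[right_nodes[0]] if right_nodes else "right"

        def strip(node: str) -> str:
            return node.split(":", 1)[1] if ":" in node else node

        edges = []
        for u, v in graph.edges:
            if parts.get(u) == 0:
                edges.append((strip(u), strip(v)))
            else:
                edges.append((strip(v), strip(u)))
        return build_bipartite(
            edges,
            left_role,
            right_role,
            left_nodes=[strip(n) for n in left_nodes],
            right_nodes=[strip(n) for n in right_nodes],
            name=name or graph.name or path.stem,
        )
    raise ValueError(f"unknown import format {fmt!r}; use 'sif' or 'graphml'")


def write_node_attributes(network: BipartiteNetwork, path) -> None:
    """Node-attribute TSV (node, role, degree) with deterministic ordering."""
    summary = degree_summary(network)
    lines = ["node\trole\tdegree"]
    for part, role, nodes in (
        ("left", network.left_role, network.left),
        ("right", network.right_role, network.right),
    ):
        for node in sorted(nodes):
            lines.append(f"{role}:{node}\t{role}\t{summary.per_node[(part, node)]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
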