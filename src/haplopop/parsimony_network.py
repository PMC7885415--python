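"""Statistical-parsimony (TCS-style) haplotype network construction.

Haplotypes are connected by single mutational steps, inserting anonymous
median (inferred intermediate) nodes where the observed haplotypes are
more than one step apart, up to a parsimony connection limit: the
largest number of steps that can be accepted with a given confidence
(conventionally 95%) that the connection involves no superimposed
change at any site.

Probability-of-parsimony model
------------------------------
Published descriptions of the statistical-parsimony limit differ in
detail; the variant implemented here is a sequential distinct-sites
model, documented so results are reproducible: mutations along the path
between two haplotypes of length ``L`` are assumed to strike sites
uniformly and independently, and a ``j``-step connection is parsimonious
when all ``j`` mutations strike distinct sites,

    P(j) = prod_{i=1}^{j-1} (1 - i / L),

a closed form that is 1 at ``j = 1``, strictly decreasing in ``j`` and
non-decreasing in ``L``. The connection limit ``j_max`` is the largest
``j`` with ``P(j) >= alpha``; a fixed limit may be imposed instead.

Network construction connects candidate haplotype pairs in increasing
step distance; a pair is linked only when its nodes lie in different
connected components, so the result is a deterministic forest (loops
from equally parsimonious alternatives are not retained). Pairs further
apart than the connection limit stay in separate subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
from networkx.utils import UnionFind

from .differentiation import hamming

__all__ = [
    "ParsimonyLimit",
    "HaplotypeNetwork",
    "probability_parsimony",
    "connection_limit",
    "build_network",
    "to_edge_table",
    "to_node_table",
    "to_nexus",
]


def probability_parsimony(j: int, L: int) -> float:
    """P(a j-step connection involves no repeated site), sequence length L."""
    if j < 1:
        raise ValueError("j must be >= 1")
    if L < 1:
        raise ValueError("L must be >= 1")
    p = 1.0
    for i in range(1, j):
        p *= max(0.0, 1.0 - i / L)
    return p


@dataclass(frozen=True)
class ParsimonyLimit:
    alpha: float
    j_max: int
    L: int


def connection_limit(
    L: int, alpha: float = 0.95, fixed_limit: int | None = None
) -> ParsimonyLimit:
    """Largest step count connectable at the given parsimony confidence.

    ``fixed_limit`` overrides the probabilistic computation (escape hatch
    for matching an externally chosen limit).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if fixed_limit is not None:
        if fixed_limit < 1:
            raise ValueError("fixed_limit must be >= 1")
        return ParsimonyLimit(alpha, fixed_limit, L)
    j = 1
    while probability_parsimony(j + 1, L) >= alpha:
        j += 1
    return ParsimonyLimit(alpha, j, L)


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Forest of haplotype nodes and inferred median nodes.

    Every edge spans exactly one mutational step. Node attributes on
    ``graph``: ``kind`` ("sampled" | "median"), ``frequency`` (0 for
    medians), ``populations`` (mapping, possibly empty).
    """

    graph: nx.Graph
    limit: ParsimonyLimit

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"]

    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]


def build_network(
    hap_seqs: Mapping[str, str],
    frequencies: Mapping[str, int],
    limit: ParsimonyLimit,
    populations: Mapping[str, Mapping[str, int]] | None = None,
) -> HaplotypeNetwork:
    """Build the statistical-parsimony network.

    Candidate pairs are processed in increasing Hamming distance
    ``d = 1 .. j_max``; at equal distance, pairs with a higher summed
    haplotype frequency come first, ties broken lexicographically — a
    fully deterministic order. A pair is connected only when its
    endpoints are in different components; connecting a pair at distance
    ``d`` inserts ``d - 1`` median nodes (named ``M1``, ``M2``, ...,
    zero frequency) along the new path.
    """
    names = list(hap_seqs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate haplotype names")
    for name in names:
        if frequencies.get(name, 0) < 1:
            raise ValueError(f"haplotype {name!r} must have frequency >= 1")
    lengths = {len(s) for s in hap_seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")

    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = hamming(hap_seqs[a], hap_seqs[b])
            if 1 <= d <= limit.j_max:
                u, v = sorted((a, b))
                pairs.append((d, -(frequencies[a] + frequencies[b]), u, v))
    pairs.sort()

    g = nx.Graph()
    populations = populations or {}
    for name in names:
        g.add_node(
            name,
            kind="sampled",
            frequency=int(frequencies[name]),
            populations=dict(populations.get(name, {})),
        )

    uf = UnionFind(names)
    median_counter = 0
    for d, _, u, v in pairs:
        if uf[u] == uf[v]:
            continue
        path = [u]
        for _ in range(d - 1):
            median_counter += 1
            m = f"M{median_counter}"
            g.add_node(m, kind="median", frequency=0, populations={})
            path.append(m)
        path.append(v)
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b, steps=1)
        uf.union(u, v)
    return HaplotypeNetwork(g, limit)


def to_edge_table(network: HaplotypeNetwork) -> list[tuple[str, str]]:
    """Sorted (node, node) edge list; every edge is one mutational step."""
    return sorted(tuple(sorted(e)) for e in network.graph.edges)


def to_node_table(network: HaplotypeNetwork) -> list[dict[str, object]]:
    """Node records (name, kind, frequency, per-population composition)."""
    rows = []
    for name, data in sorted(network.graph.nodes(data=True)):
        rows.append(
            {
                "node": name,
                "kind": data["kind"],
                "frequency": data["frequency"],
                "populations": ";".join(
                    f"{p}:{c}" for p, c in sorted(data["populations"].items())
                ),
            }
        )
    return rows


def to_nexus(network: HaplotypeNetwork) -> str:
    """NEXUS export: a Taxa block plus an Edges-based Network block.

    The format is a minimal viewer-compatible dialect: taxa are the
    sampled haplotypes, vertices include the inferred medians, and each
    edge represents one mutational step.
    """
    sampled = sorted(network.sampled_nodes())
    all_nodes = sorted(network.graph.nodes)
    index = {n: i + 1 for i, n in enumerate(all_nodes)}
    lines = ["#NEXUS", "", "BEGIN TAXA;"]
    lines.append(f"    DIMENSIONS NTAX={len(sampled)};")
    lines.append("    TAXLABELS")
    for n in sampled:
        lines.append(f"        {n}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN NETWORK;")
    lines.append(
        f"    DIMENSIONS NVERTICES={network.graph.number_of_nodes()} "
        f"NEDGES={network.graph.number_of_edges()};"
    )
    lines.append("    TRANSLATE")
    for n in all_nodes:
        freq = network.graph.nodes[n]["frequency"]
        lines.append(f"        {index[n]} {n} [frequency={freq}],")
    lines.append("    ;")
    lines.append("    EDGES")
    for k, (u, v) in enumerate(to_edge_table(network), start=1):
        lines.append(f"        {k} {index[u]} {index[v]} [steps=1],")
    lines.append("    ;")
    lines.append("END;")
    return "\n".join(lines) + "\n"
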