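"""Community detection and node-role cartography on food networks.

Communities are found with the Louvain method on the absolute partial
correlations; only communities of at least two food groups are reported, with
edge-free groups listed separately as conditionally independent. Node roles
follow the within-community degree z-score (WC) / participation coefficient
(PC) cartography: WC >= 1.0 marks a hub, and PC bands separate provincial,
connector and kinless hubs and the non-hub roles. Communities of matching
composition across diet-quality strata are given a shared number via greedy
Jaccard matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .networks import NetworkModel

ROLES = (
    "provincial_hub", "connector_hub", "kinless_hub",
    "ultra_peripheral", "peripheral", "non_hub_connector", "non_hub_kinless",
    "isolated",
)

UNASSIGNED = -1  # community id for nodes outside any reported (size >= 2) community


def build_graph(model: NetworkModel) -> nx.Graph:
    """Undirected weighted graph from a fitted network.

    Nodes are the retained food groups (with consumption prevalence as an
    attribute); one edge per nonzero partial correlation, weighted by its
    absolute value with the sign kept as an attribute.
    """
    g = nx.Graph()
    for name in model.groups:
        g.add_node(name, prevalence_pct=float(model.prevalence_pct.get(name, 0.0) * 100))
    for i, j in sorted(model.edges):
        pc = float(model.partial_corr[i, j])
        g.add_edge(model.groups[i], model.groups[j],
                   weight=abs(pc), sign=1 if pc > 0 else -1, partial_correlation=pc)
    return g


def modularity(graph: nx.Graph, membership: dict) -> float:
    """Weighted Newman-Girvan modularity of a node->community mapping.

    Q = (1/2m) * sum_ij (w_ij - k_i k_j / 2m) * delta(c_i, c_j) with weighted
    degrees k and total weight m. An empty (edgeless) graph has Q = 0.
    """
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]}")
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    deg = dict(graph.degree(weight="weight"))
    q = 0.0
    for u, v, w in graph.edges(data="weight", default=1.0):
        if membership[u] == membership[v]:
            q += w  # each undirected edge counts twice in the sum over ordered pairs
    q /= m
    comm_deg: dict = {}
    for node, c in membership.items():
        comm_deg[c] = comm_deg.get(c, 0.0) + deg.get(node, 0.0)
    q -= sum(d * d for d in comm_deg.values()) / (4.0 * m * m)
    return float(q)


@dataclass
class Partition:
    """Community assignment with modularity and size->=2 community reporting."""

    membership: dict            # node -> community id (UNASSIGNED for singletons)
    modularity: float
    communities: dict           # id -> sorted node list, all of size >= 2
    singletons: list            # conditionally independent / unassigned nodes

    def community_table(self) -> pd.DataFrame:
        rows = [{"group": n, "community": c} for n, c in sorted(self.membership.items())]
        return pd.DataFrame(rows, columns=["group", "community"])


def louvain_partition(graph: nx.Graph, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Seeded Louvain on edge weight |partial correlation|.

    Communities of size >= 2 are numbered 1..K by decreasing size (ties by
    lexicographically smallest member, for determinism); singleton communities
    are reported separately as conditionally independent nodes and given the
    UNASSIGNED id.
    """
    if graph.number_of_nodes() == 0:
        return Partition(membership={}, modularity=0.0, communities={}, singletons=[])
    comms = louvain_communities(graph, weight="weight", resolution=resolution, seed=seed)
    sized = sorted((c for c in comms if len(c) >= 2), key=lambda c: (-len(c), min(c)))
    membership: dict = {}
    communities: dict = {}
    for k, nodes in enumerate(sized, start=1):
        communities[k] = sorted(nodes)
        for n in nodes:
            membership[n] = k
    singletons = sorted(n for c in comms if len(c) < 2 for n in c)
    for n in singletons:
        membership[n] = UNASSIGNED
    q = modularity(graph, {n: (f"s_{n}" if c == UNASSIGNED else c)
                           for n, c in membership.items()})
    return Partition(membership=membership, modularity=q,
                     communities=communities, singletons=singletons)


def _internal_degree(graph: nx.Graph, membership: dict, node, community, *, weighted: bool) -> float:
    k = 0.0
    for nbr in graph.neighbors(node):
        if membership.get(nbr) == community:
            k += graph[node][nbr].get("weight", 1.0) if weighted else 1.0
    return k


def within_community_degree(graph: nx.Graph, partition: Partition, node, *,
                            weighted: bool = False) -> float:
    """WC z-score: the node's internal link count standardized over its community.

    Uses binary link counts by default (the classical cartography convention;
    set ``weighted=True`` to use link strengths), population standard
    deviation, and the convention WC = 0 when the community's internal degrees
    are constant (sd = 0) or the node is a singleton.
    """
    c = partition.membership.get(node)
    if c is None:
        raise ValueError(f"node {node!r} not in partition")
    if c == UNASSIGNED:
        return 0.0
    members = partition.communities[c]
    kappas = np.array([_internal_degree(graph, partition.membership, n, c, weighted=weighted)
                       for n in members])
    sd = kappas.std()  # population sd
    if sd == 0:
        return 0.0
    me = kappas[members.index(node)]
    return float((me - kappas.mean()) / sd)


def participation_coefficient(graph: nx.Graph, partition: Partition, node, *,
                              weighted: bool = False) -> float:
    """PC = 1 - sum_s (k_is / k_i)^2 over the communities the node touches.

    0 when every edge stays inside the node's own community, approaching 1 as
    edges spread uniformly over communities; 0 by convention for isolated
    nodes. Singleton neighbours count as their own (per-node) communities.
    """
    per_comm: dict = {}
    total = 0.0
    for nbr in graph.neighbors(node):
        w = graph[node][nbr].get("weight", 1.0) if weighted else 1.0
        c = partition.membership.get(nbr)
        key = f"s_{nbr}" if c == UNASSIGNED else c
        per_comm[key] = per_comm.get(key, 0.0) + w
        total += w
    if total == 0:
        return 0.0
    return float(1.0 - sum((k / total) ** 2 for k in per_comm.values()))


def classify_role(wc: float, pc: float) -> str:
    """Role from the (WC, PC) cartography rule set.

    Hubs are WC >= 1.0: provincial (PC <= 0.30), connector (0.30 < PC <= 0.75),
    kinless (PC > 0.75). Non-hubs: ultra-peripheral (PC <= 0.05), peripheral
    (0.05 < PC <= 0.62), non-hub connector (0.62 < PC < 0.80), non-hub kinless
    (PC >= 0.80) — the published bands overlap at exactly PC = 0.80, resolved
    here in favour of kinless.
    """
    if not 0.0 <= pc <= 1.0:
        raise ValueError("PC must lie in [0, 1]")
    if wc >= 1.0:
        if pc <= 0.30:
            return "provincial_hub"
        if pc <= 0.75:
            return "connector_hub"
        return "kinless_hub"
    if pc <= 0.05:
        return "ultra_peripheral"
    if pc <= 0.62:
        return "peripheral"
    if pc < 0.80:
        return "non_hub_connector"
    return "non_hub_kinless"


def node_role_table(graph: nx.Graph, partition: Partition, *, weighted: bool = False) -> pd.DataFrame:
    """Per-node WC, PC and role; degree-0 nodes are classed ``isolated``."""
    rows = []
    for node in sorted(graph.nodes):
        if graph.degree(node) == 0:
            rows.append({"group": node, "community": partition.membership.get(node, UNASSIGNED),
                         "wc": 0.0, "pc": 0.0, "role": "isolated"})
            continue
        wc = within_community_degree(graph, partition, node, weighted=weighted)
        pc = participation_coefficient(graph, partition, node, weighted=weighted)
        rows.append({"group": node, "community": partition.membership[node],
                     "wc": wc, "pc": pc, "role": classify_role(wc, pc)})
    return pd.DataFrame(rows, columns=["group", "community", "wc", "pc", "role"])


def match_communities(
    partition_a: Partition,
    partition_b: Partition,
    threshold: float = 0.25,
) -> tuple[dict, dict]:
    """Give similar communities across two strata a shared number.

    Greedy maximum-Jaccard matching over the size->=2 communities: pairs are
    taken in decreasing Jaccard order (deterministic tie-break on community
    ids) while both sides are unmatched and Jaccard >= ``threshold``; matched
    pairs share a number, everything else gets a fresh one. The pairing is
    symmetric in the argument order.

    Returns ``(renumber_a, renumber_b)`` mapping original ids to shared ids.
    """
    pairs = []
    for ca, nodes_a in partition_a.communities.items():
        sa = set(nodes_a)
        for cb, nodes_b in partition_b.communities.items():
            sb = set(nodes_b)
            jac = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
            if jac >= threshold:
                pairs.append((jac, ca, cb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    map_a: dict = {}
    map_b: dict = {}
    next_id = 1
    for jac, ca, cb in pairs:
        if ca in map_a or cb in map_b:
            continue
        map_a[ca] = next_id
        map_b[cb] = next_id
        next_id += 1
    for ca in sorted(partition_a.communities):
        if ca not in map_a:
            map_a[ca] = next_id
            next_id += 1
    for cb in sorted(partition_b.communities):
        if cb not in map_b:
            map_b[cb] = next_id
            next_id += 1
    return map_a, map_b
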