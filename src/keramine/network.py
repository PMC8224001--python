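"""Protein sequence similarity network (SSN) and Louvain communities.

Nodes are proteases (three-strain queries plus the keratinase and
non-keratinase reference panels); an undirected edge joins two proteins when
the better of the two directed alignment E-values passes the threshold.  Edge
weight is -log10(E) capped at 300 (E = 0 maps to 300), the standard SSN
weighting.  Communities are detected with weighted Louvain; a query protein
is "keratinase-linked" when its community contains at least one functional
keratinase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .align import AlignmentHit
from .records import CATEGORY_KERATINASE, CATEGORY_QUERY, ProteinRecord

MAX_EDGE_WEIGHT = 300.0


def evalue_weight(evalue: float) -> float:
    if evalue <= 0.0:
        return MAX_EDGE_WEIGHT
    return min(MAX_EDGE_WEIGHT, -math.log10(evalue))


def build_network(
    hits: Iterable[AlignmentHit],
    threshold: float = 1e-40,
    records: Sequence[ProteinRecord] | None = None,
    unit_weights: bool = False,
) -> nx.Graph:
    """Build the similarity network from directed alignment hits.

    Bidirectional hits collapse to a single undirected edge keeping the
    minimum E-value (and the identity of that hit).  Self-hits are dropped.
    ``records`` adds isolated nodes and node attributes (strain, category).
    """
    graph = nx.Graph(threshold=threshold)
    if records is not None:
        for rec in records:
            graph.add_node(rec.id, strain=rec.strain, category=rec.category)
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        if hit.query == hit.subject:
            continue
        key = (hit.query, hit.subject) if hit.query < hit.subject else (
            hit.subject, hit.query
        )
        prev = best.get(key)
        if prev is None or hit.evalue < prev.evalue:
            best[key] = hit
    for (a, b), hit in best.items():
        if hit.evalue <= threshold:
            graph.add_edge(
                a, b,
                evalue=hit.evalue,
                identity_pct=hit.identity_pct,
                weight=1.0 if unit_weights else evalue_weight(hit.evalue),
            )
    return graph


@dataclass
class Community:
    id: int
    members: list[str]
    contains_functional_keratinase: bool = False
    contains_query: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def detect_communities(
    network: nx.Graph, resolution: float = 1.0, seed: int = 0,
    n_restarts: int = 8,
) -> tuple[list[Community], list[str]]:
    """Weighted Louvain community detection, deterministic for a fixed seed.

    Louvain is a greedy modularity maximizer whose result depends on node
    processing order, so the algorithm is restarted ``n_restarts`` times with
    seeds derived from ``seed`` and the highest-modularity partition is kept
    (ties keep the earlier restart).  Communities of size >= 2 are reported
    with ids 1.. by decreasing size (ties to the lexicographically smallest
    member); singleton nodes are returned separately.
    """
    if network.number_of_nodes() == 0:
        return [], []
    rng = np.random.default_rng(seed)
    partition = None
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        restart_seed = int(rng.integers(2**31))
        cand = nx.community.louvain_communities(
            network, weight="weight", resolution=resolution, seed=restart_seed
        )
        q = nx.community.modularity(
            network, cand, weight="weight", resolution=resolution
        ) if network.number_of_edges() else 0.0
        if q > best_q + 1e-12:
            best_q, partition = q, cand
    parts = sorted(
        (sorted(p) for p in partition), key=lambda p: (-len(p), p[0])
    )
    communities: list[Community] = []
    singletons: list[str] = []
    next_id = 1
    for members in parts:
        if len(members) < 2:
            singletons.extend(members)
            continue
        cats = {network.nodes[m].get("category") for m in members}
        communities.append(
            Community(
                id=next_id,
                members=members,
                contains_functional_keratinase=CATEGORY_KERATINASE in cats,
                contains_query=CATEGORY_QUERY in cats,
            )
        )
        next_id += 1
    return communities, sorted(singletons)


@dataclass
class LinkageResult:
    #: query ids sharing a community (or an edge, in direct-edge mode) with a
    #: functional keratinase.
    linked: set[str] = field(default_factory=set)
    per_strain_counts: dict[str, int] = field(default_factory=dict)
    #: id -> (best identity %, best evalue) to a keratinase in its community,
    #: over direct network edges; None entries mean no direct edge exists.
    best_hit: dict[str, tuple[float, float] | None] = field(default_factory=dict)


def link_keratinases(
    communities: Sequence[Community],
    network: nx.Graph,
    mode: str = "community",
) -> LinkageResult:
    """Flag query proteins linked to functional keratinases.

    ``mode="community"``: linked iff the protein's community contains a
    functional keratinase.  ``mode="direct-edge"``: a direct network edge to
    a keratinase is required.
    """
    if mode not in ("community", "direct-edge"):
        raise ValueError("mode must be 'community' or 'direct-edge'")
    result = LinkageResult()
    for comm in communities:
        keratinases = [
            m for m in comm.members
            if network.nodes[m].get("category") == CATEGORY_KERATINASE
        ]
        if not keratinases:
            continue
        for m in comm.members:
            if network.nodes[m].get("category") != CATEGORY_QUERY:
                continue
            direct = [
                (network.edges[m, k]["identity_pct"], network.edges[m, k]["evalue"])
                for k in keratinases if network.has_edge(m, k)
            ]
            if mode == "direct-edge" and not direct:
                continue
            result.linked.add(m)
            result.best_hit[m] = max(direct, key=lambda t: t[0]) if direct else None
            strain = network.nodes[m].get("strain", "")
            result.per_strain_counts[strain] = (
                result.per_strain_counts.get(strain, 0) + 1
            )
    return result


def annotate_network(
    network: nx.Graph,
    communities: Sequence[Community],
    linkage: LinkageResult,
) -> None:
    """Attach community ids and keratinase-linked flags as node attributes."""
    comm_of = {m: c.id for c in communities for m in c.members}
    for node in network.nodes:
        network.nodes[node]["community"] = comm_of.get(node, -1)
        network.nodes[node]["keratinase_linked"] = node in linkage.linked


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tevalue\tidentity_pct\tweight\n")
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data['evalue']:.3g}\t{data['identity_pct']:.2f}\t"
                f"{data['weight']:.3f}\n"
            )


def write_communities_table(
    communities: Sequence[Community], singletons: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("community_id\tmember\tsize\tcontains_keratinase\tcontains_query\n")
        for c in communities:
            for m in c.members:
                fh.write(
                    f"{c.id}\t{m}\t{c.size}\t{int(c.contains_functional_keratinase)}"
                    f"\t{int(c.contains_query)}\n"
                )
        for m in singletons:
            fh.write(f"singleton\t{m}\t1\t0\t0\n")
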