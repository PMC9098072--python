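"""Query-specific interaction networks and order-k process inheritance.

A network is built either for a set of immune processes (all proteins
annotated to them, plus the metabolites linked to those proteins) or for a
set of metabolites (the metabolites plus their protein partners).  Within a
network, metabolites inherit immune processes from proteins: at order 1
from their direct protein partners only, at orders 2 and 3 additionally
from proteins one or two protein-protein steps beyond (one
metabolite-protein hop followed by at most order-1 protein-protein hops).
Metabolite-metabolite edges never transmit processes.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

import networkx as nx

from .ingest import (
    MMI, PMI, PPI, AtlasDatabase, AtlasLookupError, Edge, EdgeSet,
)

logger = logging.getLogger("immetnet")

PROTEIN = "protein"
METABOLITE = "metabolite"

QUERY_BY_PROCESS = "by_process"
QUERY_BY_METABOLITE = "by_metabolite"


@dataclass
class InteractionNetwork:
    """A query-specific subgraph of the atlas.

    ``nodes`` maps node id to kind (``protein`` or ``metabolite``); edges
    are the atlas edges restricted to the node set.  Proteins with zero
    edges are retained but flagged in ``isolated_proteins``.
    """

    nodes: dict[str, str]
    edges: EdgeSet
    query_mode: str = QUERY_BY_PROCESS
    query_ids: frozenset = frozenset()
    isolated_proteins: frozenset = frozenset()

    def __post_init__(self) -> None:
        self._adj: dict[str, set] = {n: set() for n in self.nodes}
        for e in self.edges:
            self._adj[e.a].add(e.b)
            self._adj[e.b].add(e.a)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def metabolites(self) -> list[str]:
        return sorted(n for n, k in self.nodes.items() if k == METABOLITE)

    @property
    def proteins(self) -> list[str]:
        return sorted(n for n, k in self.nodes.items() if k == PROTEIN)

    def neighbors(self, node_id: str) -> frozenset:
        return frozenset(self._adj[node_id])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in sorted(self.nodes):
            g.add_node(node, kind=self.nodes[node])
        for e in self.edges:
            if e.confidence is not None:
                g.add_edge(e.a, e.b, edge_type=e.etype,
                           confidence=e.confidence)
            else:
                g.add_edge(e.a, e.b, edge_type=e.etype)
        return g

    @classmethod
    def from_edgelist(cls, nodes: dict[str, str],
                      edges: Iterable[tuple]) -> "InteractionNetwork":
        """Build a network from (a, b, etype[, confidence]) tuples (tests)."""
        eset = EdgeSet()
        for tup in edges:
            eset.add(*tup)
        return cls(nodes=dict(nodes), edges=eset)


def _restrict_edges(atlas: AtlasDatabase, proteins: set,
                    metabolites: set) -> EdgeSet:
    edges = EdgeSet()
    for e in atlas.edges:
        if e.etype == PPI and e.a in proteins and e.b in proteins:
            edges.add(e.a, e.b, PPI, e.confidence)
        elif e.etype == MMI and e.a in metabolites and e.b in metabolites:
            edges.add(e.a, e.b, MMI)
        elif e.etype == PMI:
            met, prot = (e.a, e.b) if e.a in atlas.metabolites else (e.b, e.a)
            if met in metabolites and prot in proteins:
                edges.add(met, prot, PMI)
    return edges


def _finish(atlas: AtlasDatabase, proteins: set, metabolites: set,
            mode: str, query_ids: Iterable[str]) -> InteractionNetwork:
    edges = _restrict_edges(atlas, proteins, metabolites)
    touched: set = set()
    for e in edges:
        touched.add(e.a)
        touched.add(e.b)
    isolated = frozenset(sorted(proteins - touched))
    if isolated:
        logger.info("network: %d isolated protein(s) retained but flagged",
                    len(isolated))
    nodes = {p: PROTEIN for p in sorted(proteins)}
    nodes.update({m: METABOLITE for m in sorted(metabolites)})
    return InteractionNetwork(
        nodes=nodes, edges=edges, query_mode=mode,
        query_ids=frozenset(query_ids), isolated_proteins=isolated,
    )


def build_process_network(atlas: AtlasDatabase,
                          process_ids: Iterable[str]) -> InteractionNetwork:
    """Network for one or more immune processes.

    Nodes are the proteins annotated to any queried process plus all
    metabolites linked to those proteins; edges are the atlas PPI among the
    proteins, PMI between them and the metabolites, and MMI among the
    metabolites.
    """
    process_ids = set(process_ids)
    for pid in sorted(process_ids):
        if pid not in atlas.ontology:
            raise AtlasLookupError(f"unknown process id {pid!r}")
    proteins: set = set()
    for pid in process_ids:
        proteins |= atlas.process_proteins(pid)
    metabolites: set = set()
    for prot in proteins:
        metabolites |= atlas.pmi_metabolites(prot)
    return _finish(atlas, proteins, metabolites, QUERY_BY_PROCESS,
                   process_ids)


def build_metabolite_network(atlas: AtlasDatabase,
                             metabolite_ids: Iterable[str]
                             ) -> InteractionNetwork:
    """Network for one or more metabolites of interest.

    Nodes are the query metabolites plus their protein partners.  A query
    metabolite with no protein partner stays in the network as a singleton;
    no process inheritance is possible for it.
    """
    metabolite_ids = set(metabolite_ids)
    for mid in sorted(metabolite_ids):
        if mid not in atlas.metabolites:
            raise AtlasLookupError(f"unknown metabolite id {mid!r}")
    proteins: set = set()
    for mid in metabolite_ids:
        partners = atlas.pmi_partners(mid)
        if not partners:
            logger.warning(
                "network: metabolite %s has no protein partner; no process "
                "inheritance is possible", mid,
            )
        proteins |= partners
    return _finish(atlas, proteins, set(metabolite_ids),
                   QUERY_BY_METABOLITE, metabolite_ids)


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

class Association(NamedTuple):
    metabolite_id: str
    process_id: str
    supporting_protein_ids: frozenset
    order_found: int


@dataclass
class AssociationSet:
    """Inherited (metabolite, process) pairs with their supporting proteins."""

    associations: list[Association] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {
            (a.metabolite_id, a.process_id): a for a in self.associations
        }

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[Association]:
        return iter(self.associations)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._index

    def pairs(self) -> frozenset:
        return frozenset(self._index)

    def get(self, metabolite_id: str,
            process_id: str) -> Optional[Association]:
        return self._index.get((metabolite_id, process_id))

    def support(self, metabolite_id: str, process_id: str) -> frozenset:
        a = self._index.get((metabolite_id, process_id))
        return a.supporting_protein_ids if a else frozenset()

    def by_metabolite(self, metabolite_id: str) -> list[Association]:
        return [a for a in self.associations
                if a.metabolite_id == metabolite_id]


def _adjacency(atlas: AtlasDatabase,
               network: Optional[InteractionNetwork],
               scope: str):
    """Return (pmi-partners, ppi-partners) lookup functions for *scope*."""
    if scope == "atlas" or network is None:
        return atlas.pmi_partners, atlas.ppi_partners
    pmi_adj: dict[str, set] = {}
    ppi_adj: dict[str, set] = {}
    for e in network.edges:
        if e.etype == PMI:
            met, prot = (e.a, e.b) if network.nodes[e.a] == METABOLITE \
                else (e.b, e.a)
            pmi_adj.setdefault(met, set()).add(prot)
        elif e.etype == PPI:
            ppi_adj.setdefault(e.a, set()).add(e.b)
            ppi_adj.setdefault(e.b, set()).add(e.a)
    return (lambda m: frozenset(pmi_adj.get(m, ())),
            lambda p: frozenset(ppi_adj.get(p, ())))


def inherit_processes(atlas: AtlasDatabase,
                      network: Optional[InteractionNetwork],
                      order: int,
                      scope: str = "network") -> AssociationSet:
    """Order-*order* inheritance of immune processes by metabolites.

    For each metabolite, the processes of every protein reachable by one
    metabolite-protein edge followed by at most ``order - 1``
    protein-protein edges are collected.  ``order_found`` records the
    minimal qualifying depth (the metabolite-protein hop counts as step 1);
    ``supporting_protein_ids`` lists every contributing protein.

    With ``scope="network"`` (default) only edges of the built network are
    traversed; ``scope="atlas"`` traverses the full atlas instead (used by
    gold-standard evaluation).  ``network=None`` runs atlas-wide inheritance
    over every metabolite with at least one protein partner.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"inheritance order must be 1, 2 or 3, got {order}")
    if scope not in ("network", "atlas"):
        raise ValueError(f"unknown inheritance scope {scope!r}")
    pmi_partners, ppi_partners = _adjacency(atlas, network, scope)
    if network is None:
        metabolites = sorted(
            m for m in atlas.metabolites.metabolites if atlas.pmi_partners(m)
        )
    else:
        metabolites = network.metabolites

    associations: list[Association] = []
    for met in metabolites:
        depth_of: dict[str, int] = {}
        frontier = deque((p, 1) for p in sorted(pmi_partners(met)))
        for p, _ in frontier:
            depth_of[p] = 1
        while frontier:
            prot, depth = frontier.popleft()
            if depth >= order:
                continue
            for nxt in sorted(ppi_partners(prot)):
                if nxt not in depth_of:
                    depth_of[nxt] = depth + 1
                    frontier.append((nxt, depth + 1))
        support: dict[str, set] = {}
        found_at: dict[str, int] = {}
        for prot, depth in depth_of.items():
            for proc in atlas.protein_processes(prot):
                support.setdefault(proc, set()).add(prot)
                if proc not in found_at or depth < found_at[proc]:
                    found_at[proc] = depth
        for proc in sorted(support):
            associations.append(Association(
                met, proc, frozenset(support[proc]), found_at[proc],
            ))
    return AssociationSet(associations=associations)
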