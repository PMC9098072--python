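"""Association scoring: centrality, precision, overrepresentation, biomarkers.

Four quantities are attached to every inherited (metabolite, process) pair:

* **harmonic closeness** of the metabolite in the query network -- the sum
  of reciprocal shortest-path hop distances to all other nodes (unreachable
  nodes contribute zero, so the score is well defined on disconnected
  graphs), normalized to the network size by dividing by ``n - 1``;
* **precision** -- the fraction of the metabolite's database interactions
  that fall inside the process network (``ratio`` mode, default), optionally
  divided by the process-network node count (``corrected`` mode);
* **Fisher's exact p-value** for overrepresentation of the association in
  the network relative to the database background, one-sided (greater) by
  default;
* **q-value** from Benjamini-Hochberg FDR correction pooled over all pairs
  of the run, with significance at q < 0.05.

Biomarker candidates are the significant pairs whose centrality and
precision both exceed the mean plus two (sample) standard deviations of the
significant set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ingest import AtlasDatabase, ConsistencyError, ValidationError
from .network import (
    AssociationSet, InteractionNetwork, build_process_network,
    inherit_processes,
)

logger = logging.getLogger("immetnet")

ONE_SIDED = "one_sided_greater"
TWO_SIDED = "two_sided"

RATIO = "ratio"
CORRECTED = "corrected"

DEFAULT_ALPHA = 0.05
DEFAULT_SD_MULTIPLIER = 2.0

TABLE_COLUMNS = ["metabolite_id", "process_id", "centrality", "precision",
                 "p", "q", "significant", "biomarker"]


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentralityScore:
    node_id: str
    raw: float
    normalized: float


def harmonic_closeness(network: InteractionNetwork,
                       node_id: str) -> CentralityScore:
    """Harmonic closeness of one node over unweighted shortest paths.

    ``raw = sum_{j != i} 1 / d(i, j)``; unreachable nodes contribute 0.
    ``normalized = raw / (n - 1)`` with ``n`` the network node count, which
    maps the score onto [0, 1].  A singleton network scores 0.
    """
    if node_id not in network.nodes:
        raise KeyError(f"node {node_id!r} not in network")
    g = _graph_of(network)
    raw = sum(1.0 / d
              for d in nx.single_source_shortest_path_length(g, node_id)
              .values() if d > 0)
    n = network.n_nodes
    normalized = raw / (n - 1) if n > 1 else 0.0
    return CentralityScore(node_id=node_id, raw=raw, normalized=normalized)


def _graph_of(network: InteractionNetwork) -> nx.Graph:
    g = getattr(network, "_nx_cache", None)
    if g is None:
        g = network.to_networkx()
        network._nx_cache = g
    return g


# ---------------------------------------------------------------------------
# precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionInputs:
    """Counts feeding the precision score of metabolite i for process j.

    ``N_ij``: interacting nodes of i inside the process-j network;
    ``N_i``: interacting nodes of i in the whole atlas;
    ``V_j``: node count of the process-j network.
    """

    N_ij: int
    N_i: int
    V_j: int


def precision_score(inputs: PrecisionInputs, mode: str = RATIO) -> float:
    """``ratio`` mode: N_ij / N_i.  ``corrected`` mode: N_ij / (N_i * V_j)."""
    if inputs.N_i <= 0:
        raise ValueError(
            "precision undefined for a metabolite with no interactions"
        )
    if not 0 <= inputs.N_ij <= inputs.N_i:
        raise ConsistencyError(
            f"invalid precision inputs: N_ij={inputs.N_ij}, N_i={inputs.N_i}"
        )
    if mode == RATIO:
        return inputs.N_ij / inputs.N_i
    if mode == CORRECTED:
        if inputs.V_j <= 0:
            raise ValueError("corrected precision needs a nonempty network")
        return inputs.N_ij / (inputs.N_i * inputs.V_j)
    raise ValueError(f"unknown precision mode {mode!r}")


def precision_inputs(atlas: AtlasDatabase, metabolite_id: str,
                     process_id: str,
                     process_network: Optional[InteractionNetwork] = None
                     ) -> PrecisionInputs:
    """Count a metabolite's interactions inside vs outside a process network."""
    pn = process_network or build_process_network(atlas, {process_id})
    neighbors = atlas.neighbors(metabolite_id)
    return PrecisionInputs(
        N_ij=len(neighbors & set(pn.nodes)),
        N_i=len(neighbors),
        V_j=pn.n_nodes,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency cell in {self}")


def fisher_p(table: ContingencyTable, sided: str = ONE_SIDED) -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    One-sided (greater): probability of tables at least as extreme toward
    enrichment (top-left cell >= observed) at fixed margins.  Two-sided:
    sum of point probabilities no larger than the observed one.  All
    arithmetic is exact-integer, so ties in the two-sided rule are exact
    and no overflow can occur.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        logger.warning("fisher_p: all-zero table; p = 1.0")
        return 1.0
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    weights = {x: math.comb(row1, x) * math.comb(row2, col1 - x)
               for x in range(lo, hi + 1)}
    denom = math.comb(n, col1)
    if sided == ONE_SIDED:
        num = sum(w for x, w in weights.items() if x >= a)
    elif sided == TWO_SIDED:
        observed = weights[a]
        num = sum(w for w in weights.values() if w <= observed)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return num / denom


def metabolite_contingency(atlas: AtlasDatabase,
                           network: InteractionNetwork,
                           metabolite_id: str, process_id: str,
                           order: int = 1,
                           _net: Optional[AssociationSet] = None,
                           _db: Optional[AssociationSet] = None
                           ) -> ContingencyTable:
    """Metabolite-based overrepresentation cells for one pair.

    ``a``: protein-mediated associations of the metabolite to the process in
    the network; ``b``: its associations to other processes in the network;
    ``c``: its database associations to the process minus ``a``; ``d``: the
    total number of its database process associations minus ``b``.
    Association multiplicities are supporting-protein counts at the run's
    inheritance order.
    """
    if metabolite_id not in network.nodes:
        raise KeyError(f"metabolite {metabolite_id!r} not in network")
    net = _net if _net is not None else inherit_processes(
        atlas, network, order, scope="network")
    db = _db if _db is not None else inherit_processes(
        atlas, None, order)
    a = len(net.support(metabolite_id, process_id))
    b = sum(len(assoc.supporting_protein_ids)
            for assoc in net.by_metabolite(metabolite_id)
            if assoc.process_id != process_id)
    db_specific = len(db.support(metabolite_id, process_id))
    db_total = sum(len(assoc.supporting_protein_ids)
                   for assoc in db.by_metabolite(metabolite_id))
    c = db_specific - a
    d = db_total - b
    if c < 0 or d < 0:
        raise ConsistencyError(
            f"network association counts exceed database counts for "
            f"({metabolite_id}, {process_id}): a={a}, b={b}, "
            f"db_specific={db_specific}, db_total={db_total}"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


def process_contingency(atlas: AtlasDatabase,
                        network: InteractionNetwork,
                        process_id: str) -> ContingencyTable:
    """Process-based overrepresentation cells.

    Appearances are protein-annotation instances: ``a`` counts the process
    among the network's proteins, ``b`` among all atlas proteins, ``c`` and
    ``d`` the corresponding counts over all other processes.
    """
    net_proteins = network.proteins
    a = sum(1 for p in net_proteins
            if process_id in atlas.protein_processes(p))
    b = len(atlas.process_proteins(process_id))
    if a == 0 and b == 0:
        raise ValidationError(
            f"process {process_id!r} has no annotations in network or atlas"
        )
    c = sum(len(atlas.protein_processes(p) - {process_id})
            for p in net_proteins)
    d = sum(len(rec.process_ids - {process_id})
            for rec in atlas.proteins.proteins.values())
    return ContingencyTable(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def adjust_fdr(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = list(p_values)
    if not p:
        return []
    if min(p) < 0 or max(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# the association table
# ---------------------------------------------------------------------------

def rank_associations(atlas: AtlasDatabase,
                      network: InteractionNetwork,
                      order: int = 1, *,
                      sided: str = ONE_SIDED,
                      precision_mode: str = RATIO,
                      alpha: float = DEFAULT_ALPHA,
                      sd_multiplier: float = DEFAULT_SD_MULTIPLIER
                      ) -> pd.DataFrame:
    """Score every inherited pair of the network and rank the result.

    Returns one row per (metabolite, process) pair with normalized
    centrality, precision, p, BH q, a significance flag at ``q < alpha``
    and a biomarker flag (see :func:`select_biomarkers`).  Rows are sorted
    by q ascending, ties broken by precision then centrality descending,
    then by metabolite id.
    """
    net_assoc = inherit_processes(atlas, network, order, scope="network")
    if not len(net_assoc):
        return pd.DataFrame(columns=TABLE_COLUMNS)
    db_assoc = inherit_processes(atlas, None, order)
    centrality = {
        m: harmonic_closeness(network, m).normalized
        for m in network.metabolites
    }
    pn_cache: dict[str, InteractionNetwork] = {}
    rows = []
    for assoc in net_assoc:
        m, j = assoc.metabolite_id, assoc.process_id
        if j not in pn_cache:
            pn_cache[j] = build_process_network(atlas, {j})
        inputs = precision_inputs(atlas, m, j, process_network=pn_cache[j])
        table = metabolite_contingency(atlas, network, m, j, order,
                                       _net=net_assoc, _db=db_assoc)
        rows.append({
            "metabolite_id": m,
            "process_id": j,
            "centrality": centrality[m],
            "precision": precision_score(inputs, mode=precision_mode),
            "p": fisher_p(table, sided=sided),
        })
    df = pd.DataFrame(rows)
    df["q"] = adjust_fdr(df["p"])
    df["significant"] = df["q"] < alpha
    df = df.sort_values(
        by=["q", "precision", "centrality", "metabolite_id", "process_id"],
        ascending=[True, False, False, True, True],
    ).reset_index(drop=True)
    flagged = select_biomarkers(df, sd_multiplier=sd_multiplier)
    key = set(zip(flagged["metabolite_id"], flagged["process_id"]))
    df["biomarker"] = [
        (m, j) in key for m, j in zip(df["metabolite_id"], df["process_id"])
    ]
    return df[TABLE_COLUMNS]


def select_biomarkers(table: pd.DataFrame,
                      sd_multiplier: float = DEFAULT_SD_MULTIPLIER
                      ) -> pd.DataFrame:
    """Significant rows exceeding mean + k*SD on centrality AND precision.

    The mean and sample (n-1) standard deviation are computed over the
    significant rows only; both inequalities are strict.  With fewer than
    two significant rows the SD is undefined and nothing is flagged.
    """
    sig = table[table["significant"]] if "significant" in table else table
    if len(sig) < 2:
        if len(table):
            logger.warning(
                "select_biomarkers: %d significant row(s); SD undefined, "
                "no biomarkers flagged", len(sig),
            )
        return sig.iloc[0:0]
    thr_c = sig["centrality"].mean() + sd_multiplier * sig["centrality"].std(ddof=1)
    thr_p = sig["precision"].mean() + sd_multiplier * sig["precision"].std(ddof=1)
    return sig[(sig["centrality"] > thr_c) & (sig["precision"] > thr_p)]


def summarize_superclass_distribution(table: pd.DataFrame,
                                      atlas: AtlasDatabase,
                                      group_map: dict[str, str],
                                      exclude_superclasses: Iterable[str] = ()
                                      ) -> pd.DataFrame:
    """Unique-metabolite counts per (process group, metabolite superclass).

    ``group_map`` maps process ids to user-defined group labels (e.g. a
    textbook categorization of immune responses); unmapped processes fall
    into group ``"other"``.  Superclass exclusion (e.g. lipids) is applied
    before counting.
    """
    excluded = set(exclude_superclasses)
    cells: dict[tuple[str, str], set] = {}
    for m, j in zip(table["metabolite_id"], table["process_id"]):
        superclass = atlas.metabolites[m].superclass
        if superclass in excluded:
            continue
        group = group_map.get(j, "other")
        cells.setdefault((group, superclass), set()).add(m)
    rows = [{"group": g, "superclass": s, "n_metabolites": len(mets)}
            for (g, s), mets in sorted(cells.items())]
    return pd.DataFrame(rows, columns=["group", "superclass", "n_metabolites"])
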