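"""Readers, inclusion filters, and the merged atlas store.

The atlas is assembled from five flat, database-style tables:

* ``go_terms.tsv``    -- immune-process ontology terms with parent links,
  restricted to the declared root ("immune system process", GO:0002376)
  and its descendants
* ``proteins.tsv``    -- protein catalog with immune-process annotations
* ``metabolites.tsv`` -- metabolite catalog with chemical taxonomy,
  biological/inorganic flags, protein cross-links and a reaction-compound id
* ``ppi.tsv``         -- protein-protein interactions with an integer
  confidence score on the 0-1000 scale
* ``reactions.tsv``   -- reaction participant lists, expanded all-vs-all
  into metabolite-metabolite interactions

Dialect is fixed: UTF-8, tab-separated, header row required, ``|`` as the
in-cell list separator, empty string meaning absent.

Inclusion rules applied here: metabolites must be biological and not
inorganic; metabolite-protein links pointing at proteins without any
immune-process annotation are dropped; protein-protein edges below the
confidence threshold are dropped.  All graphs are undirected; edges are
canonicalized (lexicographic endpoint order), deduplicated (maximum
confidence kept) and never contain self-loops.
"""

from __future__ import annotations

import logging
import os
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

import pandas as pd

logger = logging.getLogger("immetnet")

#: edge type tags
PPI = "PPI"  # protein-protein
PMI = "PMI"  # protein-metabolite
MMI = "MMI"  # metabolite-metabolite

LIST_SEP = "|"
DEFAULT_ROOT = "GO:0002376"
DEFAULT_MIN_CONFIDENCE = 400  # "medium" on the 0-1000 scale


class AtlasError(Exception):
    """Base class for atlas construction and analysis errors."""


class SchemaError(AtlasError):
    """An input table does not have the documented shape."""


class ValidationError(AtlasError):
    """An input table violates a content invariant."""


class ConsistencyError(AtlasError):
    """Derived quantities contradict each other (internal error)."""


class AtlasLookupError(AtlasError, KeyError):
    """An identifier does not resolve in the atlas."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return self.args[0] if self.args else ""


# ---------------------------------------------------------------------------
# table helpers
# ---------------------------------------------------------------------------

def _read_table(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _split(cell: str) -> list[str]:
    return [tok for tok in cell.split(LIST_SEP) if tok] if cell else []


def _join(tokens: Iterable[str]) -> str:
    return LIST_SEP.join(sorted(tokens))


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

class Edge(NamedTuple):
    a: str
    b: str
    etype: str
    confidence: Optional[int] = None


class EdgeSet:
    """Canonical, duplicate-free set of undirected typed edges.

    Endpoints are stored in lexicographic order; adding an existing edge
    keeps the maximum confidence; self-loops are silently refused.
    """

    def __init__(self, edges: Iterable[Edge] = ()):
        self._edges: dict[tuple[str, str, str], Edge] = {}
        for e in edges:
            self.add(e.a, e.b, e.etype, e.confidence)

    def add(self, a: str, b: str, etype: str,
            confidence: Optional[int] = None) -> bool:
        """Add an edge; returns True if a new edge was created."""
        if a == b:
            return False
        if b < a:
            a, b = b, a
        key = (a, b, etype)
        prev = self._edges.get(key)
        if prev is not None:
            if confidence is not None and (
                prev.confidence is None or confidence > prev.confidence
            ):
                self._edges[key] = Edge(a, b, etype, confidence)
            return False
        self._edges[key] = Edge(a, b, etype, confidence)
        return True

    def union(self, *others: "EdgeSet") -> "EdgeSet":
        merged = EdgeSet(self)
        for other in others:
            for e in other:
                merged.add(e.a, e.b, e.etype, e.confidence)
        return merged

    def of_type(self, etype: str) -> list[Edge]:
        return [e for e in self if e.etype == etype]

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self._edges.values()))

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, item) -> bool:
        if isinstance(item, Edge):
            a, b, etype = item.a, item.b, item.etype
        else:
            a, b, etype = item
        if b < a:
            a, b = b, a
        return (a, b, etype) in self._edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeSet):
            return NotImplemented
        return self._edges == other._edges

    def __repr__(self) -> str:
        return f"EdgeSet({len(self)} edges)"


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

class Term(NamedTuple):
    term_id: str
    name: str
    parent_ids: frozenset


@dataclass
class ProcessOntology:
    """Immune-process terms reachable from the declared root."""

    terms: dict[str, Term]
    root_id: str

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def process_ids(self) -> list[str]:
        """All non-root terms, i.e. the processes metabolites can inherit."""
        return sorted(t for t in self.terms if t != self.root_id)


def _detect_cycle(parents: dict[str, frozenset]) -> Optional[str]:
    """Return one member of a parent-link cycle, or None."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = dict.fromkeys(parents, WHITE)
    for start in sorted(parents):
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [
            (start, iter(sorted(parents[start])))
        ]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in parents:
                    continue
                if color[nxt] == GRAY:
                    return nxt
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(sorted(parents[nxt]))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return None


def read_go_terms(path: str | os.PathLike,
                  root_id: str = DEFAULT_ROOT) -> ProcessOntology:
    """Read ontology terms and restrict them to *root_id* and its descendants.

    Terms with no parent path to the root are dropped with a warning; a
    parent cycle raises :class:`ValidationError` naming one cycle member.
    """
    df = _read_table(path, ["term_id", "name", "parent_ids"])
    parents: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.term_id in parents:
            raise ValidationError(f"{path}: duplicate term_id {row.term_id!r}")
        parents[row.term_id] = frozenset(_split(row.parent_ids))
        names[row.term_id] = row.name
    if root_id not in parents:
        raise ValidationError(f"{path}: declared root {root_id!r} not present")
    member = _detect_cycle(parents)
    if member is not None:
        raise ValidationError(
            f"{path}: parent-link cycle detected involving {member!r}"
        )
    # reachability: walk child links from the root
    children: dict[str, set] = {t: set() for t in parents}
    for term, pids in parents.items():
        for pid in pids:
            if pid in children:
                children[pid].add(term)
    reachable = {root_id}
    queue = deque([root_id])
    while queue:
        for child in children[queue.popleft()]:
            if child not in reachable:
                reachable.add(child)
                queue.append(child)
    dropped = sorted(set(parents) - reachable)
    for term in dropped:
        logger.warning(
            "go_terms: term %s not reachable from root %s; dropped",
            term, root_id,
        )
    terms = {
        t: Term(t, names[t], parents[t] & reachable)
        for t in sorted(reachable)
    }
    onto = ProcessOntology(terms=terms, root_id=root_id)
    onto.n_rows = len(df)  # type: ignore[attr-defined]
    return onto


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

class Protein(NamedTuple):
    protein_id: str
    name: str
    process_ids: frozenset


@dataclass
class ProteinCatalog:
    proteins: dict[str, Protein]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)

    def __getitem__(self, protein_id: str) -> Protein:
        return self.proteins[protein_id]

    def immune_ids(self) -> list[str]:
        """Proteins carrying at least one immune-process annotation."""
        return sorted(
            p for p, rec in self.proteins.items() if rec.process_ids
        )


def read_proteins(path: str | os.PathLike,
                  ontology: ProcessOntology) -> ProteinCatalog:
    """Read the protein catalog; unknown process annotations are dropped.

    Proteins may legitimately end up with an empty process set -- they are
    retained in the catalog but excluded later from metabolite-protein
    linking.
    """
    df = _read_table(path, ["protein_id", "name", "process_ids"])
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate protein_id {dup.iloc[0]!r}")
    proteins: dict[str, Protein] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        annotated = _split(row.process_ids)
        kept = frozenset(p for p in annotated if p in ontology)
        if len(kept) < len(set(annotated)):
            n_dropped += len(set(annotated)) - len(kept)
            logger.warning(
                "proteins: %s: dropped %d annotation(s) not in the ontology",
                row.protein_id, len(set(annotated)) - len(kept),
            )
        proteins[row.protein_id] = Protein(row.protein_id, row.name, kept)
    catalog = ProteinCatalog(proteins=proteins)
    catalog.n_rows = len(df)  # type: ignore[attr-defined]
    catalog.n_dropped_annotations = n_dropped  # type: ignore[attr-defined]
    return catalog


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

class Metabolite(NamedTuple):
    metabolite_id: str
    name: str
    class_: str
    superclass: str
    protein_ids: frozenset
    compound_id: str


@dataclass
class MetaboliteCatalog:
    metabolites: dict[str, Metabolite]
    n_excluded: int = 0

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self.metabolites

    def __len__(self) -> int:
        return len(self.metabolites)

    def __getitem__(self, metabolite_id: str) -> Metabolite:
        return self.metabolites[metabolite_id]

    def compound_index(self) -> dict[str, str]:
        index: dict[str, str] = {}
        for mid in sorted(self.metabolites):
            cid = self.metabolites[mid].compound_id
            if not cid:
                continue
            if cid in index:
                logger.warning(
                    "metabolites: compound id %s maps to both %s and %s; "
                    "keeping %s", cid, index[cid], mid, index[cid],
                )
                continue
            index[cid] = mid
        return index


def _parse_flag(value: str, column: str, path) -> int:
    if value not in ("0", "1"):
        raise SchemaError(f"{path}: column {column} must be 0/1, got {value!r}")
    return int(value)


def read_metabolites(path: str | os.PathLike) -> MetaboliteCatalog:
    """Read the metabolite catalog and apply the inclusion filter.

    Rows flagged non-biological (synthetic drugs) or inorganic are excluded;
    the exclusion count is logged and recorded on the catalog.
    """
    df = _read_table(path, [
        "metabolite_id", "name", "class", "superclass",
        "is_biological", "is_inorganic", "protein_ids", "compound_id",
    ])
    dup = df["metabolite_id"][df["metabolite_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path}: duplicate metabolite_id {dup.iloc[0]!r}"
        )
    df = df.rename(columns={"class": "class_"})  # `class` is a keyword
    metabolites: dict[str, Metabolite] = {}
    n_excluded = 0
    for row in df.itertuples(index=False):
        biological = _parse_flag(row.is_biological, "is_biological", path)
        inorganic = _parse_flag(row.is_inorganic, "is_inorganic", path)
        if not biological or inorganic:
            n_excluded += 1
            continue
        metabolites[row.metabolite_id] = Metabolite(
            row.metabolite_id, row.name, row.class_,
            row.superclass, frozenset(_split(row.protein_ids)),
            row.compound_id,
        )
    if n_excluded:
        logger.info(
            "metabolites: excluded %d non-biological/inorganic row(s)",
            n_excluded,
        )
    catalog = MetaboliteCatalog(metabolites=metabolites, n_excluded=n_excluded)
    catalog.n_rows = len(df)  # type: ignore[attr-defined]
    return catalog


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def read_ppi(path: str | os.PathLike, catalog: ProteinCatalog,
             min_confidence: int = DEFAULT_MIN_CONFIDENCE) -> EdgeSet:
    """Read scored protein-protein interactions.

    Duplicate rows for the same pair keep the maximum score; the confidence
    threshold is then applied, so raising *min_confidence* never adds edges.
    """
    df = _read_table(path, ["protein_a", "protein_b", "combined_score"])
    best: dict[tuple[str, str], int] = {}
    n_self = n_missing = 0
    for row in df.itertuples(index=False):
        try:
            score = int(row.combined_score)
        except ValueError:
            raise SchemaError(
                f"{path}: non-integer combined_score {row.combined_score!r}"
            ) from None
        a, b = row.protein_a, row.protein_b
        if a == b:
            n_self += 1
            continue
        if a not in catalog or b not in catalog:
            n_missing += 1
            continue
        if b < a:
            a, b = b, a
        if score > best.get((a, b), -1):
            best[(a, b)] = score
    if n_self:
        logger.info("ppi: dropped %d self-loop row(s)", n_self)
    if n_missing:
        logger.info("ppi: dropped %d row(s) with unknown endpoint(s)",
                    n_missing)
    edges = EdgeSet()
    for (a, b), score in best.items():
        if score >= min_confidence:
            edges.add(a, b, PPI, score)
    edges.n_rows = len(df)  # type: ignore[attr-defined]
    return edges


def read_pmi(catalog_m: MetaboliteCatalog,
             catalog_p: ProteinCatalog) -> EdgeSet:
    """Derive metabolite-protein edges from the metabolite cross-links.

    Links pointing at proteins without any immune-process annotation are
    excluded (counted, not fatal), as are links to unknown protein ids.
    """
    edges = EdgeSet()
    n_unresolved = n_nonimmune = 0
    for mid in sorted(catalog_m.metabolites):
        for pid in sorted(catalog_m[mid].protein_ids):
            if pid not in catalog_p:
                n_unresolved += 1
                continue
            if not catalog_p[pid].process_ids:
                n_nonimmune += 1
                continue
            edges.add(mid, pid, PMI)
    if n_unresolved:
        logger.warning("pmi: %d link(s) to unresolvable protein ids dropped",
                       n_unresolved)
    if n_nonimmune:
        logger.info(
            "pmi: %d link(s) to proteins without immune-process annotations "
            "dropped", n_nonimmune,
        )
    edges.n_dropped_nonimmune = n_nonimmune  # type: ignore[attr-defined]
    return edges


def expand_reactions(path: str | os.PathLike,
                     catalog_m: MetaboliteCatalog) -> EdgeSet:
    """All-vs-all expansion of reactions into metabolite-metabolite edges.

    Each reactant-product combination becomes one undirected edge; self
    pairs are excluded and duplicates across reactions merged.  Compound ids
    that do not map to a retained metabolite are logged, not fatal.
    """
    df = _read_table(path, ["reaction_id", "reactant_ids", "product_ids"])
    index = catalog_m.compound_index()
    edges = EdgeSet()
    unmapped: set[str] = set()

    def _map(cids: list[str]) -> list[str]:
        out = []
        for cid in cids:
            mid = index.get(cid)
            if mid is None:
                unmapped.add(cid)
            else:
                out.append(mid)
        return out

    for row in df.itertuples(index=False):
        reactants = _map(_split(row.reactant_ids))
        products = _map(_split(row.product_ids))
        for r in reactants:
            for p in products:
                edges.add(r, p, MMI)
    if unmapped:
        logger.warning("reactions: %d unmapped compound id(s): %s",
                       len(unmapped), _join(sorted(unmapped)[:5]))
    edges.n_rows = len(df)  # type: ignore[attr-defined]
    return edges


# ---------------------------------------------------------------------------
# the merged atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasDatabase:
    """Merged store of processes, proteins, metabolites and typed edges.

    This is the "background" against which all network statistics are
    computed.  Neighbor and association lookups are index-backed and
    consistent with the edge set.
    """

    ontology: ProcessOntology
    proteins: ProteinCatalog
    metabolites: MetaboliteCatalog
    edges: EdgeSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ppi_adj: dict[str, set] = {}
        self._pmi_by_met: dict[str, set] = {}
        self._pmi_by_prot: dict[str, set] = {}
        self._mmi_adj: dict[str, set] = {}
        self._proc_proteins: dict[str, set] = {}
        for e in self.edges:
            if e.etype == PPI:
                self._ppi_adj.setdefault(e.a, set()).add(e.b)
                self._ppi_adj.setdefault(e.b, set()).add(e.a)
            elif e.etype == PMI:
                met, prot = (e.a, e.b) if e.a in self.metabolites else (e.b, e.a)
                self._pmi_by_met.setdefault(met, set()).add(prot)
                self._pmi_by_prot.setdefault(prot, set()).add(met)
            else:
                self._mmi_adj.setdefault(e.a, set()).add(e.b)
                self._mmi_adj.setdefault(e.b, set()).add(e.a)
        for pid, rec in self.proteins.proteins.items():
            for proc in rec.process_ids:
                self._proc_proteins.setdefault(proc, set()).add(pid)

    # -- lookups ----------------------------------------------------------

    def pmi_partners(self, metabolite_id: str) -> frozenset:
        return frozenset(self._pmi_by_met.get(metabolite_id, ()))

    def pmi_metabolites(self, protein_id: str) -> frozenset:
        return frozenset(self._pmi_by_prot.get(protein_id, ()))

    def ppi_partners(self, protein_id: str) -> frozenset:
        return frozenset(self._ppi_adj.get(protein_id, ()))

    def mmi_partners(self, metabolite_id: str) -> frozenset:
        return frozenset(self._mmi_adj.get(metabolite_id, ()))

    def neighbors(self, node_id: str) -> frozenset:
        """All interacting nodes of *node_id*, regardless of edge type."""
        if node_id in self.metabolites:
            return self.pmi_partners(node_id) | self.mmi_partners(node_id)
        return self.ppi_partners(node_id) | self.pmi_metabolites(node_id)

    def protein_processes(self, protein_id: str) -> frozenset:
        return self.proteins[protein_id].process_ids

    def process_proteins(self, process_id: str) -> frozenset:
        return frozenset(self._proc_proteins.get(process_id, ()))

    @property
    def process_ids(self) -> list[str]:
        return self.ontology.process_ids


def assemble_atlas(ontology: ProcessOntology,
                   proteins: ProteinCatalog,
                   metabolites: MetaboliteCatalog,
                   ppi: EdgeSet | None = None,
                   pmi: EdgeSet | None = None,
                   mmi: EdgeSet | None = None,
                   provenance: dict | None = None) -> AtlasDatabase:
    """Merge validated components into an :class:`AtlasDatabase`.

    Raises :class:`ValidationError` on dangling edge endpoints or on
    metabolite-protein edges whose protein carries no immune process.
    """
    edges = EdgeSet()
    for eset in (ppi, pmi, mmi):
        if eset is not None:
            for e in eset:
                edges.add(e.a, e.b, e.etype, e.confidence)
    for e in edges:
        if e.etype == PPI:
            if e.a not in proteins or e.b not in proteins:
                raise ValidationError(f"dangling PPI endpoint in {e}")
        elif e.etype == MMI:
            if e.a not in metabolites or e.b not in metabolites:
                raise ValidationError(f"dangling MMI endpoint in {e}")
        else:
            met, prot = (e.a, e.b) if e.a in metabolites else (e.b, e.a)
            if met not in metabolites or prot not in proteins:
                raise ValidationError(f"dangling PMI endpoint in {e}")
            if not proteins[prot].process_ids:
                raise ValidationError(
                    f"PMI edge {e} touches protein {prot} with no "
                    "immune-process annotation"
                )
    return AtlasDatabase(
        ontology=ontology, proteins=proteins, metabolites=metabolites,
        edges=edges, provenance=dict(provenance or {}),
    )


def load_atlas(go_terms: str, proteins: str, metabolites: str,
               ppi: str, reactions: str,
               root_id: str = DEFAULT_ROOT,
               min_confidence: int = DEFAULT_MIN_CONFIDENCE) -> AtlasDatabase:
    """Read the five tables and assemble the atlas in one call."""
    onto = read_go_terms(go_terms, root_id=root_id)
    prot = read_proteins(proteins, onto)
    mets = read_metabolites(metabolites)
    ppi_edges = read_ppi(ppi, prot, min_confidence=min_confidence)
    pmi_edges = read_pmi(mets, prot)
    mmi_edges = expand_reactions(reactions, mets)
    provenance = {
        str(go_terms): onto.n_rows,
        str(proteins): prot.n_rows,
        str(metabolites): mets.n_rows,
        str(ppi): ppi_edges.n_rows,
        str(reactions): mmi_edges.n_rows,
    }
    return assemble_atlas(onto, prot, mets, ppi_edges, pmi_edges, mmi_edges,
                          provenance=provenance)


# ---------------------------------------------------------------------------
# writers (round-trip support)
# ---------------------------------------------------------------------------

def write_atlas(atlas: AtlasDatabase, out_dir: str | os.PathLike) -> dict:
    """Write an atlas back to the five table formats.

    Re-reading the written tables with :func:`load_atlas` (same root and any
    threshold <= the stored confidences) reproduces equal node and edge sets.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, f"{name}.tsv")
             for name in ("go_terms", "proteins", "metabolites",
                          "ppi", "reactions")}

    rows = [{"term_id": t.term_id, "name": t.name,
             "parent_ids": _join(t.parent_ids)}
            for t in (atlas.ontology.terms[k]
                      for k in sorted(atlas.ontology.terms))]
    _write_tsv(paths["go_terms"], rows, ["term_id", "name", "parent_ids"])

    rows = [{"protein_id": p.protein_id, "name": p.name,
             "process_ids": _join(p.process_ids)}
            for p in (atlas.proteins[k]
                      for k in sorted(atlas.proteins.proteins))]
    _write_tsv(paths["proteins"], rows, ["protein_id", "name", "process_ids"])

    rows = [{"metabolite_id": m.metabolite_id, "name": m.name,
             "class": m.class_, "superclass": m.superclass,
             "is_biological": "1", "is_inorganic": "0",
             "protein_ids": _join(m.protein_ids),
             "compound_id": m.compound_id}
            for m in (atlas.metabolites[k]
                      for k in sorted(atlas.metabolites.metabolites))]
    _write_tsv(paths["metabolites"], rows,
               ["metabolite_id", "name", "class", "superclass",
                "is_biological", "is_inorganic", "protein_ids",
                "compound_id"])

    rows = [{"protein_a": e.a, "protein_b": e.b,
             "combined_score": str(e.confidence)}
            for e in atlas.edges.of_type(PPI)]
    _write_tsv(paths["ppi"], rows, ["protein_a", "protein_b",
                                    "combined_score"])

    rxn_rows = []
    for i, e in enumerate(atlas.edges.of_type(MMI), start=1):
        ca = atlas.metabolites[e.a].compound_id
        cb = atlas.metabolites[e.b].compound_id
        if not ca or not cb:
            raise ValidationError(
                f"cannot serialize MMI edge {e}: endpoint lacks a compound id"
            )
        rxn_rows.append({"reaction_id": f"R{i:06d}",
                         "reactant_ids": ca, "product_ids": cb})
    _write_tsv(paths["reactions"], rxn_rows,
               ["reaction_id", "reactant_ids", "product_ids"])
    return paths


def _write_tsv(path: str, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in columns) + "\n")
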