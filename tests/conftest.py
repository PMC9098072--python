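import os

import pytest

import immetnet as im


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    im.tcell_toy(d)
    return d


@pytest.fixture(scope="session")
def toy_atlas(toy_dir):
    return load_fixture_atlas(toy_dir)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Default-configuration synthetic atlas with planted truths."""
    d = tmp_path_factory.mktemp("fixture")
    result = im.generate_fixture(im.FixtureConfig(seed=1), d)
    return load_fixture_atlas(d), result.truth


@pytest.fixture(scope="session")
def default_scored(default_fixture):
    """Atlas-wide first-order association table of the default fixture."""
    atlas, truth = default_fixture
    network = im.build_process_network(atlas, atlas.process_ids)
    table = im.rank_associations(atlas, network, 1)
    return atlas, truth, table


def load_fixture_atlas(out_dir):
    from immetnet.cli import build_atlas, load_manifest
    return build_atlas(load_manifest(os.path.join(out_dir, "manifest.json")))


def small_config(seed, **overrides):
    """A compact unplanted configuration for property sweeps."""
    params = dict(
        seed=seed, n_processes=6, n_proteins=24, n_metabolites=14,
        frac_immune_proteins=0.7, ppi_density=0.15, pmi_per_metabolite=1.5,
        n_reactions=4, n_planted_committed=0, n_planted_isolated=1,
        n_planted_enriched=0, n_planted_excluded=0,
    )
    params.update(overrides)
    return im.FixtureConfig(**params)


def mini_atlas(proteins, metabolites, ppi=(), mmi=()):
    """Assemble a tiny atlas directly from dicts (no files).

    *proteins*: protein id -> iterable of process ids;
    *metabolites*: metabolite id -> iterable of partner protein ids;
    *ppi*: (a, b, score) triples; *mmi*: (a, b) pairs.
    """
    root = im.ingest.DEFAULT_ROOT
    proc_ids = sorted({p for procs in proteins.values() for p in procs})
    terms = {root: im.ingest.Term(root, "root", frozenset())}
    for pid in proc_ids:
        terms[pid] = im.ingest.Term(pid, pid, frozenset({root}))
    onto = im.ProcessOntology(terms=terms, root_id=root)
    pcat = im.ProteinCatalog(proteins={
        pid: im.ingest.Protein(pid, pid, frozenset(procs))
        for pid, procs in proteins.items()
    })
    mcat = im.MetaboliteCatalog(metabolites={
        mid: im.ingest.Metabolite(mid, mid, "cls", "superclass",
                                  frozenset(partners), f"C{mid}")
        for mid, partners in metabolites.items()
    })
    ppi_edges = im.EdgeSet()
    for a, b, score in ppi:
        ppi_edges.add(a, b, im.PPI, score)
    pmi_edges = im.read_pmi(mcat, pcat)
    mmi_edges = im.EdgeSet()
    for a, b in mmi:
        mmi_edges.add(a, b, im.MMI)
    return im.assemble_atlas(onto, pcat, mcat, ppi_edges, pmi_edges,
                             mmi_edges)


def write_tsv(path, text):
    path.write_text(text.replace("    ", "\t"), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bfs_harmonic(adj, node, n_nodes):
    """Brute-force harmonic closeness from an adjacency dict."""
    from collections import deque
    dist = {node: 0}
    queue = deque([node])
    while queue:
        cur = queue.popleft()
        for nxt in adj.get(cur, ()):
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                queue.append(nxt)
    raw = sum(1.0 / d for d in dist.values() if d > 0)
    return raw, raw / (n_nodes - 1) if n_nodes > 1 else 0.0


def fisher_enumeration(a, b, c, d, sided):
    """Exact-rational Fisher p by enumerating all tables at fixed margins."""
    from fractions import Fraction
    from math import factorial

    def point(x):
        cells = (x, a + b - x, a + c - x, d - a + x)
        if min(cells) < 0:
            return None
        num = (factorial(a + b) * factorial(c + d) * factorial(a + c)
               * factorial(b + d))
        den = factorial(a + b + c + d)
        for cell in cells:
            den *= factorial(cell)
        return Fraction(num, den)

    probs = {}
    for x in range(0, a + b + c + d + 1):
        p = point(x)
        if p is not None:
            probs[x] = p
    if sided == "one_sided_greater":
        total = sum(p for x, p in probs.items() if x >= a)
    else:
        observed = probs[a]
        total = sum(p for p in probs.values() if p <= observed)
    return float(total)


def walk_inheritance(atlas, pmi_adj, ppi_adj, metabolite, order):
    """Exhaustive walk enumeration: 1 PMI hop + up to order-1 PPI hops."""
    found = {}
    # unrestricted walks explode on dense graphs; revisiting a protein at an
    # equal-or-deeper depth cannot discover anything new, so prune there
    best = {}

    def visit_bounded(protein, depth):
        if best.get(protein, 99) <= depth:
            return
        best[protein] = depth
        for proc in atlas.protein_processes(protein):
            found.setdefault(proc, set()).add(protein)
        if depth < order:
            for nxt in ppi_adj(protein):
                visit_bounded(nxt, depth + 1)

    for protein in pmi_adj(metabolite):
        visit_bounded(protein, 1)
    return found
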