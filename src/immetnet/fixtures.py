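"""Seeded synthetic atlas inputs with planted, recoverable structure.

:func:`generate_fixture` writes the five ingest tables plus a
``planted_truth.json`` manifest.  The planted structure mirrors what the
downstream statistics are supposed to recover:

* *committed* metabolites are wired exclusively to the proteins of one
  dedicated process, so their ratio-precision in that process is exactly
  1.0 and they rank first in its network;
* the first committed metabolite doubles as the planted *outlier* pair: its
  exclusive neighborhood is enlarged far beyond everything else, so it is
  the unique association exceeding the mean + 2 SD biomarker threshold on
  both centrality and precision among the significant set;
* *enriched* metabolites share one dedicated process with most (but not
  all) of their interactions inside it -- strongly overrepresented, hence
  significant, with clustered sub-maximal precision and centrality; they
  populate the significant set so the biomarker threshold has a
  nondegenerate baseline;
* *isolated* metabolites have zero protein links and therefore can never
  inherit a process;
* optional *excluded* rows (non-biological or inorganic) exercise the
  metabolite inclusion filter.

Planted clusters are kept as detached graph components: the random
(Erdos-Renyi + per-process hub star) protein-protein layer spans only the
general, non-planted immune proteins, so planted centralities are
analytically predictable for any seed.  A single integer seed governs all
randomness and identical seed + config yields byte-identical files.

:func:`tcell_toy` writes a fixed miniature atlas analogous to a
T-cell-immunity process network: five metabolites sharing one hub-protein
neighbor set (hence one centrality value), one of them interacting with no
protein outside the process (precision 1.0), and three nucleotide-like
metabolites on peripheral proteins -- eight metabolites in the process
network in total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .ingest import DEFAULT_MIN_CONFIDENCE, DEFAULT_ROOT, AtlasError

logger = logging.getLogger("immetnet")


class ConfigError(AtlasError):
    """A fixture configuration requests an impossible plant."""


# plant geometry; chosen so planted-truth recovery is analytic, not tuned
OUTLIER_DEGREE = 40          # exclusive partners of the outlier metabolite
COMMITTED_DEGREE = 3         # exclusive partners of other committed metabolites
DECOY_POOL_SIZE = 14         # proteins of the shared enriched process
DECOY_IN_DEGREE = 12         # in-process partners per enriched metabolite
DECOY_OUT_DEGREES = (3, 4, 5)  # out-of-process partners, cycled
PLANTED_PPI_SCORE = 900

DEFAULT_SUPERCLASSES = (
    "Organic acids and derivatives",
    "Organic nitrogen compounds",
    "Organic oxygen compounds",
    "Nucleosides, nucleotides, and analogues",
    "Benzenoids",
)

FILE_NAMES = ("go_terms", "proteins", "metabolites", "ppi", "reactions")


@dataclass
class FixtureConfig:
    seed: int = 0
    n_processes: int = 12
    n_proteins: int = 140
    n_metabolites: int = 50
    frac_immune_proteins: float = 0.75
    ppi_density: float = 0.05
    pmi_per_metabolite: float = 2.0
    n_reactions: int = 12
    n_planted_committed: int = 3
    n_planted_isolated: int = 2
    n_planted_enriched: int = 10
    n_planted_excluded: int = 0
    superclass_labels: tuple = DEFAULT_SUPERCLASSES

    def __post_init__(self) -> None:
        counts = {
            "n_processes": self.n_processes,
            "n_proteins": self.n_proteins,
            "n_metabolites": self.n_metabolites,
            "n_reactions": self.n_reactions,
            "n_planted_committed": self.n_planted_committed,
            "n_planted_isolated": self.n_planted_isolated,
            "n_planted_enriched": self.n_planted_enriched,
            "n_planted_excluded": self.n_planted_excluded,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        for name, value in (("frac_immune_proteins",
                             self.frac_immune_proteins),
                            ("ppi_density", self.ppi_density)):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.pmi_per_metabolite < 0:
            raise ConfigError("pmi_per_metabolite must be >= 0")
        if not self.superclass_labels:
            raise ConfigError("superclass_labels must be nonempty")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FixtureConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown fixture config key(s): "
                              f"{sorted(unknown)}")
        if "superclass_labels" in data:
            data["superclass_labels"] = tuple(data["superclass_labels"])
        return cls(**data)


@dataclass
class FixtureResult:
    out_dir: str
    paths: dict
    truth: dict


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_fixture(config: FixtureConfig,
                     out_dir: str | os.PathLike) -> FixtureResult:
    """Write the five ingest tables, a build manifest and the planted truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    has_decoys = cfg.n_planted_enriched > 0

    # ---- processes -------------------------------------------------------
    n_reserved = cfg.n_planted_committed + (1 if has_decoys else 0)
    if cfg.n_processes < n_reserved + 1:
        raise ConfigError(
            f"n_processes={cfg.n_processes} too small: need at least "
            f"{n_reserved + 1} (planted processes plus one background)"
        )
    proc_ids = [f"GO:8{i:06d}" for i in range(1, cfg.n_processes + 1)]
    committed_procs = proc_ids[:cfg.n_planted_committed]
    decoy_proc = proc_ids[cfg.n_planted_committed] if has_decoys else None
    background_procs = proc_ids[n_reserved:]

    # ---- proteins --------------------------------------------------------
    proteins: list[tuple[str, tuple]] = []  # (id, sorted process ids)

    def _new_proteins(count: int, procs: tuple) -> list[str]:
        start = len(proteins) + 1
        ids = [f"P{start + k:05d}" for k in range(count)]
        proteins.extend((pid, tuple(sorted(procs))) for pid in ids)
        return ids

    outlier_prots: list[str] = []
    committed_prots: list[list[str]] = []
    for i, proc in enumerate(committed_procs):
        degree = OUTLIER_DEGREE if i == 0 else COMMITTED_DEGREE
        ids = _new_proteins(degree, (proc,))
        committed_prots.append(ids)
        if i == 0:
            outlier_prots = ids
    pool_prots = _new_proteins(DECOY_POOL_SIZE, (decoy_proc,)) \
        if has_decoys else []
    decoy_out_prots: list[list[str]] = []
    for i in range(cfg.n_planted_enriched):
        k = DECOY_OUT_DEGREES[i % len(DECOY_OUT_DEGREES)]
        bg = background_procs[i % len(background_procs)]
        decoy_out_prots.append(_new_proteins(k, (bg,)))

    n_remaining = cfg.n_proteins - len(proteins)
    if n_remaining < 0:
        raise ConfigError(
            f"n_proteins={cfg.n_proteins} too small for the requested "
            f"plants (need at least {len(proteins)})"
        )
    n_general_immune = int(round(cfg.frac_immune_proteins * n_remaining))
    if cfg.n_planted_committed and not outlier_prots:
        raise ConfigError("committed metabolites requested but no immune "
                          "proteins can be allocated")
    general_immune: list[str] = []
    for _ in range(n_general_immune):
        n_ann = int(rng.integers(1, 3))
        procs = rng.choice(background_procs, size=min(n_ann,
                           len(background_procs)), replace=False)
        general_immune.extend(_new_proteins(1, tuple(procs)))
    general_plain = _new_proteins(n_remaining - n_general_immune, ())
    general_all = general_immune + general_plain

    # ---- metabolites -----------------------------------------------------
    n_planted_mets = (cfg.n_planted_committed + cfg.n_planted_enriched
                      + cfg.n_planted_isolated + cfg.n_planted_excluded)
    n_background_mets = cfg.n_metabolites - n_planted_mets
    if n_background_mets < 0:
        raise ConfigError(
            f"n_metabolites={cfg.n_metabolites} too small for the requested "
            f"plants (need at least {n_planted_mets})"
        )

    met_rows: list[dict] = []
    labels = list(cfg.superclass_labels)

    def _new_met(name: str, partners: tuple, superclass: str,
                 biological: int = 1, inorganic: int = 0) -> str:
        idx = len(met_rows) + 1
        mid = f"M{idx:05d}"
        met_rows.append({
            "metabolite_id": mid, "name": name,
            "class": f"{superclass} subclass", "superclass": superclass,
            "is_biological": str(biological), "is_inorganic": str(inorganic),
            "protein_ids": "|".join(sorted(partners)),
            "compound_id": f"C{idx:05d}",
        })
        return mid

    committed_mets = [
        _new_met(f"committed metabolite {i + 1}", tuple(committed_prots[i]),
                 labels[i % len(labels)])
        for i in range(cfg.n_planted_committed)
    ]
    decoy_mets = []
    for i in range(cfg.n_planted_enriched):
        picks = sorted(rng.choice(pool_prots, size=DECOY_IN_DEGREE,
                                  replace=False))
        decoy_mets.append(_new_met(
            f"enriched metabolite {i + 1}",
            tuple(picks) + tuple(decoy_out_prots[i]),
            labels[i % len(labels)],
        ))
    isolated_mets = [
        _new_met(f"isolated metabolite {i + 1}", (),
                 labels[i % len(labels)])
        for i in range(cfg.n_planted_isolated)
    ]
    background_mets = []
    for i in range(n_background_mets):
        count = min(int(rng.poisson(cfg.pmi_per_metabolite)), 4,
                    len(general_all))
        partners = tuple(sorted(rng.choice(general_all, size=count,
                                           replace=False))) if count else ()
        superclass = str(rng.choice(labels))
        background_mets.append(_new_met(
            f"background metabolite {i + 1}", partners, superclass,
        ))
    excluded_mets = []
    for i in range(cfg.n_planted_excluded):
        partners = (general_all[i % len(general_all)],) if general_all else ()
        excluded_mets.append(_new_met(
            f"excluded metabolite {i + 1}", partners,
            labels[i % len(labels)],
            # alternate the two exclusion reasons: synthetic vs inorganic
            biological=i % 2, inorganic=i % 2,
        ))

    # ---- protein-protein layer ------------------------------------------
    ppi_rows: dict[tuple[str, str], int] = {}

    def _add_ppi(a: str, b: str, score: int) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if score > ppi_rows.get(key, -1):
            ppi_rows[key] = score

    for ids in committed_prots:
        for other in ids[1:]:
            _add_ppi(ids[0], other, PLANTED_PPI_SCORE)  # hub star
    if pool_prots:
        for other in pool_prots[1:]:
            _add_ppi(pool_prots[0], other, PLANTED_PPI_SCORE)
    proc_members: dict[str, list] = {p: [] for p in background_procs}
    general_set = set(general_immune)
    for pid, procs in proteins:
        if pid in general_set:
            for proc in procs:
                proc_members[proc].append(pid)
    for proc in background_procs:
        members = sorted(proc_members[proc])
        for other in members[1:]:
            _add_ppi(members[0], other, PLANTED_PPI_SCORE)
    ordered = sorted(general_immune)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if rng.random() < cfg.ppi_density:
                _add_ppi(a, b, int(rng.integers(150, 1000)))

    # ---- reactions -------------------------------------------------------
    compound_of = {row["metabolite_id"]: row["compound_id"]
                   for row in met_rows}
    rxn_rows: list[dict] = []
    participants = background_mets
    for r in range(cfg.n_reactions):
        if r == 0 and isolated_mets and participants:
            reactants = [isolated_mets[0]]
            products = [participants[0]]
        elif len(participants) >= 2:
            n_r = int(rng.integers(1, 3))
            n_p = int(rng.integers(1, 3))
            size = min(n_r + n_p, len(participants))
            if size < 2:
                continue
            chosen = list(rng.choice(participants, size=size, replace=False))
            reactants, products = chosen[:max(1, size - n_p)], \
                chosen[max(1, size - n_p):]
            if not products:
                continue
        else:
            continue
        rxn_rows.append({
            "reaction_id": f"R{len(rxn_rows) + 1:05d}",
            "reactant_ids": "|".join(compound_of[m] for m in reactants),
            "product_ids": "|".join(compound_of[m] for m in products),
        })

    # ---- write -----------------------------------------------------------
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, f"{name}.tsv")
             for name in FILE_NAMES}

    go_rows = [{"term_id": DEFAULT_ROOT, "name": "immune system process",
                "parent_ids": ""}]
    go_rows += [{"term_id": pid, "name": f"immune process {i + 1}",
                 "parent_ids": DEFAULT_ROOT}
                for i, pid in enumerate(proc_ids)]
    _write(paths["go_terms"], go_rows, ["term_id", "name", "parent_ids"])

    prot_rows = [{"protein_id": pid, "name": f"protein {pid[1:]}",
                  "process_ids": "|".join(procs)}
                 for pid, procs in proteins]
    _write(paths["proteins"], prot_rows, ["protein_id", "name",
                                          "process_ids"])

    _write(paths["metabolites"], met_rows,
           ["metabolite_id", "name", "class", "superclass", "is_biological",
            "is_inorganic", "protein_ids", "compound_id"])

    _write(paths["ppi"],
           [{"protein_a": a, "protein_b": b, "combined_score": str(s)}
            for (a, b), s in sorted(ppi_rows.items())],
           ["protein_a", "protein_b", "combined_score"])

    _write(paths["reactions"], rxn_rows,
           ["reaction_id", "reactant_ids", "product_ids"])

    manifest = {name: f"{name}.tsv" for name in FILE_NAMES}
    manifest["root_id"] = DEFAULT_ROOT
    manifest["min_confidence"] = DEFAULT_MIN_CONFIDENCE
    paths["manifest"] = os.path.join(out_dir, "manifest.json")
    _write_json(paths["manifest"], manifest)

    truth = {
        "seed": cfg.seed,
        "committed": dict(zip(committed_mets, committed_procs)),
        "outlier": ([committed_mets[0], committed_procs[0]]
                    if committed_mets else None),
        "enriched": {m: decoy_proc for m in decoy_mets},
        "isolated": isolated_mets,
        "excluded": excluded_mets,
    }
    paths["planted_truth"] = os.path.join(out_dir, "planted_truth.json")
    _write_json(paths["planted_truth"], truth)
    return FixtureResult(out_dir=str(out_dir), paths=paths, truth=truth)


def _write(path: str, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in columns) + "\n")


def _write_json(path: str, data: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# the packaged miniature atlas
# ---------------------------------------------------------------------------

TOY_PROCESS = "GO:0002711"  # positive regulation of T cell-mediated immunity

_TOY_TABLES = {
    "go_terms": """\
term_id	name	parent_ids
GO:0002376	immune system process
GO:0002711	positive regulation of T cell-mediated immunity	GO:0002376
GO:0006955	immune response	GO:0002376
GO:0019882	antigen processing and presentation	GO:0002376
""",
    "proteins": """\
protein_id	name	process_ids
P10001	TCRA	GO:0002711|GO:0006955
P10002	TCRB	GO:0002711|GO:0006955
P10003	CD3E	GO:0002711
P10004	ICAM1	GO:0002711
P10005	ITGAL	GO:0002711
P10006	ORPHAN1	GO:0002711
P20001	NFKB1	GO:0006955
P20002	TAP1	GO:0019882
P20003	TAP2	GO:0019882
""",
    "metabolites": """\
metabolite_id	name	class	superclass	is_biological	is_inorganic	protein_ids	compound_id
M00001	sphingosine-like	Sphingoid bases	Organic nitrogen compounds	1	0	P10001|P10002|P10003|P20001|P20002	C00001
M00002	sphinganine-like	Sphingoid bases	Organic nitrogen compounds	1	0	P10001|P10002|P10003|P20001	C00002
M00003	phytosphingosine-like	Sphingoid bases	Organic nitrogen compounds	1	0	P10001|P10002|P10003|P20002	C00003
M00004	dihydroceramide-like	Ceramides	Organic acids and derivatives	1	0	P10001|P10002|P10003|P20003	C00004
M00005	dehydrosphinganine-like	Sphingoid bases	Organic oxygen compounds	1	0	P10001|P10002|P10003	C00005
M00006	adenosylmethionine-like	Nucleosides	Nucleosides, nucleotides, and analogues	1	0	P10004|P20001	C00006
M00007	adp-like	Nucleotides	Nucleosides, nucleotides, and analogues	1	0	P10004|P10005|P20001|P20002	C00007
M00008	atp-like	Nucleotides	Nucleosides, nucleotides, and analogues	1	0	P10005|P20001|P20002	C00008
M00009	glucose-like	Sugars	Organic oxygen compounds	1	0	P20001	C00009
""",
    "ppi": """\
protein_a	protein_b	combined_score
P10001	P10002	900
P10001	P10003	820
P10002	P10003	850
P10001	P10004	700
P10002	P10005	650
P10001	P20001	550
P20002	P20003	500
""",
    "reactions": """\
reaction_id	reactant_ids	product_ids
R00001	C00008	C00007
R00002	C00009	C00008
""",
}

#: the five metabolites sharing one in-process neighbor set
TOY_SHARED_METS = ("M00001", "M00002", "M00003", "M00004", "M00005")
#: the metabolite with no interaction outside the process
TOY_EXCLUSIVE_MET = "M00005"


def tcell_toy(out_dir: str | os.PathLike) -> dict:
    """Write the packaged miniature atlas; returns the file paths.

    The content is fixed (checked into the package source), so repeated
    writes are byte-identical on any platform.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, content in _TOY_TABLES.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
        paths[name] = path
    manifest = {name: f"{name}.tsv" for name in FILE_NAMES}
    manifest["root_id"] = DEFAULT_ROOT
    manifest["min_confidence"] = DEFAULT_MIN_CONFIDENCE
    paths["manifest"] = os.path.join(out_dir, "manifest.json")
    _write_json(paths["manifest"], manifest)
    return paths
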