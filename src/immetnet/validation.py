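"""Gold-standard evaluation of predicted metabolite-process associations.

The gold standard is a set of (metabolite, process) pairs with occurrence
counts, typically derived from literature co-occurrence.  Pairs observed
only once are removed to limit false positives, and pairs whose metabolite
belongs to an excluded superclass (e.g. lipids, whose nomenclature defeats
text mining) can be dropped regardless of count.

Predictions are compared against the gold standard over a declared
universe of candidate pairs; by default the universe is every
(retained metabolite, immune process) pair formable from the atlas, which
is the natural negative background given that the atlas itself is the
statistical background everywhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .ingest import AtlasDatabase, ValidationError
from .network import AssociationSet, inherit_processes

logger = logging.getLogger("immetnet")


@dataclass(frozen=True)
class GoldStandardSet:
    pairs: frozenset
    source_counts: dict

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs


def read_gold(path) -> dict:
    """Read a pair-count table (metabolite_id, process_id, occurrence_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["metabolite_id", "process_id", "occurrence_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    counts: dict = {}
    for row in df.itertuples(index=False):
        counts[(row.metabolite_id, row.process_id)] = \
            counts.get((row.metabolite_id, row.process_id), 0) + \
            int(row.occurrence_count)
    return counts


def filter_gold_standard(counts: dict, min_count: int = 2,
                         exclude_superclasses: Iterable[str] = (),
                         atlas: Optional[AtlasDatabase] = None
                         ) -> GoldStandardSet:
    """Apply the occurrence-count and superclass filters.

    Pairs with fewer than *min_count* occurrences are removed; pairs whose
    metabolite belongs to an excluded superclass are removed regardless of
    count (superclass lookup requires *atlas*).
    """
    excluded_sc = set(exclude_superclasses)
    if excluded_sc and atlas is None:
        raise ValueError("superclass exclusion requires the atlas")
    kept: dict = {}
    n_low = n_sc = 0
    for pair, count in counts.items():
        if count < 0:
            raise ValidationError(f"negative occurrence count for {pair}")
        if count < min_count:
            n_low += 1
            continue
        if excluded_sc:
            met = pair[0]
            if met in atlas.metabolites and \
                    atlas.metabolites[met].superclass in excluded_sc:
                n_sc += 1
                continue
        kept[pair] = count
    logger.info(
        "gold standard: removed %d pair(s) below count %d and %d pair(s) "
        "of excluded superclasses; %d retained",
        n_low, min_count, n_sc, len(kept),
    )
    return GoldStandardSet(pairs=frozenset(kept), source_counts=kept)


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and the derived performance metrics.

    Metrics with a zero denominator are ``None`` (undefined), never 0:
    specificity = TN/(TN+FP), sensitivity = TP/(TP+FN),
    precision = TP/(TP+FP),
    accuracy = (TN+TP)/(TN+TP+FN+FP),
    F1 = TP/(TP + (FP+FN)/2).
    """

    TP: int
    TN: int
    FP: int
    FN: int
    specificity: Optional[float]
    sensitivity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    universe_size: int


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def confusion(predicted, gold, universe) -> ConfusionSummary:
    """Compare predicted pairs with the gold standard over *universe*."""
    if isinstance(predicted, AssociationSet):
        predicted = predicted.pairs()
    predicted = frozenset(predicted)
    gold_pairs = gold.pairs if isinstance(gold, GoldStandardSet) \
        else frozenset(gold)
    universe = frozenset(universe)
    if not predicted <= universe:
        raise ValidationError(
            f"{len(predicted - universe)} predicted pair(s) outside the "
            "declared universe"
        )
    if not gold_pairs <= universe:
        raise ValidationError(
            f"{len(gold_pairs - universe)} gold pair(s) outside the "
            "declared universe"
        )
    tp = len(predicted & gold_pairs)
    fp = len(predicted - gold_pairs)
    fn = len(gold_pairs - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionSummary(
        TP=tp, TN=tn, FP=fp, FN=fn,
        specificity=_safe_div(tn, tn + fp),
        sensitivity=_safe_div(tp, tp + fn),
        precision=_safe_div(tp, tp + fp),
        accuracy=_safe_div(tn + tp, len(universe)),
        f1=_safe_div(tp, tp + 0.5 * (fp + fn)),
        universe_size=len(universe),
    )


def atlas_universe(atlas: AtlasDatabase) -> frozenset:
    """All (retained metabolite, immune process) candidate pairs."""
    mets = sorted(atlas.metabolites.metabolites)
    procs = atlas.process_ids
    return frozenset((m, j) for m in mets for j in procs)


def compare_orders(atlas: AtlasDatabase, gold,
                   orders: Iterable[int] = (1, 2, 3),
                   universe: Optional[frozenset] = None,
                   drop_unknown: bool = False) -> pd.DataFrame:
    """Atlas-wide inheritance at each order, evaluated against one gold set.

    Emits one row per order.  Because order-k associations nest, the
    sensitivity column is non-decreasing and the specificity column
    non-increasing down the table.
    """
    if universe is None:
        universe = atlas_universe(atlas)
    gold_pairs = gold.pairs if isinstance(gold, GoldStandardSet) \
        else frozenset(gold)
    if drop_unknown:
        outside = gold_pairs - universe
        if outside:
            logger.warning("compare_orders: dropping %d gold pair(s) "
                           "outside the universe", len(outside))
            gold_pairs = gold_pairs & universe
    rows = []
    for order in orders:
        predicted = inherit_processes(atlas, None, order).pairs()
        summary = confusion(predicted, gold_pairs, universe)
        rows.append({"order": order, **summary.__dict__})
    return pd.DataFrame(rows)
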