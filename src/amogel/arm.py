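"""Class association rule mining over discretized multi-omics features.

Every training sample of a subtype is a transaction whose items are
(feature, level) pairs.  Per class, closed frequent itemsets are mined with a
levelwise Apriori search; the minimum support is found adaptively by stepping
it down until the itemset count passes a per-class rule budget, which keeps
rule counts balanced across subtypes of very different prevalence.  Each
itemset becomes a rule ``antecedent => subtype`` whose confidence is computed
over the whole training database; rules are ranked by an information-content
interestingness score

    IC = log2(information gain) + log2(correlation) + log2(confidence)

where the rule-level information gain and class correlation are the means of
per-gene statistics (mutual information with the subtype label in bits, and
the strongest one-vs-rest point-biserial correlation of the level code) over
the antecedent's features.
"""

from __future__ import annotations


import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from sklearn.metrics import mutual_info_score

from .io_formats import LEVEL_NAMES
from .preprocess import DiscretizedDataset, SplitSpec

logger = logging.getLogger(__name__)


class Item(NamedTuple):
    """One (feature, discretization level) antecedent element."""

    feature_uid: str
    level: int  # 0 low, 1 medium, 2 high


Itemset = frozenset  # of Item


def _itemset_key(itemset: Iterable[Item]) -> tuple:
    return tuple(sorted(itemset))


@dataclass
class TransactionDB:
    """All training transactions of one subtype.

    Each transaction carries exactly one item per feature (its level for that
    sample), so |transaction| = number of features.
    """

    class_label: str
    transactions: list[frozenset]

    @property
    def n(self) -> int:
        return len(self.transactions)


@dataclass
class ClassAssociationRule:
    antecedent: frozenset
    consequent: str
    support: float        # fraction of the class's transactions containing A
    confidence: float     # P(class | A) over the full training DB
    info_gain: float = 0.0      # mean per-gene mutual information (bits)
    correlation: float = 0.0    # mean per-gene class correlation
    information_content: float = float("nan")

    def sort_key(self) -> tuple:
        # -inf information content sorts last; then support desc, then lexicographic
        return (-self.information_content, -self.support, _itemset_key(self.antecedent))


@dataclass
class GeneStats:
    """Per-feature mutual information (bits) and class-correlation strength."""

    infogain: dict[str, float] = field(default_factory=dict)
    correlation: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Transactions & support
# ---------------------------------------------------------------------------

def build_transactions(dds: DiscretizedDataset, split: SplitSpec,
                       class_label: str) -> TransactionDB:
    """One transaction per training sample of `class_label`."""
    rows = dds.rows_for(split.train_ids)
    labels = np.array(dds.labels)[rows]
    cls_rows = rows[labels == class_label]
    if cls_rows.size == 0:
        raise ValueError(f"class {class_label!r} absent from the training split")
    uids = dds.feature_uids
    transactions = [
        frozenset(Item(uid, int(lev)) for uid, lev in zip(uids, dds.levels[r]))
        for r in cls_rows
    ]
    return TransactionDB(class_label, transactions)


def support(itemset: frozenset, db: TransactionDB) -> float:
    """Fraction of db transactions containing every item of `itemset`."""
    if not itemset:
        raise ValueError("itemset must be non-empty")
    if db.n == 0:
        return 0.0
    hits = sum(1 for t in db.transactions if itemset <= t)
    return hits / db.n


class _BoolDB:
    """Columnar boolean view of a TransactionDB for fast support counting."""

    def __init__(self, db: TransactionDB):
        items = sorted({it for t in db.transactions for it in t})
        self.items: list[Item] = items
        self.index = {it: j for j, it in enumerate(items)}
        self.mat = np.zeros((len(db.transactions), len(items)), dtype=bool)
        for i, t in enumerate(db.transactions):
            for it in t:
                self.mat[i, self.index[it]] = True
        self.imat = self.mat.astype(np.int64)  # matmul does not take bools
        self.n = len(db.transactions)


# ---------------------------------------------------------------------------
# Closed frequent itemset mining
# ---------------------------------------------------------------------------

def mine_closed_frequent_itemsets(db: TransactionDB, min_support: float,
                                  max_len: int | None = None
                                  ) -> list[tuple[frozenset, float]]:
    """Levelwise Apriori followed by an exact closure filter.

    Returns every itemset with support >= min_support (and size <= max_len
    when capped) that has no proper superset of equal support.  Closure is
    checked against single-item extensions, which is exact regardless of the
    length cap: any equal-support superset implies an equal-support one-item
    extension.  Output is sorted by (support desc, size asc, lexicographic).
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    bdb = _BoolDB(db)
    if bdb.n == 0 or not bdb.items:
        return []
    min_count = min_support * bdb.n - 1e-9
    col_counts = bdb.mat.sum(axis=0)

    # frontier: list of (item index tuple, cover mask)
    frontier = [((j,), bdb.mat[:, j]) for j in np.flatnonzero(col_counts >= min_count)]
    frequent: list[tuple[tuple[int, ...], np.ndarray]] = list(frontier)
    size = 1
    while frontier and (max_len is None or size < max_len):
        nxt = []
        # prefix join: extend each itemset with a larger item index
        for idx, cover in frontier:
            last = idx[-1]
            cand_counts = cover.astype(np.int64) @ bdb.imat  # co-occurrence per item
            for j in range(last + 1, len(bdb.items)):
                if cand_counts[j] >= min_count:
                    nxt.append((idx + (j,), cover & bdb.mat[:, j]))
        frontier = nxt
        frequent.extend(frontier)
        size += 1

    out = []
    for idx, cover in frequent:
        count = int(cover.sum())
        # closed iff no item outside the set is present in every covering transaction
        ext_counts = cover.astype(np.int64) @ bdb.imat
        ext_counts[list(idx)] = -1
        if ext_counts.max(initial=-1) == count:
            continue
        itemset = frozenset(bdb.items[j] for j in idx)
        out.append((itemset, count / bdb.n))
    out.sort(key=lambda e: (-e[1], len(e[0]), _itemset_key(e[0])))
    return out


def iterative_min_support_search(db: TransactionDB, max_rules: int,
                                 init_support: float = 0.9, step: float = 0.05,
                                 floor: float = 0.1, max_len: int | None = None
                                 ) -> tuple[float, list[tuple[frozenset, float]]]:
    """Step min_support down from `init_support` until the closed-itemset
    count reaches `max_rules`, or the floor is hit.

    Returns the stopping support and its itemsets.  The itemset count is
    non-increasing in min_support, so the first support meeting the budget is
    the largest such support on the trajectory.
    """
    if not (init_support > floor > 0):
        raise ValueError("need init_support > floor > 0")
    if step <= 0:
        raise ValueError("step must be positive")
    s = init_support
    while True:
        itemsets = mine_closed_frequent_itemsets(db, s, max_len=max_len)
        if len(itemsets) >= max_rules or s <= floor + 1e-12:
            if len(itemsets) < max_rules:
                logger.info("class %s: hit support floor %.3f with %d itemsets "
                            "(< budget %d)", db.class_label, s, len(itemsets), max_rules)
            return s, itemsets
        s = max(floor, s - step)


def initial_support_from_db(db: TransactionDB) -> float:
    """1/|db|-scaled alternative initial support: 1 - 1/n, floored at 0.5."""
    return max(0.5, 1.0 - 1.0 / max(db.n, 2))


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def generate_cars(itemsets: list[tuple[frozenset, float]], class_label: str,
                  dbs: Mapping[str, TransactionDB],
                  min_confidence: float = 0.5) -> list[ClassAssociationRule]:
    """Turn mined itemsets into rules and drop those below min_confidence.

    Confidence is #(class transactions containing A) / #(all training
    transactions containing A).
    """
    rules = []
    for itemset, sup in itemsets:
        in_class = sum(1 for t in dbs[class_label].transactions if itemset <= t)
        total = sum(sum(1 for t in db.transactions if itemset <= t) for db in dbs.values())
        if total == 0:
            continue
        conf = in_class / total
        if conf >= min_confidence:
            rules.append(ClassAssociationRule(itemset, class_label, sup, conf))
    return rules


def gene_stats(dds: DiscretizedDataset, split: SplitSpec) -> GeneStats:
    """Training-set mutual information (bits) and class correlation per feature.

    Correlation is the largest |Pearson r| between the 0/1/2 level code and a
    one-vs-rest class indicator, over classes, clipped to [0, 1]; degenerate
    (constant) features score 0 for both statistics.
    """
    rows = dds.rows_for(split.train_ids)
    y = np.array(dds.labels)[rows]
    classes = np.unique(y)
    onehot = {c: (y == c).astype(float) for c in classes}
    stats = GeneStats()
    for j, uid in enumerate(dds.feature_uids):
        lev = dds.levels[rows, j].astype(float)
        mi = mutual_info_score(y, lev) / math.log(2)
        stats.infogain[uid] = max(float(mi), 0.0)
        if lev.std() == 0:
            stats.correlation[uid] = 0.0
            continue
        best = 0.0
        for c in classes:
            ind = onehot[c]
            if ind.std() == 0:
                continue
            r = abs(float(np.corrcoef(lev, ind)[0, 1]))
            best = max(best, r)
        stats.correlation[uid] = min(best, 1.0)
    return stats


def score_car(rule: ClassAssociationRule, stats: GeneStats) -> float:
    """Information-content interestingness of one rule.

    Any zero component yields -inf so the rule ranks after every finite
    score.  The rule-level information gain and correlation are arithmetic
    means of the per-gene statistics over the antecedent features.
    """
    feats = sorted({it.feature_uid for it in rule.antecedent})
    rule.info_gain = float(np.mean([stats.infogain[f] for f in feats]))
    rule.correlation = float(np.mean([stats.correlation[f] for f in feats]))
    if rule.info_gain <= 0 or rule.correlation <= 0 or rule.confidence <= 0:
        rule.information_content = float("-inf")
    else:
        rule.information_content = (math.log2(rule.info_gain)
                                    + math.log2(rule.correlation)
                                    + math.log2(rule.confidence))
    return rule.information_content


def select_top_k(rules_by_class: Mapping[str, list[ClassAssociationRule]],
                 k: int) -> list[ClassAssociationRule]:
    """Keep the k most interesting rules per class; classes contribute equally."""
    if k <= 0:
        raise ValueError("k must be positive")
    out = []
    for cls in sorted(rules_by_class):
        out.extend(sorted(rules_by_class[cls], key=ClassAssociationRule.sort_key)[:k])
    return out


def selected_genes(cars: list[ClassAssociationRule]) -> list[str]:
    """De-duplicated, lexicographically ordered antecedent features.

    Defines the node set (and node order) of every downstream graph.
    """
    genes = sorted({it.feature_uid for r in cars for it in r.antecedent})
    if not genes:
        raise ValueError("no genes in the selected rules")
    return genes


def cba_prune(rules: list[ClassAssociationRule], dds: DiscretizedDataset,
              split: SplitSpec) -> list[ClassAssociationRule]:
    """Interface stub for database-coverage (CBA-style) rule pruning."""
    raise NotImplementedError("CBA rule pruning is not provided by this package")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_rules(rules: list[ClassAssociationRule], path: str | Path) -> None:
    payload = [
        {
            "antecedent": [[it.feature_uid, LEVEL_NAMES[it.level]] for it in sorted(r.antecedent)],
            "consequent": r.consequent,
            "support": r.support,
            "confidence": r.confidence,
            "info_gain": r.info_gain,
            "correlation": r.correlation,
            "information_content": (None if math.isinf(r.information_content)
                                    else r.information_content),
        }
        for r in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rules(path: str | Path) -> list[ClassAssociationRule]:
    rules = []
    for d in json.loads(Path(path).read_text()):
        ant = frozenset(Item(f, LEVEL_NAMES.index(lv)) for f, lv in d["antecedent"])
        ic = d["information_content"]
        rules.append(ClassAssociationRule(
            ant, d["consequent"], d["support"], d["confidence"], d["info_gain"],
            d["correlation"], float("-inf") if ic is None else ic))
    return rules
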