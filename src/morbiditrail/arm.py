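"""Apriori association-rule mining over disease-system co-occurrence.

Transactions are the disease-system sets of the cross-sectional sample,
one per participant.  The miner is the classic levelwise Apriori:
candidate (k+1)-itemsets are joined from frequent k-itemsets sharing a
(k-1)-prefix and pruned by support anti-monotonicity before counting.
With seven items the search space is tiny; support counting is
vectorised over a boolean participant × item matrix.

Conventions for the ranked pattern tables: itemsets are grouped by order
(singleton / pair / trio), ranked within a stratum by raw support with
deterministic tie-breaks (support desc, lift desc, lexicographic), and
the printed ``pct`` is the within-order relative frequency — the share
of an itemset's occurrences among all frequent itemsets of the same
order in that stratum.  Lift for an order ≥ 2 itemset is the maximum
lift over its binary partitions (lift is symmetric in antecedent and
consequent, so direction does not matter).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

#: age bands for stratified mining, closed on both ends
AGE_BANDS: tuple[tuple[int, int], ...] = ((19, 37), (38, 56), (57, 75), (76, 94))

DEFAULT_MIN_SUPPORT = 0.005
DEFAULT_MIN_CONFIDENCE = 0.07


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float


def age_band_label(age) -> str | None:
    """Band label for an age, or None outside the mined 19–94 range."""
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def _to_bool_matrix(transactions) -> tuple[np.ndarray, list]:
    """Coerce transactions (iterable of sets, or item-column DataFrame)
    into a boolean matrix plus the item label list."""
    if isinstance(transactions, pd.DataFrame):
        items = list(transactions.columns)
        mat = transactions.to_numpy(dtype=bool)
    else:
        tx = [frozenset(t) for t in transactions]
        items = sorted({i for t in tx for i in t})
        index = {it: k for k, it in enumerate(items)}
        mat = np.zeros((len(tx), len(items)), dtype=bool)
        for r, t in enumerate(tx):
            for it in t:
                mat[r, index[it]] = True
    return mat, items


def mine_frequent_itemsets(transactions, min_support: float = DEFAULT_MIN_SUPPORT):
    """All itemsets with support ≥ ``min_support`` (Apriori levelwise).

    Returns a list of :class:`FrequentItemset`, sorted by (order, -support,
    lexicographic items).
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    mat, items = _to_bool_matrix(transactions)
    n = mat.shape[0]
    if n == 0:
        raise ValueError("transaction list is empty")

    supports: dict[frozenset, float] = {}
    # level 1
    s1 = mat.mean(axis=0)
    frequent = []
    for k, it in enumerate(items):
        if s1[k] >= min_support:
            supports[frozenset([it])] = float(s1[k])
            frequent.append((it,))
    level = sorted(frequent)

    col = {it: k for k, it in enumerate(items)}
    while level:
        candidates = _join_and_prune(level)
        next_level = []
        for cand in candidates:
            idx = [col[i] for i in cand]
            supp = float(mat[:, idx].all(axis=1).mean())
            if supp >= min_support:
                supports[frozenset(cand)] = supp
                next_level.append(cand)
        level = sorted(next_level)

    out = [FrequentItemset(items=k, support=v) for k, v in supports.items()]
    out.sort(key=lambda fi: (len(fi.items), -fi.support, tuple(sorted(fi.items))))
    return out


def _join_and_prune(level: list[tuple]) -> list[tuple]:
    """Apriori-gen: join k-itemsets sharing a (k-1)-prefix, prune any
    candidate with an infrequent k-subset."""
    freq = set(level)
    k = len(level[0])
    candidates = []
    for a, b in combinations(level, 2):
        if a[: k - 1] == b[: k - 1]:
            cand = tuple(sorted(set(a) | set(b)))
            if all(tuple(sorted(s)) in freq for s in combinations(cand, k)):
                candidates.append(cand)
    return sorted(set(candidates))


def generate_rules(itemsets, min_confidence: float = DEFAULT_MIN_CONFIDENCE):
    """All rules A→B with A∪B frequent and confidence ≥ ``min_confidence``.

    ``itemsets`` is the output of :func:`mine_frequent_itemsets` (the
    supports of all frequent subsets are needed for confidence and lift).
    """
    supports = {fi.items: fi.support for fi in itemsets}
    rules = []
    for itemset, supp in supports.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                a = frozenset(ante)
                b = itemset - a
                if a not in supports or b not in supports:
                    continue  # subset below threshold: confidence undefined here
                conf = supp / supports[a]
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=a, consequent=b, support=supp,
                            confidence=conf, lift=conf / supports[b],
                        )
                    )
    rules.sort(
        key=lambda r: (-r.support, -r.lift, tuple(sorted(r.antecedent)), tuple(sorted(r.consequent)))
    )
    return rules


def _itemset_lift(itemset: frozenset, supports: dict) -> float:
    """Maximum lift over binary partitions of the itemset; lift is
    symmetric, so each unordered partition is evaluated once."""
    if len(itemset) < 2:
        return float("nan")
    supp = supports[itemset]
    best = -np.inf
    seen = set()
    for r in range(1, len(itemset)):
        for ante in combinations(sorted(itemset), r):
            a = frozenset(ante)
            b = itemset - a
            key = frozenset((a, b))
            if key in seen or a not in supports or b not in supports:
                continue
            seen.add(key)
            best = max(best, supp / (supports[a] * supports[b]))
    return float(best) if np.isfinite(best) else float("nan")


def stratified_patterns(
    transactions: pd.DataFrame,
    stratify_by: str | None = None,
    top_k: int = 7,
    min_support: float = DEFAULT_MIN_SUPPORT,
    orders=(1, 2, 3),
    min_cell: int = 30,
) -> pd.DataFrame:
    """Ranked frequent-pattern tables per stratum and itemset order.

    ``transactions`` is a DataFrame of boolean item columns plus, when
    ``stratify_by`` is given, that stratum column.  Strata with fewer
    than ``min_cell`` transactions are emitted with ``sparse=True``.
    Returns a tidy frame (stratum, order, rank, items, count, support,
    pct, lift, sparse).
    """
    if stratify_by is None:
        groups = [("overall", transactions)]
        item_cols = [c for c in transactions.columns if transactions[c].dropna().isin([0, 1, True, False]).all()]
    else:
        item_cols = [c for c in transactions.columns if c != stratify_by]
        groups = [
            (label, g) for label, g in transactions.groupby(stratify_by, observed=True)
        ]
    rows = []
    for label, g in groups:
        sparse = len(g) < min_cell
        if len(g) == 0:
            rows.append({"stratum": label, "order": None, "rank": None, "items": "",
                         "count": 0, "support": np.nan, "pct": np.nan,
                         "lift": np.nan, "sparse": True})
            continue
        bool_df = g[item_cols].astype(bool)
        itemsets = mine_frequent_itemsets(bool_df, min_support=min_support)
        supports = {fi.items: fi.support for fi in itemsets}
        n = len(g)
        for order in orders:
            of_order = [fi for fi in itemsets if len(fi.items) == order]
            total = sum(fi.support for fi in of_order)
            ranked = sorted(
                of_order,
                key=lambda fi: (
                    -fi.support,
                    -(0 if order == 1 else _itemset_lift(fi.items, supports)),
                    tuple(sorted(fi.items)),
                ),
            )
            for rank, fi in enumerate(ranked[:top_k], start=1):
                rows.append({
                    "stratum": label,
                    "order": order,
                    "rank": rank,
                    "items": ",".join(sorted(fi.items)),
                    "count": int(round(fi.support * n)),
                    "support": fi.support,
                    "pct": 100.0 * fi.support / total if total > 0 else np.nan,
                    "lift": _itemset_lift(fi.items, supports) if order >= 2 else np.nan,
                    "sparse": sparse,
                })
    return pd.DataFrame(rows)


def select_trio(itemsets_or_table) -> frozenset:
    """The modelling trio: the frequent 3-itemset with highest support
    (ties → higher lift, then lexicographic).

    Accepts the output of :func:`mine_frequent_itemsets` or of
    :func:`stratified_patterns`.
    """
    if isinstance(itemsets_or_table, pd.DataFrame):
        t = itemsets_or_table
        trios = t[(t["order"] == 3) & t["items"].astype(bool)]
        if trios.empty:
            raise ValueError("no frequent trio found; lower min_support")
        trios = trios.sort_values(
            ["support", "lift", "items"], ascending=[False, False, True], kind="mergesort"
        )
        return frozenset(trios.iloc[0]["items"].split(","))
    itemsets = list(itemsets_or_table)
    supports = {fi.items: fi.support for fi in itemsets}
    trios = [fi for fi in itemsets if len(fi.items) == 3]
    if not trios:
        raise ValueError("no frequent trio found; lower min_support")
    trios.sort(
        key=lambda fi: (-fi.support, -_itemset_lift(fi.items, supports), tuple(sorted(fi.items)))
    )
    return trios[0].items


def rules_to_frame(rules) -> pd.DataFrame:
    """Flatten rules into a tidy DataFrame for CSV output."""
    return pd.DataFrame(
        [
            {
                "antecedent": ",".join(sorted(r.antecedent)),
                "consequent": ",".join(sorted(r.consequent)),
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
            }
            for r in rules
        ]
    )
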