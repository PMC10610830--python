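"""Frequent-pattern and association-rule mining over symbolic HRV windows.

A *transaction* is the set of distinct windowed subsequences from one
recording's one band, so support is the fraction of recordings (of a given
emotion) whose band exhibits a pattern. Mining proceeds per emotion:

1. FP-growth finds all itemsets with support >= min_support.
2. Association rules X -> Y (X, Y disjoint, X u Y frequent) are kept when
   their reliability (confidence) sup(X u Y)/sup(X) >= min_reliability; the
   reliability is the rule's strength.
3. Potential rules: for window pairs (P, Q) occupying consecutive start
   positions in a level sequence, a correlation (joint support by default,
   lift optionally) >= threshold together with an existing rule on P yields
   a new rule with strength = strength(P-rule) x correlation.
4. Rules from all emotions are merged by pattern; any pattern carrying
   every emotion label (a "universal" rule, useless for discrimination) is
   removed.

FP-growth is implemented here directly: a prefix tree with header links,
mined recursively over conditional pattern bases. Tests check it against
brute-force enumeration.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

Item = Hashable
Itemset = frozenset


@dataclass
class Transaction:
    """Distinct windows of one recording/band, plus their adjacency pairs."""

    items: frozenset
    emotion_label: str | None = None
    adjacent_pairs: frozenset = frozenset()     # {(P, Q): Q starts right after P}

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("transaction must be non-empty")


@dataclass
class Rule:
    """A mined pattern: a frequent itemset or an X -> Y implication."""

    itemset: Itemset                      # full pattern (X u Y for implications)
    strength: float                       # support / reliability / product, in (0, 1]
    origin: str                           # "frequent" | "association" | "potential"
    antecedent: Itemset | None = None
    consequent: Itemset | None = None
    labels: frozenset = frozenset()       # emotions the pattern was mined from
    strengths_by_label: dict = field(default_factory=dict)

    def key(self) -> tuple:
        return (self.itemset, self.antecedent, self.consequent, self.origin)

    def match_patterns(self) -> frozenset:
        """Symbol tuples a single window can be compared against."""
        return self.itemset


@dataclass
class RuleSet:
    rules: list[Rule]
    band: str = ""

    def __len__(self) -> int:
        return len(self.rules)


def support(itemset: Iterable[Item], transactions: Sequence[Transaction]) -> float:
    """Fraction of transactions containing every item of the itemset."""
    if not transactions:
        raise ValueError("empty transaction list")
    target = frozenset(itemset)
    hits = sum(1 for t in transactions if target <= t.items)
    return hits / len(transactions)


# --- FP-growth ---------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.link: _Node | None = None


def _build_tree(itemsets: Iterable[tuple[tuple, int]], min_count: int):
    """Build an FP-tree from (ordered item tuple, count) pairs."""
    counts: Counter = Counter()
    cached = list(itemsets)
    for items, cnt in cached:
        for item in items:
            counts[item] += cnt
    frequent = {i for i, c in counts.items() if c >= min_count}
    # order: descending count, ties broken by repr for determinism
    rank = {i: (-counts[i], repr(i)) for i in frequent}
    root = _Node(None, None)
    header: dict = {}
    for items, cnt in cached:
        filtered = sorted((i for i in items if i in frequent), key=rank.__getitem__)
        node = root
        for item in filtered:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                if item in header:
                    child.link = header[item]
                header[item] = child
            child.count += cnt
            node = child
    return root, header, counts


def _mine_tree(header, counts, min_count, suffix, out, max_size):
    items = sorted(header, key=lambda i: (counts[i], repr(i)))  # least frequent first
    for item in items:
        new_suffix = suffix | {item}
        out[frozenset(new_suffix)] = counts[item]
        if max_size is not None and len(new_suffix) >= max_size:
            continue
        # conditional pattern base for `item`
        base = []
        node = header[item]
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                base.append((tuple(reversed(path)), node.count))
            node = node.link
        if base:
            _root, sub_header, sub_counts = _build_tree(base, min_count)
            if sub_header:
                _mine_tree(sub_header, sub_counts, min_count, new_suffix, out,
                           max_size)


def mine_frequent(
    transactions: Sequence[Transaction],
    min_support: float,
    max_size: int | None = None,
) -> list[tuple[Itemset, float]]:
    """All itemsets with support >= min_support, via FP-growth.

    ``max_size`` optionally caps the itemset cardinality (None = exact,
    unbounded enumeration). Output is sorted (size, then repr) for
    determinism.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not transactions:
        raise ValueError("empty transaction list")
    n = len(transactions)
    # support >= min_support  <=>  count >= ceil(min_support * n); the epsilon
    # keeps floating-point products like 0.3 * 10 on the boundary
    min_count = max(1, math.ceil(min_support * n - 1e-9))
    itemsets = [(tuple(sorted(t.items, key=repr)), 1) for t in transactions]
    _root, header, counts = _build_tree(itemsets, min_count)
    found: dict[Itemset, int] = {}
    _mine_tree(header, counts, min_count, frozenset(), found, max_size)
    result = [(iset, cnt / n) for iset, cnt in found.items()]
    result.sort(key=lambda p: (len(p[0]), repr(sorted(p[0], key=repr))))
    return result


def reliability(
    antecedent: Iterable[Item], consequent: Iterable[Item],
    transactions: Sequence[Transaction],
) -> float:
    """Confidence of X -> Y: frequency(X u Y) / frequency(X)."""
    x = frozenset(antecedent)
    y = frozenset(consequent)
    sup_x = support(x, transactions)
    if sup_x == 0:
        raise ValueError("antecedent has zero support")
    return support(x | y, transactions) / sup_x


def mine_association(
    frequent_itemsets: Sequence[tuple[Itemset, float]],
    transactions: Sequence[Transaction],
    min_reliability: float,
) -> list[Rule]:
    """All rules X -> Y with X u Y frequent and reliability >= min_reliability.

    Rule strength is the reliability. Supports of all antecedents are read
    from the frequent list itself (every subset of a frequent itemset is
    frequent, so lookups never miss).
    """
    sup = {iset: s for iset, s in frequent_itemsets}
    rules: list[Rule] = []
    for iset, s_full in frequent_itemsets:
        if len(iset) < 2:
            continue
        items = sorted(iset, key=repr)
        for r in range(1, len(items)):
            for combo in itertools.combinations(items, r):
                x = frozenset(combo)
                y = iset - x
                s_x = sup.get(x)
                if s_x is None:
                    s_x = support(x, transactions)
                rel = s_full / s_x
                if rel >= min_reliability:
                    rules.append(Rule(itemset=iset, strength=min(rel, 1.0),
                                      origin="association",
                                      antecedent=x, consequent=y))
    rules.sort(key=lambda r: (repr(sorted(r.itemset, key=repr)),
                              repr(sorted(r.antecedent, key=repr))))
    return rules


def mine_potential(
    frequent_itemsets: Sequence[tuple[Itemset, float]],
    rules: Sequence[Rule],
    transactions: Sequence[Transaction],
    correlation_threshold: float,
    mode: str = "joint",
) -> list[Rule]:
    """Promote adjacent window pairs (P, Q) to rules.

    The correlation of a pair is the joint support of {P, Q} across
    transactions (``joint`` mode) or its lift sup(PQ)/(sup(P) sup(Q))
    (``lift`` mode, clipped to 1). If it reaches the threshold and an
    association rule with antecedent {P} exists, a potential rule is
    emitted with strength = strength(P-rule) x correlation, clipped to
    (0, 1].
    """
    if mode not in ("joint", "lift"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    pairs: set[tuple] = set()
    for t in transactions:
        pairs |= set(t.adjacent_pairs)
    best_rule_for: dict[Itemset, float] = {}
    for r in rules:
        if r.antecedent is not None and len(r.antecedent) == 1:
            key = r.antecedent
            best_rule_for[key] = max(best_rule_for.get(key, 0.0), r.strength)
    out: list[Rule] = []
    for p, q in sorted(pairs, key=repr):
        p_key = frozenset([p])
        s_p = best_rule_for.get(p_key)
        if s_p is None:
            continue
        joint = support([p, q], transactions)
        if mode == "lift":
            denom = support([p], transactions) * support([q], transactions)
            corr = min(joint / denom, 1.0) if denom > 0 else 0.0
        else:
            corr = joint
        if corr < correlation_threshold or corr == 0:
            continue
        strength = min(s_p * corr, 1.0)
        if strength <= 0:
            continue
        out.append(Rule(itemset=frozenset([p, q]), strength=strength,
                        origin="potential", antecedent=p_key,
                        consequent=frozenset([q])))
    return out


def mine_emotion_rules(
    transactions: Sequence[Transaction],
    min_support: float = 0.10,
    min_reliability: float = 0.60,
    correlation_threshold: float = 0.30,
    correlation_mode: str = "joint",
    max_itemset_size: int | None = 2,
) -> list[Rule]:
    """Full single-emotion mining: frequent + association + potential rules."""
    fi = mine_frequent(transactions, min_support, max_size=max_itemset_size)
    assoc = mine_association(fi, transactions, min_reliability)
    potential = mine_potential(fi, assoc, transactions, correlation_threshold,
                               mode=correlation_mode)
    frequent_rules = [Rule(itemset=iset, strength=min(s, 1.0), origin="frequent")
                      for iset, s in fi]
    return frequent_rules + assoc + potential


def filter_universal(
    per_emotion_rules: dict[str, Sequence[Rule]],
    all_emotions: Iterable[str] | None = None,
    band: str = "",
) -> RuleSet:
    """Merge rules across emotions and drop patterns common to all emotions.

    Rules are merged by (itemset, antecedent, consequent, origin); label
    sets are unioned and the merged strength is the maximum across
    emotions (per-emotion strengths retained on the rule). A rule whose
    label set covers every emotion is removed.
    """
    emotions = frozenset(all_emotions if all_emotions is not None
                         else per_emotion_rules)
    merged: dict[tuple, Rule] = {}
    for emotion, rules in sorted(per_emotion_rules.items()):
        for r in rules:
            key = r.key()
            if key not in merged:
                merged[key] = Rule(itemset=r.itemset, strength=r.strength,
                                   origin=r.origin, antecedent=r.antecedent,
                                   consequent=r.consequent,
                                   labels=frozenset([emotion]),
                                   strengths_by_label={emotion: r.strength})
            else:
                m = merged[key]
                m.labels = m.labels | {emotion}
                m.strength = max(m.strength, r.strength)
                m.strengths_by_label[emotion] = max(
                    m.strengths_by_label.get(emotion, 0.0), r.strength)
    kept = [r for r in merged.values() if r.labels != emotions]
    kept.sort(key=lambda r: (r.origin, repr(sorted(r.itemset, key=repr)),
                             repr(r.antecedent)))
    return RuleSet(rules=kept, band=band)


def brute_force_frequent(
    transactions: Sequence[Transaction], min_support: float,
) -> list[tuple[Itemset, float]]:
    """Exhaustive frequent-itemset enumeration (test oracle, tiny corpora only)."""
    universe = sorted({i for t in transactions for i in t.items}, key=repr)
    out = []
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            s = support(combo, transactions)
            if s >= min_support - 1e-12:
                out.append((frozenset(combo), s))
    out.sort(key=lambda p: (len(p[0]), repr(sorted(p[0], key=repr))))
    return out
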