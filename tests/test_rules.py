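import itertools

import numpy as np
import pytest

from hrvemotion.rules import (
    Rule,
    Transaction,
    brute_force_frequent,
    filter_universal,
    mine_association,
    mine_emotion_rules,
    mine_frequent,
    mine_potential,
    reliability,
    support,
)


def T(*items, emotion=None, pairs=()):
    return Transaction(items=frozenset(items), emotion_label=emotion,
                       adjacent_pairs=frozenset(pairs))


def random_corpus(rng, n_items=6, n_transactions=30):
    universe = [f"i{k}" for k in range(n_items)]
    out = []
    for _ in range(n_transactions):
        size = rng.integers(1, n_items + 1)
        out.append(T(*rng.choice(universe, size=size, replace=False)))
    return out


class TestSupport:
    def test_all_and_none(self):
        txns = [T("a", "b") for _ in range(10)]
        assert support(["a"], txns) == 1.0
        assert support(["z"], txns) == 0.0

    def test_counting(self):
        txns = [T("a") for _ in range(4)] + [T("b") for _ in range(6)]
        assert support(["a"], txns) == pytest.approx(0.4)

    def test_empty_transactions_rejected(self):
        with pytest.raises(ValueError):
            support(["a"], [])

    def test_anti_monotone(self):
        rng = np.random.default_rng(0)
        txns = random_corpus(rng)
        assert support(["i0"], txns) >= support(["i0", "i1"], txns)


class TestFPGrowth:
    def test_single_transaction(self):
        out = mine_frequent([T("a")], min_support=1.0)
        assert out == [(frozenset(["a"]), 1.0)]

    def test_disjoint_transactions_full_support_empty(self):
        out = mine_frequent([T("a"), T("b")], min_support=1.0)
        assert out == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        txns = random_corpus(rng, n_items=6, n_transactions=rng.integers(5, 50))
        min_sup = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
        fp = dict(mine_frequent(txns, min_sup))
        brute = dict(brute_force_frequent(txns, min_sup))
        assert fp.keys() == brute.keys()
        for k in fp:
            assert fp[k] == pytest.approx(brute[k])

    def test_max_size_caps_cardinality(self):
        txns = [T("a", "b", "c") for _ in range(5)]
        out = mine_frequent(txns, 0.5, max_size=2)
        assert max(len(s) for s, _ in out) == 2

    def test_invalid_min_support(self):
        with pytest.raises(ValueError):
            mine_frequent([T("a")], 0.0)


class TestAssociation:
    def test_reliability_values(self):
        txns = [T("a", "b")] * 2 + [T("a")] * 2 + [T("c")] * 6
        assert reliability(["a"], ["b"], txns) == pytest.approx(0.5)
        assert reliability(["c"], ["a"], txns) == 0.0

    def test_zero_antecedent_support_rejected(self):
        with pytest.raises(ValueError):
            reliability(["z"], ["a"], [T("a")])

    def test_singleton_itemsets_give_no_rules(self):
        txns = [T("a"), T("b")]
        fi = mine_frequent(txns, 0.5)
        assert mine_association(fi, txns, 0.1) == []

    def test_toy_rule_strength(self):
        txns = [T("a", "b")] * 6 + [T("c")] * 4
        fi = mine_frequent(txns, 0.5)
        rules = mine_association(fi, txns, 0.6)
        ab = [r for r in rules if r.antecedent == frozenset(["a"])]
        assert len(ab) == 1 and ab[0].strength == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rule_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        txns = random_corpus(rng, n_items=5, n_transactions=20)
        min_sup, min_rel = 0.2, 0.5
        fi = mine_frequent(txns, min_sup)
        got = {(r.antecedent, r.consequent): r.strength
               for r in mine_association(fi, txns, min_rel)}
        # oracle: enumerate X -> Y over all frequent itemsets directly
        expected = {}
        for iset, _s in brute_force_frequent(txns, min_sup):
            if len(iset) < 2:
                continue
            for r in range(1, len(iset)):
                for x in itertools.combinations(sorted(iset), r):
                    rel = support(iset, txns) / support(x, txns)
                    if rel >= min_rel:
                        expected[(frozenset(x), iset - frozenset(x))] = rel
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_strengths_bounded(self):
        rng = np.random.default_rng(7)
        txns = random_corpus(rng)
        rules = mine_emotion_rules(txns, 0.2, 0.3, 0.2, max_itemset_size=None)
        assert all(0 < r.strength <= 1 for r in rules)


class TestPotential:
    def test_below_threshold_empty(self):
        txns = [T("p", "q", pairs=[("p", "q")])] + [T("x")] * 9
        fi = mine_frequent(txns, 0.05)
        rules = mine_association(fi, txns, 0.5)
        assert mine_potential(fi, rules, txns, correlation_threshold=0.5) == []

    def test_product_strength(self):
        # P-rule strength 1.0 and joint frequency 0.5 -> potential strength 0.5
        txns = ([T("p", "r", "q", pairs=[("p", "q")])] * 5
                + [T("p", "r")] * 5)
        fi = mine_frequent(txns, 0.3)
        rules = mine_association(fi, txns, 0.9)
        p_rules = [r for r in rules if r.antecedent == frozenset(["p"])]
        assert any(r.strength == pytest.approx(1.0) for r in p_rules)
        pot = mine_potential(fi, rules, txns, correlation_threshold=0.3)
        assert len(pot) == 1
        assert pot[0].strength == pytest.approx(0.5)
        assert pot[0].itemset == frozenset(["p", "q"])

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(3)
        txns = []
        for _ in range(20):
            noise = [f"n{rng.integers(0, 20)}"]
            txns.append(T("p", "s", "q", *noise, pairs=[("p", "q")]))
        fi = mine_frequent(txns, 0.5)
        rules = mine_association(fi, txns, 0.6)
        pot = mine_potential(fi, rules, txns, correlation_threshold=0.9)
        assert any(r.itemset == frozenset(["p", "q"]) for r in pot)


class TestUniversalFilter:
    def mk(self, pattern, strength=0.8):
        return Rule(itemset=frozenset([pattern]), strength=strength,
                    origin="frequent")

    def test_pattern_in_all_emotions_removed(self):
        per = {e: [self.mk("shared")] for e in ("joy", "anger", "fear")}
        assert len(filter_universal(per).rules) == 0

    def test_private_pattern_kept_with_label(self):
        per = {"joy": [self.mk("only")], "anger": [], "fear": []}
        per = {k: v for k, v in per.items()}
        rs = filter_universal(per, all_emotions=("joy", "anger", "fear"))
        assert len(rs.rules) == 1
        assert rs.rules[0].labels == frozenset(["joy"])

    def test_shared_and_private_mix(self):
        per = {
            "joy": [self.mk("shared"), self.mk("j")],
            "anger": [self.mk("shared"), self.mk("a")],
            "fear": [self.mk("shared")],
        }
        rs = filter_universal(per)
        kept = {next(iter(r.itemset)) for r in rs.rules}
        assert kept == {"j", "a"}

    def test_never_removes_partially_shared(self):
        per = {"joy": [self.mk("x")], "anger": [self.mk("x")], "fear": []}
        rs = filter_universal(per, all_emotions=("joy", "anger", "fear"))
        assert len(rs.rules) == 1
        assert rs.rules[0].labels == frozenset(["joy", "anger"])

    def test_merged_strength_is_max(self):
        per = {"joy": [self.mk("x", 0.5)], "anger": [self.mk("x", 0.9)],
               "fear": []}
        rs = filter_universal(per)
        assert rs.rules[0].strength == pytest.approx(0.9)
        assert rs.rules[0].strengths_by_label == {"joy": 0.5, "anger": 0.9}


class TestFPGrowthProperty:
    def test_hundred_random_corpora(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            txns = random_corpus(rng, n_items=int(rng.integers(2, 7)),
                                 n_transactions=int(rng.integers(2, 51)))
            min_sup = float(rng.uniform(0.05, 0.6))
            assert dict(mine_frequent(txns, min_sup)) == pytest.approx(
                dict(brute_force_frequent(txns, min_sup)))
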