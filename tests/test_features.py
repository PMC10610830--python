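import numpy as np
import pytest

from hrvemotion.alq import sliding_subsequences
from hrvemotion.features import (
    FEATURE_COLUMNS,
    build_feature_matrix,
    match_features,
    match_features_naive,
)
from hrvemotion.rules import Rule, RuleSet


def rule(pattern, strength=1.0, band=""):
    return Rule(itemset=frozenset([tuple(pattern)]), strength=strength,
                origin="frequent")


def random_bag_and_rules(rng):
    alphabet = "ABCDEF"
    symbols = "".join(rng.choice(list(alphabet), size=rng.integers(5, 25)))
    bag = sliding_subsequences(symbols, lengths=(2, 3, 4, 5))
    rules = []
    for _ in range(rng.integers(0, 15)):
        L = int(rng.integers(2, 6))
        pattern = tuple(rng.choice(list(alphabet), size=L))
        rules.append(rule(pattern, strength=float(rng.uniform(0.1, 1.0))))
    return bag, RuleSet(rules=rules)


class TestMatchFeatures:
    def test_empty_ruleset_all_zero(self):
        bag = sliding_subsequences("ABCDE", lengths=(2, 3))
        f = match_features(bag, RuleSet(rules=[]))
        assert (f.MA, f.TC, f.FR, f.PR) == (0, 0.0, 0.0, 0.0)

    def test_every_window_matches(self):
        bag = sliding_subsequences("AAAAAAAAAAA", lengths=(2,))  # LE = 10
        f = match_features(bag, RuleSet(rules=[rule("AA", 1.0)]))
        assert f.MA == 10 and f.TC == pytest.approx(10.0)
        assert f.FR == pytest.approx(1.0) and f.PR == pytest.approx(0.1)

    def test_hand_worked_toy(self):
        # windows: AB BC CD / ABC BCD  (LE=5); rules AB (0.5), BCD (0.8)
        bag = sliding_subsequences("ABCD", lengths=(2, 3))
        rs = RuleSet(rules=[rule("AB", 0.5), rule("BCD", 0.8)])
        f = match_features(bag, rs)
        assert f.MA == 2
        assert f.TC == pytest.approx(1.3)
        assert f.FR == pytest.approx(0.4)
        assert f.PR == pytest.approx(1.0)

    def test_band_mismatch_rejected(self):
        bag = sliding_subsequences("AB", lengths=(2,))
        bag.band = "LF"
        with pytest.raises(ValueError):
            match_features(bag, RuleSet(rules=[], band="HF1"))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        bag, rs = random_bag_and_rules(rng)
        fast = match_features(bag, rs)
        slow = match_features_naive(bag, rs)
        assert fast.MA == slow.MA
        assert fast.TC == pytest.approx(slow.TC)
        assert fast.FR == pytest.approx(slow.FR)
        assert fast.PR == pytest.approx(slow.PR)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        bag, rs = random_bag_and_rules(rng)
        f = match_features(bag, rs)
        assert 0 <= f.MA <= bag.total
        assert 0.0 <= f.FR <= 1.0
        assert 0.0 <= f.PR <= 1.0

    def test_monotone_in_ruleset(self):
        rng = np.random.default_rng(5)
        bag, rs = random_bag_and_rules(rng)
        f1 = match_features(bag, rs)
        bigger = RuleSet(rules=rs.rules + [rule(("A", "B"), 0.7)])
        f2 = match_features(bag, bigger)
        assert f2.MA >= f1.MA and f2.TC >= f1.TC - 1e-12


class TestFeatureMatrix:
    def make_bags(self, symbols_by_band):
        return {band: sliding_subsequences(sym, lengths=(2, 3))
                for band, sym in symbols_by_band.items()}

    def test_empty_corpus(self):
        rulesets = {b: RuleSet(rules=[], band=b)
                    for b in ("LF", "HF1", "HF2", "HF3")}
        df = build_feature_matrix([], rulesets)
        assert df.shape == (0, 16)

    def test_shape_and_columns(self):
        bands = ("LF", "HF1", "HF2", "HF3")
        rulesets = {b: RuleSet(rules=[rule("AA", 0.5)], band=b) for b in bands}
        recs = [self.make_bags({b: "AABAA" for b in bands}) for _ in range(3)]
        df = build_feature_matrix(recs, rulesets, labels=["x", "y", "x"])
        assert df.shape == (3, 17)
        assert tuple(df.columns[:16]) == FEATURE_COLUMNS

    def test_missing_band_rejected(self):
        rulesets = {b: RuleSet(rules=[], band=b)
                    for b in ("LF", "HF1", "HF2", "HF3")}
        with pytest.raises(ValueError):
            build_feature_matrix([self.make_bags({"LF": "AA"})], rulesets)

    def test_planted_band_has_higher_match_frequency(self):
        # class with an 'AA'-rich LF band scores higher LF_FR than a class
        # whose LF band never produces the pattern
        bands = ("LF", "HF1", "HF2", "HF3")
        rulesets = {b: RuleSet(rules=[rule("AA", 1.0)], band=b) for b in bands}
        planted = [self.make_bags({b: ("AAAAA" if b == "LF" else "ABCDF")
                                   for b in bands}) for _ in range(5)]
        control = [self.make_bags({b: "ABCDF" for b in bands})
                   for _ in range(5)]
        df = build_feature_matrix(planted + control, rulesets,
                                  labels=["planted"] * 5 + ["control"] * 5)
        means = df.groupby("label")["LF_FR"].mean()
        assert means["planted"] > means["control"]
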