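"""Mine per-emotion rules from symbolic corpora with planted patterns.

Each emotion gets a private planted pattern; one pattern is planted in
every emotion and is removed by the universal-rule filter.
"""

from hrvemotion.rules import Transaction, filter_universal, mine_emotion_rules
from hrvemotion.synthetic import synth_level_corpus

emotions = ("joy", "anger", "sadness")
private = {"joy": ("A", "A", "B"), "anger": ("C", "D", "C"),
           "sadness": ("E", "E", "F")}
shared = ("A", "F")

corpora, truth = synth_level_corpus(
    {e: {"LF": (private[e], 1.0)} for e in emotions},
    n_recordings=40, seed=0)

per_emotion = {}
for e in emotions:
    txns = [Transaction(items=t.items | {shared}, emotion_label=e,
                        adjacent_pairs=t.adjacent_pairs)
            for t in corpora[e]["LF"]]
    per_emotion[e] = mine_emotion_rules(txns, min_support=0.8,
                                        min_reliability=0.8,
                                        correlation_threshold=0.9)
    print(f"{e}: {len(per_emotion[e])} rules before filtering")

ruleset = filter_universal(per_emotion, emotions, band="LF")
print(f"standard rule set after universal filtering: {len(ruleset)} rules")
for e in emotions:
    kept = any(r.itemset == frozenset([private[e]]) for r in ruleset.rules)
    print(f"  private pattern of {e} kept: {kept}")
gone = not any(r.itemset == frozenset([shared]) for r in ruleset.rules)
print(f"  shared pattern removed: {gone}")
print("Patterns present in every emotion carry no discriminative power and")
print("are dropped; each private pattern survives labeled with its emotion.")
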