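"""Enumerate the emotion-sequence taxonomy and classify a few pairs.

With 10 emotion categories plus the no-emotion state there are 120 ordered
sequences, split into activation / persistence / switch / down-regulation.
"""

from emoseq import DEFAULT_ALPHABET, NO_EMOTION, classify_sequence, enumerate_sequences

keys = enumerate_sequences(DEFAULT_ALPHABET)
by_type = {}
for key in keys:
    by_type.setdefault(key.seq_type.value, []).append(key)

print(f"{len(keys)} sequences over {DEFAULT_ALPHABET.k} emotion categories:")
for t, ks in by_type.items():
    print(f"  {t:16s} {len(ks):3d}   e.g. {ks[0]}")

for e1, e2 in [(NO_EMOTION, "sad"), ("anxious", "anxious"), ("anxious", "sad"), ("sad", NO_EMOTION)]:
    print(f"{e1:>11s} -> {e2:<11s} is {classify_sequence(e1, e2).value}")

# The counts 10 + 10 + 90 + 10 = 120 are the complete taxonomy: every ordered
# pair of states except (no_emotion -> no_emotion), which is not a sequence.
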