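"""Count sequences and compute adjusted relative frequencies for one diary.

A small hand-built diary shows how counts, marginals, and the ARF
normalisation ARF = f(E1->E2) / (f(E1) * f(E2) + 1) fit together.
"""

from emoseq import DEFAULT_ALPHABET, NO_EMOTION, PromptRecord, SubjectDiary, compute_arf, count_sequences

responses = [NO_EMOTION, "sad", "sad", "anxious", "anxious", "anxious", "sad", NO_EMOTION]
diary = SubjectDiary(
    subject_id="demo",
    group_label="demo",
    records=[PromptRecord(15.0 * i, r) for i, r in enumerate(responses)],
)

table = count_sequences(diary, DEFAULT_ALPHABET)
arf = compute_arf(table)

print(f"prompts: {len(diary)}, valid pairs: {table.n_pairs}")
print(f"marginals: sad={table.marginals['sad']}, anxious={table.marginals['anxious']}, "
      f"no_emotion={table.marginals[NO_EMOTION]}")
print("non-zero sequences (count and ARF):")
for key, count in table.counts.items():
    if count:
        print(f"  {str(key):24s} {key.seq_type.value:16s} f={count}  ARF={arf.arf[key]:.4f}")

# Each ARF divides the sequence count by the product of the two endpoint
# marginals plus one, so a frequent pair of emotions is not over-credited for
# co-occurring: persistence(anxious) has f=2 but marginal 3, giving 2/10.
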