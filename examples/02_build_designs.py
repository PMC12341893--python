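"""Build the constrained triad and pairwise designs and validate them.

Triad design: 192 presented trials (24 of them exact repeats), every word
shown 18 times, no word pair in more than 6 triads.  Pair design: 256 unique
pairs (each word in 16), each presented twice per task with opposite
instructions, in 16 blocks with no repeated pair and at most 5 occurrences
of a word per block.
"""

from semspace import design, stimuli

ws = stimuli.synthesize_word_set(seed=1)

td = design.build_triad_design(ws, seed=2)
st = design.design_stats(td)
print("Triad design:")
print(f"  presented trials: {st['n_presented']} (duplicates: {st['n_duplicates']})")
print(f"  per-word presentation counts: {sorted(set(st['word_counts'].values()))}")
print(f"  max pair multiplicity: {st['max_pair_multiplicity']} (cap 6)")
print(f"  pairs occurring once: {st['singleton_pair_count']}")
print(f"  violations: {st['violations']}")

pd_ = design.build_pair_design(ws, seed=3)
sp = design.design_stats(pd_)
print("\nPair design:")
print(f"  unique pairs: {sp['n_unique_pairs']}, trials: {sp['n_trials']}")
print(f"  pair types: {sp['pair_type_counts']}")
print(f"  pairs per word: {sorted(set(sp['pairs_per_word'].values()))}")
print(f"  max word occurrences in a block: {sp['max_word_per_block']} (cap 5)")
print(f"  violations: {sp['violations']}")
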