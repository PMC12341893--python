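"""Simulate a small cohort and compute response-consistency QC.

Control-like responders follow a 2D space built from concreteness+valence
and dominance-arousal; SV-like responders follow a valence-only space with
noisier (less deterministic) choices.  Consistency is the fraction of
repeated triads answered with the same odd word, and of pairs answered
consistently under opposite instructions; both drop with response noise.
"""

from semspace import design, qc, simulate, stimuli

ws = stimuli.synthesize_word_set(seed=1)
td = design.build_triad_design(ws, seed=2)
pdn = design.build_pair_design(ws, seed=3)

gc = simulate.GeneratorConfig(n_control=4, n_sv=4)
responses, truth = simulate.simulate_cohort(ws, td, pdn, gc, seed=4)
print(f"simulated {responses['participant_id'].nunique()} participants, "
      f"{len(responses)} responses")

rows = []
for pid, sub in responses.groupby("participant_id"):
    tri = sub[sub["task"] == "triad"]
    rows.append((pid, qc.triad_consistency(tri, td)))
    pairs = sub[sub["task"].isin(["pair_conc", "pair_val"])]
    rows.append((pid, qc.pair_consistency(pairs, pdn, "concreteness")))
report = qc.consistency_report(rows)
print("\nConsistency by participant (triad: chance = 1/3, pairs: chance = 1/2):")
print(report.to_string(index=False))
print(
    "\nControl-like participants (hc*) are systematically more "
    "self-consistent on the pairwise tasks than the noisier sv-like "
    "participants (sv*); triad consistency separates the groups too, but "
    "only 24 repeats per participant make it a coarse measure."
)
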