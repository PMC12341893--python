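"""Interpret fitted MDS dimensions by regression on the word norms.

Each dimension of the aligned posterior is regressed on the eight norms
(concreteness, valence, arousal, dominance, AoA, OND, length, prevalence);
repeating the regression over the 50 posterior samples yields, per
predictor, the fraction of samples with |t| > 1.96.  A control-like space
should load dimension 1 on concreteness+valence and dimension 2 on
dominance+arousal; an SV-like space should show valence everywhere and no
concreteness effect.
"""

from semspace import bmds, design, interpret, simulate, stimuli

ws = stimuli.synthesize_word_set(seed=1)
td = design.build_triad_design(ws, seed=2)
pdn = design.build_pair_design(ws, seed=3)
gc = simulate.GeneratorConfig(n_control=10, n_sv=10)
responses, truth = simulate.simulate_cohort(ws, td, pdn, gc, seed=4)

for group, label in (("control_like", "HC-like"), ("sv_like", "SV-like")):
    tri = responses[(responses["task"] == "triad") & (responses["group"] == group)]
    ps = bmds.fit_bmds(tri, ws.word_ids, bmds.reduced_config(), seed=5)
    ps = bmds.align_samples(ps, reference=truth["configs"][group].coords)
    mean_res, dists = interpret.interpret_fit(ps, ws)
    print(f"\n=== {label} pooled fit ===")
    for dim in (1, 2):
        frac = dists[dim].frac_significant.sort_values(ascending=False)
        top = ", ".join(f"{k} ({v:.0%})" for k, v in frac.head(3).items())
        print(f"dim {dim}: majority-significant = "
              f"{dists[dim].majority_significant()}")
        print(f"        top fractions of samples with |t| > 1.96: {top}")
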