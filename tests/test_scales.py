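import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes as scipy_procrustes

from semspace import scales, simulate
from semspace.design import PairDesign, PairTrial
from semspace.scales import (
    RelativeScale,
    build_relative_scale,
    combine_and_procrustes,
    crawford_howell,
    kendall_vs_ratings,
    stimulus_error_anova,
)
from semspace.stimuli import WordSet


def responses_from(design, chooser):
    """Build a response frame by applying chooser(left, right, instruction)."""
    rows = []
    for i, t in enumerate(design.trials):
        left, right = t.pair
        rows.append(
            {
                "trial_index": i,
                "task": t.task,
                "instruction": t.instruction,
                "word_left": left,
                "word_right": right,
                "choice": chooser(left, right, t.instruction),
            }
        )
    return pd.DataFrame(rows)


class TestRelativeScale:
    def test_always_most_concrete_scores_plus_one(self, ws, pair_design):
        target = "w17"  # concrete_positive

        def chooser(left, right, ins):
            if target in (left, right):
                other = right if left == target else left
                return target if ins == "concrete" else other
            return left

        r = responses_from(pair_design, chooser)
        rs = build_relative_scale(r, pair_design, "concreteness")
        assert rs.scores[target] == pytest.approx(1.0)
        assert rs.n_pairs[target] == 16

    def test_contradictory_choices_cancel_to_zero(self, ws, pair_design):
        # the same word chosen under both instructions of every pair: +1 and
        # -1 per pair cancel
        def chooser(left, right, ins):
            return min(left, right)

        r = responses_from(pair_design, chooser)
        rs = build_relative_scale(r, pair_design, "concreteness")
        for pair, _ in pair_design.unique_pairs:
            w = min(pair)
            assert rs.scores[w] == pytest.approx(0.0)

    def test_scores_bounded(self, ws, pair_design, rng):
        def chooser(left, right, ins):
            return left if rng.random() < 0.5 else right

        rs = build_relative_scale(
            responses_from(pair_design, chooser), pair_design, "valence"
        )
        assert (rs.scores.abs() <= 1).all()

    def test_pole_swap_negates_scores(self, ws, pair_design, rng):
        """Relabelling each response to the opposite instruction negates every
        score."""
        def chooser(left, right, ins):
            return left if rng.random() < 0.5 else right

        r = responses_from(pair_design, chooser)
        swap = {"concrete": "abstract", "abstract": "concrete"}
        r_sw = r.copy()
        r_sw["instruction"] = r_sw["instruction"].replace(swap)
        a = build_relative_scale(r, pair_design, "concreteness").scores
        b = build_relative_scale(r_sw, pair_design, "concreteness").scores
        assert np.allclose(a, -b)

    def test_missing_pairs_warn(self, ws, pair_design):
        def chooser(left, right, ins):
            return left

        r = responses_from(pair_design, chooser).iloc[:100]
        with pytest.warns(UserWarning, match="coverage"):
            build_relative_scale(r, pair_design, "concreteness")

    def test_perfect_norm_follower_gets_tau_one(self, ws, pair_design):
        """A deterministic responder ordering by the true norms produces a
        scale whose ranking agrees with the norms (tau = 1 barring ties)."""
        conc = ws.to_frame().set_index("word_id")["concreteness"]

        def chooser(left, right, ins):
            more = left if conc[left] >= conc[right] else right
            less = right if more == left else left
            return more if ins == "concrete" else less

        rs = build_relative_scale(
            responses_from(pair_design, chooser), pair_design, "concreteness"
        )
        tau, p = kendall_vs_ratings(rs, ws)
        assert tau > 0.9
        assert p < 1e-6


class TestKendall:
    def test_identical_and_reversed_orderings(self, ws):
        df = ws.to_frame().set_index("word_id")
        rs = RelativeScale(
            "valence",
            df["valence"].rank(),
            pd.Series(16, index=df.index),
        )
        tau, _ = kendall_vs_ratings(rs, ws)
        assert tau == pytest.approx(1.0)
        rs_rev = RelativeScale(
            "valence", -df["valence"].rank(), pd.Series(16, index=df.index)
        )
        tau, _ = kendall_vs_ratings(rs_rev, ws)
        assert tau == pytest.approx(-1.0)

    def test_matches_exhaustive_concordance_count(self, rng):
        """tau-b equals the brute-force concordant/discordant count with tie
        correction for every small input."""
        for n in (4, 6, 8):
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            conc = disc = tx = ty = 0
            for i, j in itertools.combinations(range(n), 2):
                sx = np.sign(x[i] - x[j])
                sy = np.sign(y[i] - y[j])
                if sx == 0 and sy == 0:
                    continue
                if sx == 0:
                    tx += 1
                elif sy == 0:
                    ty += 1
                elif sx == sy:
                    conc += 1
                else:
                    disc += 1
            denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
            expected = (conc - disc) / denom
            got = stats.kendalltau(x, y).statistic
            assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_scale_reports_undefined(self, ws):
        rs = RelativeScale(
            "valence",
            pd.Series(0.0, index=ws.word_ids),
            pd.Series(16, index=ws.word_ids),
        )
        with pytest.warns(UserWarning):
            tau, p = kendall_vs_ratings(rs, ws)
        assert np.isnan(tau)


class TestCrawfordHowell:
    def test_case_at_control_mean(self):
        res = crawford_howell(12.0, [10.0, 12.0, 14.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_direct_formula_evaluation(self, rng):
        controls = rng.normal(12, 2, size=74)
        res = crawford_howell(10.0, controls)
        m, s, n = controls.mean(), controls.std(ddof=1), 74
        expected_t = (10.0 - m) / (s * np.sqrt((n + 1) / n))
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.df == 73
        assert res.p == pytest.approx(
            2 * stats.t.sf(abs(expected_t), 73), abs=1e-12
        )

    def test_printed_style_example(self):
        # case 10 vs controls mean 12, SD 2, n 74: t = -2 / (2 sqrt(75/74))
        rng = np.random.default_rng(0)
        controls = rng.normal(size=74)
        controls = (controls - controls.mean()) / controls.std(ddof=1) * 2 + 12
        res = crawford_howell(10.0, controls)
        assert res.t == pytest.approx(-0.99334, abs=1e-4)

    def test_large_n_approaches_z_score(self, rng):
        controls = rng.normal(0, 1, size=200_000)
        controls = (controls - controls.mean()) / controls.std(ddof=1)
        res = crawford_howell(1.5, controls)
        assert res.t == pytest.approx(1.5, abs=1e-3)

    def test_two_tailed_symmetry(self, rng):
        controls = rng.normal(5, 1.3, size=30)
        m, s = controls.mean(), controls.std(ddof=1)
        hi = crawford_howell(m + 1.7 * s, controls)
        lo = crawford_howell(m - 1.7 * s, controls)
        assert hi.p == pytest.approx(lo.p, abs=1e-12)
        assert hi.t == pytest.approx(-lo.t, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = crawford_howell(3.0, [2.0, 2.0, 2.0])
        assert res.zero_variance
        assert np.isinf(res.t)


def scale_from(series, task):
    return RelativeScale(task, series, pd.Series(16, index=series.index))


class TestProcrustes:
    def _target_scales(self, ws):
        df = ws.to_frame().set_index("word_id")
        return (
            scale_from(df["valence"], "valence"),
            scale_from(df["concreteness"], "concreteness"),
        )

    def test_source_equal_to_target_has_zero_error(self, ws):
        val, conc = self._target_scales(ws)
        pr = combine_and_procrustes(val, conc, ws)
        assert pr.ss_error == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(pr.residuals, 0.0, atol=1e-12)

    def test_rotated_and_scaled_source_still_fits_exactly(self, ws):
        df = ws.to_frame().set_index("word_id")
        target = np.column_stack([df["valence"], df["concreteness"]])
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = 2.0 * target @ R.T
        val = scale_from(pd.Series(moved[:, 0], index=df.index), "valence")
        conc = scale_from(pd.Series(moved[:, 1], index=df.index), "concreteness")
        pr = combine_and_procrustes(val, conc, ws)
        assert pr.ss_error == pytest.approx(0.0, abs=1e-10)

    def test_ss_invariant_to_similarity_transform_of_source(self, ws, rng):
        df = ws.to_frame().set_index("word_id")
        src = np.column_stack([df["valence"], df["concreteness"]])
        src = src + rng.normal(0, 0.5, src.shape)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = 3.7 * src @ R.T + np.array([5.0, -2.0])
        pr_a = combine_and_procrustes(
            scale_from(pd.Series(src[:, 0], index=df.index), "valence"),
            scale_from(pd.Series(src[:, 1], index=df.index), "concreteness"),
            ws,
        )
        pr_b = combine_and_procrustes(
            scale_from(pd.Series(moved[:, 0], index=df.index), "valence"),
            scale_from(pd.Series(moved[:, 1], index=df.index), "concreteness"),
            ws,
        )
        assert pr_a.ss_error == pytest.approx(pr_b.ss_error, abs=1e-10)

    def test_matches_scipy_procrustes_disparity(self, ws, rng):
        df = ws.to_frame().set_index("word_id")
        src = np.column_stack([df["valence"], df["concreteness"]])
        src = src + rng.normal(0, 0.8, src.shape)
        pr = combine_and_procrustes(
            scale_from(pd.Series(src[:, 0], index=df.index), "valence"),
            scale_from(pd.Series(src[:, 1], index=df.index), "concreteness"),
            ws,
        )
        target = np.column_stack([df["valence"], df["concreteness"]])
        _, _, disparity = scipy_procrustes(target, src)
        assert pr.ss_error == pytest.approx(disparity, abs=1e-10)

    def test_perturbed_stimulus_carries_largest_residual(self, ws):
        df = ws.to_frame().set_index("word_id")
        src = np.column_stack([df["valence"], df["concreteness"]]).astype(float)
        victim = 5
        src[victim] += np.array([1.5, -1.5])
        pr = combine_and_procrustes(
            scale_from(pd.Series(src[:, 0], index=df.index), "valence"),
            scale_from(pd.Series(src[:, 1], index=df.index), "concreteness"),
            ws,
        )
        assert pr.residuals.idxmax() == df.index[victim]
        assert pr.ss_error == pytest.approx(pr.residuals.sum())

    def test_degenerate_source_rejected(self, ws):
        flat = pd.Series(0.0, index=ws.word_ids)
        with pytest.raises(ValueError):
            combine_and_procrustes(
                scale_from(flat, "valence"), scale_from(flat, "concreteness"), ws
            )


class TestStimulusErrorAnova:
    def _pr_with(self, ws, residuals):
        return scales.ProcrustesResult(
            rotation=np.eye(2),
            scale=1.0,
            translation=np.zeros(2),
            ss_error=float(np.sum(residuals)),
            residuals=pd.Series(residuals, index=ws.word_ids),
        )

    def test_equal_residuals_give_zero_f(self, ws):
        F, p = stimulus_error_anova(self._pr_with(ws, np.full(32, 0.3)), ws)
        assert F == 0.0
        assert p == 1.0

    def test_planted_group_effect_detected(self, ws, rng):
        resid = rng.uniform(0.0, 0.05, size=32)
        concrete = [
            i for i, w in enumerate(ws.words)
            if w.word_class.startswith("concrete")
        ]
        resid[concrete] += 1.0
        F, p = stimulus_error_anova(self._pr_with(ws, resid), ws)
        assert p < 0.01

    def test_matches_manual_mean_square_ratio(self, ws, rng):
        resid = rng.uniform(0, 1, size=32)
        F, p = stimulus_error_anova(self._pr_with(ws, resid), ws)
        groups = {}
        for r, w in zip(resid, ws.words):
            groups.setdefault(w.word_class, []).append(r)
        gs = [np.array(v) for v in groups.values()]
        grand = np.concatenate(gs).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
        manual = (ssb / 3) / (ssw / 28)
        assert F == pytest.approx(manual, rel=1e-10)


class TestEndToEndResponder:
    def test_sharp_responder_scale_orders_like_norms(self, ws, pair_design):
        prof = simulate.ParticipantProfile(
            "control_like", kappa_conc=50.0, kappa_val=50.0, lapse=0.0
        )
        r = simulate.simulate_pair_responses(ws, pair_design, prof, seed=11)
        for task, col in (("concreteness", "concreteness"), ("valence", "valence")):
            rs = build_relative_scale(r, pair_design, task)
            tau, _ = kendall_vs_ratings(rs, ws)
            assert tau > 0.85
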