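"""Pairwise-judgement analysis: relative scales, rank agreement, single-case
statistics, and Procrustes matching to the norm-based configuration.

A word scores +1 each time it is selected under the positive-pole
instruction ("concrete" / "positive"), −1 each time it is selected under the
negative-pole instruction, and 0 when unselected; the sum over a word's
trials divided by its unique-pair count (16 in the full design) yields a
relative scale in [−1, 1].  Scales are compared with the underlying norm
ratings by Kendall tau-b, individual participants are compared with a
control sample by the Crawford–Howell single-case t-test, and the 2D space
(valence scale, concreteness scale) is mapped onto the norm-rating space by
similarity Procrustes with a per-stimulus residual breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import INSTRUCTION_TASK, PairDesign, POSITIVE_POLE
from .stimuli import WORD_CLASSES, WordSet

_TASK_RATING = {"concreteness": "concreteness", "valence": "valence"}
_TASK_KEY = {"pair_conc": "concreteness", "pair_val": "valence",
             "concreteness": "concreteness", "valence": "valence"}


@dataclass
class RelativeScale:
    task: str
    scores: pd.Series          # index word_id, values in [-1, 1]
    n_pairs: pd.Series         # unique pairs per word used as the divisor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word_id": self.scores.index,
                "task": self.task,
                "score": self.scores.values,
                "n_pairs": self.n_pairs.reindex(self.scores.index).values,
            }
        )


@dataclass
class SingleCaseResult:
    case_value: float
    control_mean: float
    control_sd: float
    n_controls: int
    t: float
    df: int
    p: float
    zero_variance: bool = False


@dataclass
class ProcrustesResult:
    rotation: np.ndarray       # 2x2 orthogonal (may include reflection)
    scale: float
    translation: np.ndarray
    ss_error: float
    residuals: pd.Series       # per-stimulus squared residual

    def __post_init__(self) -> None:
        assert self.ss_error >= 0


def build_relative_scale(
    responses: pd.DataFrame, d: PairDesign, task: str
) -> RelativeScale:
    """Score one participant's pairwise responses into a relative scale.

    ``task`` is "concreteness" or "valence" (the cohort labels "pair_conc" /
    "pair_val" are accepted).  Expects columns instruction, word_left,
    word_right, choice.  Words whose pairs are partially missing are scored
    over the available pairs with a coverage warning.
    """
    task = _TASK_KEY.get(task, task)
    if task not in _TASK_RATING:
        raise ValueError(f"unknown task {task!r}")
    pos_pole = POSITIVE_POLE[task]

    expected = d.pairs_per_word()
    words = list(expected)
    raw = pd.Series(0.0, index=words)
    seen_pairs: dict[str, set] = {w: set() for w in words}

    for row in responses.itertuples():
        ins = str(row.instruction)
        if INSTRUCTION_TASK.get(ins) != task:
            continue
        choice = str(row.choice)
        pair = frozenset((str(row.word_left), str(row.word_right)))
        if choice not in pair:
            raise ValueError(f"choice {choice!r} not in pair {sorted(pair)}")
        raw[choice] += 1.0 if ins == pos_pole else -1.0
        for w in pair:
            seen_pairs[w].add(pair)

    n_pairs = pd.Series({w: len(seen_pairs[w]) for w in words})
    missing = {w for w in words if n_pairs[w] < expected[w]}
    if missing:
        warnings.warn(
            f"{len(missing)} words have incomplete pair coverage; scores "
            "computed over available pairs"
        )
    divisor = n_pairs.replace(0, np.nan)
    scores = (raw / divisor).fillna(0.0)
    return RelativeScale(task=task, scores=scores, n_pairs=n_pairs)


def kendall_vs_ratings(rs: RelativeScale, ws: WordSet) -> tuple[float, float]:
    """Kendall tau-b between a relative scale and the underlying norm ratings."""
    rating_col = _TASK_RATING[rs.task]
    df = ws.to_frame().set_index("word_id")
    common = [w for w in rs.scores.index if w in df.index]
    if len(common) < 3:
        raise ValueError("need at least 3 words")
    x = rs.scores.loc[common].to_numpy()
    y = df.loc[common, rating_col].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Kendall tau undefined")
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def crawford_howell(
    case_value: float, control_values, two_tailed: bool = True
) -> SingleCaseResult:
    """Crawford–Howell modified t-test of one case against a control sample.

    t = (case − mean) / (sd * sqrt((n + 1) / n)) with n − 1 degrees of
    freedom, treating the case as a random draw from the control population.
    """
    controls = np.asarray(control_values, dtype=float)
    n = len(controls)
    if n < 2:
        raise ValueError("need at least 2 control values")
    mean = float(controls.mean())
    sd = float(controls.std(ddof=1))
    df = n - 1
    if sd == 0:
        t = float("inf") if case_value != mean else 0.0
        t *= np.sign(case_value - mean) if case_value != mean else 1.0
        p = 0.0 if case_value != mean else 1.0
        return SingleCaseResult(case_value, mean, sd, n, t, df, p,
                                zero_variance=True)
    t = (case_value - mean) / (sd * np.sqrt((n + 1) / n))
    p_one = float(stats.t.sf(abs(t), df))
    p = 2 * p_one if two_tailed else p_one
    return SingleCaseResult(case_value, mean, sd, n, float(t), df, float(p))


def _standardize(M: np.ndarray) -> np.ndarray:
    """Column-centre and scale to unit Frobenius norm.

    The global (not per-column) scaling keeps standardization equivariant
    under similarity transforms, so the fitted SS error is invariant to any
    rotation/reflection/scaling/translation applied to either configuration.
    """
    M = M - M.mean(axis=0)
    norm = np.linalg.norm(M)
    if norm == 0:
        raise ValueError("degenerate configuration: no variance around centroid")
    return M / norm


def combine_and_procrustes(
    val_scale: RelativeScale, conc_scale: RelativeScale, ws: WordSet
) -> ProcrustesResult:
    """Map the (valence, concreteness) scale space onto the rating space.

    Both configurations are column-centred and unit-normalized, then the
    similarity transform (translation + rotation/reflection + isotropic
    scale) minimizing the residual sum of squares is fitted by SVD.  Returns
    the transform, the total SS error and per-stimulus squared residuals.
    """
    words = [w for w in val_scale.scores.index if w in conc_scale.scores.index]
    df = ws.to_frame().set_index("word_id")
    words = [w for w in words if w in df.index]
    if len(words) < 3:
        raise ValueError("need at least 3 shared words")

    source = np.column_stack(
        [val_scale.scores.loc[words], conc_scale.scores.loc[words]]
    )
    target = np.column_stack(
        [df.loc[words, "valence"], df.loc[words, "concreteness"]]
    )
    if np.linalg.matrix_rank(source - source.mean(axis=0)) == 0:
        raise ValueError("rank-0 source configuration")

    A = _standardize(source)
    B = _standardize(target)

    U, s, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    scale = float(s.sum()) / float((A ** 2).sum())
    fitted = scale * A @ R
    resid = ((fitted - B) ** 2).sum(axis=1)
    ss = float(resid.sum())
    translation = B.mean(axis=0) - scale * (A @ R).mean(axis=0)  # 0 after centring
    return ProcrustesResult(
        rotation=R,
        scale=scale,
        translation=translation,
        ss_error=ss,
        residuals=pd.Series(resid, index=words),
    )


def stimulus_error_anova(
    pr: ProcrustesResult, ws: WordSet
) -> tuple[float, float]:
    """One-way ANOVA of per-stimulus Procrustes residuals across word classes."""
    cls = {w.word_id: w.word_class for w in ws.words}
    groups = []
    for c in WORD_CLASSES:
        vals = [pr.residuals[w] for w in pr.residuals.index if cls.get(w) == c]
        if len(vals) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 stimuli")
        groups.append(np.asarray(vals))
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)
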