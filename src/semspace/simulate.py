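"""Synthetic participants: latent semantic spaces and stochastic responders.

The generator emulates two responder populations.  Control-like participants
carry a 2D semantic space whose first dimension mixes concreteness and
valence and whose second mixes dominance (+) and arousal (−); semantic-
variant-like participants carry a space driven by valence alone on both
dimensions, the degraded "circumplex" organization.  Triad responses follow
the exponential-decay odd-one-out rule (the same likelihood the inference
model assumes); pairwise responses follow a logistic comparison of the
instructed attribute, a generator-side convention since the judgement tasks
themselves imply no particular response model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .design import (
    INSTRUCTION_TASK,
    PairDesign,
    POSITIVE_POLE,
    TriadDesign,
)
from .stimuli import PREDICTOR_FEATURES, WordSet


@dataclass
class LatentConfig:
    """Per-word 2D coordinates of a latent semantic space."""

    coords: np.ndarray          # (n_words, 2)
    word_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.word_ids), 2):
            raise ValueError("coords must be (n_words, 2) aligned to word_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def index_of(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.word_ids)}


@dataclass
class ParticipantProfile:
    """Response parameters of one synthetic participant.

    delta is the odd-one-out determinism (inverse temperature of the
    exponential-decay choice rule), kappa_conc / kappa_val the logistic
    discrimination slopes of the two pairwise tasks, and lapse the
    probability of a uniform guess on any trial.
    """

    group: str                   # "control_like" | "sv_like"
    delta: float = 3.0
    kappa_conc: float = 3.0
    kappa_val: float = 3.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.kappa_conc < 0 or self.kappa_val < 0:
            raise ValueError("kappa slopes must be >= 0")
        if not (0 <= self.lapse < 1):
            raise ValueError("lapse must be in [0, 1)")


#: Feature loadings (rows = dimensions, columns = PREDICTOR_FEATURES).
def _weight_matrix(loadings: dict[str, tuple[float, float]]) -> np.ndarray:
    W = np.zeros((2, len(PREDICTOR_FEATURES)))
    for feat, (w1, w2) in loadings.items():
        j = PREDICTOR_FEATURES.index(feat)
        W[0, j] = w1
        W[1, j] = w2
    return W


CONTROL_LIKE_W = _weight_matrix(
    {"concreteness": (0.7, 0.0), "valence": (0.6, 0.0),
     "dominance": (0.0, 0.7), "arousal": (0.0, -0.5)}
)
SV_LIKE_W = _weight_matrix({"valence": (-0.9, 0.6)})

GROUP_PRESETS = {
    "control_like": {
        "W": CONTROL_LIKE_W,
        "noise_sd": 0.3,
        "delta_median": 3.0,
        "delta_log_sd": 0.3,
        "kappa_conc_median": 3.0,
        "kappa_val_median": 3.0,
        "kappa_log_sd": 0.3,
        "lapse": 0.02,
    },
    "sv_like": {
        "W": SV_LIKE_W,
        "noise_sd": 0.3,
        "delta_median": 1.5,
        "delta_log_sd": 0.3,
        "kappa_conc_median": 0.3,
        "kappa_val_median": 3.0,
        "kappa_log_sd": 0.3,
        "lapse": 0.05,
    },
}


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings (defaults mirror the study cohort)."""

    n_control: int = 77
    n_sv: int = 10
    presets: dict = field(default_factory=lambda: {
        g: dict(p, W=np.array(p["W"])) for g, p in GROUP_PRESETS.items()
    })


def minkowski_distance(a: np.ndarray, b: np.ndarray, r: float = 2.0) -> np.ndarray:
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.sum(d ** r, axis=-1) ** (1.0 / r)


def rescale_unit_square(coords: np.ndarray) -> np.ndarray:
    """Min–max rescale each dimension to [0, 1] (the inference prior support)."""
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    return (coords - lo) / span


def make_latent_config(
    ws: WordSet,
    W: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    rescale: bool = True,
) -> LatentConfig:
    """Project z-scored word norms into a 2D space: coords = Z W' + noise.

    ``W`` has shape (2, 8) over :data:`~semspace.stimuli.PREDICTOR_FEATURES`.
    With ``rescale`` the configuration is min–max mapped to the unit square,
    matching the support of the inference model's coordinate prior.
    """
    rng = np.random.default_rng(seed)
    W = np.asarray(W, dtype=float)
    if W.shape != (2, len(PREDICTOR_FEATURES)):
        raise ValueError(f"W must have shape (2, {len(PREDICTOR_FEATURES)})")
    Z = ws.zscored_features().to_numpy()
    coords = Z @ W.T
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    if rescale:
        coords = rescale_unit_square(coords)
    return LatentConfig(coords, ws.word_ids)


def triad_choice_probs(
    coords: np.ndarray, triad: tuple[int, int, int], delta: float, r: float = 2.0
) -> np.ndarray:
    """P(odd = A, B, C) under the exponential-decay rule.

    The probability of a word being the odd one out decays exponentially with
    delta times the distance between the *other two* words: the closer the
    remaining pair, the more likely the third is odd.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    a, b, c = triad
    d_bc = minkowski_distance(coords[b], coords[c], r)  # odd = a
    d_ac = minkowski_distance(coords[a], coords[c], r)  # odd = b
    d_ab = minkowski_distance(coords[a], coords[b], r)  # odd = c
    logits = -delta * np.array([d_bc, d_ac, d_ab])
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def simulate_triad_responses(
    lc: LatentConfig,
    d: TriadDesign,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
    minkowski_r: float = 2.0,
) -> pd.DataFrame:
    """Generate one participant's odd-one-out choices for every design trial.

    Returns a long-format frame with columns trial_index, word1..word3,
    choice (the odd word).  With probability ``lapse`` the choice is uniform.
    """
    rng = np.random.default_rng(seed)
    idx = lc.index_of()
    rows = []
    for t_i, trial in enumerate(d.trials):
        tri = tuple(idx[w] for w in trial.words)
        if rng.random() < profile.lapse:
            choice = int(rng.integers(3))
        else:
            p = triad_choice_probs(lc.coords, tri, profile.delta, minkowski_r)
            choice = int(rng.choice(3, p=p))
        rows.append(
            {
                "trial_index": t_i,
                "word1": trial.words[0],
                "word2": trial.words[1],
                "word3": trial.words[2],
                "choice": trial.words[choice],
            }
        )
    return pd.DataFrame(rows)


def simulate_pair_responses(
    ws: WordSet,
    d: PairDesign,
    profile: ParticipantProfile,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate one participant's pairwise choices for both judgement tasks.

    Under instruction "concrete" the left word is chosen with probability
    logistic(kappa_conc * (c_left − c_right)) on z-scored concreteness;
    "abstract" flips the sign; the valence task is analogous with kappa_val.
    """
    rng = np.random.default_rng(seed)
    z = ws.zscored_features()
    rows = []
    for t_i, trial in enumerate(d.trials):
        task = INSTRUCTION_TASK.get(trial.instruction)
        if task is None:
            raise ValueError(f"unknown instruction {trial.instruction!r}")
        attr = "concreteness" if task == "concreteness" else "valence"
        kappa = profile.kappa_conc if task == "concreteness" else profile.kappa_val
        left, right = trial.pair
        diff = z.loc[left, attr] - z.loc[right, attr]
        sign = 1.0 if trial.instruction == POSITIVE_POLE[task] else -1.0
        p_left = float(special.expit(kappa * sign * diff))
        p_left = profile.lapse * 0.5 + (1 - profile.lapse) * p_left
        choice = left if rng.random() < p_left else right
        rows.append(
            {
                "trial_index": t_i,
                "task": trial.task,
                "instruction": trial.instruction,
                "word_left": left,
                "word_right": right,
                "choice": choice,
            }
        )
    return pd.DataFrame(rows)


def draw_profile(group: str, preset: dict, rng) -> ParticipantProfile:
    """Draw participant parameters from a group preset (log-normal spreads)."""
    return ParticipantProfile(
        group=group,
        delta=float(preset["delta_median"]
                    * np.exp(rng.normal(0, preset["delta_log_sd"]))),
        kappa_conc=float(preset["kappa_conc_median"]
                         * np.exp(rng.normal(0, preset["kappa_log_sd"]))),
        kappa_val=float(preset["kappa_val_median"]
                        * np.exp(rng.normal(0, preset["kappa_log_sd"]))),
        lapse=float(preset["lapse"]),
    )


def simulate_cohort(
    ws: WordSet,
    triad_design: TriadDesign,
    pair_design: PairDesign,
    gc: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort for both tasks.

    Each group shares one latent configuration (group-level semantic space);
    participants differ in their drawn determinism/slope/lapse parameters.
    Returns a long response table (participant_id, group, task, trial fields,
    choice) and a ground-truth record holding the latent configurations,
    loadings, and per-participant profiles for recovery experiments.
    """
    gc = gc or GeneratorConfig()
    rng = np.random.default_rng(seed)

    truth: dict = {"configs": {}, "profiles": {}, "W": {}}
    frames = []
    counts = {"control_like": gc.n_control, "sv_like": gc.n_sv}
    prefix = {"control_like": "hc", "sv_like": "sv"}
    for group, n in counts.items():
        preset = gc.presets[group]
        lc = make_latent_config(
            ws, preset["W"], preset["noise_sd"], seed=rng.integers(2**31)
        )
        truth["configs"][group] = lc
        truth["W"][group] = np.asarray(preset["W"])
        for k in range(n):
            pid = f"{prefix[group]}{k + 1:03d}"
            profile = draw_profile(group, preset, rng)
            truth["profiles"][pid] = profile
            tri = simulate_triad_responses(
                lc, triad_design, profile, seed=rng.integers(2**31)
            )
            tri.insert(0, "participant_id", pid)
            tri.insert(1, "group", group)
            tri.insert(2, "task", "triad")
            pr = simulate_pair_responses(
                ws, pair_design, profile, seed=rng.integers(2**31)
            )
            pr.insert(0, "participant_id", pid)
            pr.insert(1, "group", group)
            pr["task"] = "pair_" + pr["task"].map(
                {"concreteness": "conc", "valence": "val"}
            )
            frames.append(tri)
            frames.append(pr)
    responses = pd.concat(frames, ignore_index=True)
    return responses, truth
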