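"""Word-norm data model, stimulus inclusion rules, and synthetic word-set generation.

The stimulus material crosses two manipulated psycholinguistic dimensions —
concreteness (1–5 scale) and valence (1–7 scale) — into four word classes
(abstract/concrete x positive/negative), while the remaining norms (arousal,
dominance, age of acquisition, frequency, orthographic neighbourhood density,
length, prevalence) are matched across classes.  Because the behavioural
stimulus list itself is not distributed, :func:`synthesize_word_set` draws a
statistically equivalent 32-word set from the published class means and SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

WORD_CLASSES = (
    "abstract_positive",
    "abstract_negative",
    "concrete_positive",
    "concrete_negative",
)

#: Norm features used as regression predictors (frequency is an inclusion
#: filter, not a predictor).
PREDICTOR_FEATURES = (
    "concreteness",
    "valence",
    "arousal",
    "dominance",
    "aoa",
    "orth_nd",
    "length",
    "prevalence",
)

RATING_FEATURES = PREDICTOR_FEATURES + ("log10_frequency",)

# Rating-scale bounds per feature; None means unbounded above.
FEATURE_BOUNDS: dict[str, tuple[float, float | None]] = {
    "concreteness": (1.0, 5.0),
    "valence": (1.0, 7.0),
    "arousal": (1.0, 7.0),
    "dominance": (1.0, 7.0),
    "aoa": (0.0, None),
    "log10_frequency": (0.0, None),
    "orth_nd": (0.0, None),
    "length": (1.0, None),
    "prevalence": (0.0, 1.0),
}


class InvalidNormsError(ValueError):
    """A rating field is missing or NaN."""


class ConfigError(ValueError):
    """An infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class WordNorms:
    """Ratings of a single word on nine psycholinguistic dimensions.

    Parameters
    ----------
    word_id
        Opaque label ("w01", ...).
    concreteness
        1–5 rating; low = abstract.
    valence
        1–7 rating; low = negative.
    arousal, dominance
        1–7 affective ratings.
    aoa
        Age of acquisition in years.
    log10_frequency
        Base-10 log word frequency.
    orth_nd
        Orthographic neighbourhood density (count).
    length
        Word length in letters.
    prevalence
        Fraction of the population knowing the word, in [0, 1].
    word_class
        One of :data:`WORD_CLASSES`, or ``None`` if not yet classified.
    """

    word_id: str
    concreteness: float
    valence: float
    arousal: float
    dominance: float
    aoa: float
    log10_frequency: float
    orth_nd: float
    length: float
    prevalence: float
    word_class: str | None = None

    def ratings(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in RATING_FEATURES}


@dataclass
class WordSet:
    """A stimulus set: a list of classified words."""

    words: list[WordNorms] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w.word_id for w in self.words]
        if len(set(ids)) != len(ids):
            raise ValueError("word_ids must be unique")

    def __len__(self) -> int:
        return len(self.words)

    @property
    def word_ids(self) -> list[str]:
        return [w.word_id for w in self.words]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in WORD_CLASSES}
        for w in self.words:
            if w.word_class is not None:
                counts[w.word_class] = counts.get(w.word_class, 0) + 1
        return counts

    def classes(self) -> dict[str, list[str]]:
        """Mapping word_class -> word_ids, in insertion order."""
        out: dict[str, list[str]] = {c: [] for c in WORD_CLASSES}
        for w in self.words:
            if w.word_class is not None:
                out.setdefault(w.word_class, []).append(w.word_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.words:
            row = {"word_id": w.word_id, **w.ratings(), "word_class": w.word_class}
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WordSet":
        required = {"word_id", *RATING_FEATURES}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"word-norm table missing columns: {sorted(missing)}")
        words = []
        for _, row in df.iterrows():
            wc = row.get("word_class")
            if wc is not None and (isinstance(wc, float) and math.isnan(wc)):
                wc = None
            words.append(
                WordNorms(
                    word_id=str(row["word_id"]),
                    word_class=wc,
                    **{f: float(row[f]) for f in RATING_FEATURES},
                )
            )
        return cls(words)

    def feature_matrix(self, features=PREDICTOR_FEATURES) -> np.ndarray:
        return np.array([[getattr(w, f) for f in features] for w in self.words])

    def zscored_features(self, features=PREDICTOR_FEATURES) -> pd.DataFrame:
        """Within-set z-scored feature matrix (ddof=1).

        Raises
        ------
        ValueError
            If a feature has zero variance across the set (it cannot be
            standardized), naming the feature.
        """
        X = self.feature_matrix(features)
        sd = X.std(axis=0, ddof=1)
        for f, s in zip(features, sd):
            if s == 0 or not np.isfinite(s):
                raise ValueError(f"feature {f!r} has zero variance; cannot z-score")
        Z = (X - X.mean(axis=0)) / sd
        return pd.DataFrame(Z, columns=list(features), index=self.word_ids)


# --- inclusion / classification rules -------------------------------------

ABSTRACT_BAND = (1.5, 2.5)
CONCRETE_BAND = (4.0, 5.0)
NEGATIVE_BAND = (2.0, 4.0)   # valence in [2, 4) is negative
POSITIVE_BAND = (4.0, 6.0)   # valence in (4, 6] is positive; exactly 4 excluded
MIN_LOG10_FREQUENCY = 1.0
MIN_PREVALENCE = 0.98


def classify_word(norms: WordNorms) -> str:
    """Classify a word into one of the four stimulus classes, or exclude it.

    Inclusion requires log10 frequency >= 1 and prevalence >= 0.98.
    Concreteness in [1.5, 2.5] is abstract, [4, 5] is concrete; the middle of
    the scale is excluded.  Valence in [2, 4) is negative, (4, 6] positive;
    valence exactly 4 sits on both printed interval boundaries and is excluded
    as ambiguous, as are values outside [2, 6].

    Returns the class label, or an exclusion code prefixed ``"excluded:"``
    (``low_frequency``, ``low_prevalence``, ``mid_concreteness``,
    ``out_of_range_valence``).
    """
    for f in RATING_FEATURES:
        v = getattr(norms, f)
        if v is None or not math.isfinite(float(v)):
            raise InvalidNormsError(f"rating {f!r} is missing or non-finite")

    if norms.log10_frequency < MIN_LOG10_FREQUENCY:
        return "excluded:low_frequency"
    if norms.prevalence < MIN_PREVALENCE:
        return "excluded:low_prevalence"

    c = norms.concreteness
    if ABSTRACT_BAND[0] <= c <= ABSTRACT_BAND[1]:
        conc = "abstract"
    elif CONCRETE_BAND[0] <= c <= CONCRETE_BAND[1]:
        conc = "concrete"
    else:
        return "excluded:mid_concreteness"

    v = norms.valence
    if NEGATIVE_BAND[0] <= v < NEGATIVE_BAND[1]:
        val = "negative"
    elif POSITIVE_BAND[0] < v <= POSITIVE_BAND[1]:
        val = "positive"
    else:
        return "excluded:out_of_range_valence"

    return f"{conc}_{val}"


# --- synthetic word-set generation ----------------------------------------

# Published class means and SDs for the two manipulated features.
MANIPULATED_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "concreteness": {
        "abstract_positive": (2.04, 0.3),
        "abstract_negative": (2.03, 0.3),
        "concrete_positive": (4.4, 0.3),
        "concrete_negative": (4.4, 0.3),
    },
    "valence": {
        "abstract_positive": (5.2, 0.4),
        "abstract_negative": (2.6, 0.4),
        "concrete_positive": (5.3, 0.4),
        "concrete_negative": (2.8, 0.4),
    },
}

# Matched (nuisance) features: pooled mean/SD shared by all classes.
NUISANCE_DEFAULTS: dict[str, tuple[float, float]] = {
    "aoa": (8.3, 1.5),
    "arousal": (4.5, 0.7),
    "dominance": (4.4, 0.6),
    "orth_nd": (2.4, 3.2),
    "length": (6.9, 1.6),
    "log10_frequency": (2.5, 0.6),
    "prevalence": (0.99, 0.01),
}

_MAX_RESAMPLE = 1000


def default_generator_config() -> dict[str, dict[str, dict[str, float]]]:
    """Default feature -> class -> {mean, sd} configuration."""
    cfg: dict[str, dict[str, dict[str, float]]] = {}
    for feat, per_class in MANIPULATED_DEFAULTS.items():
        cfg[feat] = {c: {"mean": m, "sd": s} for c, (m, s) in per_class.items()}
    for feat, (m, s) in NUISANCE_DEFAULTS.items():
        cfg[feat] = {c: {"mean": m, "sd": s} for c in WORD_CLASSES}
    return cfg


def _truncnorm_draw(rng, mean, sd, lo, hi):
    if sd == 0:
        if (lo is not None and mean < lo) or (hi is not None and mean > hi):
            raise ConfigError(f"degenerate mean {mean} outside bounds [{lo}, {hi}]")
        return mean
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def synthesize_word_set(
    config: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    seed: int | np.random.Generator = 0,
    n_per_class: int = 8,
) -> WordSet:
    """Draw a synthetic stimulus set of ``4 * n_per_class`` classified words.

    Features are drawn per class from truncated normals (respecting each
    rating scale's bounds); a word is resampled until :func:`classify_word`
    assigns it its intended class, so the generated set always passes the
    inclusion rules.  Orthographic neighbourhood density and length are
    rounded to nonnegative integers, prevalence is clamped to [0.98, 1].

    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cfg = default_generator_config()
    if config is not None:
        for feat, per_class in config.items():
            if feat not in cfg:
                raise ConfigError(f"unknown feature {feat!r} in generator config")
            for c, ms in per_class.items():
                cfg[feat][c] = dict(ms)

    words: list[WordNorms] = []
    i = 0
    for cls_name in WORD_CLASSES:
        for _ in range(n_per_class):
            i += 1
            word = _draw_word(rng, cfg, cls_name, f"w{i:02d}")
            words.append(word)
    return WordSet(words)


def _draw_word(rng, cfg, cls_name, word_id) -> WordNorms:
    for _ in range(_MAX_RESAMPLE):
        vals = {}
        for feat in RATING_FEATURES:
            ms = cfg[feat][cls_name]
            lo, hi = FEATURE_BOUNDS[feat]
            v = _truncnorm_draw(rng, ms["mean"], ms["sd"], lo, hi)
            if feat in ("orth_nd", "length"):
                v = float(max(0, round(v)))
            if feat == "prevalence":
                v = float(np.clip(v, MIN_PREVALENCE, 1.0))
            vals[feat] = v
        candidate = WordNorms(word_id=word_id, **vals)
        if classify_word(candidate) == cls_name:
            return replace(candidate, word_class=cls_name)
    raise ConfigError(
        f"could not draw a word of class {cls_name!r} passing the inclusion "
        f"rules after {_MAX_RESAMPLE} attempts; check the configured means/SDs"
    )


def check_matching(ws: WordSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature class means/SDs and a one-way ANOVA across classes.

    Returns a DataFrame indexed by feature with per-class ``mean_<class>`` /
    ``sd_<class>`` columns plus ``F``, ``p`` and a boolean ``differs`` flag
    (ANOVA p below ``alpha``).  Used to confirm that the manipulated features
    (concreteness, valence) separate the classes while the nuisance features
    remain matched.
    """
    by_class = {c: [w for w in ws.words if w.word_class == c] for c in WORD_CLASSES}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 words; ANOVA undefined")

    rows = []
    for feat in RATING_FEATURES:
        groups = [
            np.array([getattr(w, feat) for w in members])
            for members in by_class.values()
        ]
        if np.ptp(np.concatenate(groups)) == 0:
            F, p = 0.0, 1.0  # feature constant everywhere: no between-class variance
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                F, p = stats.f_oneway(*groups)
            if not np.isfinite(F):
                F, p = float(F), 0.0
        row = {"feature": feat}
        for c, g in zip(by_class, groups):
            row[f"mean_{c}"] = float(np.mean(g))
            row[f"sd_{c}"] = float(np.std(g, ddof=1))
        row["F"] = float(F)
        row["p"] = float(p)
        row["differs"] = bool(p < alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def read_word_norms(path) -> WordSet:
    """Read a word-norm CSV (columns word_id, ratings..., word_class)."""
    return WordSet.from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_word_norms(ws: WordSet, path) -> None:
    # %.17g keeps float64 ratings bit-exact through a CSV round trip
    ws.to_frame().to_csv(path, index=False, float_format="%.17g")
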