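"""Constrained experimental designs for the triad and pairwise judgement tasks.

Triad design: 192 presented trials over 32 words — 168 unique triads plus 24
exact repeats used for within-participant consistency — with every word shown
exactly 18 times, no unordered pair in more than 6 triads, and a replacement
pass that minimizes pairs occurring in only one triad.

Pair design: 256 unique pairs (16 same-quadrant pairs per class, 32 pairs for
each of the four one-shared-dimension class pairings, 32 for each of the two
no-shared-dimension pairings), every word in exactly 16 pairs; each pair is
presented twice per task with opposite instructions, packed into 16 blocks
with no pair repeated within a block and no word more than 5 times per block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import WORD_CLASSES, WordSet


class ConfigError(ValueError):
    pass


class DesignSearchError(RuntimeError):
    """The randomized constraint search failed within its restart budget."""


# --------------------------------------------------------------------------
# Triad design
# --------------------------------------------------------------------------

@dataclass
class TriadTrial:
    words: tuple[str, str, str]
    is_repeat: bool = False
    repeat_of: int | None = None


@dataclass
class TriadDesign:
    trials: list[TriadTrial]
    word_ids: list[str]

    @property
    def n_presented(self) -> int:
        return len(self.trials)

    @property
    def n_duplicates(self) -> int:
        return sum(t.is_repeat for t in self.trials)

    def unique_triads(self) -> list[frozenset]:
        return [frozenset(t.words) for t in self.trials if not t.is_repeat]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": range(len(self.trials)),
                "word1": [t.words[0] for t in self.trials],
                "word2": [t.words[1] for t in self.trials],
                "word3": [t.words[2] for t in self.trials],
                "is_repeat": [t.is_repeat for t in self.trials],
                "repeat_of": [
                    -1 if t.repeat_of is None else t.repeat_of for t in self.trials
                ],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TriadDesign":
        required = {"trial_index", "word1", "word2", "word3", "is_repeat", "repeat_of"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"triad design CSV missing columns: {sorted(missing)}")
        df = df.sort_values("trial_index")
        trials = [
            TriadTrial(
                (str(r.word1), str(r.word2), str(r.word3)),
                bool(r.is_repeat),
                None if int(r.repeat_of) < 0 else int(r.repeat_of),
            )
            for r in df.itertuples()
        ]
        word_ids = sorted({w for t in trials for w in t.words})
        return cls(trials, word_ids)


def _pairs_of(triad) -> list[frozenset]:
    a, b, c = sorted(triad)  # stable order: set iteration is hash-dependent
    return [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]


def build_triad_design(
    ws: WordSet,
    seed: int = 0,
    n_presented: int = 192,
    n_duplicates: int = 24,
    pair_cap: int = 6,
    min_initial_occurrences: int = 12,
    replace_budget: int = 10_000,
) -> TriadDesign:
    """Build a balanced triad design.

    Stage 1 draws ``n_presented - n_duplicates`` unique triads under the pair
    multiplicity cap, keeping per-word counts within one of each other.
    Stage 2 selects ``n_duplicates`` of them to repeat so that every word's
    presented count is exactly ``3 * n_presented / n_words``.  Stage 3 is a
    greedy 2-opt pass that reduces the number of pairs occurring in a single
    triad while preserving counts and the cap.

    Deterministic given ``seed``.
    """
    words = ws.word_ids if isinstance(ws, WordSet) else list(ws)
    n_words = len(words)
    if n_words < 4:
        raise ConfigError("need at least 4 words")
    if (3 * n_presented) % n_words != 0:
        raise ConfigError(
            f"3 * n_presented = {3 * n_presented} not divisible by {n_words} words; "
            "exact per-word balance impossible"
        )
    n_unique = n_presented - n_duplicates
    if n_unique < 1 or n_duplicates < 0:
        raise ConfigError("n_duplicates must be in [0, n_presented)")
    from math import comb

    if n_unique > comb(n_words, 3):
        raise ConfigError("more unique triads requested than exist")

    target = 3 * n_presented // n_words
    rng = np.random.default_rng(seed)

    for _restart in range(20):
        try:
            triads, counts = _sample_unique_triads(
                rng, words, n_unique, pair_cap, target, min_initial_occurrences
            )
            dup_idx = _select_duplicates(rng, triads, counts, n_duplicates, target, words)
        except DesignSearchError:
            continue
        triads = _reduce_singleton_pairs(
            rng, triads, dup_idx, pair_cap, replace_budget
        )
        return _assemble_triad_design(rng, triads, dup_idx, words)
    raise DesignSearchError(
        "triad design search failed: could not satisfy per-word balance and "
        f"pair cap {pair_cap} within the restart budget"
    )


def _sample_unique_triads(rng, words, n_unique, pair_cap, target, min_occ):
    """Randomized greedy sampling of unique triads, keeping counts level."""
    counts = {w: 0 for w in words}
    pair_mult: dict[frozenset, int] = {}
    chosen: set[frozenset] = set()
    triads: list[frozenset] = []
    max_count = target  # presented-count ceiling before duplication
    for _ in range(n_unique):
        placed = False
        for _attempt in range(200):
            # favour low-count words to keep the configuration balanced
            order = sorted(words, key=lambda w: (counts[w], rng.random()))
            k = 6 if len(words) >= 6 else len(words)
            cand = list(rng.permutation(order[:k]))[:3]
            tri = frozenset(cand)
            if len(tri) != 3 or tri in chosen:
                continue
            if any(counts[w] + 1 > max_count for w in tri):
                continue
            if any(pair_mult.get(p, 0) + 1 > pair_cap for p in _pairs_of(tri)):
                continue
            chosen.add(tri)
            triads.append(tri)
            for w in tri:
                counts[w] += 1
            for p in _pairs_of(tri):
                pair_mult[p] = pair_mult.get(p, 0) + 1
            placed = True
            break
        if not placed:
            raise DesignSearchError("stuck while sampling unique triads")
    # level-filling keeps counts within 1 of each other, which subsumes the
    # minimum-occurrence requirement of the initial random stage
    del min_occ
    return triads, counts


def _select_duplicates(rng, triads, counts, n_dup, target, words):
    """Choose n_dup distinct triads to repeat so presented counts hit target."""
    need = {w: target - counts[w] for w in words}
    if any(v < 0 for v in need.values()) or sum(need.values()) != 3 * n_dup:
        raise DesignSearchError("unique-triad counts incompatible with duplication")
    if n_dup == 0:
        if any(need.values()):
            raise DesignSearchError("nonzero deficit with zero duplicates")
        return []

    n = len(triads)
    sel = list(rng.choice(n, size=n_dup, replace=False))

    def deficit(selection):
        inc = {w: 0 for w in counts}
        for i in selection:
            for w in triads[i]:
                inc[w] += 1
        return sum(abs(inc[w] - need[w]) for w in counts)

    cur = deficit(sel)
    sel_set = set(sel)
    for _ in range(20_000):
        if cur == 0:
            return sorted(sel_set)
        i_out = sel[rng.integers(len(sel))]
        i_in = int(rng.integers(n))
        if i_in in sel_set:
            continue
        new_sel = [i for i in sel if i != i_out] + [i_in]
        d = deficit(new_sel)
        if d <= cur:
            sel, sel_set, cur = new_sel, set(new_sel), d
    raise DesignSearchError("duplicate selection hill-climb did not converge")


def _reduce_singleton_pairs(rng, triads, dup_idx, pair_cap, budget):
    """2-opt pass: re-partition two triads' six words to remove singleton pairs.

    Swapping words between two triads preserves every word's count exactly,
    so balance is untouched; moves are accepted when they do not increase the
    singleton-pair count and respect the multiplicity cap.
    """
    triads = list(triads)
    dup_set = set(dup_idx)

    def pair_mult_table(ts):
        m: dict[frozenset, int] = {}
        for t in ts:
            for p in _pairs_of(t):
                m[p] = m.get(p, 0) + 1
        return m

    mult = pair_mult_table(triads)
    n_singletons = sum(1 for v in mult.values() if v == 1)
    chosen = set(triads)

    for _ in range(budget):
        if n_singletons == 0:
            break
        singles = [p for p, v in mult.items() if v == 1]
        if not singles:
            break
        p = singles[rng.integers(len(singles))]
        # the unique triad containing this singleton pair
        i = next(
            idx for idx, t in enumerate(triads) if p <= t
        )
        if i in dup_set:
            continue  # keep duplicated triads fixed so repeat flags stay valid
        j = int(rng.integers(len(triads)))
        if j == i or j in dup_set:
            continue
        a, b = triads[i], triads[j]
        pool = a | b
        if len(pool) != 6:
            continue
        pool = sorted(pool)  # stable base order: set iteration is hash-dependent
        rng.shuffle(pool)
        new_a, new_b = frozenset(pool[:3]), frozenset(pool[3:])
        if new_a in chosen or new_b in chosen or new_a == new_b:
            continue
        trial_mult = dict(mult)
        for t in (a, b):
            for q in _pairs_of(t):
                trial_mult[q] -= 1
        ok = True
        for t in (new_a, new_b):
            for q in _pairs_of(t):
                trial_mult[q] = trial_mult.get(q, 0) + 1
                if trial_mult[q] > pair_cap:
                    ok = False
        if not ok:
            continue
        new_singles = sum(1 for v in trial_mult.values() if v == 1)
        if new_singles <= n_singletons:
            chosen.discard(a)
            chosen.discard(b)
            chosen.add(new_a)
            chosen.add(new_b)
            triads[i], triads[j] = new_a, new_b
            mult = {q: v for q, v in trial_mult.items() if v > 0}
            n_singletons = new_singles
    return triads


def _assemble_triad_design(rng, triads, dup_idx, words) -> TriadDesign:
    trials: list[TriadTrial] = []
    first_index: dict[frozenset, int] = {}
    for tri in triads:
        order = tuple(rng.permutation(sorted(tri)))
        first_index[tri] = len(trials)
        trials.append(TriadTrial(order))
    for i in dup_idx:
        tri = triads[i]
        order = tuple(rng.permutation(sorted(tri)))
        trials.append(TriadTrial(order, is_repeat=True, repeat_of=first_index[tri]))
    return TriadDesign(trials, list(words))


# --------------------------------------------------------------------------
# Pair design
# --------------------------------------------------------------------------

PAIR_TYPES = ("same_quadrant", "share_one_dimension", "share_none")

#: Instructions per task; index 0 is the positive pole of the attribute.
TASK_INSTRUCTIONS = {
    "concreteness": ("concrete", "abstract"),
    "valence": ("positive", "negative"),
}
INSTRUCTION_TASK = {
    ins: task for task, pair in TASK_INSTRUCTIONS.items() for ins in pair
}
POSITIVE_POLE = {"concreteness": "concrete", "valence": "positive"}

# class pairings sharing exactly one of (concreteness level, valence sign)
_SHARE_ONE = [
    ("abstract_positive", "abstract_negative"),
    ("concrete_positive", "concrete_negative"),
    ("abstract_positive", "concrete_positive"),
    ("abstract_negative", "concrete_negative"),
]
_SHARE_NONE = [
    ("abstract_positive", "concrete_negative"),
    ("abstract_negative", "concrete_positive"),
]


def pair_type(class_a: str, class_b: str) -> str:
    """Quadrant relation of a pair given the two words' classes."""
    if class_a == class_b:
        return "same_quadrant"
    ca, va = class_a.split("_")
    cb, vb = class_b.split("_")
    shared = (ca == cb) + (va == vb)
    return "share_one_dimension" if shared == 1 else "share_none"


@dataclass
class PairTrial:
    pair: tuple[str, str]          # (left, right) as presented
    instruction: str
    block: int                      # 1-based
    task: str
    ptype: str


@dataclass
class PairDesign:
    unique_pairs: list[tuple[frozenset, str]]  # (pair, pair_type)
    trials: list[PairTrial] = field(default_factory=list)
    word_ids: list[str] = field(default_factory=list)
    n_blocks: int = 16

    def trials_for_task(self, task: str) -> list[PairTrial]:
        return [t for t in self.trials if t.task == task]

    def pairs_per_word(self) -> dict[str, int]:
        counts = {w: 0 for w in self.word_ids}
        for p, _ in self.unique_pairs:
            for w in p:
                counts[w] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": range(len(self.trials)),
                "task": [t.task for t in self.trials],
                "block": [t.block for t in self.trials],
                "word_left": [t.pair[0] for t in self.trials],
                "word_right": [t.pair[1] for t in self.trials],
                "instruction": [t.instruction for t in self.trials],
                "pair_type": [t.ptype for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairDesign":
        required = {
            "trial_index", "task", "block", "word_left", "word_right",
            "instruction", "pair_type",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pair design CSV missing columns: {sorted(missing)}")
        df = df.sort_values("trial_index")
        trials = [
            PairTrial(
                (str(r.word_left), str(r.word_right)),
                str(r.instruction),
                int(r.block),
                str(r.task),
                str(r.pair_type),
            )
            for r in df.itertuples()
        ]
        seen: dict[frozenset, str] = {}
        for t in trials:
            seen.setdefault(frozenset(t.pair), t.ptype)
        word_ids = sorted({w for t in trials for w in t.pair})
        return cls(list(seen.items()), trials, word_ids, int(df["block"].max()))


def _regular_same_quadrant_pairs(rng, members):
    """16 pairs among 8 words with every word in exactly 4 (circulant graph)."""
    perm = list(rng.permutation(members))
    n = len(perm)
    pairs = []
    for off in (1, 2):
        for i in range(n):
            pairs.append(frozenset((perm[i], perm[(i + off) % n])))
    return sorted(set(pairs), key=lambda p: sorted(p))


def _regular_bipartite_pairs(rng, left, right, degree):
    """degree-regular bipartite pairs via stacked random matchings."""
    n = len(left)
    base = list(rng.permutation(right))
    pairs = []
    for k in range(degree):
        for i in range(n):
            pairs.append(frozenset((left[i], base[(i + k) % n])))
    return pairs


def build_pair_design(
    ws: WordSet,
    seed: int = 0,
    n_blocks: int = 16,
    max_word_per_block: int = 5,
    restarts: int = 200,
) -> PairDesign:
    """Build the pairwise-judgement design for both tasks.

    256 unique pairs are constructed so that each word participates in
    exactly 16 (4 within its quadrant, 4 with each of the two one-dimension
    neighbours, 4 across both dimensions).  Each pair is presented twice per
    task with opposite instructions; the 512 presentations per task fill 16
    blocks of 32 under the no-repeated-pair and at-most-5-per-word block
    constraints.  Both tasks share the block structure.
    """
    classes = ws.classes()
    for c in WORD_CLASSES:
        if len(classes.get(c, [])) != 8:
            raise ConfigError(
                f"pair design requires 8 words per quadrant; class {c!r} has "
                f"{len(classes.get(c, []))}"
            )
    rng = np.random.default_rng(seed)

    unique: list[tuple[frozenset, str]] = []
    for c in WORD_CLASSES:
        for p in _regular_same_quadrant_pairs(rng, classes[c]):
            unique.append((p, "same_quadrant"))
    for ca, cb in _SHARE_ONE:
        for p in _regular_bipartite_pairs(rng, classes[ca], classes[cb], 4):
            unique.append((p, "share_one_dimension"))
    for ca, cb in _SHARE_NONE:
        for p in _regular_bipartite_pairs(rng, classes[ca], classes[cb], 4):
            unique.append((p, "share_none"))

    if len({p for p, _ in unique}) != len(unique):
        raise DesignSearchError("pair construction produced a duplicate pair")

    blocks = _assign_blocks(rng, [p for p, _ in unique], n_blocks,
                            max_word_per_block, restarts)

    ptype_of = dict(unique)
    trials: list[PairTrial] = []
    for task in TASK_INSTRUCTIONS:
        pos, neg = TASK_INSTRUCTIONS[task]
        # each pair: one presentation per half with opposite instructions,
        # polarity order randomized per pair
        for (pair, (b1, b2)) in blocks.items():
            ins = (pos, neg) if rng.random() < 0.5 else (neg, pos)
            for b, instruction in zip((b1, b2), ins):
                wa, wb = sorted(pair)
                left, right = (wa, wb) if rng.random() < 0.5 else (wb, wa)
                trials.append(
                    PairTrial((left, right), instruction, b, task, ptype_of[pair])
                )
    trials.sort(key=lambda t: (t.task, t.block))
    return PairDesign(unique, trials, ws.word_ids, n_blocks)


def _assign_blocks(rng, pairs, n_blocks, max_word_per_block, restarts):
    """Assign each pair two distinct blocks meeting the block constraints.

    Each of the ``2 * len(pairs)`` presentations goes to one block; a block
    may not contain the same pair twice nor any word more than
    ``max_word_per_block`` times.
    """
    n_pairs = len(pairs)
    cap = 2 * n_pairs // n_blocks
    if 2 * n_pairs % n_blocks != 0:
        raise ConfigError("2 * n_pairs must be divisible by n_blocks")
    for _ in range(restarts):
        block_pairs = [set() for _ in range(n_blocks)]
        block_words: list[dict] = [dict() for _ in range(n_blocks)]
        block_load = [0] * n_blocks
        order = list(rng.permutation(n_pairs))
        ok = True
        assignment: dict[frozenset, tuple[int, int]] = {}
        for idx in order:
            pair = pairs[idx]
            feas = [
                b for b in range(n_blocks)
                if block_load[b] < cap
                and pair not in block_pairs[b]
                and all(block_words[b].get(w, 0) < max_word_per_block for w in pair)
            ]
            if len(feas) < 2:
                ok = False
                break
            # least-loaded feasible blocks with random tie-break
            rng.shuffle(feas)
            feas.sort(key=lambda b: block_load[b])
            b1, b2 = feas[0], feas[1]
            for b in (b1, b2):
                block_pairs[b].add(pair)
                for w in pair:
                    block_words[b][w] = block_words[b].get(w, 0) + 1
                block_load[b] += 1
            assignment[pair] = (b1 + 1, b2 + 1)
        if ok:
            return assignment
    raise DesignSearchError(
        "block assignment failed: could not honour the no-repeat-pair and "
        f"max-{max_word_per_block}-per-word constraints in {restarts} restarts"
    )


# --------------------------------------------------------------------------
# Validators and presentation order
# --------------------------------------------------------------------------

def design_stats(d: TriadDesign | PairDesign) -> dict:
    """Deterministic constraint report for either design type."""
    if isinstance(d, TriadDesign):
        word_counts = {w: 0 for w in d.word_ids}
        pair_mult: dict[frozenset, int] = {}
        for t in d.trials:
            for w in t.words:
                word_counts[w] += 1
        for tri in d.unique_triads():
            for p in _pairs_of(tri):
                pair_mult[p] = pair_mult.get(p, 0) + 1
        singleton = sum(1 for v in pair_mult.values() if v == 1)
        violations = []
        if word_counts and len(set(word_counts.values())) > 1:
            violations.append("unequal per-word presentation counts")
        for t in d.trials:
            if len(set(t.words)) != 3:
                violations.append(f"triad with repeated word: {t.words}")
        return {
            "kind": "triad",
            "n_presented": d.n_presented,
            "n_duplicates": d.n_duplicates,
            "word_counts": word_counts,
            "pair_multiplicities": pair_mult,
            "max_pair_multiplicity": max(pair_mult.values(), default=0),
            "singleton_pair_count": singleton,
            "violations": violations,
        }

    word_pairs = d.pairs_per_word()
    type_counts = {pt: 0 for pt in PAIR_TYPES}
    for _, pt in d.unique_pairs:
        type_counts[pt] += 1
    block_loads: dict[tuple[str, int], dict[str, int]] = {}
    block_pair_seen: dict[tuple[str, int], set] = {}
    violations = []
    for t in d.trials:
        key = (t.task, t.block)
        load = block_loads.setdefault(key, {})
        for w in t.pair:
            load[w] = load.get(w, 0) + 1
        seen = block_pair_seen.setdefault(key, set())
        fp = frozenset(t.pair)
        if fp in seen:
            violations.append(f"pair {sorted(fp)} repeated in block {key}")
        seen.add(fp)
    max_block_word = max(
        (max(load.values()) for load in block_loads.values()), default=0
    )
    return {
        "kind": "pair",
        "n_unique_pairs": len(d.unique_pairs),
        "n_trials": len(d.trials),
        "pairs_per_word": word_pairs,
        "pair_type_counts": type_counts,
        "max_word_per_block": max_block_word,
        "violations": violations,
    }


def randomize_presentation(d: TriadDesign | PairDesign, seed: int = 0,
                           task: str | None = None) -> list[int]:
    """Per-participant presentation order (a permutation of trial indices).

    Triad designs: a full shuffle re-drawn until no duplicate trial is
    adjacent to its original.  Pair designs: block order is shuffled and
    trials shuffled within blocks, so blocks stay contiguous; ``task``
    restricts the permutation to one task's trials.
    """
    rng = np.random.default_rng(seed)
    if isinstance(d, TriadDesign):
        idx = np.arange(len(d.trials))
        for _ in range(1000):
            perm = rng.permutation(idx)
            pos = {int(t): i for i, t in enumerate(perm)}
            bad = any(
                t.repeat_of is not None and abs(pos[i] - pos[t.repeat_of]) == 1
                for i, t in enumerate(d.trials)
            )
            if not bad:
                return [int(i) for i in perm]
        return [int(i) for i in perm]  # pragma: no cover - virtually impossible

    trials = d.trials
    indices = [
        i for i, t in enumerate(trials) if task is None or t.task == task
    ]
    by_block: dict[tuple[str, int], list[int]] = {}
    for i in indices:
        by_block.setdefault((trials[i].task, trials[i].block), []).append(i)
    keys = list(by_block)
    order = rng.permutation(len(keys))
    out: list[int] = []
    for k in order:
        blk = by_block[keys[int(k)]]
        out.extend(int(i) for i in rng.permutation(blk))
    return out
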