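"""Data-quality metrics: response consistency on repeated presentations.

Triad task: 24 trials are exact repeats of earlier triads; a repeat is
consistent when the same odd word was chosen both times.  Pairwise tasks:
every pair is presented twice with opposite instructions; a pair is
consistent when the two chosen words differ (picking the same word as both
"most concrete" and "most abstract" is inconsistent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .design import INSTRUCTION_TASK, PairDesign, TriadDesign


@dataclass
class ConsistencyResult:
    task: str
    n_eligible: int
    n_consistent: int

    @property
    def proportion(self) -> float:
        if self.n_eligible == 0:
            return float("nan")
        return self.n_consistent / self.n_eligible


def triad_consistency(
    responses: pd.DataFrame, d: TriadDesign
) -> ConsistencyResult:
    """Proportion of duplicate triads answered with the same odd word.

    ``responses`` holds one participant's triad rows (trial_index, choice).
    Duplicates with a missing response on either presentation are dropped
    from the denominator with a warning.
    """
    choice_by_trial = dict(
        zip(responses["trial_index"].astype(int), responses["choice"].astype(str))
    )
    n_eligible = 0
    n_consistent = 0
    n_missing = 0
    for i, trial in enumerate(d.trials):
        if not trial.is_repeat:
            continue
        first = choice_by_trial.get(trial.repeat_of)
        second = choice_by_trial.get(i)
        if first is None or second is None:
            n_missing += 1
            continue
        n_eligible += 1
        n_consistent += first == second
    if n_missing:
        warnings.warn(f"{n_missing} duplicate triads missing a response")
    return ConsistencyResult("triad", n_eligible, n_consistent)


def pair_consistency(
    responses: pd.DataFrame, d: PairDesign, task: str
) -> ConsistencyResult:
    """Proportion of pairs answered consistently across opposite instructions.

    ``task`` is "concreteness" or "valence".  A pair is consistent iff the
    word chosen under the positive-pole instruction differs from the word
    chosen under the negative-pole instruction.
    """
    task = {"pair_conc": "concreteness", "pair_val": "valence"}.get(task, task)
    if task not in ("concreteness", "valence"):
        raise ValueError(f"unknown task {task!r}")
    per_pair: dict[frozenset, dict[str, str]] = {}
    for row in responses.itertuples():
        ins = str(row.instruction)
        if INSTRUCTION_TASK.get(ins) != task:
            continue
        pair = frozenset((str(row.word_left), str(row.word_right)))
        per_pair.setdefault(pair, {})[ins] = str(row.choice)
    n_eligible = 0
    n_consistent = 0
    n_missing = 0
    for pair, by_ins in per_pair.items():
        if len(by_ins) != 2:
            n_missing += 1
            continue
        a, b = by_ins.values()
        n_eligible += 1
        n_consistent += a != b
    if n_missing:
        warnings.warn(f"{n_missing} pairs missing one of the two instructions")
    return ConsistencyResult(task, n_eligible, n_consistent)


def consistency_report(rows: list[tuple[str, ConsistencyResult]]) -> pd.DataFrame:
    """Flatten (participant_id, result) pairs into the QC CSV schema."""
    return pd.DataFrame(
        [
            {
                "participant_id": pid,
                "task": r.task,
                "n_eligible": r.n_eligible,
                "n_consistent": r.n_consistent,
                "proportion": r.proportion,
            }
            for pid, r in rows
        ]
    )
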