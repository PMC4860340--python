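"""Flexibility scoring, preference labeling, and cross-context correlation.

Behavioral flexibility is measured in two contexts.  In the color context
the flexibility score is the number of trials to reverse a learned
preference minus the number of trials to learn it initially.  In the
water-tube context a bird is flexible when its object preference moves in
the functional direction between the baseline experiment (heavy objects
more functional) and the follow-up in which the formerly functional option
is disabled (previously-preferred -> none, previously-preferred -> newly
functional, or none -> newly functional).  The two measures are compared
with a tie-corrected Spearman rank correlation, coding water-tube
flexibility yes = 1, anything else (including confounded birds) = 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import FlexbanditError, InsufficientDataError
from .io import (
    CORRECT_OPTION,
    OPTION_DOMAIN,
    BirdSummary,
    Experiment,
    WaterTubeSession,
)
from .stats import (
    BinomialResult,
    SpearmanResult,
    adjust_family,
    binom_two_tailed,
    spearman_tied,
)

__all__ = [
    "WaterFlex",
    "PreferenceLabel",
    "FlexibilityRecord",
    "reversal_score",
    "preference_label",
    "preference_labels",
    "preference_labels_from_counts",
    "water_flexibility",
    "cross_context",
    "first_choice_tally",
    "summary_means",
]

ALPHA = 0.05


class WaterFlex(str, enum.Enum):
    YES = "yes"
    NO = "no"
    CONFOUNDED = "confounded"
    ABSENT = "absent"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class PreferenceLabel:
    """Preferred option of one bird in one water-tube experiment.

    ``preferred`` is the majority option when the Holm-adjusted two-tailed
    binomial p is below 0.05, else ``"none"``.
    """

    bird_id: str
    experiment_id: Experiment
    preferred: str
    binomial: BinomialResult


@dataclass(frozen=True)
class FlexibilityRecord:
    """Per-bird flexibility measures across the two contexts."""

    bird_id: str
    learning_speed: Optional[int]          # trials to initial criterion
    color_flex_score: Optional[int]        # reversal trials minus learning trials
    water_flex: WaterFlex = WaterFlex.ABSENT


def reversal_score(summary: BirdSummary) -> Optional[int]:
    """Color-context flexibility score: reversal trials minus learning trials.

    ``None`` when the reversal was not completed.  A negative score (faster
    to reverse than to learn; not observed in practice) is returned as-is.
    """
    if summary.exp2_trials is None or summary.exp1_trials is None or summary.exp2_incomplete:
        return None
    return summary.exp2_trials - summary.exp1_trials


def _label_from_counts(
    bird_id: str,
    experiment: Experiment,
    majority_option: str,
    majority_count: int,
    total: int,
    result: BinomialResult,
) -> PreferenceLabel:
    preferred = "none"
    if result.p_adjusted is not None and result.p_adjusted < ALPHA and total > 0:
        if 2 * majority_count >= total:
            preferred = majority_option
        else:  # count was actually the minority; the other option dominates
            domain = OPTION_DOMAIN[experiment]
            preferred = domain[1] if majority_option == domain[0] else domain[0]
    return PreferenceLabel(
        bird_id=bird_id, experiment_id=experiment, preferred=preferred, binomial=result
    )


def preference_labels_from_counts(
    counts: Mapping[str, tuple[int, int]],
    experiment: Experiment,
    count_option: Optional[str] = None,
) -> dict[str, PreferenceLabel]:
    """Preference labels from per-bird (count, total) splits within one family.

    ``counts`` maps bird -> (count of ``count_option`` choices, total
    choices); ``count_option`` defaults to the experiment's functional
    option.  The whole mapping is one Holm family.
    """
    if count_option is None:
        count_option = CORRECT_OPTION[experiment]
    birds = list(counts)
    raw = []
    for bird in birds:
        k, n = counts[bird]
        if n == 0:
            raise InsufficientDataError(f"{bird}: zero choices")
        raw.append(binom_two_tailed(k, n, 0.5))
    adjusted = adjust_family(raw)
    return {
        bird: _label_from_counts(bird, experiment, count_option, counts[bird][0],
                                 counts[bird][1], res)
        for bird, res in zip(birds, adjusted)
    }


def preference_labels(
    family: Sequence[WaterTubeSession],
    include_accidental: bool = True,
) -> dict[str, PreferenceLabel]:
    """Preference labels for all sessions of one experiment (one Holm family).

    Choice counts include accidental insertions by default, matching the
    convention that a bird can learn from any object entering the tube.
    """
    if not family:
        raise InsufficientDataError("empty session family")
    experiments = {s.experiment_id for s in family}
    if len(experiments) != 1:
        raise FlexbanditError(
            f"a Holm family must come from one experiment, got {sorted(e.value for e in experiments)}"
        )
    experiment = next(iter(experiments))
    functional = CORRECT_OPTION[experiment]
    counts: dict[str, tuple[int, int]] = {}
    for session in family:
        by_option = session.option_counts(include_accidental=include_accidental)
        total = sum(by_option.values())
        if total == 0:
            raise InsufficientDataError(f"{session.bird_id}: zero choices")
        counts[session.bird_id] = (by_option[functional], total)
    return preference_labels_from_counts(counts, experiment, count_option=functional)


def preference_label(
    session: WaterTubeSession,
    family: Sequence[WaterTubeSession],
    include_accidental: bool = True,
) -> PreferenceLabel:
    """Preference label for one session, Holm-adjusted within its family."""
    labels = preference_labels(list(family), include_accidental=include_accidental)
    if session.bird_id not in labels:
        raise FlexbanditError(f"session bird {session.bird_id!r} not in family")
    return labels[session.bird_id]


def water_flexibility(
    label3: PreferenceLabel,
    label4: PreferenceLabel,
    confound: bool = False,
) -> WaterFlex:
    """Did the preference move in the functional direction between the
    baseline and the switched experiment?

    The move counts as flexible when the bird goes from the formerly
    functional option to none, from the formerly functional option to the
    newly functional one, or from none to the newly functional one.  A
    confound annotation (e.g. fixation on the apparatus modification itself)
    overrides the outcome.
    """
    if confound:
        return WaterFlex.CONFOUNDED
    before = CORRECT_OPTION[label3.experiment_id]   # functional in the baseline
    after = CORRECT_OPTION[label4.experiment_id]    # functional after the switch
    flexible_moves = {(before, "none"), (before, after), ("none", after)}
    if (label3.preferred, label4.preferred) in flexible_moves:
        return WaterFlex.YES
    return WaterFlex.NO


def cross_context(records: Iterable[FlexibilityRecord]) -> SpearmanResult:
    """Spearman correlation between water-tube flexibility and the color
    flexibility score.

    Birds need both measures; confounded birds are retained and coded as
    not-flexible (0), as are plain "no" birds.
    """
    usable = [
        r
        for r in records
        if r.color_flex_score is not None and r.water_flex is not WaterFlex.ABSENT
    ]
    if len(usable) < 3:
        raise InsufficientDataError(f"need >= 3 birds with both measures, got {len(usable)}")
    coded = [1.0 if r.water_flex is WaterFlex.YES else 0.0 for r in usable]
    scores = [float(r.color_flex_score) for r in usable]
    return spearman_tied(coded, scores)


def first_choice_tally(
    sessions: Iterable[WaterTubeSession],
) -> dict[Experiment, dict[str, object]]:
    """Per-experiment counts of the option chosen first in trial 1.

    Birds lacking trial-1 data are listed under ``"missing"``.
    """
    tally: dict[Experiment, dict[str, object]] = {}
    for session in sessions:
        exp = session.experiment_id
        if exp not in tally:
            entry: dict[str, object] = {opt: 0 for opt in OPTION_DOMAIN[exp]}
            entry["missing"] = []
            tally[exp] = entry
        first = session.first_choice()
        if first is None:
            tally[exp]["missing"].append(session.bird_id)  # type: ignore[union-attr]
        else:
            tally[exp][first] = tally[exp][first] + 1  # type: ignore[operator]
    return tally


def summary_means(
    summaries: Sequence[BirdSummary],
) -> tuple[Optional[float], Optional[float]]:
    """Mean trials to criterion: initial learning (all birds with a value)
    and reversal (completers only).  Full precision; round in reports."""
    if not summaries:
        raise InsufficientDataError("no summaries")
    exp1 = [s.exp1_trials for s in summaries if s.exp1_trials is not None]
    exp2 = [
        s.exp2_trials
        for s in summaries
        if s.exp2_trials is not None and not s.exp2_incomplete
    ]
    mean1 = sum(exp1) / len(exp1) if exp1 else None
    mean2 = sum(exp2) / len(exp2) if exp2 else None
    return mean1, mean2
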