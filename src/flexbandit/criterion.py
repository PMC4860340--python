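"""Sequential proficiency-criterion detection for two-choice learning data.

A bird is proficient once, at the end of a completed evaluation block, the
most recent ``window`` trials contain at least ``min_correct_window`` correct
choices and each of the two most recent blocks contains at least
``min_correct_per_block`` correct choices.  With the defaults (17 of the most
recent 20, at least 8 of each of the last two sets of 10) the window rule
alone has a two-tailed chance probability of about 0.003.

The criterion is checked only at completed block boundaries, never
mid-block: every published trials-to-proficiency count under this rule is a
multiple of the block size.  The per-block sub-criterion is read as ">= 8 in
each of the two most recent blocks", the weakest reading consistent with the
published counts (it excludes 7+10 splits that reach 17 overall).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import ConfigurationError, InsufficientDataError
from .io import TrialSequence

__all__ = [
    "CriterionSpec",
    "CriterionResult",
    "RefresherOutcome",
    "DEFAULT_SPEC",
    "evaluate_criterion",
    "refresher_outcome",
    "criterion_tail_probability",
]


@dataclass(frozen=True)
class CriterionSpec:
    """Parameters of the sequential proficiency rule.

    window:
        number of most-recent trials examined (default 20).
    min_correct_window:
        correct choices required within the window (default 17).
    block:
        evaluation granularity in trials; must divide ``window`` (default 10).
    min_correct_per_block:
        correct choices required in each of the two most recent blocks
        (default 8).
    refresher_first_block_min:
        correct choices in the first block that count as remembering a
        previously learned association (default 9, i.e. 9 or 10 of 10).
    """

    window: int = 20
    min_correct_window: int = 17
    block: int = 10
    min_correct_per_block: int = 8
    refresher_first_block_min: int = 9

    def __post_init__(self) -> None:
        if self.window < 1 or self.block < 1:
            raise ConfigurationError("window and block must be positive")
        if self.min_correct_window > self.window:
            raise ConfigurationError("min_correct_window cannot exceed window")
        if self.window % self.block != 0:
            raise ConfigurationError("block must divide window")
        if self.min_correct_per_block > self.block:
            raise ConfigurationError("min_correct_per_block cannot exceed block")
        if not (0 <= self.refresher_first_block_min <= self.block):
            raise ConfigurationError("refresher_first_block_min outside block range")


DEFAULT_SPEC = CriterionSpec()


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of the sequential rule for one trial sequence."""

    passed: bool
    trials_to_criterion: Optional[int]
    evaluated_at: tuple[int, ...] = field(default_factory=tuple)


class RefresherOutcome(str, enum.Enum):
    REMEMBERED = "remembered"
    NEEDS_REFRESHER = "needs_refresher"


def evaluate_criterion(seq: TrialSequence, spec: CriterionSpec = DEFAULT_SPEC) -> CriterionResult:
    """Return the earliest block boundary at which the proficiency rule holds.

    The rule is checked at T = window, window + block, window + 2*block, ...
    up to the last completed block.  ``trials_to_criterion`` is the smallest
    such T, or ``None`` if the rule is never satisfied.
    """
    outcomes = seq.outcomes
    n = len(outcomes)
    evaluated: list[int] = []
    for t in range(spec.window, n + 1, spec.block):
        if t % spec.block != 0:
            continue  # window not aligned to block grid; unreachable with block | window
        evaluated.append(t)
        window_correct = sum(outcomes[t - spec.window : t])
        last_block = sum(outcomes[t - spec.block : t])
        prev_block = sum(outcomes[t - 2 * spec.block : t - spec.block])
        if (
            window_correct >= spec.min_correct_window
            and last_block >= spec.min_correct_per_block
            and prev_block >= spec.min_correct_per_block
        ):
            return CriterionResult(True, t, tuple(evaluated))
    return CriterionResult(False, None, tuple(evaluated))


def refresher_outcome(seq: TrialSequence, spec: CriterionSpec = DEFAULT_SPEC) -> RefresherOutcome:
    """Decide from the first block whether a bird remembers a prior association.

    ``REMEMBERED`` iff the first ``block`` trials contain at least
    ``refresher_first_block_min`` correct choices; otherwise the bird is sent
    back to re-achieve the original criterion before the reversal.
    """
    if seq.n_trials < spec.block:
        raise InsufficientDataError(
            f"need at least {spec.block} trials, got {seq.n_trials}"
        )
    first_block_correct = sum(seq.outcomes[: spec.block])
    if first_block_correct >= spec.refresher_first_block_min:
        return RefresherOutcome.REMEMBERED
    return RefresherOutcome.NEEDS_REFRESHER


def criterion_tail_probability(spec: CriterionSpec = DEFAULT_SPEC) -> float:
    """Two-tailed exact binomial probability of the window rule at chance.

    Probability of at least ``min_correct_window`` successes in ``window``
    trials at p = 0.5, doubled.  For the default 17/20 rule this is ~0.00258.
    """
    from .stats import binom_two_tailed

    return binom_two_tailed(spec.min_correct_window, spec.window, 0.5).p_raw
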