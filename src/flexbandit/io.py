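"""Data model and CSV readers/writers for trial-by-trial choice records.

The unit record is a :class:`ChoiceEvent`: one option chosen by one bird at
one (trial, choice) position within an experiment.  Color-association
experiments allow exactly one choice per trial and collapse to a
:class:`TrialSequence` of per-trial correct/incorrect outcomes; water-tube
experiments allow several object or tube insertions per trial and are held
as a :class:`WaterTubeSession`.

CSV layout (one row per choice, header required)::

    bird_id,experiment_id,trial_index,choice_index,option,is_correct,is_accidental,trial_success

Trial and choice indices are 1-based.  Booleans are written ``true``/``false``.
Refused or aborted trials are represented by absent rows, never imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import SchemaError, StructureError, ValidationError

__all__ = [
    "Experiment",
    "OPTION_DOMAIN",
    "CORRECT_OPTION",
    "ASSOCIATION_EXPERIMENTS",
    "WATER_TUBE_EXPERIMENTS",
    "ChoiceEvent",
    "TrialSequence",
    "WaterTubeSession",
    "BirdSummary",
    "read_choices",
    "write_choices",
    "to_trial_sequence",
    "group_events",
    "read_summaries",
    "write_summaries",
]


class Experiment(str, enum.Enum):
    """The study's experiments, in protocol order."""

    EXP1_COLOR = "EXP1_COLOR"          # gold rewarded (learning speed)
    EXP1_REFRESHER = "EXP1_REFRESHER"  # gold rewarded (memory check / refresher)
    EXP2_REVERSAL = "EXP2_REVERSAL"    # silver rewarded (reversal learning)
    EXP3_HVL = "EXP3_HVL"              # heavy vs light, heavy more functional
    EXP4_MAGIC = "EXP4_MAGIC"          # heavy vs light, heavy stuck to magnet
    EXP5_NW = "EXP5_NW"                # narrow vs wide, equal water levels
    EXP6_NW_UNEQ = "EXP6_NW_UNEQ"      # narrow vs wide, unequal water levels

    def __str__(self) -> str:  # plain token in CSVs and reports
        return self.value


#: Valid option tokens per experiment.
OPTION_DOMAIN: dict[Experiment, tuple[str, str]] = {
    Experiment.EXP1_COLOR: ("gold", "silver"),
    Experiment.EXP1_REFRESHER: ("gold", "silver"),
    Experiment.EXP2_REVERSAL: ("gold", "silver"),
    Experiment.EXP3_HVL: ("heavy", "light"),
    Experiment.EXP4_MAGIC: ("heavy", "light"),
    Experiment.EXP5_NW: ("narrow", "wide"),
    Experiment.EXP6_NW_UNEQ: ("narrow", "wide"),
}

#: The rewarded / functional option per experiment.
CORRECT_OPTION: dict[Experiment, str] = {
    Experiment.EXP1_COLOR: "gold",
    Experiment.EXP1_REFRESHER: "gold",
    Experiment.EXP2_REVERSAL: "silver",
    Experiment.EXP3_HVL: "heavy",
    Experiment.EXP4_MAGIC: "light",
    Experiment.EXP5_NW: "narrow",
    Experiment.EXP6_NW_UNEQ: "wide",
}

ASSOCIATION_EXPERIMENTS = frozenset(
    {Experiment.EXP1_COLOR, Experiment.EXP1_REFRESHER, Experiment.EXP2_REVERSAL}
)
WATER_TUBE_EXPERIMENTS = frozenset(
    {Experiment.EXP3_HVL, Experiment.EXP4_MAGIC, Experiment.EXP5_NW, Experiment.EXP6_NW_UNEQ}
)

CSV_COLUMNS = (
    "bird_id",
    "experiment_id",
    "trial_index",
    "choice_index",
    "option",
    "is_correct",
    "is_accidental",
    "trial_success",
)


@dataclass(frozen=True)
class ChoiceEvent:
    """One option chosen at one (trial, choice) position.

    ``is_correct`` marks the currently rewarded/functional option,
    ``is_accidental`` marks accidental object insertions (retained in all
    downstream counts, matching the study's inclusion rule), and
    ``trial_success`` marks whether food was obtained by the end of the trial.
    """

    bird_id: str
    experiment_id: Experiment
    trial_index: int
    choice_index: int
    option: str
    is_correct: bool
    is_accidental: bool = False
    trial_success: bool = False

    def __post_init__(self) -> None:
        if self.trial_index < 1 or self.choice_index < 1:
            raise ValidationError(
                f"indices are 1-based, got trial {self.trial_index}, "
                f"choice {self.choice_index}"
            )
        domain = OPTION_DOMAIN[self.experiment_id]
        if self.option not in domain:
            raise ValidationError(
                f"option {self.option!r} not in domain {domain} "
                f"for {self.experiment_id}"
            )


@dataclass(frozen=True)
class TrialSequence:
    """Ordered per-trial outcomes for one bird in one association experiment."""

    bird_id: str
    experiment_id: Experiment
    outcomes: tuple[bool, ...]
    rewarded_option: str = ""
    side_sequence: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.outcomes) < 1:
            raise ValidationError("a trial sequence needs at least one trial")
        if self.side_sequence is not None and len(self.side_sequence) != len(self.outcomes):
            raise ValidationError("side_sequence length must equal trial count")

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)

    @property
    def n_correct(self) -> int:
        return sum(self.outcomes)


@dataclass(frozen=True)
class WaterTubeSession:
    """Ordered multi-choice-per-trial records for one bird in one water-tube experiment."""

    bird_id: str
    experiment_id: Experiment
    events: tuple[ChoiceEvent, ...]
    n_trials: int = 20

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.trial_index > self.n_trials:
                raise ValidationError(
                    f"event at trial {ev.trial_index} exceeds n_trials={self.n_trials}"
                )

    def option_counts(self, include_accidental: bool = True) -> dict[str, int]:
        counts = {opt: 0 for opt in OPTION_DOMAIN[self.experiment_id]}
        for ev in self.events:
            if include_accidental or not ev.is_accidental:
                counts[ev.option] += 1
        return counts

    def first_choice(self) -> Optional[str]:
        """Option of the first choice of trial 1, or ``None`` if absent."""
        for ev in self.events:
            if ev.trial_index == 1 and ev.choice_index == 1:
                return ev.option
        return None


@dataclass(frozen=True)
class BirdSummary:
    """Per-bird trials-to-proficiency summary for the association experiments.

    ``exp2_trials`` is ``None`` both for birds that never ran the reversal and
    for the one that stopped before criterion; ``exp2_incomplete`` separates
    the two cases.
    """

    bird_id: str
    sex: str = ""
    exp1_trials: Optional[int] = None
    refresher_trials: Optional[int] = None
    exp2_trials: Optional[int] = None
    exp2_incomplete: bool = False


def _coerce_bool(value, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in {"true", "1", "t", "yes"}:
        return True
    if token in {"false", "0", "f", "no"}:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {value!r} in column {column}")


def read_choices(path, schema: Optional[Experiment] = None) -> list[ChoiceEvent]:
    """Read and validate a choices CSV.

    Events are returned grouped and ordered by (bird, experiment, trial,
    choice); within each group the indices must already be strictly
    increasing, and violations are reported with 1-based data row numbers.
    ``schema`` restricts the file to a single experiment.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    events: list[tuple[tuple, ChoiceEvent]] = []
    last_seen: dict[tuple[str, str], tuple[int, int]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            experiment = Experiment(row.experiment_id)
        except ValueError:
            raise ValidationError(f"row {i}: unknown experiment_id {row.experiment_id!r}")
        if schema is not None and experiment is not schema:
            raise ValidationError(
                f"row {i}: experiment {experiment} does not match schema {schema}"
            )
        try:
            trial = int(row.trial_index)
            choice = int(row.choice_index)
        except ValueError:
            raise ValidationError(f"row {i}: non-integer trial/choice index")
        try:
            event = ChoiceEvent(
                bird_id=row.bird_id,
                experiment_id=experiment,
                trial_index=trial,
                choice_index=choice,
                option=row.option,
                is_correct=_coerce_bool(row.is_correct, "is_correct", i),
                is_accidental=_coerce_bool(row.is_accidental, "is_accidental", i),
                trial_success=_coerce_bool(row.trial_success, "trial_success", i),
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None

        key = (event.bird_id, event.experiment_id.value)
        if key in last_seen:
            prev_trial, prev_choice = last_seen[key]
            ordered = (trial > prev_trial) or (trial == prev_trial and choice > prev_choice)
            if not ordered:
                raise ValidationError(
                    f"row {i}: (trial {trial}, choice {choice}) does not follow "
                    f"(trial {prev_trial}, choice {prev_choice}) for bird "
                    f"{event.bird_id!r} in {event.experiment_id}"
                )
        last_seen[key] = (trial, choice)
        events.append(((event.bird_id, event.experiment_id.value, trial, choice), event))

    events.sort(key=lambda pair: pair[0])
    return [ev for _, ev in events]


def write_choices(events: Iterable[ChoiceEvent], path) -> None:
    """Write events to CSV with a stable column order.

    Repeated writes of the same input are bit-identical; an empty collection
    yields a header-only file.
    """

    def fmt(flag: bool) -> str:
        return "true" if flag else "false"

    rows = [
        {
            "bird_id": ev.bird_id,
            "experiment_id": ev.experiment_id.value,
            "trial_index": ev.trial_index,
            "choice_index": ev.choice_index,
            "option": ev.option,
            "is_correct": fmt(ev.is_correct),
            "is_accidental": fmt(ev.is_accidental),
            "trial_success": fmt(ev.trial_success),
        }
        for ev in events
    ]
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False, lineterminator="\n")


def group_events(
    events: Iterable[ChoiceEvent],
) -> dict[tuple[str, Experiment], list[ChoiceEvent]]:
    """Group validated events by (bird, experiment), preserving order."""
    groups: dict[tuple[str, Experiment], list[ChoiceEvent]] = {}
    for ev in events:
        groups.setdefault((ev.bird_id, ev.experiment_id), []).append(ev)
    return groups


def to_trial_sequence(events: Sequence[ChoiceEvent]) -> TrialSequence:
    """Collapse one bird x one association experiment to per-trial outcomes.

    Raises :class:`StructureError` if the events span several birds or
    experiments, belong to a water-tube experiment, or contain more than one
    choice in any trial.
    """
    if not events:
        raise StructureError("no events to convert")
    birds = {ev.bird_id for ev in events}
    experiments = {ev.experiment_id for ev in events}
    if len(birds) != 1 or len(experiments) != 1:
        raise StructureError(
            f"expected one bird and one experiment, got birds={sorted(birds)}, "
            f"experiments={sorted(e.value for e in experiments)}"
        )
    experiment = next(iter(experiments))
    if experiment not in ASSOCIATION_EXPERIMENTS:
        raise StructureError(
            f"{experiment} is not a one-choice-per-trial association experiment"
        )
    seen_trials: set[int] = set()
    outcomes = []
    for ev in events:
        if ev.trial_index in seen_trials or ev.choice_index != 1:
            raise StructureError(
                f"trial {ev.trial_index} of bird {ev.bird_id!r} has more than one choice"
            )
        seen_trials.add(ev.trial_index)
        outcomes.append(ev.is_correct)
    return TrialSequence(
        bird_id=next(iter(birds)),
        experiment_id=experiment,
        outcomes=tuple(outcomes),
        rewarded_option=CORRECT_OPTION[experiment],
    )


SUMMARY_COLUMNS = (
    "bird_id",
    "sex",
    "exp1_trials",
    "refresher_trials",
    "exp2_trials",
    "exp2_status",
)


def read_summaries(path) -> list[BirdSummary]:
    """Read a per-bird summary CSV (empty cell = missing; status column marks
    an attempted-but-incomplete reversal)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    def opt_int(token: str) -> Optional[int]:
        token = token.strip()
        return int(token) if token else None

    out = []
    for row in frame.itertuples(index=False):
        out.append(
            BirdSummary(
                bird_id=row.bird_id,
                sex=row.sex,
                exp1_trials=opt_int(row.exp1_trials),
                refresher_trials=opt_int(row.refresher_trials),
                exp2_trials=opt_int(row.exp2_trials),
                exp2_incomplete=row.exp2_status.strip().lower() == "incomplete",
            )
        )
    return out


def write_summaries(summaries: Iterable[BirdSummary], path) -> None:
    rows = [
        {
            "bird_id": s.bird_id,
            "sex": s.sex,
            "exp1_trials": "" if s.exp1_trials is None else s.exp1_trials,
            "refresher_trials": "" if s.refresher_trials is None else s.refresher_trials,
            "exp2_trials": "" if s.exp2_trials is None else s.exp2_trials,
            "exp2_status": "incomplete" if s.exp2_incomplete else "",
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(
        path, index=False, lineterminator="\n"
    )
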