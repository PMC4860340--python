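"""Synthetic-data generators emulating the study's structure.

Three generators cover everything the analysis consumes: epsilon-schedule
bandit agents producing one-choice-per-trial color-association sequences
(truncated at criterion passage, mirroring the study's stopping rule),
pseudorandomized rewarded-side placements (alternate for the first two
trials, then never the same side more than twice in a row), and multi-
choice-per-trial water-tube sessions with occasional accidental insertions.

The epsilon-decreasing schedule is geometric with a floor,
eps_t = max(floor, (1 - r)^(t - 1)): the exploration probability starts at
complete uncertainty (eps_1 = 1) and decays rapidly with experience, the
one-parameter family closest to the verbal description of the strategy.
Every generator consumes a single explicitly seeded stream; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criterion import DEFAULT_SPEC, CriterionSpec, evaluate_criterion
from .exceptions import ConfigurationError, FlexbanditError
from .io import CORRECT_OPTION, OPTION_DOMAIN, ChoiceEvent, Experiment, TrialSequence, WaterTubeSession
from .strategy import Strategy, classify_strategy

__all__ = [
    "AgentParams",
    "WaterTubeSimParams",
    "gen_side_sequence",
    "simulate_agent",
    "simulate_water_tube",
    "strategy_recovery",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of an epsilon-schedule bandit agent.

    strategy:
        which epsilon schedule the agent follows.
    exploration_trials:
        length m of the pure exploration prefix (epsilon-first only); the
        default of 2 is the optimal one-sample-per-option exploration.
    decay_rate:
        geometric decay rate r of the exploration probability
        (epsilon-decreasing only); eps_t = max(floor, (1 - r)^(t - 1)).
        The default of 0.03 keeps exploration spread over tens of trials,
        yielding criterion passage in 20-90 trials (the observed range)
        while leaving the generating strategy statistically identifiable:
        a much faster decay frequently produces error-free tails that are
        indistinguishable from the epsilon-first strategy.
    epsilon_floor:
        lower bound on the exploration probability, keeping a trickle of
        late exploration as real birds show.
    """

    strategy: Strategy
    exploration_trials: int = 2
    decay_rate: float = 0.03
    epsilon_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (Strategy.EPSILON_FIRST, Strategy.EPSILON_DECREASING):
            raise ConfigurationError(f"cannot simulate strategy {self.strategy}")
        if self.exploration_trials < 1:
            raise ConfigurationError("exploration_trials must be >= 1")
        if not (0.0 < self.decay_rate < 1.0):
            raise ConfigurationError("decay_rate must lie in (0, 1)")
        if not (0.0 <= self.epsilon_floor <= 1.0):
            raise ConfigurationError("epsilon_floor must lie in [0, 1]")


@dataclass(frozen=True)
class WaterTubeSimParams:
    """Parameters of a simulated water-tube session.

    pref_correct:
        per-choice probability of the functional option (deliberate choices).
    choices_min, choices_max:
        inclusive range of choices per trial (published sessions average
        roughly 1.5-3.5 choices per 20-trial experiment).
    accident_rate:
        probability a choice is an accidental insertion (option then uniform).
    success_threshold:
        functional-option insertions needed for the trial to end in food.
    """

    pref_correct: float = 0.5
    n_trials: int = 20
    choices_min: int = 1
    choices_max: int = 4
    accident_rate: float = 0.03
    success_threshold: int = 2
    seed: int = 0
    experiment: Experiment = Experiment.EXP3_HVL
    bird_id: str = "sim"

    def __post_init__(self) -> None:
        for name in ("pref_correct", "accident_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not (1 <= self.choices_min <= self.choices_max):
            raise ConfigurationError("need 1 <= choices_min <= choices_max")
        if self.success_threshold < 1:
            raise ConfigurationError("success_threshold must be >= 1")


def gen_side_sequence(n: int, seed: int) -> tuple[str, ...]:
    """Pseudorandomized L/R placements of the rewarded option.

    The first two placements alternate; thereafter the same side never
    appears three times in a row, choosing uniformly among the admissible
    continuations.
    """
    if n < 2:
        raise FlexbanditError(f"need n >= 2 placements, got {n}")
    rng = np.random.default_rng(seed)
    sides = ["L", "R"]
    first = sides[rng.integers(2)]
    seq = [first, "R" if first == "L" else "L"]
    while len(seq) < n:
        if seq[-1] == seq[-2]:  # two in a row: forced flip
            seq.append("R" if seq[-1] == "L" else "L")
        else:
            seq.append(sides[rng.integers(2)])
    return tuple(seq[:n])


def _side_extend(seq: list[str], rng: np.random.Generator) -> None:
    """Append one admissible side to a partial pseudorandomized sequence."""
    if len(seq) == 0:
        seq.append("L" if rng.integers(2) == 0 else "R")
    elif len(seq) == 1:
        seq.append("R" if seq[0] == "L" else "L")
    elif seq[-1] == seq[-2]:
        seq.append("R" if seq[-1] == "L" else "L")
    else:
        seq.append("L" if rng.integers(2) == 0 else "R")


def simulate_agent(
    params: AgentParams,
    n_max: int = 200,
    spec: CriterionSpec = DEFAULT_SPEC,
    experiment: Experiment = Experiment.EXP1_COLOR,
    bird_id: str = "agent",
) -> TrialSequence:
    """Simulate one agent on the two-option task, stopping at criterion.

    Epsilon-first: the first ``exploration_trials`` trials explore (for
    m >= 2 the first two sample each option once in random order, further
    exploration trials are uniform); every later trial exploits the rewarded
    option.  Epsilon-decreasing: at trial t the agent explores (uniform
    choice) with probability eps_t = max(floor, (1 - r)^(t - 1)), else
    exploits.  The sequence is truncated at criterion passage or ``n_max``.
    """
    if n_max < 20:
        raise ConfigurationError(f"n_max must be >= 20, got {n_max}")
    rng = np.random.default_rng(params.seed)
    outcomes: list[bool] = []
    sides: list[str] = []

    if params.strategy is Strategy.EPSILON_FIRST:
        m = params.exploration_trials
        prefix: list[bool] = []
        if m >= 2:
            pair = [True, False]
            rng.shuffle(pair)
            prefix.extend(pair)
        for _ in range(len(prefix), m):
            prefix.append(bool(rng.integers(2)))
        for t in range(1, n_max + 1):
            _side_extend(sides, rng)
            if t <= m:
                outcomes.append(prefix[t - 1])
            else:
                outcomes.append(True)
    else:
        for t in range(1, n_max + 1):
            _side_extend(sides, rng)
            eps = max(params.epsilon_floor, (1.0 - params.decay_rate) ** (t - 1))
            if rng.random() < eps:
                outcomes.append(bool(rng.integers(2)))
            else:
                outcomes.append(True)

    full = TrialSequence(
        bird_id=bird_id,
        experiment_id=experiment,
        outcomes=tuple(outcomes),
        rewarded_option=CORRECT_OPTION[experiment],
        side_sequence=tuple(sides),
    )
    result = evaluate_criterion(full, spec)
    if result.passed:
        t = result.trials_to_criterion
        return TrialSequence(
            bird_id=bird_id,
            experiment_id=experiment,
            outcomes=tuple(outcomes[:t]),
            rewarded_option=CORRECT_OPTION[experiment],
            side_sequence=tuple(sides[:t]),
        )
    return full


def simulate_water_tube(params: WaterTubeSimParams) -> WaterTubeSession:
    """Simulate one multi-choice-per-trial water-tube session.

    Each deliberate choice is the functional option with probability
    ``pref_correct``; with probability ``accident_rate`` a choice is instead
    an accidental insertion with a uniformly random option.  A trial
    succeeds once its functional-option insertions (deliberate or
    accidental) reach ``success_threshold``.
    """
    rng = np.random.default_rng(params.seed)
    functional = CORRECT_OPTION[params.experiment]
    domain = OPTION_DOMAIN[params.experiment]
    other = domain[1] if functional == domain[0] else domain[0]

    events: list[ChoiceEvent] = []
    for trial in range(1, params.n_trials + 1):
        n_choices = int(rng.integers(params.choices_min, params.choices_max + 1))
        picks: list[tuple[str, bool]] = []
        for _ in range(n_choices):
            if rng.random() < params.accident_rate:
                option = functional if rng.integers(2) == 0 else other
                picks.append((option, True))
            else:
                option = functional if rng.random() < params.pref_correct else other
                picks.append((option, False))
        success = sum(1 for opt, _ in picks if opt == functional) >= params.success_threshold
        for c, (option, accidental) in enumerate(picks, start=1):
            events.append(
                ChoiceEvent(
                    bird_id=params.bird_id,
                    experiment_id=params.experiment,
                    trial_index=trial,
                    choice_index=c,
                    option=option,
                    is_correct=option == functional,
                    is_accidental=accidental,
                    trial_success=success,
                )
            )
    return WaterTubeSession(
        bird_id=params.bird_id,
        experiment_id=params.experiment,
        events=tuple(events),
        n_trials=params.n_trials,
    )


def strategy_recovery(
    n_agents: int,
    first_params: AgentParams | None = None,
    decreasing_params: AgentParams | None = None,
    seed: int = 0,
    n_max: int = 200,
) -> pd.DataFrame:
    """Simulate agents of each strategy, classify them, and tabulate
    generated vs assigned labels (a confusion table)."""
    if n_agents < 0:
        raise ConfigurationError("n_agents must be >= 0")
    labels = [s.value for s in Strategy]
    if n_agents == 0:
        return pd.DataFrame(
            0,
            index=pd.Index([], name="generated"),
            columns=pd.Index(labels, name="assigned"),
        )
    if first_params is None:
        first_params = AgentParams(strategy=Strategy.EPSILON_FIRST)
    if decreasing_params is None:
        decreasing_params = AgentParams(strategy=Strategy.EPSILON_DECREASING)

    rng = np.random.default_rng(seed)
    generated = [Strategy.EPSILON_FIRST.value, Strategy.EPSILON_DECREASING.value]
    table = pd.DataFrame(
        0,
        index=pd.Index(generated, name="generated"),
        columns=pd.Index(labels, name="assigned"),
    )
    for base in (first_params, decreasing_params):
        for _ in range(n_agents):
            child_seed = int(rng.integers(0, 2**31 - 1))
            params = AgentParams(
                strategy=base.strategy,
                exploration_trials=base.exploration_trials,
                decay_rate=base.decay_rate,
                epsilon_floor=base.epsilon_floor,
                seed=child_seed,
            )
            seq = simulate_agent(params, n_max=n_max)
            assigned = classify_strategy(seq, allow_incomplete=True)
            table.loc[base.strategy.value, assigned.label.value] += 1
    return table
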