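"""Learning-curve construction and bandit learning-strategy classification.

A two-choice learning experiment is a contextual binary multi-armed bandit:
one choice per trial, two options, one rewarded.  Two canonical approximate
solutions are distinguished here.  Under the *epsilon-first* strategy the
agent spends an initial exploration phase (epsilon*N trials) sampling the
options and then exploits for the remaining (1-epsilon)*N trials without
further errors.  Under the *epsilon-decreasing* strategy the exploration
probability decays gradually with experience, producing a rising
proportion-correct curve.

The operational rule: a sequence is *epsilon_first* when every incorrect
trial falls within the first ``exploration_budget`` trials (default 4, two
samples per option); otherwise it is *epsilon_decreasing* when the
least-squares slope of the binned proportion-correct curve is positive; flat
or falling curves with late errors are *unclassified*.  Slope significance
is deliberately not tested — with a handful of bins the sign is the only
robust feature, and the published assignments were made by eye from exactly
these curves.

Two anomaly flags annotate, but never change, the label: ``late_dip`` (a
bin at or below chance after two consecutive bins at or above 0.75 — a
second exploration phase) and ``irregular_start`` (the early bins jump by
more than one step non-monotonically, a pattern with no clean
probability-theory reading).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, FlexbanditError, InsufficientDataError
from .io import TrialSequence

__all__ = [
    "BinSeries",
    "Strategy",
    "StrategyLabel",
    "bin_proportions",
    "ols_slope",
    "classify_strategy",
    "plot_learning_curve",
]


class Strategy(str, enum.Enum):
    EPSILON_FIRST = "epsilon_first"
    EPSILON_DECREASING = "epsilon_decreasing"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class BinSeries:
    """Proportion correct within consecutive complete non-overlapping bins."""

    bin_width: int
    proportions: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.proportions)


@dataclass(frozen=True)
class StrategyLabel:
    """Strategy assignment with its evidence.

    ``exploration_end`` is the 1-based index of the last incorrect trial
    (0 when the sequence is error-free); ``bin_slope`` is the OLS slope of
    the binned learning curve in proportion per bin.
    """

    label: Strategy
    exploration_end: int
    bin_slope: float
    anomalies: frozenset[str] = frozenset()


def bin_proportions(seq: TrialSequence, bin_width: int = 4) -> BinSeries:
    """Proportion correct per consecutive complete bin; trailing partial bin dropped."""
    if bin_width < 1:
        raise ConfigurationError(f"bin_width must be >= 1, got {bin_width}")
    if seq.n_trials < bin_width:
        raise InsufficientDataError(
            f"need at least {bin_width} trials for one bin, got {seq.n_trials}"
        )
    n_bins = seq.n_trials // bin_width
    outcomes = np.asarray(seq.outcomes[: n_bins * bin_width], dtype=float)
    props = outcomes.reshape(n_bins, bin_width).mean(axis=1)
    return BinSeries(bin_width=bin_width, proportions=tuple(float(p) for p in props))


def ols_slope(series: BinSeries) -> float:
    """Least-squares slope of bin proportion against 1-based bin index."""
    if series.n_bins < 2:
        raise InsufficientDataError("need at least 2 bins for a slope")
    x = np.arange(1, series.n_bins + 1, dtype=float)
    slope, _ = np.polyfit(x, np.asarray(series.proportions, dtype=float), 1)
    return float(slope)


def _detect_anomalies(series: BinSeries) -> frozenset[str]:
    props = series.proportions
    flags = set()
    # late_dip: a chance-level-or-worse bin after two consecutive strong bins
    for i in range(2, series.n_bins):
        if props[i] <= 0.5 and props[i - 1] >= 0.75 and props[i - 2] >= 0.75:
            flags.add("late_dip")
            break
    # irregular_start: first-half bins non-monotone by more than one step
    step = 1.0 / series.bin_width
    half = props[: max(2, series.n_bins // 2)]
    for i in range(1, len(half)):
        if half[i] < half[i - 1] - step - 1e-12:
            flags.add("irregular_start")
            break
    return frozenset(flags)


def classify_strategy(
    seq: TrialSequence,
    exploration_budget: int = 4,
    bin_width: int = 4,
    criterion_result=None,
    allow_incomplete: bool = True,
) -> StrategyLabel:
    """Assign an epsilon-first / epsilon-decreasing / unclassified label.

    Parameters
    ----------
    seq
        Per-trial outcomes for one bird in one association experiment.
    exploration_budget
        Trials allowed for the pure exploration prefix of the epsilon-first
        strategy; the default of 4 is two samples per option.
    bin_width
        Learning-curve bin width for the slope rule.
    criterion_result
        Optional :class:`~flexbandit.criterion.CriterionResult`; when given
        and not passed, ``allow_incomplete`` must be set.
    """
    if exploration_budget < 0:
        raise ConfigurationError("exploration_budget must be non-negative")
    if criterion_result is not None and not criterion_result.passed and not allow_incomplete:
        raise FlexbanditError(
            "sequence did not reach criterion; pass allow_incomplete=True to classify anyway"
        )

    incorrect_trials = [i + 1 for i, ok in enumerate(seq.outcomes) if not ok]
    exploration_end = incorrect_trials[-1] if incorrect_trials else 0

    series = bin_proportions(seq, bin_width=bin_width)
    if series.n_bins < 2:
        raise InsufficientDataError("need at least 2 bins to classify")
    slope = ols_slope(series)
    anomalies = _detect_anomalies(series)

    if exploration_end <= exploration_budget:
        label = Strategy.EPSILON_FIRST
    elif slope > 0:
        label = Strategy.EPSILON_DECREASING
    else:
        label = Strategy.UNCLASSIFIED
    return StrategyLabel(
        label=label,
        exploration_end=exploration_end,
        bin_slope=slope,
        anomalies=anomalies,
    )


def plot_learning_curve(seq: TrialSequence, bin_width: int = 4, ax=None):
    """Plot the binned learning curve (proportion correct vs bin) for one bird."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    series = bin_proportions(seq, bin_width=bin_width)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = np.arange(1, series.n_bins + 1)
    ax.plot(x, series.proportions, marker="o", color="black")
    ax.axhline(0.5, linestyle="--", color="gray", linewidth=0.8)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel(f"{bin_width}-trial bin")
    ax.set_ylabel("Proportion correct")
    ax.set_title(f"{seq.bird_id} - {seq.experiment_id}")
    return ax
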