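"""One-command regeneration of the study-summary artifacts.

``run_pipeline`` takes choice-level inputs (or, when only the published
summary tables are available, per-bird summary and split tables), runs every
analysis stage — sequential criterion detection, strategy classification,
binomial preference tests with Holm correction, flexibility scoring, and the
two Spearman correlations — and writes CSV tables, a machine-readable JSON
report, and optional learning-curve figures.  Output is deterministic given
identical inputs and seed: floats are rounded to a fixed precision and JSON
keys are sorted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import criterion as crit
from . import flexibility as flex
from . import strategy as strat
from .exceptions import (
    DegenerateInputError,
    FlexbanditError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)
from .io import (
    ASSOCIATION_EXPERIMENTS,
    WATER_TUBE_EXPERIMENTS,
    BirdSummary,
    Experiment,
    WaterTubeSession,
    group_events,
    read_choices,
    read_summaries,
    to_trial_sequence,
)

log = logging.getLogger("flexbandit")

__all__ = ["RunConfig", "run_pipeline", "format_p"]


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run.

    Either ``choices`` (trial-level association CSV) or ``summaries``
    (per-bird summary CSV) must be given for the color context; either
    ``sessions`` (choice-level water-tube CSV) or ``splits`` (per-bird
    count/total CSV) for the water-tube context.  ``confounds`` marks birds
    whose preference switch was invalidated by an apparatus confound.
    """

    choices: Optional[Path] = None
    sessions: Optional[Path] = None
    summaries: Optional[Path] = None
    splits: Optional[Path] = None
    confounds: dict[str, bool] = field(default_factory=dict)
    out_dir: Path = Path("flexbandit_report")
    spec: crit.CriterionSpec = crit.DEFAULT_SPEC
    bin_width: int = 4
    exploration_budget: int = 4
    include_accidental: bool = True
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("choices", "sessions", "summaries", "splits"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out_dir = Path(self.out_dir)


def format_p(p: float) -> str:
    """Round a p-value the way the report tables print it: two decimals from
    0.10 upward, one significant figure below."""
    if p >= 0.095:
        return f"{p:.2f}"
    if p <= 0.0:
        return "0"
    exponent = math.floor(math.log10(p))
    rounded = round(p, -exponent)
    return f"{rounded:.{max(0, -exponent)}f}"


def _round(value, digits: int = 10):
    if isinstance(value, float):
        return round(value, digits)
    return value


def _association_stage(config: RunConfig):
    """Criterion results, strategy labels, and per-bird summaries from
    trial-level data (or summaries directly)."""
    sequences = {}
    criterion_rows = []
    strategy_rows = []
    summaries: list[BirdSummary] = []

    if config.choices is not None:
        events = read_choices(config.choices)
        if not events:
            raise ValidationError(f"{config.choices}: no events")
        per_bird: dict[str, dict[Experiment, object]] = {}
        for (bird, experiment), group in group_events(events).items():
            if experiment not in ASSOCIATION_EXPERIMENTS:
                continue
            try:
                seq = to_trial_sequence(group)
            except FlexbanditError as err:
                raise type(err)(f"stage association [{bird} {experiment}]: {err}") from None
            sequences[(bird, experiment)] = seq
            result = crit.evaluate_criterion(seq, config.spec)
            criterion_rows.append(
                {
                    "bird_id": bird,
                    "experiment_id": experiment.value,
                    "n_trials": seq.n_trials,
                    "passed": result.passed,
                    "trials_to_criterion": result.trials_to_criterion,
                }
            )
            try:
                label = strat.classify_strategy(
                    seq,
                    exploration_budget=config.exploration_budget,
                    bin_width=config.bin_width,
                    criterion_result=result,
                )
                strategy_rows.append(
                    {
                        "bird_id": bird,
                        "experiment_id": experiment.value,
                        "label": label.label.value,
                        "exploration_end": label.exploration_end,
                        "bin_slope": round(label.bin_slope, 10),
                        "anomalies": ";".join(sorted(label.anomalies)),
                    }
                )
            except InsufficientDataError:
                pass
            per_bird.setdefault(bird, {})[experiment] = result
        for bird, results in sorted(per_bird.items()):
            exp1 = results.get(Experiment.EXP1_COLOR)
            exp2 = results.get(Experiment.EXP2_REVERSAL)
            refresher = results.get(Experiment.EXP1_REFRESHER)
            summaries.append(
                BirdSummary(
                    bird_id=bird,
                    exp1_trials=exp1.trials_to_criterion if exp1 else None,
                    refresher_trials=refresher.trials_to_criterion if refresher else None,
                    exp2_trials=exp2.trials_to_criterion if exp2 else None,
                    exp2_incomplete=bool(exp2 and not exp2.passed),
                )
            )
    elif config.summaries is not None:
        summaries = read_summaries(config.summaries)
    else:
        raise ValidationError("no color-context input: give choices or summaries")
    return sequences, criterion_rows, strategy_rows, summaries


def _watertube_stage(config: RunConfig):
    """Preference labels per experiment family from session data or splits."""
    labels_by_experiment: dict[Experiment, dict[str, flex.PreferenceLabel]] = {}
    sessions_by_experiment: dict[Experiment, list[WaterTubeSession]] = {}

    if config.sessions is not None:
        events = read_choices(config.sessions)
        for (bird, experiment), group in group_events(events).items():
            if experiment not in WATER_TUBE_EXPERIMENTS:
                continue
            n_trials = max(ev.trial_index for ev in group)
            session = WaterTubeSession(
                bird_id=bird,
                experiment_id=experiment,
                events=tuple(group),
                n_trials=max(20, n_trials),
            )
            sessions_by_experiment.setdefault(experiment, []).append(session)
        for experiment, family in sessions_by_experiment.items():
            labels_by_experiment[experiment] = flex.preference_labels(
                family, include_accidental=config.include_accidental
            )
    elif config.splits is not None:
        frame = pd.read_csv(config.splits, dtype=str, keep_default_na=False)
        required = ["bird_id", "experiment_id", "count", "total"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{config.splits}: missing columns {missing}")
        has_option = "count_option" in frame.columns
        per_experiment: dict[Experiment, dict[str, tuple[int, int]]] = {}
        count_options: dict[Experiment, str] = {}
        for row in frame.itertuples(index=False):
            experiment = Experiment(row.experiment_id)
            per_experiment.setdefault(experiment, {})[row.bird_id] = (
                int(row.count),
                int(row.total),
            )
            if has_option and row.count_option:
                previous = count_options.setdefault(experiment, row.count_option)
                if previous != row.count_option:
                    raise ValidationError(
                        f"{config.splits}: mixed count_option values for {experiment}"
                    )
        for experiment, counts in per_experiment.items():
            labels_by_experiment[experiment] = flex.preference_labels_from_counts(
                counts, experiment, count_option=count_options.get(experiment)
            )
    return labels_by_experiment, sessions_by_experiment


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Stage errors propagate with the stage name and the offending
    bird/experiment in the message.
    """
    log.info(
        "pipeline parameters: spec=%s bin_width=%d exploration_budget=%d "
        "include_accidental=%s seed=%d",
        config.spec, config.bin_width, config.exploration_budget,
        config.include_accidental, config.seed,
    )
    sequences, criterion_rows, strategy_rows, summaries = _association_stage(config)
    labels_by_experiment, sessions_by_experiment = _watertube_stage(config)

    # preference table (published-table-2 style statistical columns)
    preference_rows = []
    for experiment in sorted(labels_by_experiment, key=lambda e: e.value):
        for bird, label in sorted(labels_by_experiment[experiment].items()):
            preference_rows.append(
                {
                    "bird_id": bird,
                    "experiment_id": experiment.value,
                    "successes": label.binomial.successes,
                    "n_choices": label.binomial.n,
                    "p_raw": _round(label.binomial.p_raw),
                    "p_holm": _round(label.binomial.p_adjusted),
                    "p_holm_printed": format_p(label.binomial.p_adjusted),
                    "preferred": label.preferred,
                }
            )

    # water-tube flexibility determination (baseline -> switched experiment)
    water_flex: dict[str, flex.WaterFlex] = {}
    labels3 = labels_by_experiment.get(Experiment.EXP3_HVL, {})
    labels4 = labels_by_experiment.get(Experiment.EXP4_MAGIC, {})
    for bird in sorted(set(labels3) & set(labels4)):
        water_flex[bird] = flex.water_flexibility(
            labels3[bird], labels4[bird], confound=config.confounds.get(bird, False)
        )

    # flexibility records across contexts
    records = []
    for summary in summaries:
        records.append(
            flex.FlexibilityRecord(
                bird_id=summary.bird_id,
                learning_speed=summary.exp1_trials,
                color_flex_score=flex.reversal_score(summary),
                water_flex=water_flex.get(summary.bird_id, flex.WaterFlex.ABSENT),
            )
        )
    flexibility_rows = [
        {
            "bird_id": r.bird_id,
            "learning_speed": r.learning_speed,
            "color_flex_score": r.color_flex_score,
            "water_flex": r.water_flex.value,
        }
        for r in records
    ]

    # the two Spearman correlations
    def spearman_entry(x, y):
        try:
            result = flex.spearman_tied(x, y)
        except (DegenerateInputError, FlexbanditError) as err:
            return {"error": str(err)}
        return {
            "rho": _round(result.rho),
            "S": _round(result.S),
            "n": result.n,
            "p_approx": _round(result.p_approx),
        }

    speed_pairs = [
        (r.learning_speed, r.color_flex_score)
        for r in records
        if r.learning_speed is not None and r.color_flex_score is not None
    ]
    if len(speed_pairs) >= 3:
        speed_vs_flex = spearman_entry(
            [p[0] for p in speed_pairs], [p[1] for p in speed_pairs]
        )
    else:
        speed_vs_flex = {"error": "fewer than 3 birds with both measures"}
    try:
        cross = flex.cross_context(records)
        cross_entry = {
            "rho": _round(cross.rho),
            "S": _round(cross.S),
            "n": cross.n,
            "p_approx": _round(cross.p_approx),
        }
    except (DegenerateInputError, InsufficientDataError) as err:
        cross_entry = {"error": str(err)}

    # summary means and first choices
    mean1, mean2 = (None, None)
    if summaries:
        mean1, mean2 = flex.summary_means(summaries)
    first_choices = {}
    for experiment, family in sessions_by_experiment.items():
        tally = flex.first_choice_tally(family)[experiment]
        first_choices[experiment.value] = tally

    report = {
        "parameters": {
            "criterion": {
                "window": config.spec.window,
                "min_correct_window": config.spec.min_correct_window,
                "block": config.spec.block,
                "min_correct_per_block": config.spec.min_correct_per_block,
                "refresher_first_block_min": config.spec.refresher_first_block_min,
            },
            "bin_width": config.bin_width,
            "exploration_budget": config.exploration_budget,
            "include_accidental": config.include_accidental,
            "seed": config.seed,
        },
        "criterion_results": criterion_rows,
        "strategy_labels": strategy_rows,
        "preference_tests": preference_rows,
        "flexibility": flexibility_rows,
        "spearman_learning_vs_flex": speed_vs_flex,
        "spearman_cross_context": cross_entry,
        "mean_trials_exp1": _round(mean1) if mean1 is not None else None,
        "mean_trials_exp2_completers": _round(mean2) if mean2 is not None else None,
        "first_choices_trial1": first_choices,
    }

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if criterion_rows:
        pd.DataFrame(criterion_rows).to_csv(out / "criterion_table.csv", index=False)
    if strategy_rows:
        pd.DataFrame(strategy_rows).to_csv(out / "strategy_table.csv", index=False)
    if preference_rows:
        pd.DataFrame(preference_rows).to_csv(out / "preference_table.csv", index=False)
    if flexibility_rows:
        pd.DataFrame(flexibility_rows).to_csv(out / "flexibility_table.csv", index=False)

    if config.make_plots and sequences:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for (bird, experiment), seq in sorted(sequences.items()):
            if seq.n_trials < 2 * config.bin_width:
                continue
            ax = strat.plot_learning_curve(seq, bin_width=config.bin_width)
            ax.figure.tight_layout()
            ax.figure.savefig(fig_dir / f"{bird}_{experiment.value}.png", dpi=100)
            plt.close(ax.figure)

    return report
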