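import pytest

from flexbandit import datasets
from flexbandit.exceptions import DegenerateInputError, InsufficientDataError
from flexbandit.flexibility import (
    FlexibilityRecord,
    PreferenceLabel,
    WaterFlex,
    cross_context,
    first_choice_tally,
    preference_label,
    preference_labels,
    preference_labels_from_counts,
    reversal_score,
    summary_means,
    water_flexibility,
)
from flexbandit.io import BirdSummary, Experiment
from flexbandit.stats import BinomialResult
from flexbandit.synth import WaterTubeSimParams, simulate_water_tube


def label_of(preferred, experiment=Experiment.EXP3_HVL, bird="b"):
    return PreferenceLabel(
        bird_id=bird,
        experiment_id=experiment,
        preferred=preferred,
        binomial=BinomialResult(10, 20, 0.5, 1.0),
    )


class TestReversalScore:
    @pytest.mark.parametrize(
        "exp1,exp2,expected", [(30, 100, 70), (40, 70, 30), (50, 50, 0)]
    )
    def test_completed_reversals(self, exp1, exp2, expected):
        summary = BirdSummary("b", "M", exp1_trials=exp1, exp2_trials=exp2)
        assert reversal_score(summary) == expected

    def test_incomplete_reversal_is_missing(self):
        summary = BirdSummary("b", "M", exp1_trials=30, exp2_trials=None, exp2_incomplete=True)
        assert reversal_score(summary) is None


class TestPreferenceLabels:
    def test_even_split_has_no_preference(self):
        labels = preference_labels_from_counts(
            {"b1": (16, 32)}, Experiment.EXP4_MAGIC, count_option="heavy"
        )
        assert labels["b1"].preferred == "none"
        assert labels["b1"].binomial.p_raw == pytest.approx(1.0)

    def test_published_switched_experiment_family(self):
        labels = preference_labels_from_counts(
            datasets.watertube_splits(Experiment.EXP4_MAGIC),
            Experiment.EXP4_MAGIC,
            count_option="heavy",
        )
        batido = labels["Batido"]
        assert batido.preferred == "heavy"
        assert batido.binomial.p_adjusted == pytest.approx(0.0154, abs=5e-4)
        assert labels["Tequila"].preferred == "none"

    def test_degenerate_family_of_one(self):
        labels = preference_labels_from_counts(
            {"b1": (20, 20)}, Experiment.EXP3_HVL
        )
        label = labels["b1"]
        assert label.preferred == "heavy"
        assert label.binomial.p_adjusted == pytest.approx(label.binomial.p_raw)

    def test_orientation_invariance(self):
        counts = {"b1": (33, 43), "b2": (18, 32)}
        heavy_side = preference_labels_from_counts(
            counts, Experiment.EXP3_HVL, count_option="heavy"
        )
        flipped = {b: (n - k, n) for b, (k, n) in counts.items()}
        light_side = preference_labels_from_counts(
            flipped, Experiment.EXP3_HVL, count_option="light"
        )
        for bird in counts:
            assert heavy_side[bird].binomial.p_raw == pytest.approx(
                light_side[bird].binomial.p_raw, rel=1e-12
            )
            assert heavy_side[bird].preferred == light_side[bird].preferred

    def test_session_counts_include_accidentals(self):
        session = simulate_water_tube(
            WaterTubeSimParams(pref_correct=1.0, accident_rate=0.5, seed=7)
        )
        with_acc = preference_label(session, [session], include_accidental=True)
        without = preference_label(session, [session], include_accidental=False)
        assert with_acc.binomial.n >= without.binomial.n
        assert without.binomial.successes == without.binomial.n  # deliberate all-functional

    def test_zero_choice_session_rejected(self):
        with pytest.raises(InsufficientDataError):
            preference_labels_from_counts({"b1": (0, 0)}, Experiment.EXP3_HVL)


class TestWaterFlexibility:
    def test_functional_direction_moves_are_flexible(self):
        l3_heavy = label_of("heavy", Experiment.EXP3_HVL)
        l3_none = label_of("none", Experiment.EXP3_HVL)
        for l4_pref in ("none", "light"):
            assert (
                water_flexibility(l3_heavy, label_of(l4_pref, Experiment.EXP4_MAGIC))
                is WaterFlex.YES
            )
        assert (
            water_flexibility(l3_none, label_of("light", Experiment.EXP4_MAGIC))
            is WaterFlex.YES
        )

    def test_unchanged_or_backward_moves_are_not(self):
        for pref in ("heavy", "light", "none"):
            outcome = water_flexibility(
                label_of(pref, Experiment.EXP3_HVL),
                label_of(pref, Experiment.EXP4_MAGIC),
            )
            assert outcome in (WaterFlex.NO, WaterFlex.YES)
            if pref != "none":  # same-label never counts as flexible
                assert outcome is WaterFlex.NO
        assert (
            water_flexibility(
                label_of("none", Experiment.EXP3_HVL),
                label_of("heavy", Experiment.EXP4_MAGIC),
            )
            is WaterFlex.NO
        )

    def test_exhaustive_same_label_never_flexible(self):
        for pref in ("heavy", "light", "none"):
            outcome = water_flexibility(
                label_of(pref, Experiment.EXP3_HVL),
                label_of(pref, Experiment.EXP4_MAGIC),
                confound=False,
            )
            assert outcome in (WaterFlex.NO, WaterFlex.CONFOUNDED) or pref == "none"

    def test_confound_overrides(self):
        assert (
            water_flexibility(
                label_of("none", Experiment.EXP3_HVL),
                label_of("heavy", Experiment.EXP4_MAGIC),
                confound=True,
            )
            is WaterFlex.CONFOUNDED
        )


class TestCrossContext:
    def test_published_five_bird_table(self):
        records = [
            FlexibilityRecord("Tequila", 30, 70, WaterFlex.YES),
            FlexibilityRecord("Margarita", 30, 70, WaterFlex.CONFOUNDED),
            FlexibilityRecord("Cerveza", 30, 60, WaterFlex.CONFOUNDED),
            FlexibilityRecord("Horchata", 30, 100, WaterFlex.NO),
            FlexibilityRecord("Refresco", 20, 50, WaterFlex.YES),
        ]
        result = cross_context(records)
        assert result.S == pytest.approx(28.89, abs=0.005)
        assert result.rho == pytest.approx(-0.44, abs=0.005)
        assert result.n == 5

    def test_absent_and_scoreless_birds_excluded(self):
        records = [
            FlexibilityRecord("a", 30, 70, WaterFlex.YES),
            FlexibilityRecord("b", 30, 60, WaterFlex.NO),
            FlexibilityRecord("c", 30, 40, WaterFlex.NO),
            FlexibilityRecord("d", 30, None, WaterFlex.YES),
            FlexibilityRecord("e", 30, 50, WaterFlex.ABSENT),
        ]
        assert cross_context(records).n == 3

    def test_uniform_water_flex_is_degenerate(self):
        records = [
            FlexibilityRecord(str(i), 30, 40 + 10 * i, WaterFlex.NO) for i in range(4)
        ]
        with pytest.raises(DegenerateInputError):
            cross_context(records)

    def test_matches_stats_oracle_on_synthetic_table(self, rng):
        from flexbandit.stats import spearman_tied

        flex = [WaterFlex.YES if b else WaterFlex.NO for b in rng.integers(0, 2, 12)]
        if len(set(flex)) < 2:
            flex[0] = WaterFlex.YES if flex[1] is WaterFlex.NO else WaterFlex.NO
        scores = [int(s) for s in rng.integers(20, 120, 12)]
        records = [
            FlexibilityRecord(str(i), 30, s, f) for i, (s, f) in enumerate(zip(scores, flex))
        ]
        expected = spearman_tied(
            [1.0 if f is WaterFlex.YES else 0.0 for f in flex], [float(s) for s in scores]
        )
        result = cross_context(records)
        assert result.rho == pytest.approx(expected.rho, abs=1e-12)
        assert result.S == pytest.approx(expected.S, abs=1e-9)


class TestTalliesAndMeans:
    def test_first_choice_unanimous(self):
        sessions = [
            simulate_water_tube(WaterTubeSimParams(pref_correct=1.0, accident_rate=0.0, seed=i, bird_id=f"b{i}"))
            for i in range(6)
        ]
        tally = first_choice_tally(sessions)[Experiment.EXP3_HVL]
        assert tally["heavy"] == 6 and tally["light"] == 0 and tally["missing"] == []

    def test_empty_collection(self):
        assert first_choice_tally([]) == {}

    def test_mixed_sessions_match_recount(self, rng):
        sessions = [
            simulate_water_tube(
                WaterTubeSimParams(pref_correct=0.5, seed=int(s), bird_id=f"b{i}")
            )
            for i, s in enumerate(rng.integers(0, 10_000, 8))
        ]
        tally = first_choice_tally(sessions)[Experiment.EXP3_HVL]
        manual = {"heavy": 0, "light": 0}
        for session in sessions:
            first = [e for e in session.events if e.trial_index == 1 and e.choice_index == 1]
            manual[first[0].option] += 1
        assert tally["heavy"] == manual["heavy"] and tally["light"] == manual["light"]

    def test_study_summary_means(self):
        mean1, mean2 = summary_means(datasets.association_summaries())
        assert round(mean1) == 31
        assert round(mean2) == 91

    def test_single_bird(self):
        mean1, mean2 = summary_means([BirdSummary("b", "F", 30, 10, 90)])
        assert mean1 == 30 and mean2 == 90
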