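import numpy as np
import pytest

from flexbandit import datasets
from flexbandit.io import Experiment, TrialSequence


@pytest.fixture
def refresco_seq() -> TrialSequence:
    """Error on trial 1, correct ever after: the canonical epsilon-first pattern."""
    return datasets.refresco_exp1_sequence()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160503)


def make_sequence(outcomes, experiment=Experiment.EXP1_COLOR, bird="b1") -> TrialSequence:
    return TrialSequence(
        bird_id=bird,
        experiment_id=experiment,
        outcomes=tuple(bool(o) for o in outcomes),
        rewarded_option="gold",
    )
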