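import numpy as np
import pytest

from gazecourse.design import build_item_set, latin_square_lists
from gazecourse.fixio import bin_experiment
from gazecourse.simulate import GeneratorParams, simulate_experiment
from gazecourse.timecourse import add_log_ratio


@pytest.fixture(scope="session")
def study_design():
    """The study's item set (14 occupations x 3 displays, 28 fillers) and
    its six Latin-square lists."""
    item_set = build_item_set(14, 3, 28)
    return item_set, latin_square_lists(item_set)


@pytest.fixture(scope="session")
def small_experiment(study_design):
    """A small simulated experiment (6 participants, one per list)."""
    item_set, lists = study_design
    params = GeneratorParams(n_participants=6)
    return simulate_experiment(item_set, lists, params, seed=42)


@pytest.fixture(scope="session")
def small_logratio(small_experiment):
    bins = bin_experiment(small_experiment["fixations"], small_experiment["meta"])
    return add_log_ratio(bins)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
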