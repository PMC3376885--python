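import numpy as np
import pytest

import wagertrack as wt


@pytest.fixture(scope="session")
def stimulus_table():
    return wt.load_stimulus_table()


@pytest.fixture(scope="session")
def sequences(stimulus_table):
    return wt.stimulus_sequences()


@pytest.fixture(scope="session")
def small_cohort(sequences, stimulus_table):
    """3 agents per sequence (33 participants), default parameters, seed 0."""
    return wt.simulate_cohort(
        sequences, n_per_sequence=3, seed=0, sequence_ids=list(stimulus_table["id"])
    )


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    feats = wt.features_table(small_cohort)
    blocks = wt.blocks_table(small_cohort)
    scores = wt.score_cohort(small_cohort, blocks)
    return feats, blocks, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
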