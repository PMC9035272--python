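import numpy as np
import pytest

from twostay import CohortSpec, LearnerSpec, generate_cohort

# small-but-real learner settings shared across the suite: a single
# hyperparameter candidate skips the grid search, modest forests keep fits fast
FAST_RF = dict(hyperparameters={"n_estimators": 60}, grid={})
FAST_LINEAR = dict(hyperparameters={}, grid={})


def fast_rf_spec(task="regression", seed=0):
    return LearnerSpec("tree_ensemble", task, seed=seed, **FAST_RF)


def fast_linear_spec(task="regression", seed=0):
    return LearnerSpec("penalized_linear", task, seed=seed, **FAST_LINEAR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort from the default generator, shared read-only."""
    return generate_cohort(CohortSpec(n=4000, seed=101))


@pytest.fixture(scope="session")
def separable_cohort():
    """Prolonged status is a deterministic function of the smoking feature."""
    return generate_cohort(CohortSpec(n=2000, seed=7, separable_mode=True))


@pytest.fixture()
def xy(default_cohort):
    table = default_cohort.to_frame()
    return table.drop(columns=["los_days"]), table["los_days"].to_numpy()
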