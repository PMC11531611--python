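import numpy as np
import pandas as pd
import pytest

from msnpred import msn, synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort with no planted effects, shared across tests."""
    spec = syn.SyntheticCohortSpec(n_patients=25, n_controls=15, seed=11)
    features = syn.generate_features(spec)
    cohort = syn.generate_demographics(spec)
    return spec, features, cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """n=59 patient cohort with the canonical planted degree -> outcome
    signal at population R^2 0.5."""
    spec = syn.SyntheticCohortSpec(
        n_patients=59, n_controls=10, seed=5,
        outcome_weights=syn.example_outcome_weights(),
    )
    features, cohort, metrics = syn.simulate_cohort(spec, target_r2=0.5)
    return spec, features, cohort, metrics


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_network(rng, n=10, density=None, subject="s1"):
    """A valid random MSNetwork on n generic regions."""
    z = rng.standard_normal((n, 7))
    net = msn.build_msn(z, subject_id=subject)
    if density is not None:
        net = msn.threshold_by_density(net, density)
    return net
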