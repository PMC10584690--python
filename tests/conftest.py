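import numpy as np
import pytest

from chromfiber import accesshmm, synthdata


@pytest.fixture(scope="session")
def rate_map():
    """A moderate-size rate map shared by decoding tests."""
    return synthdata.make_rate_map(2712, adenine_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def control_hmm(rate_map):
    """Chain HMM calibrated from simulated positive/negative controls."""
    pos = synthdata.simulate_controls(rate_map, 200, "positive", seed=12)
    neg = synthdata.simulate_controls(rate_map, 200, "negative", seed=13)
    p_acc = accesshmm.emissions_from_controls(*synthdata.control_counts(pos))
    p_inacc = accesshmm.emissions_from_controls(*synthdata.control_counts(neg))
    p_inacc = np.minimum(p_inacc, p_acc)
    return accesshmm.build_hmm(rate_map.adenine_positions, p_acc, p_inacc, 1000.0)


def random_hmm_instance(rng, n_adenines):
    """A random small HMM plus observations, for oracle-equivalence tests."""
    positions = np.sort(rng.choice(np.arange(1, 400), size=n_adenines, replace=False))
    p_acc = rng.uniform(0.2, 1.0, size=n_adenines)
    p_inacc = p_acc * rng.uniform(0.01, 0.9, size=n_adenines)
    hmm = accesshmm.AccessibilityHMM(
        adenine_positions=positions,
        p_meth_acc=p_acc,
        p_meth_inacc=np.clip(p_inacc, 1e-6, None),
        expected_run_length=rng.uniform(2.0, 2000.0),
        initial_accessible=0.5,
    )
    calls = rng.integers(0, 2, size=n_adenines)
    return hmm, calls
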