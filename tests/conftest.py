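import numpy as np
import pytest

from cjshet.scenarios import CaptureHistoryMatrix, ScenarioSpec, default_scenarios, simulate_dataset


@pytest.fixture(scope="session")
def scenarios():
    """The four generating regimes at the study's production dimensions."""
    return default_scenarios()


@pytest.fixture(scope="session")
def null_spec():
    """Homogeneous-detection generator used for null-distribution checks."""
    return ScenarioSpec("constant", p_mean=0.4, p_sd=0.0)


@pytest.fixture(scope="session")
def symmetric_dataset(scenarios):
    """One production-scale dataset from the symmetric-beta regime."""
    return simulate_dataset(scenarios["symmetric"], rng_seed=20_240_101)


def make_history_matrix(histories):
    """Build a CaptureHistoryMatrix from a list of 0/1 tuples."""
    det = np.asarray(histories, dtype=np.int8)
    first = det.argmax(axis=1)
    return CaptureHistoryMatrix(detections=det, first_capture=first)


@pytest.fixture
def hand_histories():
    """The three-history fixture used for hand-counted m-array checks."""
    return make_history_matrix([(1, 0, 1), (1, 1, 0), (1, 1, 1)])


def enumerate_history_loglik(history, first, phi, p):
    """Independent oracle: probability of a capture history by exhaustive
    enumeration of the latent death time (alive through occasion a, then
    dead), with constant phi and p."""
    y = list(history)
    K = len(y)
    prob = 0.0
    for a in range(first, K):  # a = last occasion alive
        term = phi ** (a - first)
        if a < K - 1:
            term *= 1.0 - phi
        ok = True
        for t in range(first + 1, K):
            if t <= a:
                term *= p if y[t] else 1.0 - p
            elif y[t]:
                ok = False
                break
        if ok:
            prob += term
    return np.log(prob) if prob > 0 else -np.inf
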