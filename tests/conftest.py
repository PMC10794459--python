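import numpy as np
import pandas as pd
import pytest

import tiltlab as tl

OBLIQUE_OFFSETS = np.array([3.57, 7.14, 10.70, 14.29, 17.80, 21.42, 25.00])
CARDINAL_OFFSETS = np.array([0.71, 1.43, 2.14, 2.86, 3.57, 4.29, 5.00])


@pytest.fixture(scope="session")
def design():
    return tl.DesignConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_psychometric_data(offsets, n_trials, n_correct, orientation=45.0):
    key = tl.ConditionKey("p0", "web", "temporal", orientation)
    return tl.PsychometricData(key, np.asarray(offsets), np.asarray(n_trials), np.asarray(n_correct))


def logistic_counts(offsets, a, beta, n_per_level, rng=None):
    """Binomial counts from the increasing 2AFC logistic (exact when rng=None)."""
    p = 0.5 + 0.5 / (1 + np.exp(-(np.asarray(offsets) - a) / beta))
    if rng is None:
        return np.round(p * n_per_level).astype(int)
    return rng.binomial(n_per_level, p)


def make_threshold_table(Y_by_session, session_orders=None):
    """Build a long threshold table from {session: (n, 2, 4) arrays}."""
    tasks = ["temporal", "spatial"]
    orients = [0.0, 90.0, -45.0, 45.0]
    rows = []
    for session, Y in Y_by_session.items():
        n = Y.shape[0]
        for i in range(n):
            order = 1 if session_orders is None else session_orders[session][i]
            for a, task in enumerate(tasks):
                for b, orient in enumerate(orients):
                    rows.append(
                        {
                            "participant_id": f"p{i:03d}",
                            "session": session,
                            "session_order": order,
                            "task": task,
                            "orientation": orient,
                            "threshold": Y[i, a, b],
                            "se_threshold": 0.1,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    """One small but complete simulated web+lab study shared across tests."""
    pop = tl.ObserverPopulationConfig(n_participants=6, seed=42)
    trials, observers = tl.simulate_study(pop, sessions=("web", "lab"), seed=42)
    return trials, observers
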