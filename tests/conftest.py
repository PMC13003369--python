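import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phptfrac import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort_50k():
    """One 50 000-patient cohort at generator defaults, shared across tests."""
    cfg = SimulationConfig(n=50_000, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2 000-patient default cohort for cheap structural checks."""
    cfg = SimulationConfig(n=2_000, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_followups():
    """Six subjects with a hand-computable Aalen-Johansen estimate."""
    return pd.DataFrame(
        {
            "patient_id": [f"S{i}" for i in range(6)],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 2, 0, 1, 2, 0],
            "fracture_site": ["hip", "none", "none", "spine", "none", "none"],
        }
    )


def make_uncensored_followups(rng, n, t_scale=4.0, p_event_site=None):
    """Fully observed fracture data (no censoring, no deaths) for oracles."""
    sites = p_event_site or {"hip": 0.3, "spine": 0.3, "forearm": 0.2, "humerus": 0.2}
    names = list(sites)
    probs = np.array([sites[s] for s in names])
    return pd.DataFrame(
        {
            "patient_id": [f"U{i}" for i in range(n)],
            "time": rng.exponential(t_scale, n) + 1e-6,
            "event": np.ones(n, dtype=int),
            "fracture_site": rng.choice(names, size=n, p=probs / probs.sum()),
        }
    )
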