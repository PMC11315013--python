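import numpy as np
import pandas as pd
import pytest

from bedtherm.simulate import (ArtifactSpec, PhysioParams, simulate_study,
                               simulate_subject_night)
from bedtherm.evaluate import preprocess_study


@pytest.fixture(scope="session")
def physio():
    return PhysioParams()


@pytest.fixture(scope="session")
def clean_session(physio):
    """One clean (artifact-free) 120-minute home session."""
    return simulate_subject_night(physio, "home", 120, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A small noisy study: 6 home subjects x 2 nights + 4 lab subjects x 1
    night, 90-minute sessions, default artifact rates."""
    return simulate_study(6, 2, 4, 1, PhysioParams(), ArtifactSpec(),
                          seed=7, duration=90)


@pytest.fixture(scope="session")
def small_features(small_study):
    return preprocess_study(small_study)


def make_identity_tables(n_sessions=6, n_minutes=120, seed=0, noise=0.0):
    """Feature tables where S is exactly V1: the pipeline should recover the
    identity map on V1.  V-triples are descending by construction."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_sessions):
        base = 30.0 + rng.uniform(-0.5, 0.5)
        walk = np.cumsum(rng.normal(0, 0.03, size=n_minutes))
        walk -= np.linspace(0, walk[-1], n_minutes)  # bridge: stays near base
        # slow sweep so every session covers the shared V1 range densely
        t = np.arange(n_minutes)
        sweep = rng.uniform(0.8, 1.2) * np.sin(
            2 * np.pi * t / rng.uniform(80, 140) + rng.uniform(0, 2 * np.pi))
        v1 = base + sweep + walk
        v2 = v1 - rng.uniform(0.0, 0.5, size=n_minutes)
        v3 = v2 - rng.uniform(0.0, 0.5, size=n_minutes)
        s = v1 + (rng.normal(0, noise, size=n_minutes) if noise else 0.0)
        tables.append(pd.DataFrame({
            "n": np.arange(1, n_minutes + 1), "V1": v1, "V2": v2, "V3": v3,
            "S": s, "valid": True}))
    return tables
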