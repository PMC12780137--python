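import dataclasses

import numpy as np
import pandas as pd
import pytest

import msmfrailty as mf


@pytest.fixture(scope="session")
def default_config() -> mf.SimConfig:
    return mf.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated illness-death dataset at default parameters, n=200."""
    cfg = dataclasses.replace(mf.DEFAULT_CONFIG, n=200, seed=42)
    dataset, truth = mf.simulate_dataset(cfg)
    return dataset, truth


@pytest.fixture()
def tiny_dataset() -> mf.MultistateDataset:
    """Three hand-built subjects: one full illness-death path, one direct
    death, one censored in the healthy state."""
    rows = [
        # subject 0: ill at t=2, dies at t=7
        dict(id=0, from_state=1, to_state=2, tstart=0.0, tstop=2.0, status=1, x=0.5),
        dict(id=0, from_state=1, to_state=3, tstart=0.0, tstop=2.0, status=0, x=0.5),
        dict(id=0, from_state=2, to_state=3, tstart=2.0, tstop=7.0, status=1, x=0.5),
        # subject 1: dies directly at t=3
        dict(id=1, from_state=1, to_state=2, tstart=0.0, tstop=3.0, status=0, x=-1.0),
        dict(id=1, from_state=1, to_state=3, tstart=0.0, tstop=3.0, status=1, x=-1.0),
        # subject 2: censored healthy at t=4
        dict(id=2, from_state=1, to_state=2, tstart=0.0, tstop=4.0, status=0, x=0.0),
        dict(id=2, from_state=1, to_state=3, tstart=0.0, tstop=4.0, status=0, x=0.0),
    ]
    return mf.MultistateDataset(data=pd.DataFrame(rows), covariates=("x",))


@pytest.fixture(scope="session")
def single_transition_view():
    """A 30-row single-transition survival table with two covariates."""
    rng = np.random.default_rng(5)
    n = 30
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.5, size=n).astype(float)
    t = rng.exponential(1.0, size=n) * np.exp(-(0.5 * x1 - 0.3 * x2))
    c = rng.exponential(2.0, size=n)
    return pd.DataFrame({
        "id": np.arange(n),
        "entry": 0.0,
        "duration": np.minimum(t, c),
        "status": (t <= c).astype(int),
        "cluster": np.arange(n) % 6,
        "x1": x1,
        "x2": x2,
    })
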