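"""Shared fixtures: small synthetic libraries, toy GP states, fingerprints."""

from __future__ import annotations

import numpy as np
import pytest

from mfbo.assaysim import NoiseConfig, make_oracle
from mfbo.benchdata import generate_synthetic_library
from mfbo.surrogate import FidelitySchedule, Observation, SurrogateState


def random_fps(n: int, n_bits: int = 64, density: float = 0.2, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return (rng.random((n, n_bits)) < density).astype(np.uint8)


def make_state(
    X: np.ndarray,
    f: np.ndarray,
    y: np.ndarray,
    amplitude: float = 1.0,
    B: np.ndarray | None = None,
    noises: np.ndarray | None = None,
    n_levels: int = 3,
    standardize: bool = False,
) -> SurrogateState:
    """Build a SurrogateState with hand-chosen hyperparameters (no fitting).

    With ``standardize=False`` the state uses identity scaling so posterior
    algebra can be checked against textbook formulas directly.
    """
    f = np.asarray(f, dtype=int)
    y = np.asarray(y, dtype=float)
    if B is None:
        B = np.eye(n_levels)
    if noises is None:
        noises = np.full(n_levels, 1e-6)
    y_mean = np.zeros(n_levels)
    y_sd = np.ones(n_levels)
    if standardize:
        for lv in range(n_levels):
            sel = f == lv
            if sel.sum() >= 2:
                y_mean[lv] = y[sel].mean()
                sd = y[sel].std(ddof=1)
                y_sd[lv] = sd if sd > 1e-12 else 1.0
    obs = [Observation(f"m{i}", int(f[i]), float(y[i])) for i in range(len(y))]
    state = SurrogateState(
        observations=obs,
        ids=[o.molecule_id for o in obs],
        X=np.asarray(X),
        f=f,
        amplitude=amplitude,
        B=np.asarray(B, dtype=float),
        noises=np.asarray(noises, dtype=float),
        y_mean=y_mean,
        y_sd=y_sd,
        n_levels=n_levels,
    )
    state._factorize()
    return state


@pytest.fixture(scope="session")
def tiny_library():
    """A deterministic 60-molecule synthetic library."""
    return generate_synthetic_library(60, 0.85, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_library():
    """A deterministic 200-molecule synthetic library for campaign tests."""
    return generate_synthetic_library(200, 0.85, 0.5, seed=7)


@pytest.fixture()
def tiny_oracle(tiny_library):
    return make_oracle(tiny_library, seed=5)


@pytest.fixture()
def noiseless_oracle(tiny_library):
    return make_oracle(
        tiny_library,
        noise=NoiseConfig(low_fraction_of_range=0.0, medium_sd=0.0, high_sd=0.0),
        seed=5,
    )


@pytest.fixture()
def default_schedule():
    return FidelitySchedule.default(budget=10.0)
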