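"""Shared fixtures: a fast default configuration and the steady two-crypt
reference state (computed once per session, reused by regeneration and
observable tests)."""

from __future__ import annotations

import numpy as np
import pytest

from cryptmorph import Config, CryptSimulator, make_initial_state
from cryptmorph.model_state import apply_overrides


@pytest.fixture()
def fast_config() -> Config:
    """Default parameters at the working resolution used throughout the tests."""
    return apply_overrides(Config(), ["numerics.n_points=128", "numerics.dt=0.002"])


@pytest.fixture(scope="session")
def steady_two_crypt():
    """Steady two-crypt state from de-novo formation on the fixed domain.

    Session-scoped: formation costs ~30 s and several tests start from it.
    Returns (config, RunResult).
    """
    cfg = apply_overrides(Config(), ["numerics.n_points=128", "numerics.dt=0.002"])
    grid = cfg.grid()
    cells, morph = make_initial_state("uniform_noisy_wnt", grid, {"c0": 0.1}, seed=1)
    sim = CryptSimulator(cfg, cells, morph, grid=grid, freeze_length=True)
    result = sim.run(t_end=100.0, stop_at_steady=True)
    assert result.timeseries["crypt_count"].iloc[-1] == 2
    return cfg, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
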