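"""Shared fixtures: model defaults and cached simulation runs.

The expensive population runs are session-scoped so that unit,
property and acceptance-style checks can share them instead of
re-simulating.
"""

from __future__ import annotations

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import allelopop as ap
from allelopop.config import default_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec() -> ap.TransitionSpec:
    return ap.TransitionSpec()


@pytest.fixture(scope="session")
def rates(spec) -> ap.RateMatrices:
    return ap.build_rate_matrices(spec)


@pytest.fixture(scope="session")
def expr() -> ap.ExpressionParams:
    return ap.ExpressionParams()


@pytest.fixture(scope="session")
def div() -> ap.DivisionParams:
    return ap.DivisionParams()


@pytest.fixture(scope="session")
def base_config():
    return default_config()


def sized_config(config, n_cells: int, t_end: float, seed: int, **sim_kwargs):
    """Config with a fixed-size population (constant-number from the start)."""
    return config.with_(
        sim=replace(
            config.sim, n_initial=n_cells, n_cap=n_cells, t_end=t_end, seed=seed, **sim_kwargs
        )
    )


@pytest.fixture(scope="session")
def equilibrium_run(base_config):
    """Wild-type equilibrium, 2500 cells, 150 h, deterministic protein dynamics."""
    cfg = sized_config(base_config, 2500, 150.0, seed=101)
    return ap.run_equilibrium(cfg, seed=101)


@pytest.fixture(scope="session")
def noisy_equilibrium_run(base_config):
    """Equilibrium with 20% transcriptional noise (Euler-Maruyama dynamics)."""
    cfg = sized_config(base_config, 2000, 120.0, seed=103)
    cfg = cfg.with_(expr=replace(cfg.expr, eta=0.2))
    return ap.run_equilibrium(cfg, seed=103)


@pytest.fixture(scope="session")
def knockout_study(base_config):
    cfg = sized_config(base_config, 3000, 120.0, seed=105)
    return ap.run_knockout_study(cfg, seed=105)


@pytest.fixture(scope="session")
def shutoff_study(base_config):
    cfg = sized_config(base_config, 2500, 120.0, seed=107)
    return ap.run_shutoff_study(cfg, seed=107)
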