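"""Shared fixtures: small populations, recordings and sweep products.

Expensive artifacts are session-scoped so the suite simulates each one once.
Hypothesis runs derandomized (fixed seed) for reproducible CI behavior.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popfail.glm import GLMFitConfig, simulate_spikes
from popfail.stimuli import generate_white_noise, white_noise_patch_statistics
from popfail.synthetic_data import (
    SCOTOPIC_LIKE,
    Regime,
    StudyConfig,
    make_population,
    make_recording,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wn_stats5():
    return white_noise_patch_statistics(5)


@pytest.fixture(scope="session")
def small_population():
    """5-cell scotopic-like ground-truth population (cheap, reused widely)."""
    cfg = StudyConfig(n_cells=5)
    return make_population(SCOTOPIC_LIKE, n_cells=5, geometry_seed=11, config=cfg)


@pytest.fixture(scope="session")
def small_recording(small_population):
    """Short synthetic session from the 5-cell population."""
    return make_recording(
        small_population,
        fit_minutes=1.0,
        n_repeats=40,
        repeat_seconds=4.0,
        decode_minutes=0.75,
        seed=11,
        regime=SCOTOPIC_LIKE,
        config=StudyConfig(n_cells=5),
    )


@pytest.fixture(scope="session")
def uncoupled_recording():
    """Conditionally independent population (zero coupling), repeated raster."""
    cfg = StudyConfig(n_cells=5)
    regime = Regime("uncoupled", coupling_gain=0.0, coupling_extent=1)
    pop = make_population(regime, n_cells=5, geometry_seed=21, config=cfg)
    stim = generate_white_noise(
        int(4.0 * cfg.refresh), cfg.grid, seed=np.random.default_rng(22),
        pixel_size=cfg.pixel_size, refresh=cfg.refresh,
    )
    raster = simulate_spikes(pop, stim, 40, np.random.default_rng(23))
    return pop, stim, raster


@pytest.fixture(scope="session")
def fast_fit_config():
    return GLMFitConfig(max_alternations=3, inner_maxiter=60)
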