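import numpy as np
import pytest
from scipy import stats

from melscreen.screen import NullDensity


@pytest.fixture(scope="session")
def normal_null() -> NullDensity:
    """Analytic standard-normal null on a dense grid (no KDE noise)."""
    grid = np.linspace(-8.0, 8.0, 2001)
    dens = stats.norm.pdf(grid)
    dens = dens / np.trapezoid(dens, grid)
    cdf = np.concatenate(
        [[0.0], np.cumsum(np.diff(grid) * (dens[1:] + dens[:-1]) / 2.0)])
    return NullDensity(grid, np.maximum(dens, 1e-10), cdf, bandwidth=0.1)


@pytest.fixture(scope="session")
def planted_screen():
    """Small two-replicate screen with 20 planted genes at theta = 2."""
    from melscreen.synth import ScreenSimConfig, simulate_screen

    effects = {f"gene{j:05d}": 2.0 for j in range(20)}
    cfg = ScreenSimConfig(n_genes=120, n_safe_controls=1000,
                          effect_dist=effects, seed=11, n_replicates=2)
    return simulate_screen(cfg), effects
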