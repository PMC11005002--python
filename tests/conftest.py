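"""Shared fixtures: miniature grids, geometries, and smooth random states."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from melon4d import (FieldState, ModelParameters, NucleusGeometry,
                     SimulationGrid)


@pytest.fixture(autouse=True)
def _silence_seed_warnings():
    """Seed-overlap warnings are expected with the reference layout."""
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*seed.*")
        yield


@pytest.fixture
def small_grid() -> SimulationGrid:
    """8³ box of 2 μm side — the derivative-oracle playground."""
    return SimulationGrid((8, 8, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def mini_grid() -> SimulationGrid:
    """Miniature version of the reference domain (24×36×12, h = 0.25 μm)."""
    return SimulationGrid((24, 36, 12), (6.0, 9.0, 3.0))


@pytest.fixture
def mini_geometry() -> NucleusGeometry:
    return NucleusGeometry()


def smooth_random_state(grid: SimulationGrid, n_chromosomes: int = 2,
                        seed: int = 0, sigma: float = 1.0) -> FieldState:
    """Random fields in (0, 1), mildly smoothed so gradients are sane."""
    rng = np.random.default_rng(seed)

    def make() -> np.ndarray:
        return gaussian_filter(rng.random(grid.shape), sigma)

    phi = np.stack([make() for _ in range(n_chromosomes)])
    return FieldState(phi=phi, psi1=make(), psi2=make(), eta=make())


@pytest.fixture
def random_state(small_grid) -> FieldState:
    return smooth_random_state(small_grid, n_chromosomes=2, seed=42)


def uniform_state(grid: SimulationGrid, n_chromosomes: int,
                  phi_val: float = 0.0, psi1_val: float = 0.0,
                  psi2_val: float = 0.0, eta_val: float = 0.0) -> FieldState:
    shape = grid.shape
    return FieldState(
        phi=np.full((n_chromosomes,) + shape, float(phi_val)),
        psi1=np.full(shape, float(psi1_val)),
        psi2=np.full(shape, float(psi2_val)),
        eta=np.full(shape, float(eta_val)))


def free_params(n: int = 2, **overrides) -> ModelParameters:
    """Parameters with every coupling and constraint switched off."""
    base = dict(n_chromosomes=n, a1=0.0, a2=0.0, a3=0.0, a4=0.0,
                beta0=0.0, beta_phi=0.0, beta_psi1=0.0, beta_psi2=0.0,
                beta_psi1psi2=0.0, gamma1=0.0, gamma2=0.0,
                eps_phi=0.0, eps_psi1=0.0, eps_psi2=0.0,
                target_V=[0.0] * n, target_v=[0.0] * n, target_w=[0.0] * n)
    base.update(overrides)
    return ModelParameters(**base)
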