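"""Shared fixtures: analytic reference profiles and reusable pools."""

from __future__ import annotations

import numpy as np
import pytest

from saxsemble import (SaxsProfile, default_pool_spec, sample_linker_pool)

Q_MIN, Q_MAX = 0.00621, 0.333


@pytest.fixture(scope="session")
def qgrid() -> np.ndarray:
    return np.linspace(Q_MIN, Q_MAX, 220)


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Uniform-ball form factor intensity: I = i0 * [3 j1(qR)/(qR)]^2."""
    x = q * radius
    return i0 * (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


def gaussian_intensity(q: np.ndarray, rg: float, i0: float = 1.0) -> np.ndarray:
    """Exact Guinier-law profile I = i0 * exp(-(q rg)^2 / 3)."""
    return i0 * np.exp(-((q * rg) ** 2) / 3.0)


@pytest.fixture(scope="session")
def sphere_profile(qgrid) -> SaxsProfile:
    I = sphere_intensity(qgrid, 30.0, i0=7.0)
    return SaxsProfile(qgrid, I, sigma=np.full_like(I, 1e-4 * I[0]))


@pytest.fixture(scope="session")
def small_pool():
    """15 conformers with cached profiles on a 150-point grid."""
    pool = sample_linker_pool(default_pool_spec(), 15, seed=9)
    pool.compute_profiles(np.linspace(Q_MIN, Q_MAX, 150))
    return pool


@pytest.fixture(scope="session")
def medium_pool():
    """60 conformers with cached profiles (for recovery tests)."""
    pool = sample_linker_pool(default_pool_spec(), 60, seed=29)
    pool.compute_profiles(np.linspace(Q_MIN, Q_MAX, 150))
    return pool
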