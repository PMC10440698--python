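"""Shared fixtures and instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from echelonsnn import (SNNLayerModel, SpikeTrain, generate_poisson_spikes,
                        generate_random_layer)

GRID_DENSITIES = (0.02, 0.1, 0.5, 1.0)


def random_instance(seed: int, T: int = 108,
                    max_pre: int = 256, max_post: int = 64,
                    max_delay: int = 8) -> tuple[SNNLayerModel, SpikeTrain]:
    """One randomized (layer, spike train) pair from the verification grid:
    d in [1, 8], density in {0.02, 0.1, 0.5, 1}, n_pre <= 256, n_post <= 64."""
    rng = np.random.default_rng(seed)
    n_pre = int(rng.integers(4, max_pre + 1))
    n_post = int(rng.integers(2, max_post + 1))
    d = int(rng.integers(1, max_delay + 1))
    density = float(rng.choice(GRID_DENSITIES))
    model = generate_random_layer(n_pre, n_post, d, density,
                                  seed=int(rng.integers(2 ** 31)))
    spikes = generate_poisson_spikes(0.2, T, n_pre,
                                     seed=int(rng.integers(2 ** 31)))
    return model, spikes


def tiny_model(weights: np.ndarray, delays: np.ndarray,
               delay_range: int) -> SNNLayerModel:
    """Hand-built layer from explicit (n_post, n_pre) weight/delay arrays."""
    weights = np.asarray(weights)
    connected = weights != 0
    return SNNLayerModel(
        n_pre=weights.shape[1], n_post=weights.shape[0],
        delay_range=delay_range, weights=weights,
        delays=np.where(connected, np.asarray(delays), 0),
        connected=connected, density=float(connected.mean()))


def random_echelon(rng: np.random.Generator, max_rows: int = 64,
                   max_cols: int = 64):
    """A random matrix pushed through echelon_reorder, for splitting tests."""
    from echelonsnn import echelon_reorder
    rows = int(rng.integers(1, max_rows + 1))
    cols = int(rng.integers(1, max_cols + 1))
    density = float(rng.uniform(0.02, 0.6))
    mat = (rng.random((rows, cols)) < density) * rng.integers(
        -9, 10, size=(rows, cols))
    return echelon_reorder(np.asarray(mat, dtype=np.int64))


def brute_force_min_area(e) -> int:
    """Independent tiling oracle: per 4-row band, try every 16-gridline start
    and keep the smallest right-anchored rectangle covering the band's
    nonzeros; bands without data need no rectangle."""
    from echelonsnn import align
    cols16 = align(e.n_cols, 16)
    values = e.values
    total = 0
    for top in range(0, values.shape[0], 4):
        band = values[top:top + 4]
        if not band.any():
            continue
        best = None
        for start in range(0, cols16, 16):
            if not band[:, :min(start, band.shape[1])].any():
                area = 4 * (cols16 - start)
                best = area if best is None else min(best, area)
        total += best
    return total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
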