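"""Shared fixtures.

The phantom-based pipeline fixtures are session-scoped because level-set
segmentation of magnified slices is the expensive step; several tests
inspect different properties of the same seeded runs.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lvfractal import (
    LvPhantomSpec,
    SegmentationParams,
    analyze_stack,
    magnify,
    make_lv_stack,
    segment_blood_pool,
    slice_fd,
)
from lvfractal.phantom import make_lv_slice

COMPLEXITY_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
NOISE_GRID = (0.0, 5.0, 10.0)
DICE_COMPLEXITIES = (0.0, 0.25, 0.5, 0.75, 1.0)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


@pytest.fixture(scope="session")
def complexity_grid_global_fds() -> dict[float, float]:
    """Global FD of one phantom stack per complexity level, fixed seed."""
    out = {}
    for c in COMPLEXITY_GRID:
        stack, _ = make_lv_stack(LvPhantomSpec(complexity=c, seed=7))
        out[c] = analyze_stack(stack).global_fd
    return out


@pytest.fixture(scope="session")
def default_stack_result():
    """Analysis of the default phantom stack (complexity 0.5, seed 0)."""
    stack, truths = make_lv_stack(LvPhantomSpec(seed=0))
    return analyze_stack(stack), truths


@pytest.fixture(scope="session")
def smooth_stack_result():
    """Noise-free zero-complexity stack: smooth circular pools."""
    stack, _ = make_lv_stack(LvPhantomSpec(complexity=0.0, noise_sd=0.0, seed=2))
    return analyze_stack(stack)


@pytest.fixture(scope="session")
def dice_grid() -> dict[tuple[float, float], float]:
    """Dice vs ground truth across complexity x noise, mid-ventricular slice."""
    out = {}
    for c in DICE_COMPLEXITIES:
        for sigma in NOISE_GRID:
            spec = LvPhantomSpec(complexity=c, noise_sd=sigma, seed=3)
            sl, truth = make_lv_slice(spec, 0.4, c, np.random.default_rng(3))
            pool = segment_blood_pool(magnify(sl, 4))
            truth_mag = ndimage.zoom(
                truth["pool"].astype(np.uint8), 4, order=0
            ).astype(bool)
            out[(c, sigma)] = dice_coefficient(pool.mask, truth_mag)
    return out


@pytest.fixture(scope="session")
def param_grid_slice_fds() -> list[float]:
    """Per-slice FDs over a seeded phantom parameter grid (>= 50 cases)."""
    fds = []
    for i, c in enumerate(COMPLEXITY_GRID):
        for j, sigma in enumerate(NOISE_GRID):
            for k, frac in enumerate((0.1, 0.35, 0.6, 0.85)):
                spec = LvPhantomSpec(complexity=c, noise_sd=sigma,
                                     seed=100 + 17 * i + 5 * j + k)
                rng = np.random.default_rng(spec.seed)
                sl, _ = make_lv_slice(spec, frac, c * (0.5 + 0.5 * frac), rng)
                fds.append(slice_fd(sl).fd)
    return fds
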