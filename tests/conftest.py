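"""Shared fixtures and independent brute-force oracles.

Oracle implementations here deliberately use naive loops and stay independent
of the vectorised library code paths they validate.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from dosiomics.core import DoseGrid, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def uniform_grid():
    """8x8x8 uniform 10 Gy dose with a full mask."""
    dose = DoseGrid(np.full((8, 8, 8), 10.0))
    mask = RoiMask(np.ones((8, 8, 8), dtype=bool))
    return dose, mask


@pytest.fixture
def random_grid(rng):
    dose = DoseGrid(rng.uniform(0.0, 60.0, size=(6, 7, 5)))
    mask_values = rng.uniform(size=(6, 7, 5)) < 0.8
    mask_values[0, 0, 0] = True  # never empty
    return dose, RoiMask(mask_values)


# ------------------------------------------------------------------ oracles

def glcm_bruteforce(levels: np.ndarray, ng: int, direction, distance: int = 1,
                    symmetric: bool = True) -> np.ndarray:
    """Exhaustive pair enumeration; levels 0 = outside mask."""
    counts = np.zeros((ng, ng))
    offset = tuple(c * distance for c in direction)
    shape = levels.shape
    for v in itertools.product(*(range(s) for s in shape)):
        w = tuple(v[k] + offset[k] for k in range(3))
        if any(not 0 <= w[k] < shape[k] for k in range(3)):
            continue
        a, b = levels[v], levels[w]
        if a > 0 and b > 0:
            counts[a - 1, b - 1] += 1
            if symmetric:
                counts[b - 1, a - 1] += 1
    return counts


def glrlm_bruteforce(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Scan-line run enumeration: walk forward from every run start."""
    shape = levels.shape
    runs: list[tuple[int, int]] = []
    for v in itertools.product(*(range(s) for s in shape)):
        if levels[v] == 0:
            continue
        prev = tuple(v[k] - direction[k] for k in range(3))
        if all(0 <= prev[k] < shape[k] for k in range(3)) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        nxt = tuple(v[k] + direction[k] for k in range(3))
        while all(0 <= nxt[k] < shape[k] for k in range(3)) and levels[nxt] == levels[v]:
            length += 1
            nxt = tuple(nxt[k] + direction[k] for k in range(3))
        runs.append((int(levels[v]), length))
    rmax = max((ln for _, ln in runs), default=1)
    counts = np.zeros((ng, rmax))
    for lvl, ln in runs:
        counts[lvl - 1, ln - 1] += 1
    return counts


def auc_bruteforce(scores, y) -> float:
    """O(n^2) Mann-Whitney with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for s1 in pos:
        for s0 in neg:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_quantized(rng, shape, ng, hole_fraction=0.25) -> np.ndarray:
    """Random gray-level grid with masked-out holes (level 0)."""
    levels = rng.integers(1, ng + 1, size=shape)
    holes = rng.uniform(size=shape) < hole_fraction
    levels[holes] = 0
    if (levels > 0).sum() == 0:
        levels.flat[0] = 1
    return levels.astype(np.int32)
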