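"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's KD-tree code path: all
pair and neighborhood counting here is a plain O(n²) distance scan in
numpy, so tests comparing the two are a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
import pytest

from trackdamage import EventSet


def brute_force_pairs(coords: np.ndarray, r: float) -> set[tuple[int, int]]:
    """All unordered index pairs with Euclidean separation <= r (O(n²))."""
    n = len(coords)
    pairs = set()
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off in np.nonzero(d <= r)[0]:
            pairs.add((i, i + 1 + int(off)))
    return pairs


def brute_force_ncl(coords: np.ndarray, center: np.ndarray, r: float) -> int:
    """Events within r of a center, closed boundary (O(n))."""
    return int(np.count_nonzero(np.linalg.norm(coords - center, axis=1) <= r))


def make_eventset(coords, edep=30.0, kind="ION") -> EventSet:
    """EventSet from an explicit coordinate array with uniform edep/kind."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    edep = np.full(n, edep) if np.isscalar(edep) else np.asarray(edep, float)
    kinds = np.full(n, kind) if isinstance(kind, str) else np.asarray(kind)
    return EventSet(np.zeros(n, dtype=int), coords, kinds, edep)


@pytest.fixture
def random_eventset():
    """Factory for reproducible random event sets of a given size/extent."""

    def _make(n: int, seed: int, extent_nm: float = 20.0) -> EventSet:
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-extent_nm, extent_nm, size=(n, 3))
        edep = rng.uniform(1.0, 60.0, size=n)
        kind = np.where(rng.random(n) < 0.5, "ION", "EXC")
        return EventSet(np.zeros(n, dtype=int), coords, kind, edep)

    return _make
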