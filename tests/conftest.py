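"""Shared fixtures and the brute-force boolean-array oracle.

The oracle represents an interval set as a plain boolean occupancy array over
cells and implements union / set-minus with numpy logical ops -- a path fully
independent of the package's interval arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest

from placecode.algebra import Interval, IntervalSet, TonotopicAxis


def to_mask(s, n_cells: int) -> np.ndarray:
    """Boolean occupancy of an IntervalSet (or list of Interval)."""
    mask = np.zeros(n_cells, dtype=bool)
    parts = s.parts if isinstance(s, IntervalSet) else s
    for p in parts:
        mask[p.start:p.stop] = True
    return mask


def mask_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a | b

def mask_setminus(exc: np.ndarray, inh: np.ndarray) -> np.ndarray:
    return exc & ~inh


def mask_to_parts(mask: np.ndarray) -> list[tuple[int, int]]:
    """Canonical (start, length) runs of a boolean array."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def assert_matches_oracle(result: IntervalSet, mask: np.ndarray) -> None:
    """Result must cover exactly the oracle cells *and* be canonical."""
    assert [(p.start, p.length) for p in result.parts] == mask_to_parts(mask)


def random_interval_set(rng: np.random.Generator, axis: TonotopicAxis,
                        max_parts: int = 3) -> IntervalSet:
    parts = []
    for _ in range(rng.integers(0, max_parts + 1)):
        start = int(rng.integers(0, axis.n_cells))
        length = int(rng.integers(1, axis.n_cells - start + 1))
        parts.append(Interval(start, length))
    return IntervalSet(axis, parts)


@pytest.fixture
def axis64() -> TonotopicAxis:
    return TonotopicAxis(n_cells=64, max_len=16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
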