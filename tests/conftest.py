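"""Shared fixtures: analytic bin generators and random parameter draws."""

from __future__ import annotations

import numpy as np
import pytest

from rifseg import models as m
from rifseg.preprocess import BinSeries

PAPER_TIME_GRID = np.array([0, 1, 2, 3, 4, 5, 6, 8, 10, 15], dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def time_grid():
    return PAPER_TIME_GRID.copy()


def random_params(rng, **overrides) -> m.ModelParams:
    """A random valid parameter set in laboratory-plausible ranges."""
    kw = dict(
        alpha=float(rng.uniform(5, 80)),          # molecules/min
        lam=float(rng.uniform(0.05, 2.0)),        # 1/min
        v=float(rng.uniform(600, 3600)),          # nt/min (10-60 nt/s)
        n=float(rng.uniform(0, 5000)),
    )
    kw.update(overrides)
    return m.ModelParams(**kw)


def analytic_bin(position: float, curve: np.ndarray, times: np.ndarray,
                 replicates: int = 1, noise_rng=None, strand: str = "+",
                 scale: float = 1.0) -> BinSeries:
    """Wrap a model curve into a BinSeries, optionally Poisson-noised."""
    if noise_rng is None:
        ab = np.tile(curve, (replicates, 1)).astype(float)
    else:
        ab = noise_rng.poisson(np.maximum(curve, 0.0) * scale,
                               size=(replicates, curve.size)) / scale
    return BinSeries(position=int(position), strand=strand, abundance=ab,
                     times=times)


def brute_force_segment(n: int, score, penalty: float, min_len: int,
                        maximize: bool = False) -> float:
    """Exhaustive optimum over all segmentations of n elements.

    ``score(i, j)`` scores the half-open fragment [i, j); returns the
    optimal total (sum of fragment scores plus penalty per split).
    """
    import itertools

    table = {(i, j): score(i, j)
             for i in range(n) for j in range(i + min_len, n + 1)}
    best = None
    for k in range(1, n + 1):
        for cuts in itertools.combinations(range(1, n), k - 1):
            bounds = [0, *cuts, n]
            if any(b - a < min_len for a, b in zip(bounds, bounds[1:])):
                continue
            total = sum(table[(a, b)] for a, b in zip(bounds, bounds[1:]))
            total += penalty * (k - 1)
            if best is None or (total > best if maximize else total < best):
                best = total
    return best
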