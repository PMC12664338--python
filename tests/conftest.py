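"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use different mechanics from the implementation
(full window enumeration instead of sliding windows, explicit rank
computation instead of library calls) so agreement is informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import actdsem as ad


# ---------------------------------------------------------------------------
# oracles


def nonwear_oracle(
    counts: np.ndarray,
    min_window_min: int = 60,
    allowance_min: int = 2,
    low_count_max: int = 100,
) -> np.ndarray:
    """Brute-force non-wear scanner enumerating every window.

    A minute is non-wear iff some window [a, b] of length >= min_window_min
    contains it, with all counts <= low_count_max and at most allowance_min
    minutes in (0, low_count_max]. Enumerates all O(n^2) windows through
    cumulative counts on a broadcast grid.

    Returns the wear mask (True = wear).
    """
    counts = np.asarray(counts)
    n = counts.size
    if n == 0:
        return np.ones(0, dtype=bool)
    low = counts <= low_count_max
    nonzero_low = low & (counts > 0)
    high_cum = np.concatenate([[0], np.cumsum(~low)])
    nz_cum = np.concatenate([[0], np.cumsum(nonzero_low)])
    idx = np.arange(n)
    a, b = np.meshgrid(idx, idx, indexing="ij")
    valid = (
        (a <= b)
        & (b - a + 1 >= min_window_min)
        & (high_cum[b + 1] - high_cum[a] == 0)
        & (nz_cum[b + 1] - nz_cum[a] <= allowance_min)
    )
    b_max = np.where(valid.any(axis=1), (valid * (b + 1)).max(axis=1) - 1, -1)
    covered = np.maximum.accumulate(b_max) >= idx
    return ~covered


def _average_ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r via explicit average ranks plus Pearson on ranks,
    with the two-sided t-approximation p-value."""
    rx = _average_ranks(np.asarray(x, float))
    ry = _average_ranks(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    n = len(rx)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def random_count_stream(rng: np.random.Generator, n: int) -> np.ndarray:
    """Minute counts with long zero runs, low-count noise and active bouts,
    structured to exercise the non-wear rule's edge cases."""
    counts = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        kind = rng.choice(["zero", "low", "active"], p=[0.5, 0.25, 0.25])
        length = int(rng.integers(1, 120))
        j = min(i + length, n)
        if kind == "low":
            counts[i:j] = rng.integers(1, 101, size=j - i)
        elif kind == "active":
            counts[i:j] = rng.integers(101, 2000, size=j - i)
        i = j
    return counts


def minute_series(counts, person_id="p1", start="2022-03-07") -> ad.EpochSeries:
    return ad.EpochSeries(
        person_id=person_id,
        epoch_length_s=60,
        start_time=pd.Timestamp(start),
        counts=np.asarray(counts, dtype=int),
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_panel():
    """8 persons x 7 days with a little missingness, fixed seed."""
    panel, effects = ad.simulate_panel(
        ad.PanelSimSpec(n_persons=8, t_days=7, seed=42, missing_day_prob=0.1)
    )
    return panel, effects


@pytest.fixture(scope="session")
def small_draws(small_panel):
    """A short but real posterior sample on the small panel."""
    panel, _ = small_panel
    config = ad.FitConfig(iterations=600, thin=3, n_chains=2, seed=7)
    return ad.fit(panel, config), panel
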