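"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute every connectivity measure by explicit
element-by-element summation loops over time, staying independent of the
vectorized implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hoconn import RegionTimeSeries, standardize
from hoconn import generative as g


# ---------------------------------------------------------------- oracles


def oracle_moment(rows: dict[str, np.ndarray], indices) -> float:
    """(1/T) sum_t prod_j X_j(t) by explicit loop."""
    T = len(next(iter(rows.values())))
    total = 0.0
    for t in range(T):
        prod = 1.0
        for lab in indices:
            prod *= rows[lab][t]
        total += prod
    return total / T


def oracle_cokurtosis(rows, i, j, k, l) -> float:
    m = lambda *idx: oracle_moment(rows, idx)  # noqa: E731
    return m(i, j, k, l) - m(i, j) * m(k, l) - m(i, k) * m(j, l) - m(i, l) * m(j, k)


def oracle_edge_raw(rows, e1, e2) -> float:
    """Normalized product sum of the two edge time series (no centering)."""
    (i, j), (k, l) = e1, e2
    T = len(rows[i])
    num = den1 = den2 = 0.0
    for t in range(T):
        a = rows[i][t] * rows[j][t]
        b = rows[k][t] * rows[l][t]
        num += a * b
        den1 += a * a
        den2 += b * b
    return num / math.sqrt(den1 * den2)


def oracle_edge_redundant(rows, e1, e2) -> float:
    (i, j), (k, l) = e1, e2
    m = lambda *idx: oracle_moment(rows, idx)  # noqa: E731
    num = m(i, j) * m(k, l) + m(i, k) * m(j, l) + m(i, l) * m(j, k)
    d1 = 2.0 * m(i, j) ** 2 + m(i, i) * m(j, j)
    d2 = 2.0 * m(k, l) ** 2 + m(k, k) * m(l, l)
    return num / math.sqrt(d1 * d2)


def rows_of(ts: RegionTimeSeries) -> dict[str, np.ndarray]:
    return {lab: ts.data[r] for r, lab in enumerate(ts.region_ids)}


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ts(rng) -> RegionTimeSeries:
    """Standardized 4x20 matrix for exact oracle comparisons."""
    data = rng.standard_normal((4, 20))
    return standardize(RegionTimeSeries(data, ["A", "B", "C", "D"]))


@pytest.fixture(scope="session")
def null_series():
    """Gaussian (psi=0) autocorrelated series at the reference conditions."""
    p = g.ARParams(n=3, psi=0.0, innovation=g.SkewNormalSpec(3.0), tau=2.0, r=0.4)
    return g.simulate(p, 1200, seed=101)


@pytest.fixture(scope="session")
def skewed_series():
    """Strong third-order connectivity (psi=1, alpha=3) series."""
    p = g.ARParams(n=3, psi=1.0, innovation=g.SkewNormalSpec(3.0), tau=2.0, r=0.4)
    return g.simulate(p, 1200, seed=102)


def chunked_recovery(params, measure_fn, truth, n_chunks=20, chunk_T=100_000, seed=0):
    """Mean of independent long-run estimates vs closed form, in MC SEs.

    Returns the z-score (mean - truth) / (SD / sqrt(n_chunks)).
    """
    rng = np.random.default_rng(seed)
    vals = np.array(
        [measure_fn(g.simulate(params, chunk_T, seed=rng)) for _ in range(n_chunks)]
    )
    se = vals.std(ddof=1) / math.sqrt(n_chunks)
    return (vals.mean() - truth) / se
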