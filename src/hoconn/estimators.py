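"""Plug-in estimators of multivariate moments and cumulant-based connectivity.

Measures
--------
correlation2
    Pearson correlation of two regions (second-order non-redundant
    correlation).
coskewness
    Normalized third-order cumulant of three distinct regions.  For
    z-scored signals the third cumulant equals the third moment, so the
    estimator is the temporal mean of the triple product.
cokurtosis
    Normalized fourth-order cumulant of four distinct regions:
    m_ijkl - m_ij m_kl - m_ik m_jl - m_il m_jk.  Zero for jointly Gaussian
    signals; the multivariate analogue of excess kurtosis.
edge_connectivity_raw / _redundant / _corrected
    The edge connectivity is the normalized fourth moment
    m_ijkl / sqrt(m_iijj m_kkll) — the cosine similarity of the two edge
    product time series X_i X_j and X_k X_l.  Its redundant (Gaussian)
    part replaces all fourth moments by their Wick pairings of second
    moments; the corrected measure is raw minus redundant and vanishes for
    Gaussian data.

All estimators use 1/T temporal averaging on z-scored signals.  Because
the z-score uses the 1/(T-1) variance, the second self-moment of a
standardized row is (T-1)/T; this small finite-T offset is a documented
consequence of the conventions, not corrected for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .timeseries import RegionTimeSeries, standardize

__all__ = [
    "CumulantEstimate",
    "DegenerateEdgeError",
    "sample_moment",
    "correlation2",
    "coskewness",
    "cokurtosis",
    "edge_connectivity_raw",
    "edge_connectivity_redundant",
    "edge_connectivity_corrected",
    "measure_statistic",
    "MEASURES",
]

logger = logging.getLogger(__name__)


class DegenerateEdgeError(ValueError):
    """An edge product signal has zero norm; edge connectivity undefined."""


@dataclass
class CumulantEstimate:
    """One connectivity estimate with its index tuple and provenance.

    ``indices`` has length equal to ``order``; for the edge measures the
    four indices are the two edges (i, j) and (k, l) in order.  ``se``,
    ``ci`` and ``p_value`` are filled in by the inference layer.
    """

    order: int
    indices: tuple
    measure: str
    value: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.indices = tuple(str(i) for i in self.indices)
        if self.order not in (2, 3, 4):
            raise ValueError("order must be 2, 3 or 4")
        if len(self.indices) != self.order:
            raise ValueError("indices length must match order")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be nonnegative")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _standardized(x: RegionTimeSeries) -> RegionTimeSeries:
    if not x.standardized:
        logger.debug("input not flagged standardized; z-scoring automatically")
        return standardize(x)
    return x


def _check_distinct(indices: Sequence[str]) -> None:
    if len(set(map(str, indices))) != len(indices):
        raise ValueError(
            f"connectivity measures are defined for distinct regions; got {tuple(indices)}"
        )


def sample_moment(x: RegionTimeSeries, indices: Sequence[str]) -> float:
    """1/T-average of the product of the indexed signals.

    Repeated labels are allowed (internal moments such as m_iijj are
    needed by the edge measures); 2 to 4 indices are supported.
    Permutation-invariant by construction.
    """
    if not 2 <= len(indices) <= 4:
        raise ValueError("sample_moment takes 2 to 4 indices")
    x = _standardized(x)
    return float(np.prod(x.rows(indices), axis=0).mean())


def correlation2(x: RegionTimeSeries, i: str, j: str) -> CumulantEstimate:
    """Pearson correlation (up to the (T-1)/T convention offset)."""
    if str(i) == str(j):
        warnings.warn(
            f"self-pair correlation of region {i!r} is (T-1)/T by convention, not 1",
            stacklevel=2,
        )
    x = _standardized(x)
    return CumulantEstimate(2, (i, j), "correlation", sample_moment(x, (i, j)))


def coskewness(x: RegionTimeSeries, i: str, j: str, k: str) -> CumulantEstimate:
    """Normalized third-order cumulant of three distinct regions."""
    _check_distinct((i, j, k))
    x = _standardized(x)
    return CumulantEstimate(3, (i, j, k), "coskewness", sample_moment(x, (i, j, k)))


def _cokurtosis_value(x: RegionTimeSeries, i, j, k, l) -> float:
    m4 = sample_moment(x, (i, j, k, l))
    return (
        m4
        - sample_moment(x, (i, j)) * sample_moment(x, (k, l))
        - sample_moment(x, (i, k)) * sample_moment(x, (j, l))
        - sample_moment(x, (i, l)) * sample_moment(x, (j, k))
    )


def cokurtosis(x: RegionTimeSeries, i: str, j: str, k: str, l: str) -> CumulantEstimate:
    """Normalized fourth-order cumulant of four distinct regions."""
    _check_distinct((i, j, k, l))
    x = _standardized(x)
    return CumulantEstimate(4, (i, j, k, l), "cokurtosis", _cokurtosis_value(x, i, j, k, l))


def _edge_indices(edge1, edge2) -> tuple:
    (i, j), (k, l) = edge1, edge2
    if str(i) == str(j) or str(k) == str(l):
        raise ValueError("an edge must join two distinct regions")
    return str(i), str(j), str(k), str(l)


def edge_connectivity_raw(x: RegionTimeSeries, edge1, edge2) -> CumulantEstimate:
    """Normalized fourth moment of the two edge product signals; in [-1, 1]."""
    i, j, k, l = _edge_indices(edge1, edge2)
    x = _standardized(x)
    denom = sample_moment(x, (i, i, j, j)) * sample_moment(x, (k, k, l, l))
    if denom <= 0.0:
        raise DegenerateEdgeError(f"edge product signal has zero norm for {edge1}/{edge2}")
    value = sample_moment(x, (i, j, k, l)) / np.sqrt(denom)
    return CumulantEstimate(4, (i, j, k, l), "edge_raw", float(value))


def edge_connectivity_redundant(x: RegionTimeSeries, edge1, edge2) -> CumulantEstimate:
    """Gaussian (Wick) part of the edge connectivity, from second moments only."""
    i, j, k, l = _edge_indices(edge1, edge2)
    x = _standardized(x)
    m = lambda *idx: sample_moment(x, idx)  # noqa: E731
    num = m(i, j) * m(k, l) + m(i, k) * m(j, l) + m(i, l) * m(j, k)
    d1 = 2 * m(i, j) ** 2 + m(i, i) * m(j, j)
    d2 = 2 * m(k, l) ** 2 + m(k, k) * m(l, l)
    if d1 <= 0.0 or d2 <= 0.0:
        raise DegenerateEdgeError(f"degenerate edge for {edge1}/{edge2}")
    return CumulantEstimate(4, (i, j, k, l), "edge_redundant", float(num / np.sqrt(d1 * d2)))


def edge_connectivity_corrected(x: RegionTimeSeries, edge1, edge2) -> CumulantEstimate:
    """Non-redundant edge connectivity: raw minus redundant part."""
    i, j, k, l = _edge_indices(edge1, edge2)
    x = _standardized(x)
    raw = edge_connectivity_raw(x, edge1, edge2).value
    red = edge_connectivity_redundant(x, edge1, edge2).value
    return CumulantEstimate(4, (i, j, k, l), "edge_corrected", raw - red)


#: measure name -> (order, estimator taking (x, *indices))
MEASURES: dict[str, tuple[int, Callable]] = {
    "correlation": (2, correlation2),
    "coskewness": (3, coskewness),
    "cokurtosis": (4, cokurtosis),
    "edge_raw": (4, lambda x, i, j, k, l: edge_connectivity_raw(x, (i, j), (k, l))),
    "edge_redundant": (4, lambda x, i, j, k, l: edge_connectivity_redundant(x, (i, j), (k, l))),
    "edge_corrected": (4, lambda x, i, j, k, l: edge_connectivity_corrected(x, (i, j), (k, l))),
}


def estimate(x: RegionTimeSeries, measure: str, indices: Sequence[str]) -> CumulantEstimate:
    """Dispatch by measure name (the CLI entry point into the estimators)."""
    try:
        order, fn = MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}") from None
    if len(indices) != order:
        raise ValueError(f"measure {measure!r} needs {order} region labels")
    return fn(x, *indices)


def measure_statistic(measure: str, indices: Sequence[str]) -> Callable[[RegionTimeSeries], float]:
    """A scalar statistic ts -> value, suitable for bootstrap/surrogate tests.

    The statistic is the full plug-in pipeline: each (re)sampled series is
    z-scored before the moment averages are taken.
    """
    order, fn = MEASURES[measure]
    if len(indices) != order:
        raise ValueError(f"measure {measure!r} needs {order} region labels")
    idx = tuple(indices)

    def stat(ts: RegionTimeSeries) -> float:
        return fn(ts, *idx).value

    return stat
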