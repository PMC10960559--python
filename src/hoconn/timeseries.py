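"""Region-by-time signal container and z-scoring.

All connectivity measures in this package operate on a matrix of regional
signals, one row per region and one column per time point.  Estimators
assume z-scored rows: sample mean zero (1/T convention) and sample variance
one (1/(T-1) convention).  The two conventions are deliberate — they match
the standard z-score — and imply that the 1/T second sample moment of a
standardized row is (T-1)/T, not 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "DegenerateSignalError",
    "standardize",
]

#: absolute tolerance used when checking the standardization invariants
STANDARD_TOL = 1e-10


class DegenerateSignalError(ValueError):
    """A regional signal has zero sample variance and cannot be z-scored."""


@dataclass
class RegionTimeSeries:
    """A multivariate time series of regional signals.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_timepoints)
        Signal values; arbitrary units unless ``standardized``.
    region_ids : sequence of str
        Ordered region labels, one per row.
    standardized : bool
        True if every row has sample mean 0 (1/T) and sample variance 1
        (1/(T-1)).  Set by :func:`standardize`; trusted but re-checkable
        via :meth:`check_standardized`.
    meta : dict
        Free-form provenance (e.g. simulation parameters and seed).
    """

    data: np.ndarray
    region_ids: Sequence[str]
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_regions x n_timepoints) array")
        self.region_ids = [str(r) for r in self.region_ids]
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region labels for {self.data.shape[0]} rows"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region labels must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal values must be finite")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.region_ids.index(str(label))
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None

    def rows(self, labels: Sequence[str]) -> np.ndarray:
        """Rows for the given labels, in the given order (repeats allowed)."""
        return self.data[[self.index_of(lab) for lab in labels]]

    def check_standardized(self, tol: float = STANDARD_TOL) -> bool:
        T = self.n_timepoints
        mean_ok = np.all(np.abs(self.data.mean(axis=1)) <= tol)
        var = (self.data**2).sum(axis=1) / (T - 1) - self.data.mean(axis=1) ** 2 * T / (T - 1)
        return bool(mean_ok and np.all(np.abs(var - 1.0) <= tol))

    def standardize(self) -> "RegionTimeSeries":
        return standardize(self)

    def with_data(self, data: np.ndarray, standardized: bool | None = None) -> "RegionTimeSeries":
        """Copy with new data and the same labels."""
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            standardized=self.standardized if standardized is None else standardized,
            meta=dict(self.meta),
        )


def standardize(x: RegionTimeSeries) -> RegionTimeSeries:
    """Z-score every row: mean 0 (1/T) and variance 1 (1/(T-1)).

    Idempotent: already-standardized input is returned unchanged (same
    object).  A constant row raises :class:`DegenerateSignalError` naming
    the offending region.
    """
    if x.standardized:
        return x
    centered = x.data - x.data.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    bad = np.flatnonzero(ss == 0.0)
    if bad.size:
        raise DegenerateSignalError(
            f"region {x.region_ids[bad[0]]!r} has zero sample variance"
        )
    sd = np.sqrt(ss / (x.n_timepoints - 1))
    return x.with_data(centered / sd[:, None], standardized=True)
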