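"""Seed-based higher-order connectivity maps over multi-subject ensembles.

A correlation map fixes one seed pair (left/right homologues) and shows
the average correlation of each target region with the two seeds.  A
coskewness map instead fixes *two* seed regions and varies one target: it
shows which third regions engage in genuine three-way interactions with
the seed pair.  Fourth-order maps fix the same two seeds and let a
*target pair* (typically a homologous left/right pair) vary, using either
the cokurtosis or the corrected edge connectivity, the two edges being
(seed1, seed2) and (target1, target2).

Group inference bootstraps subjects (independent resampling) to obtain
the sampling distribution of the group mean per target, derives a
two-sided normal-approximation p-value from the bootstrap SE, and applies
Bonferroni correction over the number of targets in the map.

Every map value is produced by the per-tuple estimators in
:mod:`hoconn.estimators` — there is no separate vectorized math path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators
from .timeseries import RegionTimeSeries

__all__ = [
    "SubjectEnsemble",
    "ConnectivityMap",
    "coskewness_map",
    "fourth_order_map",
    "correlation_map",
    "group_threshold",
    "random_ktuple_distribution",
    "interpret_sign",
    "map_to_frame",
]


@dataclass
class SubjectEnsemble:
    """Per-subject region-by-time series sharing one region set.

    homologous_pairs, when given, are disjoint (label, label) pairs used
    as joint targets for fourth-order maps.
    """

    subjects: list[RegionTimeSeries]
    homologous_pairs: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("ensemble needs at least one subject")
        ids = self.subjects[0].region_ids
        for s, ts in enumerate(self.subjects):
            if ts.region_ids != ids:
                raise ValueError(f"subject {s} has a different region ordering")
        if self.homologous_pairs is not None:
            self.homologous_pairs = [(str(a), str(b)) for a, b in self.homologous_pairs]
            flat = [lab for pair in self.homologous_pairs for lab in pair]
            if len(set(flat)) != len(flat):
                raise ValueError("homologous pairs must be disjoint")
            for lab in flat:
                self.subjects[0].index_of(lab)

    @property
    def region_ids(self) -> list[str]:
        return self.subjects[0].region_ids

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def standardized_subjects(self) -> list[RegionTimeSeries]:
        """Per-subject z-scored copies (standardization is per subject)."""
        return [ts.standardize() for ts in self.subjects]


@dataclass
class ConnectivityMap:
    """Per-target group statistics for a fixed seed set.

    targets are region labels (third-order/correlation maps) or label
    pairs (fourth-order maps).  subject_values has one row per subject
    and one column per target; group_mean is its column mean.  p, se and
    mask are filled by :func:`group_threshold`.
    """

    seed: tuple
    targets: list
    measure: str
    group_mean: np.ndarray
    subject_values: np.ndarray = field(repr=False)
    se: np.ndarray | None = None
    p: np.ndarray | None = None
    mask: np.ndarray | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.group_mean = np.asarray(self.group_mean, dtype=float)
        self.subject_values = np.asarray(self.subject_values, dtype=float)
        if self.subject_values.shape[1] != len(self.targets):
            raise ValueError("subject_values must have one column per target")
        if self.p is not None and (np.any(self.p < 0) or np.any(self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def _subject_map(ens: SubjectEnsemble, targets: list, per_subject) -> np.ndarray:
    subs = ens.standardized_subjects()
    return np.array([[per_subject(ts, tgt) for tgt in targets] for ts in subs])


def coskewness_map(ens: SubjectEnsemble, seed_pair: tuple[str, str]) -> ConnectivityMap:
    """Coskewness of the two fixed seeds with every other target region."""
    s1, s2 = (str(s) for s in seed_pair)
    ens.subjects[0].index_of(s1), ens.subjects[0].index_of(s2)
    targets = [r for r in ens.region_ids if r not in (s1, s2)]
    values = _subject_map(
        ens, targets, lambda ts, tgt: estimators.coskewness(ts, s1, s2, tgt).value
    )
    return ConnectivityMap((s1, s2), targets, "coskewness", values.mean(axis=0), values)


def fourth_order_map(
    ens: SubjectEnsemble, seed_pair: tuple[str, str], measure: str = "cokurtosis"
) -> ConnectivityMap:
    """Fourth-order measure of the seed pair with every homologous target pair.

    For the edge measures the two edges are (seed1, seed2) and (t1, t2).
    Target pairs overlapping the seeds are excluded.
    """
    if measure not in ("cokurtosis", "edge_corrected", "edge_raw"):
        raise ValueError("measure must be cokurtosis, edge_corrected or edge_raw")
    if ens.homologous_pairs is None:
        raise ValueError("fourth-order maps need homologous_pairs")
    s1, s2 = (str(s) for s in seed_pair)
    targets = [p for p in ens.homologous_pairs if s1 not in p and s2 not in p]

    if measure == "cokurtosis":
        fn = lambda ts, tgt: estimators.cokurtosis(ts, s1, s2, tgt[0], tgt[1]).value
    elif measure == "edge_corrected":
        fn = lambda ts, tgt: estimators.edge_connectivity_corrected(ts, (s1, s2), tgt).value
    else:
        fn = lambda ts, tgt: estimators.edge_connectivity_raw(ts, (s1, s2), tgt).value
    values = _subject_map(ens, targets, fn)
    return ConnectivityMap((s1, s2), targets, measure, values.mean(axis=0), values)


def correlation_map(ens: SubjectEnsemble, seed_pair: tuple[str, str]) -> ConnectivityMap:
    """Mean over the two seeds of each target's correlation, group-averaged."""
    s1, s2 = (str(s) for s in seed_pair)
    targets = [r for r in ens.region_ids if r not in (s1, s2)]
    values = _subject_map(
        ens,
        targets,
        lambda ts, tgt: 0.5
        * (
            estimators.correlation2(ts, s1, tgt).value
            + estimators.correlation2(ts, s2, tgt).value
        ),
    )
    return ConnectivityMap((s1, s2), targets, "correlation", values.mean(axis=0), values)


def group_threshold(
    cmap: ConnectivityMap,
    alpha: float = 0.01,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    n_tests: int | None = None,
) -> ConnectivityMap:
    """Bootstrap subjects and Bonferroni-threshold the group map.

    Subjects are resampled independently with replacement ``n_boot``
    times; the SD of the resampled group means gives the SE, the p-value
    is the two-sided normal tail of group_mean / SE, and a target is
    significant when p * n_tests < alpha (n_tests defaults to the number
    of targets in the map).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    S = cmap.subject_values.shape[0]
    if S < 2:
        raise ValueError("group thresholding needs at least two subjects")
    idx = rng.integers(0, S, size=(n_boot, S))
    boot_means = cmap.subject_values[idx].mean(axis=1)  # (n_boot, n_targets)
    se = boot_means.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(cmap.group_mean) / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.norm.sf(z)
    p[(se == 0) & (cmap.group_mean == 0)] = 1.0
    n_tests = len(cmap.targets) if n_tests is None else int(n_tests)
    mask = p * n_tests < alpha
    return replace(cmap, se=se, p=p, mask=mask, alpha=alpha)


def _distinct_tuple(rng: np.random.Generator, n: int, k: int) -> tuple:
    return tuple(rng.choice(n, size=k, replace=False))


def random_ktuple_distribution(
    ens: SubjectEnsemble,
    k: int,
    n_tuples: int = 10_000,
    measure: str | None = None,
    rng: np.random.Generator | None = None,
    n_selections: int = 2,
) -> pd.DataFrame:
    """Group-averaged measure over random distinct k-tuples of regions.

    For k = 2 the measure is the correlation, for k = 3 the coskewness,
    and for k = 4 ``measure`` chooses cokurtosis (default) or an edge
    measure (the 4 indices are split into the edges (1,2) and (3,4)).
    ``n_selections`` independent tuple selections are drawn so the
    stability of the estimated distribution can be checked.  Returns one
    row per (selection, tuple) with the across-subject mean value.
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    if measure is None:
        measure = {2: "correlation", 3: "coskewness", 4: "cokurtosis"}[k]
    order, _ = estimators.MEASURES[measure]
    if order != k:
        raise ValueError(f"measure {measure!r} is order {order}, not {k}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    subs = ens.standardized_subjects()
    ids = ens.region_ids
    if len(ids) < k:
        raise ValueError("ensemble has fewer regions than the tuple size")
    rows = []
    for sel in range(n_selections):
        for _ in range(n_tuples):
            tup = _distinct_tuple(rng, len(ids), k)
            labels = tuple(ids[i] for i in tup)
            vals = [estimators.estimate(ts, measure, labels).value for ts in subs]
            rows.append(
                {"selection": sel, "indices": ",".join(labels),
                 "measure": measure, "value": float(np.mean(vals))}
            )
    return pd.DataFrame(rows)


def interpret_sign(
    x: RegionTimeSeries, indices: tuple[str, str, str], tol: float = 0.0
) -> str:
    """Qualitative reading of a third-order interaction's sign pattern.

    With all pairwise correlations non-negative, a negative coskewness
    means the three regions jointly undergo extreme *deactivations* and a
    positive one extreme *activations*.  Mixed correlation signs mean two
    regions go to one extreme while the third goes to the other.
    """
    i, j, k = indices
    csk = estimators.coskewness(x, i, j, k).value
    if abs(csk) <= tol:
        return "none"
    corrs = [
        estimators.correlation2(x, a, b).value for a, b in ((i, j), (i, k), (j, k))
    ]
    if all(c >= 0.0 for c in corrs):
        return (
            "coherent extreme activations" if csk > 0 else "coherent extreme deactivations"
        )
    return "two-vs-one extreme events"


def map_to_frame(cmap: ConnectivityMap) -> pd.DataFrame:
    """Tabular form of a map: target, group_mean, se, p, significant."""
    tgt = [t if isinstance(t, str) else ",".join(t) for t in cmap.targets]
    n = len(tgt)
    return pd.DataFrame(
        {
            "target": tgt,
            "measure": cmap.measure,
            "group_mean": cmap.group_mean,
            "se": cmap.se if cmap.se is not None else [np.nan] * n,
            "p": cmap.p if cmap.p is not None else [np.nan] * n,
            "significant": cmap.mask if cmap.mask is not None else [False] * n,
        }
    )
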