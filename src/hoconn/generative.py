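"""Non-Gaussian vector-autoregressive generative model with known ground truth.

The model couples n regions (n = 3 for third-order, n = 4 for fourth-order
studies) through a shared non-Gaussian innovation:

    X_i(t+1) = phi * X_i(t) + Z_i(t) + psi * U(t)

where Z(t) is an equicorrelated Gaussian vector (unit variances, pairwise
correlation rho) and the SAME zero-mean unit-variance non-Gaussian draw
U(t) is added to every region.  phi = exp(-1/tau) sets the autocorrelation
time-scale tau in samples (lag-k autocorrelation exp(-k/tau)); psi in
[0, 1] scales the shared non-Gaussian drive, which is the sole source of
higher-order connectivity.

Because cumulants are additive over independent summands and the
stationary solution is X(t) = sum_s phi^s E(t-1-s) with i.i.d. innovations
E = Z + psi U, every joint cumulant of X follows in closed form from the
cumulants of U.  These closed forms are the ground truths against which
the plug-in estimators are validated:

* pairwise correlation      (rho + psi^2) / (1 + psi^2)
* coskewness                (1-phi^2)^{3/2} psi^3 / ((1-phi^3)(1+psi^2)^{3/2}) * c3U
* cokurtosis                (1-phi^2)^2 psi^4 / ((1-phi^4)(1+psi^2)^2) * c4U
* raw edge connectivity     (K + 3 r^2) / (K + 1 + 2 r^2), K the cokurtosis
  (the normalized repeated-index cumulant c_iijj equals K in this model);
  its redundant part sets c4U = 0, i.e. 3 r^2 / (1 + 2 r^2).

Coskewness and cokurtosis are independent of rho; the edge connectivity is
not.  Skew-normal innovations (shape alpha) supply third-order structure,
unit-variance Student-t innovations (nu >= 5) supply fourth-order
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import lfilter

from .timeseries import RegionTimeSeries

__all__ = [
    "SkewNormalSpec",
    "StudentTSpec",
    "ARParams",
    "GroundTruth",
    "phi_from_tau",
    "rho_from_r",
    "sufficient_r_bound",
    "validate",
    "c3U",
    "c4U",
    "sample_U_skewnormal",
    "sample_U_t",
    "simulate",
    "true_correlation",
    "true_coskewness",
    "true_cokurtosis",
    "true_edge_connectivity",
    "ground_truth",
]


def phi_from_tau(tau: float) -> float:
    """AR coefficient for autocorrelation time-scale ``tau`` samples.

    The lag-k autocorrelation of the process is phi^k = exp(-k/tau).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return math.exp(-1.0 / tau)


def rho_from_r(r: float, psi: float) -> float:
    """Innovation correlation giving target pairwise signal correlation r."""
    return r + (r - 1.0) * psi**2


def sufficient_r_bound(n: int) -> float:
    """Smallest r valid for every psi in [0, 1]: r > 1/2 - 1/(2(n-1))."""
    return 0.5 - 0.5 / (n - 1)


@dataclass
class SkewNormalSpec:
    """Skew-normal innovation law, normalized to mean 0 and variance 1.

    alpha controls the skew (alpha = 0 is Gaussian; alpha > 0 right-skew,
    i.e. coherent extreme activations; negative alpha allowed for left
    skew).  delta = alpha / sqrt(1 + alpha^2) in (-1, 1).
    """

    alpha: float

    @property
    def delta(self) -> float:
        return self.alpha / math.sqrt(1.0 + self.alpha**2)

    @property
    def c3(self) -> float:
        return c3U(self)

    @property
    def c4(self) -> float:
        # excess kurtosis of the standardized skew-normal
        b2 = 2.0 * self.delta**2 / math.pi
        return 2.0 * (math.pi - 3.0) * b2**2 / (1.0 - b2) ** 2

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return sample_U_skewnormal(self, size, rng)


@dataclass
class StudentTSpec:
    """Unit-variance Student-t innovation law; nu >= 5 so c4 is finite."""

    nu: int

    def __post_init__(self) -> None:
        if int(self.nu) != self.nu or self.nu < 5:
            raise ValueError("nu must be an integer >= 5")
        self.nu = int(self.nu)

    @property
    def c3(self) -> float:
        return 0.0  # symmetric law

    @property
    def c4(self) -> float:
        return c4U(self)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return sample_U_t(self, size, rng)


InnovationSpec = Union[SkewNormalSpec, StudentTSpec]


def c3U(spec: SkewNormalSpec) -> float:
    """Third cumulant of the standardized skew-normal innovation.

    ((4-pi)/2) * (delta*sqrt(2/pi))^3 / (1 - 2 delta^2/pi)^{3/2}; rises from
    0 at delta = 0 to just under 1 as |delta| -> 1, with the sign of delta.
    """
    d = spec.delta
    b2 = 2.0 * d * d / math.pi
    return (4.0 - math.pi) / 2.0 * math.copysign(b2**1.5, d) / (1.0 - b2) ** 1.5


def c4U(spec: StudentTSpec) -> float:
    """Fourth cumulant (excess kurtosis) of the unit-variance t law: 6/(nu-4)."""
    return 6.0 / (spec.nu - 4.0)


def sample_U_skewnormal(spec: SkewNormalSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draws via the half-normal stochastic representation.

    U = sigma_U (delta |Z1| + sqrt(1-delta^2) Z2) - sigma_U delta sqrt(2/pi),
    sigma_U = sqrt(pi/(pi - 2 delta^2)), Z1, Z2 independent standard normal;
    this yields exactly mean 0 and variance 1 for every delta.
    """
    d = spec.delta
    sigma_u = math.sqrt(math.pi / (math.pi - 2.0 * d * d))
    z1 = rng.standard_normal(size)
    z2 = rng.standard_normal(size)
    return sigma_u * (d * np.abs(z1) + math.sqrt(1.0 - d * d) * z2) - sigma_u * d * math.sqrt(
        2.0 / math.pi
    )


def sample_U_t(spec: StudentTSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance t draws: sqrt((nu-2)/nu) * t_nu."""
    return math.sqrt((spec.nu - 2.0) / spec.nu) * rng.standard_t(spec.nu, size)


@dataclass
class ARParams:
    """Full parameterization of the generative model.

    Give either ``tau`` (autocorrelation time-scale, samples) or ``phi``
    (AR coefficient), and either ``r`` (target pairwise signal
    correlation) or ``rho`` (innovation correlation); the counterpart is
    derived.  ``psi`` in [0, 1] scales the shared non-Gaussian innovation.
    """

    n: int
    psi: float
    innovation: InnovationSpec
    tau: float | None = None
    phi: float | None = None
    r: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 regions")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if (self.tau is None) == (self.phi is None):
            raise ValueError("give exactly one of tau or phi")
        if self.tau is not None:
            self.phi = phi_from_tau(self.tau)
        else:
            if not 0.0 <= self.phi < 1.0:
                raise ValueError("phi must lie in [0, 1)")
            self.tau = 0.0 if self.phi == 0.0 else -1.0 / math.log(self.phi)
        if (self.r is None) == (self.rho is None):
            raise ValueError("give exactly one of r or rho")
        if self.r is not None:
            self.rho = rho_from_r(self.r, self.psi)
        else:
            self.r = (self.rho + self.psi**2) / (1.0 + self.psi**2)

    def as_dict(self) -> dict:
        inn = {"law": type(self.innovation).__name__}
        inn.update(vars(self.innovation))
        return {
            "n": self.n,
            "tau": self.tau,
            "phi": self.phi,
            "psi": self.psi,
            "r": self.r,
            "rho": self.rho,
            "innovation": inn,
        }


def validate(params: ARParams) -> None:
    """Check positive-definiteness of the innovation covariance.

    Requires rho > -1/(n-1) (smallest eigenvalue 1 + (n-1) rho of the
    equicorrelation matrix must be positive).  The error message also
    reports the conservative bound r > 1/2 - 1/(2(n-1)) that is
    sufficient for every psi in [0, 1].
    """
    bound = -1.0 / (params.n - 1)
    if not params.rho > bound:
        raise ValueError(
            f"innovation correlation rho={params.rho:.4g} must exceed {bound:.4g} "
            f"for n={params.n}; sufficient for all psi in [0,1]: "
            f"r > {sufficient_r_bound(params.n):.4g} (got r={params.r:.4g})"
        )


def _equicorrelated_sqrt(n: int, rho: float) -> np.ndarray:
    # symmetric square root of (1-rho) I + rho J
    a = math.sqrt(1.0 - rho)
    b = math.sqrt(1.0 + (n - 1) * rho)
    eye = np.eye(n)
    ones = np.ones((n, n)) / n
    return a * (eye - ones) + b * ones


def simulate(
    params: ARParams,
    T: int,
    seed: int | np.random.Generator | None = None,
    burn_in: int | None = None,
) -> RegionTimeSeries:
    """Sample T post-burn-in time points of the model.

    The process starts at X(0) = 0 and the first ``burn_in`` samples
    (default ceil(20 tau)) are discarded to reach stationarity.  The seed
    is recorded in the output metadata.
    """
    validate(params)
    if burn_in is None:
        burn_in = int(math.ceil(20.0 * min(params.tau, 1e6)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = T + burn_in
    S = _equicorrelated_sqrt(params.n, params.rho)
    Z = S @ rng.standard_normal((params.n, total))
    U = params.innovation.sample(total, rng)
    E = Z + params.psi * U
    # AR(1) recursion X(t) = phi X(t-1) + E(t) from X(0)=0
    X = lfilter([1.0], [1.0, -params.phi], E, axis=1)
    data = X[:, burn_in:]
    ids = [f"R{i+1}" for i in range(params.n)]
    meta = {
        "params": params.as_dict(),
        "seed": None if isinstance(seed, np.random.Generator) else seed,
        "burn_in": burn_in,
        "T": T,
    }
    return RegionTimeSeries(data, ids, standardized=False, meta=meta)


def true_correlation(params: ARParams) -> float:
    """Pairwise signal correlation (rho + psi^2)/(1 + psi^2) = r."""
    return (params.rho + params.psi**2) / (1.0 + params.psi**2)


def true_coskewness(params: ARParams) -> float:
    """Closed-form coskewness of any distinct triple; independent of rho."""
    phi, psi = params.phi, params.psi
    return (
        (1.0 - phi**2) ** 1.5
        * psi**3
        / ((1.0 - phi**3) * (1.0 + psi**2) ** 1.5)
        * params.innovation.c3
    )


def true_cokurtosis(params: ARParams) -> float:
    """Closed-form cokurtosis of any distinct quadruple; independent of rho."""
    phi, psi = params.phi, params.psi
    return (
        (1.0 - phi**2) ** 2
        * psi**4
        / ((1.0 - phi**4) * (1.0 + psi**2) ** 2)
        * params.innovation.c4
    )


def true_edge_connectivity(params: ARParams) -> tuple[float, float, float]:
    """(raw, redundant, corrected) edge connectivity between disjoint edges.

    raw = (K + 3 r^2)/(K + 1 + 2 r^2) with K the cokurtosis; the redundant
    part sets the fourth cumulant to zero.  Depends on rho through r.
    """
    K = true_cokurtosis(params)
    r = true_correlation(params)
    raw = (K + 3.0 * r**2) / (K + 1.0 + 2.0 * r**2)
    red = 3.0 * r**2 / (1.0 + 2.0 * r**2)
    return raw, red, raw - red


@dataclass
class GroundTruth:
    """Closed-form connectivity values for one parameter setting.

    Fourth-order entries are None when the model has fewer than four
    regions; coskewness is None below three regions.
    """

    pair_correlation: float
    coskewness: float | None = None
    cokurtosis: float | None = None
    edge_raw: float | None = None
    edge_redundant: float | None = None
    edge_corrected: float | None = None

    def as_dict(self) -> dict:
        return dict(vars(self))


def ground_truth(params: ARParams) -> GroundTruth:
    gt = GroundTruth(pair_correlation=true_correlation(params))
    if params.n >= 3:
        gt.coskewness = true_coskewness(params)
    if params.n >= 4:
        gt.cokurtosis = true_cokurtosis(params)
        gt.edge_raw, gt.edge_redundant, gt.edge_corrected = true_edge_connectivity(params)
    return gt
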